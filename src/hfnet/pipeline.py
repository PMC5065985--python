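"""End-to-end orchestration of the HFN analysis stages.

Each stage consumes the previous stage's serialized outputs, so a run is
re-entrant: ``simulate`` writes a recording, ``coupling`` a long-format
window/pair index table, ``hfn`` per-window adjacencies, ``metrics`` the
nodes x windows dynamics matrices, ``ntd`` similarity matrices, partitions
and summary JSON, ``classify`` the CA table.  ``run_pipeline`` chains them
and writes a manifest with the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .classify import FNNConfig, run_stimulus_ntd
from .coupling import sliding_window_coupling
from .graph_metrics import METRIC_NAMES, small_world_coefficients
from .hfn import (
    DEFAULT_THRESHOLD,
    hfn_sequence,
    node_pairs,
    surrogate_critical_value,
)
from .ntd import (
    MetricDynamicsMatrix,
    louvain_signed_partition,
    metric_dynamics,
    modularity_partition,
    similarity,
    state_statistics,
    summarize_dynamics,
)
from .synthetic import (
    OscillatorSpec,
    SegmentedRecording,
    default_channel_labels,
    gen_coupled_oscillators,
    gen_stimulus_schedule,
)
from .wavelet import DEFAULT_FOIS, recording_phases

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the canonical analysis values."""

    output_dir: str = "hfnet_out"
    input_recording: Optional[str] = None
    # simulation (used when no input recording is given)
    n_channels: int = 8
    fs: float = 250.0
    duration: float = 10.0
    sim_frequency: float = 10.0
    sim_snr: float = 20.0
    # analysis
    fois: Sequence[float] = field(default_factory=lambda: list(DEFAULT_FOIS))
    n_cycles: float = 5.0
    time_step: int = 5
    window_ms: float = 2000.0
    step_ms: float = 100.0
    clean_period: str = "max"
    threshold: float = DEFAULT_THRESHOLD
    surrogate_method: Optional[str] = None  # e.g. "phase-shuffle" to enable
    n_boot: int = 1000
    alpha: float = 1e-4
    n_reference: int = 10
    metrics: Sequence[str] = field(default_factory=lambda: list(METRIC_NAMES))
    # classification
    fnn: FNNConfig = field(default_factory=FNNConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _seed_for(cfg_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{cfg_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_stage(cfg: PipelineConfig, out: Path) -> Path:
    """Write a synthetic recording: noisy coupled oscillator pairs."""
    rng = np.random.default_rng(_seed_for(cfg.seed, "simulate"))
    labels = default_channel_labels(cfg.n_channels)
    specs = []
    f = cfg.sim_frequency
    for a, b in zip(labels[0::2], labels[1::2]):
        specs.append(OscillatorSpec(channel=a, frequency=f, snr=cfg.sim_snr))
        specs.append(
            OscillatorSpec(
                channel=b,
                frequency=f,
                snr=cfg.sim_snr,
                coupled_to=(a, f, 1, 1, np.pi / 8.0),
            )
        )
    schedule = gen_stimulus_schedule(
        n_events=6, seed=int(rng.integers(2**31)), first_onset=0.0
    )
    rec = gen_coupled_oscillators(
        specs,
        fs=cfg.fs,
        duration=cfg.duration,
        seed=int(rng.integers(2**31)),
        labels=labels,
        schedule=schedule,
    )
    return hio.write_recording(rec, out / "recording.tsv")


def coupling_stage(cfg: PipelineConfig, out: Path) -> Path:
    rec = hio.read_recording(out / "recording.tsv")
    fois = [f for f in cfg.fois if f < rec.fs / 2]
    phases = recording_phases(
        rec, freqs=fois, n_cycles=cfg.n_cycles, time_step=cfg.time_step
    )
    pairs = node_pairs(rec.labels, fois)
    cwt = sliding_window_coupling(
        phases,
        pairs,
        window_ms=cfg.window_ms,
        step_ms=cfg.step_ms,
        clean_period=cfg.clean_period,
    )
    path = out / "coupling.tsv"
    cwt.to_dataframe().to_csv(path, sep="\t", index=False)
    if cfg.surrogate_method:
        null = surrogate_critical_value(
            rec,
            method=cfg.surrogate_method,
            n_boot=cfg.n_boot,
            alpha=cfg.alpha,
            seed=_seed_for(cfg.seed, "surrogate"),
            fois=fois,
            window_ms=cfg.window_ms,
            step_ms=cfg.step_ms,
        )
        (out / "surrogate_null.json").write_text(
            json.dumps(
                {
                    "method": null.method,
                    "alpha": null.alpha,
                    "n_boot": null.n_boot,
                    "critical_value": null.critical_value,
                    "threshold": cfg.threshold,
                },
                indent=2,
            )
        )
    return path


def _coupling_tensor_from_table(df: pd.DataFrame):
    """Rebuild the window x pair index arrays from the long-format table."""
    from .coupling import CouplingWindowTensor

    key = ["src_channel", "src_freq", "dst_channel", "dst_freq"]
    pairs = df.loc[df.window_index == 0, key].itertuples(index=False, name=None)
    pairs = [tuple(p) for p in pairs]
    n_w = int(df.window_index.max()) + 1
    n_p = len(pairs)
    indices = {}
    for name in ("psi", "pci", "nci", "aci", "ici"):
        indices[name] = df[name].to_numpy().reshape(n_w, n_p).T
    valid = df["valid"].to_numpy().reshape(n_w, n_p).T
    return CouplingWindowTensor(
        indices=indices,
        pairs=pairs,
        ratios=[],
        window_starts=np.arange(n_w),
        window_samples=0,
        step_samples=0,
        fs_phase=0.0,
        valid=valid,
    )


def hfn_stage(cfg: PipelineConfig, out: Path) -> Path:
    df = pd.read_csv(out / "coupling.tsv", sep="\t")
    rec_meta = json.loads((out / "recording.tsv.json").read_text())
    cwt = _coupling_tensor_from_table(df)
    fois = sorted({p[1] for p in cwt.pairs} | {p[3] for p in cwt.pairs})
    graphs = hfn_sequence(
        cwt, labels=rec_meta["labels"], fois=fois, threshold=cfg.threshold
    )
    adj_dir = out / "hfn"
    adj_dir.mkdir(exist_ok=True)
    for w, g in enumerate(graphs):
        hio.write_adjacency(g, adj_dir / f"window_{w:03d}.tsv")
    hio.write_node_table(graphs[0], out / "nodes.tsv")
    hio.write_graphml(graphs[0], out / "hfn_window_000.graphml")
    costs = pd.DataFrame(
        {"window_index": range(len(graphs)), "cost": [g.cost for g in graphs]}
    )
    costs.to_csv(out / "costs.tsv", sep="\t", index=False)
    return adj_dir


def metrics_stage(cfg: PipelineConfig, out: Path) -> Path:
    from .hfn import HFNGraph, node_table

    nodes_df = pd.read_csv(out / "nodes.tsv", sep="\t")
    labels = list(dict.fromkeys(nodes_df["electrode"]))
    fois = sorted(set(nodes_df["foi_hz"]))
    nodes = node_table(labels, fois)
    adj_dir = out / "hfn"
    graphs = [
        HFNGraph(adjacency=hio.read_adjacency(p), nodes=nodes)
        for p in sorted(adj_dir.glob("window_*.tsv"))
    ]
    mdir = out / "metrics"
    mdir.mkdir(exist_ok=True)
    summaries = {}
    for name in cfg.metrics:
        m = metric_dynamics(graphs, name)
        np.savetxt(mdir / f"{name}.tsv", m.values, delimiter="\t")
        summaries[name] = summarize_dynamics(m)
    (out / "metric_summaries.json").write_text(json.dumps(summaries, indent=2))
    sw = small_world_coefficients(
        graphs[0],
        n_realizations=cfg.n_reference,
        seed=_seed_for(cfg.seed, "references"),
    )
    (out / "small_world.json").write_text(
        json.dumps(
            {
                k: getattr(sw, k)
                for k in (
                    "gamma",
                    "lam",
                    "sigma",
                    "omega",
                    "gamma_e",
                    "lambda_e",
                    "sigma_e",
                    "omega_e",
                )
            },
            indent=2,
        )
    )
    return mdir


def _load_metric_matrices(cfg: PipelineConfig, out: Path) -> dict[str, MetricDynamicsMatrix]:
    from .hfn import node_table

    nodes_df = pd.read_csv(out / "nodes.tsv", sep="\t")
    labels = list(dict.fromkeys(nodes_df["electrode"]))
    fois = sorted(set(nodes_df["foi_hz"]))
    nodes = node_table(labels, fois)
    out_d = {}
    for name in cfg.metrics:
        values = np.loadtxt(out / "metrics" / f"{name}.tsv", delimiter="\t", ndmin=2)
        out_d[name] = MetricDynamicsMatrix(values=values, metric=name, node_index=nodes)
    return out_d


def ntd_stage(cfg: PipelineConfig, out: Path) -> Path:
    matrices = _load_metric_matrices(cfg, out)
    ndir = out / "ntd"
    ndir.mkdir(exist_ok=True)
    summary = {}
    seed = _seed_for(cfg.seed, "ntd")
    for name, m in matrices.items():
        entry = {}
        for axis, partition in (
            ("temporal", modularity_partition),
            ("nodal", louvain_signed_partition),
        ):
            sim = similarity(m, axis)
            np.savetxt(ndir / f"{name}_{axis}_similarity.tsv", sim.values, delimiter="\t")
            part = partition(sim, seed=seed)
            pd.DataFrame(
                {"element": range(part.assignment.size), "module": part.assignment}
            ).to_csv(ndir / f"{name}_{axis}_partition.tsv", sep="\t", index=False)
            stats = state_statistics(part, axis)
            entry[axis] = {
                "q": part.q,
                "q_signed": part.q_signed,
                "n_modules": stats.n_modules,
                "min_size": stats.min_size,
                "max_size": stats.max_size,
                "min_run": stats.min_run,
                "max_run": stats.max_run,
            }
        summary[name] = entry
    (out / "ntd_summary.json").write_text(json.dumps(summary, indent=2))
    return ndir


def classify_stage(cfg: PipelineConfig, out: Path) -> Optional[Path]:
    rec = hio.read_recording(out / "recording.tsv")
    if rec.schedule is None:
        logger.warning("no stimulus schedule; classification stage skipped")
        return None
    matrices = _load_metric_matrices(cfg, out)
    fnn = dataclasses.replace(cfg.fnn, seed=_seed_for(cfg.seed, "classify"))
    table = run_stimulus_ntd(matrices, rec.schedule, fnn, step_ms=cfg.step_ms)
    path = out / "classification.tsv"
    table.to_csv(path, sep="\t", index=False)
    return path


STAGES = {
    "simulate": simulate_stage,
    "coupling": coupling_stage,
    "hfn": hfn_stage,
    "metrics": metrics_stage,
    "ntd": ntd_stage,
    "classify": classify_stage,
}


def run_pipeline(cfg: PipelineConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Run the requested stages (default: all) and write a manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
        if cfg.input_recording:
            stages.remove("simulate")
    if cfg.input_recording:
        src = Path(cfg.input_recording)
        if not src.exists():
            raise FileNotFoundError(f"input recording not found: {src}")
        if src.suffix.lower() == ".edf":
            rec = hio.read_edf(src)
        else:
            rec = hio.read_recording(src)
        hio.write_recording(rec, out / "recording.tsv")
    for name in stages:
        logger.info("stage: %s", name)
        STAGES[name](cfg, out)
    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": list(stages),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
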