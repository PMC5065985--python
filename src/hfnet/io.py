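"""Readers and writers for the toolkit's plain-text interchange formats.

Recordings travel as delimited text (one column per channel, header row of
labels) plus a JSON sidecar holding the sampling rate; stimulus schedules as
two-column delimited text (onset_s, class); graphs as dense matrices,
edge lists, node tables, or GraphML (via networkx).  EDF recordings can be
read when the optional ``mne`` dependency is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .hfn import HFNGraph
from .synthetic import SegmentedRecording, StimulusSchedule

__all__ = [
    "write_recording",
    "read_recording",
    "write_schedule",
    "read_schedule",
    "write_adjacency",
    "read_adjacency",
    "write_edge_list",
    "write_node_table",
    "write_graphml",
    "read_edf",
]

_SEP = "\t"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: SegmentedRecording, path: Union[str, Path]) -> Path:
    """Samples x channels delimited matrix + JSON sidecar with fs/labels."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(path, sep=_SEP, index=False)
    meta = {"fs": rec.fs, "labels": list(rec.labels), "n_samples": rec.n_samples}
    if rec.schedule is not None:
        sched_path = path.with_name(path.stem + ".events" + path.suffix)
        write_schedule(rec.schedule, sched_path)
        meta["schedule"] = sched_path.name
        meta["isi_bounds"] = list(rec.schedule.isi_bounds)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: Union[str, Path]) -> SegmentedRecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, sep=_SEP)
    schedule = None
    if meta.get("schedule"):
        schedule = read_schedule(
            path.with_name(meta["schedule"]),
            isi_bounds=tuple(meta.get("isi_bounds", (0.0, np.inf))),
        )
    return SegmentedRecording(
        data=df.to_numpy().T,
        fs=float(meta["fs"]),
        labels=list(df.columns),
        schedule=schedule,
    )


def write_schedule(schedule: StimulusSchedule, path: Union[str, Path]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"onset_s": schedule.onsets, "class": schedule.classes}
    ).to_csv(path, sep=_SEP, index=False)
    return path


def read_schedule(
    path: Union[str, Path], isi_bounds: tuple[float, float] = (0.0, np.inf)
) -> StimulusSchedule:
    df = pd.read_csv(path, sep=_SEP)
    return StimulusSchedule(
        onsets=df["onset_s"].to_numpy(float),
        classes=df["class"].to_numpy(),
        isi_bounds=isi_bounds,
    )


def write_adjacency(g: Union[HFNGraph, np.ndarray], path: Union[str, Path]) -> Path:
    adj = getattr(g, "adjacency", g)
    path = Path(path)
    np.savetxt(path, adj, delimiter=_SEP)
    return path


def read_adjacency(path: Union[str, Path]) -> np.ndarray:
    return np.loadtxt(path, delimiter=_SEP, ndmin=2)


def write_edge_list(g: HFNGraph, path: Union[str, Path]) -> Path:
    src, dst = np.nonzero(g.adjacency)
    pd.DataFrame(
        {"src": src, "dst": dst, "weight": g.adjacency[src, dst]}
    ).to_csv(Path(path), sep=_SEP, index=False)
    return Path(path)


def write_node_table(g: HFNGraph, path: Union[str, Path]) -> Path:
    pd.DataFrame(
        {
            "index": [n.index for n in g.nodes],
            "electrode": [n.electrode for n in g.nodes],
            "foi_hz": [n.foi for n in g.nodes],
        }
    ).to_csv(Path(path), sep=_SEP, index=False)
    return Path(path)


def write_graphml(g: HFNGraph, path: Union[str, Path]) -> Path:
    """GraphML export for interoperability with other graph tools."""
    import networkx as nx

    dg = nx.DiGraph()
    for n in g.nodes:
        dg.add_node(n.index, electrode=n.electrode, foi_hz=n.foi)
    for i, j in zip(*np.nonzero(g.adjacency)):
        dg.add_edge(int(i), int(j), weight=float(g.adjacency[i, j]))
    nx.write_graphml(dg, Path(path))
    return Path(path)


def read_edf(path: Union[str, Path]) -> SegmentedRecording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return SegmentedRecording(
        data=raw.get_data(), fs=float(raw.info["sfreq"]), labels=list(raw.ch_names)
    )
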