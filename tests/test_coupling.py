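import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import clean_bf, window_counts_bf
from hfnet.coupling import (
    PhaseDiffSeries,
    clean_code,
    coupling_indices,
    generalized_phase_difference,
    psi,
    ratio_for,
    sliding_window_coupling,
    ternary_code,
)
from hfnet.synthetic import OscillatorSpec, gen_coupled_oscillators
from hfnet.wavelet import PhaseTensor, recording_phases, wrap_phase


def phase_tensor(arrays, freqs=(10.0,), fs_phase=50.0):
    """PhaseTensor from raw per-channel phase series (single frequency row)."""
    if len(freqs) > 1:
        raise ValueError("helper supports one frequency row")
    phase = np.asarray([np.atleast_2d(a) for a in arrays], dtype=float)  # (C, 1, T)
    return PhaseTensor(
        phase=phase,
        freqs=np.asarray(freqs, float),
        fs_phase=fs_phase,
        valid=np.ones((1, phase.shape[2]), dtype=bool),
        labels=[f"c{i}" for i in range(len(arrays))],
    )


class TestGeneralizedPhaseDifference:
    def test_identical_series_cancel(self):
        x = np.linspace(-np.pi + 0.01, np.pi, 100)
        pt = phase_tensor([x, x])
        d = generalized_phase_difference(pt, ("c0", 10.0, "c1", 10.0))
        assert np.allclose(d.values, 0.0)
        assert d.ratio == (1, 1)

    def test_two_to_one_ratio_cancels_harmonics(self):
        t = np.linspace(0, 1, 200)
        pt2 = wrap_phase(2 * np.pi * 2 * t)
        pt4 = wrap_phase(2 * np.pi * 4 * t)
        phase = np.zeros((2, 2, 200))
        phase[0, 0] = pt2
        phase[1, 1] = pt4
        pt = PhaseTensor(
            phase=phase,
            freqs=np.array([2.0, 4.0]),
            fs_phase=50.0,
            valid=np.ones((2, 200), bool),
            labels=["a", "b"],
        )
        d = generalized_phase_difference(pt, ("a", 2.0, "b", 4.0))
        assert d.ratio == (2, 1)
        assert np.allclose(d.values, 0.0, atol=1e-12)

    def test_constant_offset_appears_negated(self):
        pt = phase_tensor([np.zeros(50), np.full(50, np.pi / 8)])
        d = generalized_phase_difference(pt, ("c0", 10.0, "c1", 10.0))
        assert np.allclose(d.values, -np.pi / 8)

    def test_inconsistent_ratio_rejected(self):
        pt = phase_tensor([np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="ratio"):
            generalized_phase_difference(pt, ("c0", 10.0, "c1", 10.0), ratio=(2, 1))

    @pytest.mark.parametrize(
        "fm,fn,expected", [(2.0, 4.0, (2, 1)), (6.0, 8.0, (4, 3)), (10.0, 10.0, (1, 1))]
    )
    def test_ratio_derivation(self, fm, fn, expected):
        assert ratio_for(fm, fn) == expected


class TestPSI:
    def test_antiphase_locking_scores_one(self):
        assert psi(np.full(100, np.pi)) == pytest.approx(1.0)

    def test_uniform_phasor_fan_scores_zero(self):
        k = np.arange(100)
        assert psi(wrap_phase(2 * np.pi * k / 100)) == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_expectation(self):
        # E[PSI] for K iid uniform phases ~ sqrt(pi)/2 / sqrt(K); K=100 ->
        # 0.0886, Monte-Carlo with 10^4 replicates, tolerance 0.005
        rng = np.random.default_rng(0)
        vals = np.abs(
            np.mean(np.exp(1j * rng.uniform(-np.pi, np.pi, (10_000, 100))), axis=1)
        )
        assert abs(vals.mean() - np.sqrt(np.pi) / 2 / 10.0) < 0.005
        # and the package function agrees with the direct formula
        sample = rng.uniform(-np.pi, np.pi, 100)
        assert psi(sample) == pytest.approx(np.abs(np.mean(np.exp(1j * sample))))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            psi(np.array([1.0, 2.0]), window=slice(0, 0))


class TestTernaryCode:
    @pytest.mark.parametrize(
        "value,code",
        [
            (np.pi / 8, 1),
            (-np.pi / 8, -1),
            (np.pi / 2, 0),
            (0.0, 0),
            (np.pi / 4, 0),
            (-np.pi / 4, 0),
            (np.pi, 0),
        ],
    )
    def test_open_interval_coding(self, value, code):
        assert ternary_code(np.array([value]))[0] == code

    def test_negating_difference_flips_code(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(-np.pi + 1e-9, np.pi, 500)
        assert np.array_equal(ternary_code(-v), -ternary_code(v))


class TestCleaning:
    def test_short_run_removed_long_run_kept(self):
        fs_phase, f = 50.0, 10.0  # period 0.1 s = 5 samples
        code = np.zeros(40, dtype=np.int8)
        code[2:5] = 1  # run of 3 samples = 0.6 T -> removed
        code[10:20] = -1  # run of 10 samples = 2 T -> kept
        out = clean_code(code, 1.0 / f, fs_phase)
        assert np.all(out[2:5] == 0)
        assert np.all(out[10:20] == -1)

    def test_run_exactly_one_period_survives(self):
        # strict comparison: duration < period removes, == period keeps
        code = np.zeros(20, dtype=np.int8)
        code[5:10] = 1  # 5 samples at 50 Hz = 0.1 s = exactly one 10-Hz period
        out = clean_code(code, 0.1, 50.0)
        assert np.all(out[5:10] == 1)

    def test_all_zero_code_unchanged(self):
        code = np.zeros(30, dtype=np.int8)
        assert np.array_equal(clean_code(code, 0.1, 50.0), code)

    def test_subsample_period_warns_and_noops(self):
        code = np.array([1, 0, -1], dtype=np.int8)
        with pytest.warns(UserWarning):
            out = clean_code(code, 0.001, 50.0)
        assert np.array_equal(out, code)

    def test_mixed_sign_runs_count_as_one_nonzero_run(self):
        code = np.array([0, 1, -1, 1, 0, 0], dtype=np.int8)  # one run of 3
        out = clean_code(code, 4 / 50.0, 50.0)  # min run 4 samples
        assert np.all(out == 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_literal_scanner_and_never_adds_locking(self, seed):
        rng = np.random.default_rng(seed)
        code = rng.choice([-1, 0, 1], size=200).astype(np.int8)
        period = rng.uniform(0.05, 0.4)
        out = clean_code(code, period, 50.0)
        assert np.array_equal(out, clean_bf(code, period, 50.0))
        # cleaning monotonicity: cleaned ACI <= raw ACI
        assert np.count_nonzero(out) <= np.count_nonzero(code)
        # cleaning only zeroes, never alters surviving codes
        assert np.all((out == code) | (out == 0))


class TestCouplingIndices:
    def test_all_positive_window_is_fully_integrated(self):
        idx = coupling_indices(np.ones(50, dtype=np.int8))
        assert idx.pci == idx.aci == idx.ici == 1.0

    def test_all_negative_window_scores_zero(self):
        idx = coupling_indices(-np.ones(50, dtype=np.int8))
        assert idx.nci == idx.aci == 1.0
        assert idx.pci == 0.0 and idx.ici == 0.0

    def test_hand_worked_mixed_window(self):
        code = np.array([1, 1, 1, 1, -1, -1, 0, 0, 0, 0], dtype=np.int8)
        idx = coupling_indices(code)
        assert idx.pci == pytest.approx(0.4)
        assert idx.nci == pytest.approx(0.2)
        assert idx.aci == pytest.approx(0.6)
        assert idx.ici == pytest.approx((0.4 + 0.6) / (2 * 0.6) * 0.4)  # 1/3

    def test_unlocked_window_has_zero_ici(self):
        idx = coupling_indices(np.zeros(10, dtype=np.int8))
        assert idx.aci == 0.0 and idx.ici == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_identities_hold_on_random_codes(self, seed):
        rng = np.random.default_rng(seed)
        code = rng.choice([-1, 0, 1], size=80).astype(np.int8)
        idx = coupling_indices(code)
        assert idx.aci == pytest.approx(idx.pci + idx.nci)
        for v in (idx.pci, idx.nci, idx.aci, idx.ici):
            assert 0.0 <= v <= 1.0


class TestSlidingWindows:
    def test_ten_second_segment_yields_81_windows(self, locked_pair_phases):
        cwt = sliding_window_coupling(locked_pair_phases, [("a", 10.0, "b", 10.0)])
        assert cwt.n_windows == 81
        assert cwt.window_samples == 100 and cwt.step_samples == 5

    def test_stationary_locking_gives_identical_windows(self, locked_pair_phases):
        cwt = sliding_window_coupling(locked_pair_phases, [("b", 10.0, "a", 10.0)])
        assert np.ptp(cwt.indices["ici"]) < 1e-12
        assert cwt.indices["ici"][0, 0] == pytest.approx(1.0)

    def test_direction_antisymmetry_is_exact(self):
        rec = gen_coupled_oscillators(
            [OscillatorSpec("a", 10.0, snr=2.0), OscillatorSpec("b", 10.0, snr=2.0)],
            seed=13,
        )
        ph = recording_phases(rec, freqs=[10.0])
        cwt = sliding_window_coupling(
            ph, [("a", 10.0, "b", 10.0), ("b", 10.0, "a", 10.0)]
        )
        assert np.array_equal(cwt.indices["pci"][0], cwt.indices["nci"][1])
        assert np.array_equal(cwt.indices["nci"][0], cwt.indices["pci"][1])
        assert np.allclose(cwt.indices["aci"][0], cwt.indices["aci"][1])
        assert np.allclose(cwt.indices["psi"][0], cwt.indices["psi"][1])

    def test_windowed_fractions_match_literal_counter(self, locked_pair_phases):
        rng = np.random.default_rng(3)
        # random ternary code injected through a synthetic phase difference
        code = rng.choice([-1, 0, 1], size=500).astype(np.int8)
        dphi = np.where(code == 1, np.pi / 8, np.where(code == -1, -np.pi / 8, np.pi))
        phase = np.zeros((2, 1, 500))
        phase[0, 0] = dphi  # channel 1 phase 0 -> difference equals dphi
        pt = PhaseTensor(
            phase=phase,
            freqs=np.array([10.0]),
            fs_phase=50.0,
            valid=np.ones((1, 500), bool),
            labels=["x", "y"],
        )
        cwt = sliding_window_coupling(
            pt, [("x", 10.0, "y", 10.0)], clean=False
        )
        for w, start in enumerate(cwt.window_starts[::10]):
            pci, nci = window_counts_bf(code, int(start), cwt.window_samples)
            assert cwt.indices["pci"][0, w * 10] == pytest.approx(pci)
            assert cwt.indices["nci"][0, w * 10] == pytest.approx(nci)

    def test_coupling_onset_raises_ici_across_boundary(self):
        # lag jitter collapses from huge to none halfway through the segment:
        # windows after the onset must show higher ICI than windows before
        rng = np.random.default_rng(4)
        fs, dur = 250.0, 10.0
        n = int(fs * dur)
        t = np.arange(n) / fs
        phi_a = 2 * np.pi * 10.0 * t
        from scipy.ndimage import gaussian_filter1d

        jitter = gaussian_filter1d(rng.standard_normal(n), 10)
        jitter = 3.0 * jitter / jitter.std()  # wandering lag before onset
        jitter[t >= 5.0] = 0.0
        phi_b = phi_a + np.pi / 8 + jitter
        rec_data = np.vstack([np.cos(phi_a), np.cos(phi_b)])
        from hfnet.synthetic import SegmentedRecording

        rec = SegmentedRecording(data=rec_data, fs=fs, labels=["a", "b"])
        ph = recording_phases(rec, freqs=[10.0])
        cwt = sliding_window_coupling(ph, [("b", 10.0, "a", 10.0)])
        ici = cwt.indices["ici"][0]
        assert ici[55:].mean() > ici[:25].mean() + 0.3

    def test_window_longer_than_segment_rejected(self, locked_pair_phases):
        with pytest.raises(ValueError, match="exceeds"):
            sliding_window_coupling(
                locked_pair_phases, [("a", 10.0, "b", 10.0)], window_ms=20_000.0
            )

    def test_long_format_table_round_trips_values(self, locked_pair_phases):
        cwt = sliding_window_coupling(
            locked_pair_phases, [("a", 10.0, "b", 10.0), ("b", 10.0, "a", 10.0)]
        )
        df = cwt.to_dataframe()
        assert len(df) == 2 * 81
        row = df[(df.window_index == 4) & (df.src_channel == "b")].iloc[0]
        assert row.ici == cwt.indices["ici"][1, 4]
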