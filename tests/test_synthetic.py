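"""Ground-truth generator: coupling, mixing, leakage, condition suites."""

import numpy as np
import pytest

from tfcausal.synthetic import (
    CouplingSpec,
    MixingSpec,
    SuiteConfig,
    UnstableModelError,
    _var_matrices,
    companion_spectral_radius,
    default_condition_specs,
    default_epoch_times,
    default_mixing,
    leakage_index,
    make_condition_suite,
    mix_to_parcels,
    read_suite,
    simulate_coupled_network,
    write_leakage_csv,
    write_suite,
)


def xcorr_lagged(a, b, lag):
    """Mean over trials of corr(a[t], b[t+lag]) on (trials, samples) arrays."""
    if lag > 0:
        a, b = a[:, :-lag], b[:, lag:]
    elif lag < 0:
        a, b = a[:, -lag:], b[:, :lag]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    return float((num / den).mean())


class TestSimulateCoupledNetwork:
    def test_no_coupling_gives_independent_sources(self):
        src = simulate_coupled_network([], 2, 200, 200.0, seed=0)
        for lag in (-5, 0, 5):
            c = xcorr_lagged(src.data[:, 0], src.data[:, 1], lag)
            assert abs(c) < 0.02

    def test_lagged_crosscorrelation_peaks_inside_window(self):
        spec = CouplingSpec(0, 1, lag=5, strength=0.8, window=(100, 400))
        src = simulate_coupled_network([spec], 2, 300, 200.0, seed=1)
        t = src.times
        inside = (t >= 150) & (t <= 380)
        outside = (t >= 600) & (t <= 1100)
        c_in = {lag: xcorr_lagged(src.data[:, 0, inside], src.data[:, 1, inside], lag)
                for lag in range(-8, 9)}
        assert max(c_in, key=c_in.get) == 5
        assert c_in[5] > 0.4
        c_out = xcorr_lagged(src.data[:, 0, outside], src.data[:, 1, outside], 5)
        assert abs(c_out) < 0.05

    def test_deterministic_given_seed(self):
        spec = CouplingSpec(0, 1, lag=3, strength=0.5, window=(0, 500))
        a = simulate_coupled_network([spec], 2, 5, 200.0, seed=9)
        b = simulate_coupled_network([spec], 2, 5, 200.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_unstable_reciprocal_coupling_rejected_naming_offender(self):
        # a strong reciprocal loop (gain 3 x 3 > 1) destabilizes the VAR;
        # a single unidirectional link never can (triangular dynamics)
        fwd = CouplingSpec(0, 1, lag=1, strength=3.0, window=(0, 1000))
        rev = CouplingSpec(1, 0, lag=1, strength=3.0, window=(0, 1000))
        with pytest.raises(UnstableModelError) as err:
            simulate_coupled_network([fwd, rev], 2, 2, 200.0, seed=0)
        assert "strength=3.0" in str(err.value)

    def test_strong_unidirectional_coupling_is_stable(self):
        spec = CouplingSpec(0, 1, lag=1, strength=5.0, window=(0, 1000))
        src = simulate_coupled_network([spec], 2, 2, 200.0, seed=0)
        assert np.all(np.isfinite(src.data))

    def test_window_outside_epoch_rejected(self):
        spec = CouplingSpec(0, 1, lag=1, strength=0.2, window=(900, 1500))
        with pytest.raises(ValueError, match="window"):
            simulate_coupled_network([spec], 2, 2, 200.0, seed=0)

    def test_default_var_is_stable(self):
        for specs in default_condition_specs().values():
            A = _var_matrices(specs, 2, 200.0, "broadband", ["vOT", "ST"])
            assert companion_spectral_radius(A) < 1.0

    def test_band_limited_source_peaks_at_carrier(self):
        src = simulate_coupled_network(
            [], 1, 50, 200.0, seed=3, source_bands=[(8.0, 12.0)]
        )
        x = src.data[:, 0, :]
        f = np.fft.rfftfreq(x.shape[1], 1 / 200.0)
        psd = (np.abs(np.fft.rfft(x, axis=1)) ** 2).mean(axis=0)
        peak = f[np.argmax(psd)]
        assert 7.0 <= peak <= 13.0


class TestMixToParcels:
    def test_identity_mixing_noiseless_reproduces_sources(self):
        src = simulate_coupled_network([], 2, 4, 200.0, seed=0)
        mix = MixingSpec(1, np.eye(2), np.inf)
        parcels = mix_to_parcels(src, mix, seed=0)
        assert len(parcels) == 2
        for p, pe in enumerate(parcels):
            assert np.allclose(pe.data[:, 0], src.data[:, p])

    def test_snr_power_accounting_within_10_percent(self):
        src = simulate_coupled_network([], 2, 120, 200.0, seed=5)
        mix = MixingSpec(3, default_mixing(2, 3, snr=1.0).mixing, 1.0)
        noisy = mix_to_parcels(src, mix, seed=11)
        clean = mix_to_parcels(src, MixingSpec(3, mix.mixing, np.inf), seed=11)
        for pn, pc in zip(noisy, clean):
            sig_power = pc.data.var()
            noise_power = (pn.data - pc.data).var()
            assert abs(sig_power / noise_power - 1.0) < 0.1

    def test_cross_parcel_leakage_gives_zero_lag_correlation(self):
        src = simulate_coupled_network([], 2, 60, 200.0, seed=6)
        M = np.array([[1.0, 0.3], [0.3, 1.0]])
        parcels = mix_to_parcels(src, MixingSpec(1, M, np.inf), seed=0)
        c = xcorr_lagged(parcels[0].data[:, 0], parcels[1].data[:, 0], 0)
        assert c > 0.3

    def test_dimension_mismatch_reports_shapes(self):
        src = simulate_coupled_network([], 3, 2, 200.0, seed=0)
        with pytest.raises(ValueError, match="2 source columns"):
            mix_to_parcels(src, MixingSpec(1, np.eye(2), 1.0), seed=0)

    def test_full_column_rank_required(self):
        M = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="rank"):
            MixingSpec(1, M, 1.0)


class TestLeakageIndex:
    def test_identity_resolution(self):
        prof = leakage_index(np.eye(3), 1)
        assert np.array_equal(prof.outgoing, [0, 1, 0])
        assert np.array_equal(prof.incoming, [0, 1, 0])

    def test_row_normalization(self):
        R = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        prof = leakage_index(R, 0)
        assert np.allclose(prof.outgoing, [1.0, 0.5, 0.0])

    def test_asymmetric_resolution_outgoing_exceeds_incoming(self):
        # seed row norms exceed column norms -> outgoing > incoming
        R = np.array([[1.0, 0.8, 0.6], [0.2, 1.0, 0.0], [0.1, 0.0, 1.0]])
        prof = leakage_index(R, 0, labels=["vOT", "A", "B"])
        assert prof.outgoing[1] > prof.incoming[1]
        assert prof.outgoing[2] > prof.incoming[2]
        assert prof.outgoing[0] == prof.incoming[0] == 1.0

    def test_zero_self_leakage_rejected(self):
        R = np.array([[0.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="self-leakage"):
            leakage_index(R, 0)

    def test_csv_export(self, tmp_path):
        prof = leakage_index(np.eye(2), 0, labels=["vOT", "ST"])
        path = tmp_path / "leak.csv"
        write_leakage_csv(path, prof)
        text = path.read_text()
        assert "vOT" in text and "outgoing" in text


class TestConditionSuite:
    def test_default_suite_matches_study_design(self):
        cfg = SuiteConfig()
        conds = cfg.resolved_conditions()
        assert set(conds) == {"RW-like", "RL1-like", "RL2-like", "RL3-like"}
        assert cfg.n_trials == 150
        suite = make_condition_suite(SuiteConfig(n_trials=4), seed=0)
        assert len(suite) == 4
        pe = suite["RW-like"][0]
        assert pe.times[0] == -200.0 and pe.times[-1] == 1100.0
        assert pe.data.shape[0] == 4

    def test_trial_override_passthrough(self):
        suite = make_condition_suite(
            SuiteConfig(n_trials=20, include=("RW-like",)), seed=0
        )
        assert suite["RW-like"][0].n_trials == 20

    def test_real_word_schedule_has_no_reverse_coupling(self):
        specs = default_condition_specs()["RW-like"]
        reverse = [s for s in specs if s.source_id == "ST"]
        assert reverse == []

    def test_feedforward_strength_tapers_with_wordlikeness(self):
        conds = default_condition_specs()
        ff = {k: next(s.strength for s in v if s.source_id == "vOT")
              for k, v in conds.items()}
        assert ff["RW-like"] > ff["RL1-like"] > ff["RL2-like"] > ff["RL3-like"]

    def test_unknown_condition_key_rejected_listing_valid(self):
        with pytest.raises(ValueError, match="RW-like"):
            make_condition_suite(SuiteConfig(include=("nope",)), seed=0)

    def test_suite_determinism(self):
        cfg = SuiteConfig(n_trials=3, include=("RW-like",))
        a = make_condition_suite(cfg, seed=4)["RW-like"][0].data
        b = make_condition_suite(cfg, seed=4)["RW-like"][0].data
        assert np.array_equal(a, b)

    def test_suite_io_roundtrip(self, tmp_path):
        cfg = SuiteConfig(n_trials=3, include=("RW-like", "RL3-like"))
        suite = make_condition_suite(cfg, seed=1)
        path = tmp_path / "suite.h5"
        write_suite(path, suite, cfg)
        back = read_suite(path)
        assert set(back) == set(suite)
        for cond in suite:
            for a, b in zip(suite[cond], back[cond]):
                assert a.parcel == b.parcel
                assert np.array_equal(a.data, b.data)
        sidecar = (tmp_path / "suite.json").read_text()
        assert "ground_truth" in sidecar and "RL3-like" in sidecar
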