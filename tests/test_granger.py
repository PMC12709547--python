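"""Spectral GC: factorization, Whittle recursion, Geweke measure, TRGC."""

import numpy as np
import pytest

from tfcausal.containers import SpectralSeries
from tfcausal.granger import (
    AutocovSequence,
    FactorizationError,
    VarModel,
    autocov_from_spectrum,
    autocov_series_from_spectrum,
    empirical_autocov,
    gc_time_frequency,
    pca_pair_reduce,
    spectral_gc,
    time_reversed_gc,
    trgc_net,
    var_autocov,
    var_spectral_matrix,
    whittle_var,
)
from tfcausal.synthetic import CouplingSpec, MixingSpec, mix_to_parcels, simulate_coupled_network
from tests.conftest import make_parcel

SFREQ = 200.0
FREQS = np.arange(4.0, 41.0)
PART = (np.array([0]), np.array([1]))


def random_stable_var(rng, dim=2, order=2, max_radius=0.85):
    A = rng.normal(0, 0.4, (order, dim, dim))
    L = rng.normal(0, 1, (dim, dim))
    Sigma = L @ L.T + 0.3 * np.eye(dim)
    model = VarModel(A, Sigma, SFREQ)
    while model.spectral_radius() >= max_radius:
        A = A * 0.8
        model = VarModel(A, Sigma, SFREQ)
    return model


def direct_yule_walker(G, p):
    """Independent oracle: explicit block-Toeplitz Yule-Walker solve."""
    d = G.shape[1]
    Gamma = np.zeros((p * d, p * d))
    for i in range(p):
        for j in range(p):
            k = j - i
            Gamma[i * d:(i + 1) * d, j * d:(j + 1) * d] = G[k] if k >= 0 else G[-k].T
    rhs = np.hstack([G[k] for k in range(1, p + 1)])
    Acoef = np.linalg.solve(Gamma.T, rhs.T).T
    A = np.stack([Acoef[:, k * d:(k + 1) * d] for k in range(p)])
    Sig = G[0].copy()
    for k in range(1, p + 1):
        Sig -= A[k - 1] @ G[k].T
    return A, Sig


def geweke_oracle_bivariate(model, freqs, L=2048):
    """Brute-force spectral GC: MA(inf) impulse-response transfer function
    plus scalar partial-covariance elimination. Independent of the
    implementation's matrix-inverse route."""
    A, Sigma = model.A, model.Sigma
    p, d, _ = A.shape
    B = [np.eye(d)]
    for k in range(1, L):
        Bk = np.zeros((d, d))
        for j in range(1, min(k, p) + 1):
            Bk += A[j - 1] @ B[k - j]
        B.append(Bk)
    B = np.asarray(B)
    ph = np.exp(-2j * np.pi * np.outer(freqs, np.arange(L)) / model.sfreq)
    H = np.einsum("fk,kij->fij", ph, B.astype(complex))
    S = H @ Sigma @ np.conj(np.swapaxes(H, 1, 2))
    out = []
    for a, b in [(0, 1), (1, 0)]:  # influence of b on a
        saa = S[:, a, a].real
        sig_b_a = Sigma[b, b] - Sigma[a, b] ** 2 / Sigma[a, a]
        intrinsic = saa - (H[:, a, b] * np.conj(H[:, a, b])).real * sig_b_a
        out.append(np.log(saa / intrinsic))
    return out[0], out[1]  # I_{y->x}, I_{x->y}


class TestAutocovFromSpectrum:
    def test_var1_roundtrip_matches_lyapunov(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        model = VarModel(A, np.eye(2), SFREQ)
        grid = np.arange(0.0, 101.0)  # full grid incl. DC and Nyquist
        S = var_spectral_matrix(model, grid)
        ss = SpectralSeries(S[None], grid, np.array([0.0]), SFREQ, n_trials=1,
                            block_sizes=(1, 1))
        G = autocov_from_spectrum(ss, 0, K=40)
        G_true = var_autocov(A, np.eye(2), 40)
        assert np.max(np.abs(G.G - G_true)) < 1e-6 * np.max(np.abs(G_true))

    def test_flat_white_spectrum_gives_delta_autocovariance(self):
        grid = np.arange(0.0, 101.0)
        S = np.tile(np.eye(2, dtype=complex), (1, grid.size, 1, 1))
        ss = SpectralSeries(S, grid, np.array([0.0]), SFREQ, n_trials=1)
        G = autocov_from_spectrum(ss, 0, K=10)
        assert np.allclose(G.G[0], np.eye(2), atol=1e-12)
        assert np.max(np.abs(G.G[1:])) < 1e-12

    def test_band_limited_grid_is_extended_not_rejected(self):
        model = random_stable_var(np.random.default_rng(0))
        S = var_spectral_matrix(model, FREQS)
        ss = SpectralSeries(S[None], FREQS, np.array([0.0]), SFREQ, n_trials=1)
        G = autocov_from_spectrum(ss, 0, K=40)
        assert np.all(np.isfinite(G.G))
        assert np.allclose(G.G[0], G.G[0].T)

    def test_lag_axis_vectorizes_over_time(self):
        model = random_stable_var(np.random.default_rng(1))
        S = var_spectral_matrix(model, FREQS)
        SS = np.stack([S, S])
        ss = SpectralSeries(SS, FREQS, np.array([0.0, 10.0]), SFREQ, n_trials=1)
        G = autocov_series_from_spectrum(ss, 20)
        assert G.shape == (2, 21, 2, 2)
        assert np.array_equal(G[0], G[1])


class TestWhittleVar:
    @pytest.mark.parametrize("order", [1, 2])
    def test_recovers_generating_model(self, rng, order):
        model = random_stable_var(rng, dim=3, order=order)
        G = var_autocov(model.A, model.Sigma, 10)
        fit = whittle_var(AutocovSequence(G, SFREQ), order=order)
        assert np.max(np.abs(fit.A - model.A)) < 1e-6
        assert np.max(np.abs(fit.Sigma - model.Sigma)) < 1e-6

    def test_matches_direct_block_toeplitz_solve(self, rng):
        for _ in range(5):
            model = random_stable_var(rng, dim=2, order=4)
            G = var_autocov(model.A, model.Sigma, 30)
            fit = whittle_var(AutocovSequence(G, SFREQ), order=12)
            A_d, Sig_d = direct_yule_walker(G, 12)
            assert np.max(np.abs(fit.A - A_d)) < 1e-8
            assert np.max(np.abs(fit.Sigma - Sig_d)) < 1e-8

    def test_white_noise_gives_zero_coefficients(self):
        G = np.zeros((5, 2, 2))
        G[0] = np.diag([1.0, 2.0])
        fit = whittle_var(AutocovSequence(G, SFREQ), order=3)
        assert np.max(np.abs(fit.A)) < 1e-12
        assert np.allclose(fit.Sigma, G[0])

    def test_invalid_autocovariance_fails_loudly(self):
        # G(1) >> G(0) cannot come from any stationary process
        G = np.stack([np.eye(2), 2.0 * np.eye(2)])
        with pytest.raises(FactorizationError):
            whittle_var(AutocovSequence(G, SFREQ), order=1)

    def test_insufficient_lags_rejected(self):
        G = var_autocov(np.array([[[0.5]]]), np.eye(1), 5)
        with pytest.raises(ValueError, match="lag"):
            whittle_var(AutocovSequence(G, SFREQ), order=10)


class TestSpectralGc:
    def test_decoupled_blocks_give_zero_gc(self):
        A = np.array([[[0.5, 0.0], [0.0, -0.3]]])
        model = VarModel(A, np.diag([1.0, 2.0]), SFREQ)
        Iyx, Ixy = spectral_gc(model, FREQS, PART)
        assert np.max(np.abs(Iyx)) < 1e-12
        assert np.max(np.abs(Ixy)) < 1e-12

    def test_unidirectional_var1_against_oracle(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        model = VarModel(A, np.eye(2), SFREQ)
        Iyx, Ixy = spectral_gc(model, FREQS, PART)
        assert np.all(Ixy > 0)
        assert np.max(np.abs(Iyx)) < 1e-12
        Oyx, Oxy = geweke_oracle_bivariate(model, FREQS)
        assert np.max(np.abs(Ixy - Oxy)) < 1e-6
        assert np.max(np.abs(Iyx - Oyx)) < 1e-6

    def test_twenty_random_var2_models_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            model = random_stable_var(rng)
            Iyx, Ixy = spectral_gc(model, FREQS, PART)
            assert Iyx.min() > -1e-10 and Ixy.min() > -1e-10
            Oyx, Oxy = geweke_oracle_bivariate(model, FREQS)
            assert np.max(np.abs(Iyx - Oyx)) < 1e-6
            assert np.max(np.abs(Ixy - Oxy)) < 1e-6

    def test_frequency_integral_equals_time_domain_measure(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.5]], [[0.1, 0.0], [0.2, -0.1]]])
        Sigma = np.array([[1.0, 0.2], [0.2, 1.5]])
        model = VarModel(A, Sigma, SFREQ)
        grid = np.arange(0.0, SFREQ, SFREQ / 512)
        Iyx, Ixy = spectral_gc(model, grid, PART)
        G = var_autocov(A, Sigma, 120)
        full = whittle_var(AutocovSequence(G, SFREQ), order=2)
        for target, source, spec_val in ((1, 0, Ixy.mean()), (0, 1, Iyx.mean())):
            Gm = G[:, [target]][:, :, [target]]
            red = whittle_var(AutocovSequence(Gm, SFREQ), order=100,
                              check_stability=False)
            time_val = np.log(red.Sigma[0, 0] / full.Sigma[target, target])
            if time_val > 1e-6:
                assert abs(spec_val - time_val) / time_val < 0.01
            else:
                assert spec_val < 1e-6

    def test_bad_partition_rejected(self):
        model = random_stable_var(np.random.default_rng(0))
        with pytest.raises(ValueError, match="partition"):
            spectral_gc(model, FREQS, (np.array([0]), np.array([0])))


class TestTimeReversal:
    def test_symmetric_autocovariance_identity(self):
        A = np.array([[[0.5, 0.2], [0.2, 0.5]]])
        G = var_autocov(A, np.eye(2), 60)
        G = 0.5 * (G + np.swapaxes(G, 1, 2))  # exactly symmetric at all lags
        seq = AutocovSequence(G, SFREQ)
        I = spectral_gc(whittle_var(seq, 20), FREQS, PART)
        R = time_reversed_gc(seq, 20, FREQS, PART)
        assert np.array_equal(I[0], R[0])
        assert np.array_equal(I[1], R[1])

    def test_unidirectional_system_flips_direction(self):
        A = np.array([[[0.5, 0.0], [0.6, 0.5]]])
        G = var_autocov(A, np.eye(2), 60)
        seq = AutocovSequence(G, SFREQ)
        Iyx, Ixy = spectral_gc(whittle_var(seq, 20), FREQS, PART)
        Ryx, Rxy = time_reversed_gc(seq, 20, FREQS, PART)
        # the reversed influence appears in the opposite direction with a
        # comparable (band-averaged, not bin-wise) magnitude
        assert abs(Ryx.mean() - Ixy.mean()) < 0.25 * Ixy.mean()
        assert Rxy.mean() < 0.05 * Ixy.mean()
        assert np.max(np.abs(Iyx)) < 1e-10
        net = trgc_net(Ixy, Iyx, Rxy, Ryx, np.array([0.0]), FREQS)
        assert net.ff.mean() > 0
        assert net.fb.mean() < 0  # the "counterintuitive" negative feedback

    def test_white_noise_reversal_near_zero(self):
        G = np.zeros((41, 2, 2))
        G[0] = np.eye(2)
        Ryx, Rxy = time_reversed_gc(AutocovSequence(G, SFREQ), 20, FREQS, PART)
        assert np.max(np.abs(Ryx)) < 1e-10 and np.max(np.abs(Rxy)) < 1e-10


class TestTrgcNet:
    def test_equal_measures_give_zero_everywhere(self):
        I = np.random.default_rng(0).uniform(0, 1, (3, 5))
        res = trgc_net(I, I.copy(), I.copy(), I.copy(),
                       np.arange(3.0), np.arange(5.0))
        assert np.all(res.ff == 0) and np.all(res.fb == 0) and np.all(res.net == 0)

    def test_net_antisymmetric_under_partition_swap(self):
        rng = np.random.default_rng(1)
        I_xy, I_yx, R_xy, R_yx = rng.uniform(0, 1, (4, 3, 5))
        t, f = np.arange(3.0), np.arange(5.0)
        a = trgc_net(I_xy, I_yx, R_xy, R_yx, t, f)
        b = trgc_net(I_yx, I_xy, R_yx, R_xy, t, f)
        assert np.array_equal(a.net, -b.net)

    def test_marginals_average_over_expected_axes(self):
        rng = np.random.default_rng(2)
        I_xy, I_yx, R_xy, R_yx = rng.uniform(0, 1, (4, 3, 5))
        res = trgc_net(I_xy, I_yx, R_xy, R_yx, np.arange(3.0), np.arange(5.0))
        assert np.allclose(res.time_marginal("net"), res.net.mean(axis=1))
        assert np.allclose(res.freq_marginal("ff"), res.ff.mean(axis=0))


class TestPcaPairReduce:
    def _pair(self, rng, vx=3, vy=3, trials=8, n=261):
        x = make_parcel(rng.standard_normal((trials, vx, n)), parcel="X")
        y = make_parcel(rng.standard_normal((trials, vy, n)), parcel="Y")
        return x, y

    def test_full_rank_projection_is_lossless(self, rng):
        # with rank == vertex count the loading matrix is orthogonal, so
        # back-projection reproduces the data exactly
        x, y = self._pair(rng)
        rp = pca_pair_reduce(x, y, rank=3)
        recon = np.einsum("vr,trn->tvn", rp.proj_x.T, rp.x)
        assert np.allclose(recon, x.data, atol=1e-8)

    def test_redundant_vertices_compress_to_rank_one(self, rng):
        n = 400
        s = rng.standard_normal((10, 1, n))
        data = np.concatenate([s, 0.9 * s, 1.1 * s], axis=1)
        data = data + 0.05 * rng.standard_normal(data.shape)
        x = make_parcel(data, times=np.arange(n) * 5.0, parcel="X")
        y = make_parcel(rng.standard_normal((10, 3, n)), times=np.arange(n) * 5.0)
        rp = pca_pair_reduce(x, y, rank=1)
        proj = np.einsum("rv,tvn->trn", rp.proj_x, data - data.mean(axis=(0, 2), keepdims=True))
        back = np.einsum("vr,trn->tvn", rp.proj_x.T, proj)
        centered = data - data.mean(axis=(0, 2), keepdims=True)
        retained = 1 - ((centered - back) ** 2).sum() / (centered ** 2).sum()
        assert retained > 0.9

    def test_rank_exceeding_vertices_rejected(self, rng):
        x, y = self._pair(rng)
        with pytest.raises(ValueError, match="rank"):
            pca_pair_reduce(x, y, rank=5)

    def test_auto_rank_clipped_to_vertex_count(self, rng):
        x, y = self._pair(rng)
        rp = pca_pair_reduce(x, y, rank="auto")
        assert rp.rank == 3  # 5..7 infeasible with 3 vertices

    def test_ranks_equal_for_both_parcels(self, rng):
        x, y = self._pair(rng, vx=3, vy=4)
        rp = pca_pair_reduce(x, y, rank=2)
        assert rp.x.shape[1] == rp.y.shape[1] == 2


class TestGcTimeFrequency:
    def test_direction_recovered_on_coupled_pair(self):
        spec = CouplingSpec(0, 1, lag=5, strength=0.8, window=(100, 400))
        src = simulate_coupled_network([spec], 2, 40, SFREQ, seed=3)
        seed_pe, target_pe = mix_to_parcels(
            src, MixingSpec(2, np.kron(np.eye(2), [[1.0], [0.8]]), 4.0),
            seed=0, parcel_labels=["X", "Y"],
        )
        rp = pca_pair_reduce(seed_pe, target_pe, rank=2)
        gc = gc_time_frequency(rp, step_ms=20.0, order=20)
        assert gc.raw_ff.min() > -1e-10 and gc.raw_fb.min() > -1e-10
        net_t = gc.time_marginal("net")
        inside = (gc.times >= 150) & (gc.times <= 380)
        base = gc.times <= -100
        assert net_t[inside].mean() > 0.05
        assert net_t[inside].mean() > 5 * abs(net_t[base].mean())


def test_empirical_autocov_matches_analytic(rng):
    model = random_stable_var(rng, dim=2, order=1, max_radius=0.7)
    n = 20000
    d = 2
    e = rng.multivariate_normal(np.zeros(d), model.Sigma, size=n + 100)
    x = np.zeros((n + 100, d))
    for t in range(1, n + 100):
        x[t] = model.A[0] @ x[t - 1] + e[t]
    G_emp = empirical_autocov(x[100:].T[None], K=3, sfreq=SFREQ)
    G_true = var_autocov(model.A, model.Sigma, 3)
    assert np.max(np.abs(G_emp.G - G_true)) < 0.1 * np.max(np.abs(G_true))
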