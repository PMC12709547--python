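"""Time-frequency multivariate Granger causality with time-reversal control.

Per analysis time point tau, the trial-averaged wavelet cross-spectral
matrix S(tau, f) is converted to an autocovariance sequence (inverse DFT of
the Hermitian-extended spectrum), a VAR model is fitted by Whittle's
multichannel Levinson recursion, and the Geweke spectral measure

    I_{y->x}(tau, f) = ln |S_xx| / |S_xx - H_xy Sigma_{yy|x} H_xy^*|

is evaluated from the model's transfer matrix H and residual covariance
Sigma (Sigma_{yy|x} = Sigma_yy - Sigma_yx Sigma_xx^-1 Sigma_xy). Raw GC is
nonnegative but biased by noise/SNR asymmetries; the time-reversed measure
(autocovariance transposed at every lag, model refitted) is subtracted to
give the corrected GC, which can legitimately be negative when the causal
asymmetry favors the opposite direction. Net GC is the difference of the
two corrected directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import ParcelEpochs, SpectralSeries
from .tfr import morlet_transform, cross_spectral_series, default_freqs

__all__ = [
    "ReducedPair",
    "AutocovSequence",
    "VarModel",
    "GcResult",
    "FactorizationError",
    "pca_pair_reduce",
    "autocov_from_spectrum",
    "autocov_series_from_spectrum",
    "empirical_autocov",
    "whittle_var",
    "spectral_gc",
    "time_reversed_gc",
    "trgc_net",
    "gc_time_frequency",
    "var_transfer",
    "var_spectral_matrix",
    "var_autocov",
]


class FactorizationError(RuntimeError):
    """Autocovariance could not be factorized into a stable VAR."""


@dataclass
class ReducedPair:
    """PCA-reduced vertex data of two parcels at a common rank."""

    x: np.ndarray  # (trials, rank, samples)
    y: np.ndarray
    rank: int
    proj_x: np.ndarray  # (rank, n_vertices_x) loading matrices
    proj_y: np.ndarray
    sfreq: float
    times: np.ndarray
    labels: tuple[str, str] = ("x", "y")


@dataclass
class AutocovSequence:
    """Autocovariance matrices G(0..K) at one analysis time point."""

    G: np.ndarray  # (K+1, d, d) real
    sfreq: float
    tau: float | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, float)
        if self.G.ndim != 3 or self.G.shape[1] != self.G.shape[2]:
            raise ValueError("G must be (K+1, d, d)")
        sym_err = np.max(np.abs(self.G[0] - self.G[0].T))
        if sym_err > 1e-8 * max(np.max(np.abs(self.G[0])), 1e-30):
            raise ValueError("G(0) must be symmetric")

    @property
    def K(self) -> int:
        return self.G.shape[0] - 1

    def transposed(self) -> "AutocovSequence":
        """Lagwise transpose: the autocovariance of the time-reversed signal."""
        return AutocovSequence(np.swapaxes(self.G, 1, 2).copy(), self.sfreq, self.tau)


@dataclass
class VarModel:
    """VAR(p): x_t = sum_k A[k] x_{t-k} + e_t, cov(e) = Sigma."""

    A: np.ndarray  # (p, d, d)
    Sigma: np.ndarray  # (d, d)
    sfreq: float
    tau: float | None = None

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def dim(self) -> int:
        return self.A.shape[1]

    def spectral_radius(self) -> float:
        p, d = self.order, self.dim
        comp = np.zeros((p * d, p * d))
        comp[:d, :] = self.A.transpose(1, 0, 2).reshape(d, p * d)
        if p > 1:
            comp[d:, :-d] = np.eye(d * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GcResult:
    """Directional, corrected, and net GC over the (tau, f) grid."""

    ff: np.ndarray  # corrected GC x->y, (n_times, n_freqs)
    fb: np.ndarray  # corrected GC y->x
    net: np.ndarray  # ff - fb
    raw_ff: np.ndarray
    raw_fb: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    pair: tuple[str, str] = ("x", "y")

    def time_marginal(self, which: str = "net") -> np.ndarray:
        """Frequency-averaged (time-resolved) GC."""
        return getattr(self, which).mean(axis=1)

    def freq_marginal(self, which: str = "net") -> np.ndarray:
        """Time-averaged (frequency-resolved) GC."""
        return getattr(self, which).mean(axis=0)


# ---------------------------------------------------------------------------
# PCA rank reduction

def _fit_projection(data_list: list[np.ndarray], rank: int) -> np.ndarray:
    """Top-``rank`` principal axes of trial-concatenated channel data."""
    X = np.concatenate([d.transpose(1, 0, 2).reshape(d.shape[1], -1) for d in data_list], axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :rank].T  # (rank, channels)


def _explained_variance(data_list: list[np.ndarray], rank: int) -> float:
    X = np.concatenate([d.transpose(1, 0, 2).reshape(d.shape[1], -1) for d in data_list], axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    ev = s ** 2
    return float(ev[:rank].sum() / ev.sum())


def pca_pair_reduce(
    x: ParcelEpochs,
    y: ParcelEpochs,
    rank: int | str = "auto",
    fit_x: list[ParcelEpochs] | None = None,
    fit_y: list[ParcelEpochs] | None = None,
) -> ReducedPair:
    """Project both parcels onto their top principal axes at a common rank.

    Equal ranks for the two parcels avoid dimensionality-driven biases in
    the GC estimates. ``rank="auto"`` picks the smallest rank in 5..7 whose
    components explain >= 95% variance in both parcels (else 5), clipped to
    the available vertex counts. ``fit_x``/``fit_y`` optionally pool epochs
    from several conditions so one shared projection serves all contrasts.
    """
    if x.n_trials != y.n_trials or not np.array_equal(x.times, y.times):
        raise ValueError("parcels must share trial count and time grid")
    fx = [e.data for e in (fit_x or [x])]
    fy = [e.data for e in (fit_y or [y])]
    min_v = min(x.n_vertices, y.n_vertices)
    if rank == "auto":
        cands = [r for r in (5, 6, 7) if r <= min_v]
        if not cands:
            rank = min_v
        else:
            rank = cands[0]
            for r in cands:
                if _explained_variance(fx, r) >= 0.95 and _explained_variance(fy, r) >= 0.95:
                    rank = r
                    break
    rank = int(rank)
    if rank < 1 or rank > min_v:
        raise ValueError(f"rank {rank} outside [1, {min_v}] for this parcel pair")
    Px = _fit_projection(fx, rank)
    Py = _fit_projection(fy, rank)
    return ReducedPair(
        x=np.einsum("rv,tvn->trn", Px, x.data),
        y=np.einsum("rv,tvn->trn", Py, y.data),
        rank=rank, proj_x=Px, proj_y=Py,
        sfreq=x.sfreq, times=x.times, labels=(x.parcel, y.parcel),
    )


# ---------------------------------------------------------------------------
# spectrum -> autocovariance

def _extend_spectrum(S: np.ndarray, freqs: np.ndarray, sfreq: float) -> np.ndarray:
    """Hermitian-extend band-limited S(..., n_freqs, d, d) to a full DFT grid.

    Missing bins below/above the analyzed band (including DC and Nyquist)
    are filled with the nearest in-band value; negative frequencies mirror
    by elementwise conjugation so the inverse DFT is real.
    """
    df = freqs[1] - freqs[0]
    if not np.allclose(np.diff(freqs), df, rtol=1e-8):
        raise ValueError("frequency grid must be uniform")
    N = int(round(sfreq / df))
    if abs(N * df - sfreq) > 1e-6 * sfreq:
        raise ValueError("sfreq must be an integer multiple of the grid step")
    j = np.round(freqs / df).astype(int)
    if not np.allclose(j * df, freqs, atol=1e-9 * sfreq):
        raise ValueError("frequencies must sit on a DFT grid (multiples of the step)")
    half = N // 2
    if j.max() > half:
        raise ValueError("frequency grid exceeds Nyquist")

    lead = S.shape[:-3]
    d = S.shape[-1]
    full = np.zeros(lead + (N, d, d), complex)
    full[..., j, :, :] = S
    if j.min() > 0:  # below-band fill (incl. DC)
        full[..., :j.min(), :, :] = S[..., :1, :, :]
    if j.max() < half:  # above-band fill up to Nyquist
        full[..., j.max() + 1:half + 1, :, :] = S[..., -1:, :, :]
    # DC (and Nyquist if N even) must be self-conjugate: keep the real part
    full[..., 0, :, :] = full[..., 0, :, :].real
    if N % 2 == 0:
        full[..., half, :, :] = full[..., half, :, :].real
    # negative frequencies: S(-f) = conj(S(f)) for a real vector process
    neg = np.arange(half + 1, N)
    full[..., neg, :, :] = np.conj(full[..., N - neg, :, :])
    return full


def autocov_series_from_spectrum(S: SpectralSeries, K: int) -> np.ndarray:
    """Autocovariances G(tau, k) for all time points at once: (n_times, K+1, d, d)."""
    full = _extend_spectrum(S.S, S.freqs, S.sfreq)
    N = full.shape[-3]
    if K >= N:
        raise ValueError(f"max lag K={K} requires a finer frequency grid (N={N})")
    G = np.fft.ifft(full, axis=-3)[..., : K + 1, :, :]
    scale = max(float(np.max(np.abs(G))), 1e-300)
    imag_resid = float(np.max(np.abs(G.imag))) / scale
    if imag_resid > 1e-8:
        raise ValueError(
            f"imaginary residual {imag_resid:.2e} in autocovariance; "
            "input spectrum violates Hermitian symmetry"
        )
    G = G.real.copy()
    G[..., 0, :, :] = 0.5 * (G[..., 0, :, :] + np.swapaxes(G[..., 0, :, :], -1, -2))
    return G


def autocov_from_spectrum(S: SpectralSeries, tau_index: int, K: int) -> AutocovSequence:
    """Autocovariance sequence at one analysis time point."""
    sub = SpectralSeries(
        S.S[tau_index:tau_index + 1], S.freqs, S.times[tau_index:tau_index + 1],
        S.sfreq, S.n_trials, S.block_sizes,
    )
    G = autocov_series_from_spectrum(sub, K)[0]
    return AutocovSequence(G, S.sfreq, tau=float(S.times[tau_index]))


def empirical_autocov(data: np.ndarray, K: int, sfreq: float = 1.0) -> AutocovSequence:
    """Sample autocovariance of (trials, d, samples) data up to lag K.

    G(k) = mean over trials of sum_t x_{t} x_{t-k}^T / (n - k), per-trial
    demeaned; used for stationary (non-time-resolved) estimation.
    """
    data = np.asarray(data, float)
    T, d, n = data.shape
    x = data - data.mean(axis=2, keepdims=True)
    G = np.empty((K + 1, d, d))
    for k in range(K + 1):
        G[k] = np.einsum("tin,tjn->ij", x[:, :, k:], x[:, :, : n - k]) / (T * (n - k))
    G[0] = 0.5 * (G[0] + G[0].T)
    return AutocovSequence(G, sfreq)


# ---------------------------------------------------------------------------
# Whittle recursion: autocovariance -> VAR

def whittle_var(G: AutocovSequence, order: int = 20, check_stability: bool = True) -> VarModel:
    """Solve the multivariate Yule-Walker equations by Whittle's recursion.

    Forward and backward predictor coefficients are built up order by order
    (the multichannel Levinson-Durbin scheme). A singular residual
    covariance triggers diagonal-loading retries before failing.
    """
    if G.K < order:
        raise ValueError(f"need autocovariances up to lag {order}, have {G.K}")
    g = G.G
    d = g.shape[1]

    def _run(load: float) -> tuple[np.ndarray, np.ndarray]:
        I_load = load * np.trace(g[0]) / d * np.eye(d)
        A: list[np.ndarray] = []  # forward coefficients A_1..A_m
        B: list[np.ndarray] = []  # backward coefficients
        V = g[0] + I_load  # forward residual covariance
        W = g[0] + I_load  # backward residual covariance
        for m in range(1, order + 1):
            D = g[m].copy()
            for k in range(1, m):
                D -= A[k - 1] @ g[m - k]
            Am = np.linalg.solve(W.T, D.T).T  # D @ W^-1
            Bm = np.linalg.solve(V.T, D).T  # D^T @ V^-1
            A_new = [A[k - 1] - Am @ B[m - 1 - k] for k in range(1, m)] + [Am]
            B_new = [B[k - 1] - Bm @ A[m - 1 - k] for k in range(1, m)] + [Bm]
            V = V - Am @ D.T
            W = W - Bm @ D
            V = 0.5 * (V + V.T)
            W = 0.5 * (W + W.T)
            A, B = A_new, B_new
        return np.stack(A), V

    load = 0.0
    for attempt in range(6):
        try:
            A, Sigma = _run(load)
        except np.linalg.LinAlgError:
            load = 1e-12 if load == 0 else load * 100
            continue
        if np.all(np.isfinite(A)) and np.all(np.isfinite(Sigma)):
            model = VarModel(A, Sigma, G.sfreq, tau=G.tau)
            if check_stability and model.spectral_radius() >= 1.0:
                load = 1e-12 if load == 0 else load * 100
                continue
            return model
        load = 1e-12 if load == 0 else load * 100
    raise FactorizationError(
        f"VAR factorization failed at tau={G.tau} even with diagonal loading"
    )


# ---------------------------------------------------------------------------
# spectral GC

def var_transfer(model: VarModel, freqs: np.ndarray) -> np.ndarray:
    """Transfer matrices H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^-1."""
    freqs = np.asarray(freqs, float)
    p, d = model.order, model.dim
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / model.sfreq)
    Af = np.eye(d)[None] - np.einsum("fk,kij->fij", z, model.A.astype(complex))
    return np.linalg.inv(Af)


def var_spectral_matrix(model: VarModel, freqs: np.ndarray) -> np.ndarray:
    """Analytic spectral matrices S(f) = H Sigma H^H (per-sample convention)."""
    H = var_transfer(model, freqs)
    return H @ model.Sigma @ np.conj(np.swapaxes(H, 1, 2))


def _partial_cov(Sigma: np.ndarray, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
    Sxx = Sigma[np.ix_(ix, ix)]
    Syy = Sigma[np.ix_(iy, iy)]
    Sxy = Sigma[np.ix_(ix, iy)]
    return Syy - Sxy.T @ np.linalg.solve(Sxx, Sxy)


def _logdet_h(M: np.ndarray) -> np.ndarray:
    """log|det| of (stacked) Hermitian positive-definite matrices."""
    Mh = 0.5 * (M + np.conj(np.swapaxes(M, -1, -2)))
    sign, ld = np.linalg.slogdet(Mh)
    return ld


def spectral_gc(
    model: VarModel,
    freqs: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Geweke spectral GC of a fitted VAR, both directions.

    Returns ``(I_y_to_x, I_x_to_y)`` over ``freqs`` for the index partition
    ``(x_indices, y_indices)``, which must be disjoint and cover the model
    dimension.
    """
    ix = np.asarray(partition[0], int)
    iy = np.asarray(partition[1], int)
    if np.intersect1d(ix, iy).size or ix.size + iy.size != model.dim:
        raise ValueError("partition blocks must be disjoint and cover the model")
    H = var_transfer(model, freqs)
    S = H @ model.Sigma @ np.conj(np.swapaxes(H, 1, 2))

    def _direction(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
        # influence of block b on block a
        Saa = S[:, ia[:, None], ia[None, :]]
        Hab = H[:, ia[:, None], ib[None, :]]
        Sig_b_a = _partial_cov(model.Sigma, ia, ib)
        intrinsic = Saa - Hab @ Sig_b_a @ np.conj(np.swapaxes(Hab, 1, 2))
        return _logdet_h(Saa) - _logdet_h(intrinsic)

    return _direction(ix, iy), _direction(iy, ix)


def time_reversed_gc(
    G: AutocovSequence,
    order: int,
    freqs: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral GC of the time-reversed process (lagwise-transposed G)."""
    model = whittle_var(G.transposed(), order)
    return spectral_gc(model, freqs, partition)


def trgc_net(
    I_xy: np.ndarray,
    I_yx: np.ndarray,
    Irev_xy: np.ndarray,
    Irev_yx: np.ndarray,
    times: np.ndarray,
    freqs: np.ndarray,
    pair: tuple[str, str] = ("x", "y"),
) -> GcResult:
    """Assemble corrected and net GC from raw and time-reversed measures.

    GC_{x->y} = I_{x->y} - Irev_{x->y}; net = GC_{x->y} - GC_{y->x}
    (antisymmetric under partition swap by construction).
    """
    ff = I_xy - Irev_xy
    fb = I_yx - Irev_yx
    return GcResult(
        ff=ff, fb=fb, net=ff - fb, raw_ff=I_xy, raw_fb=I_yx,
        times=np.asarray(times, float), freqs=np.asarray(freqs, float), pair=pair,
    )


# ---------------------------------------------------------------------------
# end-to-end time-frequency GC for a parcel pair

def gc_time_frequency(
    pair: ReducedPair,
    freqs: np.ndarray | None = None,
    step_ms: float = 10.0,
    order: int = 20,
    max_lag: int | None = None,
) -> GcResult:
    """Wavelet-spectral GC over the full (tau, f) grid for one parcel pair.

    Per time point: Hermitian-extend the trial-averaged wavelet spectral
    matrix, invert to an autocovariance sequence (max lag 2x the VAR
    order), fit forward and time-reversed VAR models, and evaluate the
    Geweke measure in both directions.
    """
    if freqs is None:
        freqs = default_freqs()
    if max_lag is None:
        max_lag = 2 * order
    px = ParcelEpochs(pair.x, pair.sfreq, pair.times, parcel=pair.labels[0])
    py = ParcelEpochs(pair.y, pair.sfreq, pair.times, parcel=pair.labels[1])
    tfr_x = morlet_transform(px, freqs, step_ms)
    tfr_y = morlet_transform(py, freqs, step_ms)
    S = cross_spectral_series(tfr_x, tfr_y)
    Gseries = autocov_series_from_spectrum(S, max_lag)
    r = pair.rank
    part = (np.arange(r), np.arange(r, 2 * r))
    n_t, n_f = S.times.size, freqs.size
    I_xy = np.empty((n_t, n_f))
    I_yx = np.empty((n_t, n_f))
    R_xy = np.empty((n_t, n_f))
    R_yx = np.empty((n_t, n_f))
    for t in range(n_t):
        G = AutocovSequence(Gseries[t], S.sfreq, tau=float(S.times[t]))
        fwd = whittle_var(G, order)
        I_yx[t], I_xy[t] = spectral_gc(fwd, freqs, part)
        R_yx[t], R_xy[t] = time_reversed_gc(G, order, freqs, part)
    return trgc_net(I_xy, I_yx, R_xy, R_yx, S.times, freqs, pair=pair.labels)


# ---------------------------------------------------------------------------
# analytic references

def var_autocov(A: np.ndarray, Sigma: np.ndarray, K: int) -> np.ndarray:
    """Closed-form autocovariance G(0..K) of a stable VAR (Lyapunov route)."""
    A = np.asarray(A, float)
    if A.ndim == 2:
        A = A[None]
    p, d, _ = A.shape
    comp = np.zeros((p * d, p * d))
    comp[:d, :] = A.transpose(1, 0, 2).reshape(d, p * d)
    if p > 1:
        comp[d:, :-d] = np.eye(d * (p - 1))
    Q = np.zeros((p * d, p * d))
    Q[:d, :d] = Sigma
    P = scipy.linalg.solve_discrete_lyapunov(comp, Q)
    G = np.empty((K + 1, d, d))
    Pk = np.eye(p * d)
    for k in range(K + 1):
        G[k] = (Pk @ P)[:d, :d]
        Pk = comp @ Pk
    G[0] = 0.5 * (G[0] + G[0].T)
    return G
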