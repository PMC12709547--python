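"""In-memory containers shared across the analysis stages.

All time axes are in milliseconds relative to stimulus onset and must be
uniformly sampled; all data arrays are trial-resolved so that ensemble
(across-trial) averaging remains available to every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceEpochs",
    "ParcelEpochs",
    "TimeFreqRep",
    "SpectralSeries",
]


def _check_times(times: np.ndarray, sfreq: float) -> None:
    times = np.asarray(times, float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D axis with at least 2 samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("times must be uniformly sampled")
    expected = 1000.0 / sfreq
    if not np.isclose(steps[0], expected, rtol=1e-4):
        raise ValueError(
            f"time step {steps[0]:.6g} ms inconsistent with sfreq={sfreq} Hz "
            f"(expected {expected:.6g} ms)"
        )


@dataclass
class SourceEpochs:
    """Latent source time courses: (n_trials, n_sources, n_samples)."""

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 3:
            raise ValueError("SourceEpochs.data must be (trials, sources, samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("data/times length mismatch")
        _check_times(self.times, self.sfreq)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in SourceEpochs.data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]


@dataclass
class ParcelEpochs:
    """Vertex-level multi-trial time courses for one parcel.

    data: (n_trials, n_vertices, n_samples); times in ms.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    parcel: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 3:
            raise ValueError("ParcelEpochs.data must be (trials, vertices, samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("data/times length mismatch")
        _check_times(self.times, self.sfreq)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in ParcelEpochs.data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    def averaged(self) -> "ParcelEpochs":
        """Vertex-averaged copy (single representative channel per parcel)."""
        return ParcelEpochs(
            self.data.mean(axis=1, keepdims=True),
            self.sfreq,
            self.times,
            parcel=self.parcel,
            condition=self.condition,
        )


@dataclass
class TimeFreqRep:
    """Complex Morlet coefficients: (n_trials, n_channels, n_freqs, n_times).

    ``times`` is the decimated analysis grid; ``valid_mask`` flags time points
    farther than half the wavelet support from either epoch edge (False =
    potentially edge-contaminated).
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    cycles_rule: str = "f/2"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, complex)
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if self.coeffs.ndim != 4:
            raise ValueError("coeffs must be (trials, channels, freqs, times)")
        if self.coeffs.shape[2] != self.freqs.size:
            raise ValueError("coeffs/freqs mismatch")
        if self.coeffs.shape[3] != self.times.size:
            raise ValueError("coeffs/times mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.times.size, bool)

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class SpectralSeries:
    """Trial-averaged cross-spectral block matrices S(tau, f).

    S: complex (n_times, n_freqs, d, d) with d = p + q for channel blocks of
    sizes (p, q); Hermitian PSD at every (tau, f).
    """

    S: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    n_trials: int
    block_sizes: tuple[int, int] = field(default=(1, 1))

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, complex)
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if self.S.ndim != 4 or self.S.shape[2] != self.S.shape[3]:
            raise ValueError("S must be (times, freqs, d, d)")
        if self.S.shape[0] != self.times.size or self.S.shape[1] != self.freqs.size:
            raise ValueError("S axes inconsistent with times/freqs grids")
        if sum(self.block_sizes) != self.S.shape[2]:
            raise ValueError("block_sizes must sum to the matrix dimension")
        herm_err = np.max(np.abs(self.S - np.conj(np.swapaxes(self.S, 2, 3))))
        scale = max(np.max(np.abs(self.S)), 1e-30)
        if herm_err > 1e-8 * scale:
            raise ValueError("S is not Hermitian within tolerance")

    @property
    def dim(self) -> int:
        return self.S.shape[2]

    def check_psd(self, tol: float = 1e-10) -> None:
        """Raise if any S(tau, f) has an eigenvalue below -tol * scale."""
        ev = np.linalg.eigvalsh(self.S)
        scale = max(float(np.max(ev)), 1e-30)
        if float(np.min(ev)) < -tol * scale:
            raise ValueError("SpectralSeries is not positive semidefinite")
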