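"""Phase slope index (PSI): coherency-based directed connectivity.

The coherency C_xy(tau, f) = S_xy / sqrt(S_xx S_yy) of a signal pair is
summed across adjacent frequencies within a band F:

    PSI_xy(tau) = Im sum_{f in F'} C_xy*(tau, f) C_xy(tau, f + df),

with F' the band bins excluding the top bin and df the grid step. A
consistent phase slope (fixed time lag) makes the summands line up in the
imaginary direction: positive PSI means x leads y. PSI is left
unnormalized (no division by its standard deviation), so magnitudes are
comparable only within one analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ParcelEpochs, SpectralSeries
from .tfr import morlet_transform, cross_spectral_series, baseline_correct, default_freqs

__all__ = [
    "BandDefinition",
    "CoherencySeries",
    "PsiResult",
    "DEFAULT_BANDS",
    "DEFAULT_WINDOWS",
    "coherency",
    "psi_time_course",
    "seed_map_psi",
    "psi_to_frame",
]


@dataclass
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")

    def bins(self, freqs: np.ndarray) -> np.ndarray:
        """Indices of grid bins inside the (inclusive) band range.

        Shared boundary bins (e.g. 7 Hz for theta and alpha) belong to both
        adjacent bands, per the printed inclusive ranges.
        """
        idx = np.flatnonzero((freqs >= self.f_lo) & (freqs <= self.f_hi))
        if idx.size and np.any(np.diff(idx) != 1):
            raise ValueError(f"band {self.name}: grid bins are not contiguous")
        return idx


# canonical bands of the analysis plus the broadband range
DEFAULT_BANDS = [
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 7.0, 13.0),
    BandDefinition("low_beta", 13.0, 20.0),
    BandDefinition("high_beta", 20.0, 30.0),
    BandDefinition("low_gamma", 30.0, 40.0),
    BandDefinition("broadband", 4.0, 40.0),
]

DEFAULT_WINDOWS = {
    "early": (100.0, 400.0),
    "middle": (400.0, 700.0),
    "late": (700.0, 1100.0),
}


@dataclass
class CoherencySeries:
    """Complex coherency per (tau, f) for one signal pair."""

    C: np.ndarray  # (n_times, n_freqs) complex
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, complex)
        if np.max(np.abs(self.C)) > 1.0 + 1e-9:
            raise ValueError("coherency magnitude exceeds 1")


@dataclass
class PsiResult:
    """PSI time courses per band for one (seed, target) pair."""

    pair: tuple[str, str]
    band_names: list[str]
    times: np.ndarray
    values: np.ndarray  # (n_bands, n_times)
    baselined: bool = False
    window_means: dict = field(default_factory=dict)  # (band, window) -> float


def coherency(series: SpectralSeries) -> CoherencySeries:
    """Normalized cross-spectrum of a 1+1-channel SpectralSeries."""
    if series.dim != 2 or series.block_sizes != (1, 1):
        raise ValueError(
            "coherency is defined for a pair of single-channel blocks; got "
            f"block sizes {series.block_sizes}"
        )
    Sxx = series.S[:, :, 0, 0].real
    Syy = series.S[:, :, 1, 1].real
    bad = (Sxx <= 0) | (Syy <= 0)
    if np.any(bad):
        t_i, f_i = np.argwhere(bad)[0]
        raise ValueError(
            f"zero auto-spectrum at tau={series.times[t_i]:.0f} ms, "
            f"f={series.freqs[f_i]:g} Hz"
        )
    C = series.S[:, :, 0, 1] / np.sqrt(Sxx * Syy)
    # clip float overshoot just above 1 (e.g. self-coherency)
    mag = np.abs(C)
    overshoot = (mag > 1.0) & (mag <= 1.0 + 1e-9)
    C[overshoot] /= mag[overshoot]
    return CoherencySeries(C, series.freqs, series.times)


def psi_time_course(C: CoherencySeries, band: BandDefinition) -> np.ndarray:
    """PSI(tau) over one frequency band (top bin excluded from the sum)."""
    idx = band.bins(C.freqs)
    if idx.size < 2:
        raise ValueError(
            f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) has "
            f"{idx.size} grid bin(s); PSI needs at least 2"
        )
    lower = idx[:-1]
    return np.imag(np.sum(np.conj(C.C[:, lower]) * C.C[:, lower + 1], axis=1))


def seed_map_psi(
    seed: ParcelEpochs,
    targets: list[ParcelEpochs],
    bands: list[BandDefinition] | None = None,
    windows: dict[str, tuple[float, float]] | None = None,
    baseline: tuple[float, float] | None = (-200.0, 0.0),
    freqs: np.ndarray | None = None,
    step_ms: float = 10.0,
) -> dict[str, PsiResult]:
    """Baselined PSI time courses and window means, seed vs. each target.

    Wavelet input is the vertex-averaged parcel time course per trial.
    Positive values mean the seed leads the target.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    windows = windows if windows is not None else DEFAULT_WINDOWS
    if freqs is None:
        freqs = default_freqs()
    tfr_seed = morlet_transform(seed.averaged(), freqs, step_ms)
    out: dict[str, PsiResult] = {}
    for target in targets:
        if not np.array_equal(target.times, seed.times):
            raise ValueError(f"target {target.parcel}: time grid differs from seed")
        tfr_t = morlet_transform(target.averaged(), freqs, step_ms)
        C = coherency(cross_spectral_series(tfr_seed, tfr_t))
        values = np.stack([psi_time_course(C, b) for b in bands])
        if baseline is not None:
            values = baseline_correct(values, C.times, baseline)
        means = {}
        for b_i, b in enumerate(bands):
            for wname, (lo, hi) in windows.items():
                m = (C.times >= lo) & (C.times <= hi)
                means[(b.name, wname)] = float(values[b_i, m].mean())
        out[target.parcel] = PsiResult(
            pair=(seed.parcel, target.parcel),
            band_names=[b.name for b in bands],
            times=C.times,
            values=values,
            baselined=baseline is not None,
            window_means=means,
        )
    return out


def psi_to_frame(results: dict[str, PsiResult]):
    """Long-format window means: columns pair, band, window, value."""
    import pandas as pd

    rows = [
        {"seed": r.pair[0], "target": r.pair[1], "band": band,
         "window": window, "value": v}
        for r in results.values()
        for (band, window), v in r.window_means.items()
    ]
    return pd.DataFrame(rows)
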