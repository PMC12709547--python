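"""Morlet wavelet decomposition and trial-averaged cross-spectra.

Common substrate of both connectivity metrics: trial data are decomposed
with complex Morlet wavelets (default 4-40 Hz in 1-Hz steps, number of
cycles = f/2, analysis grid decimated to 10-ms steps) and cross/auto
spectra are formed as ensemble (across-trial) averages of coefficient
outer products, preserving full time resolution.

With the cycles = f/2 rule the wavelet duration n_cycles/f is 0.5 s at
every frequency, i.e. constant temporal smoothing (~80 ms Gaussian SD)
across the whole grid.
"""

from __future__ import annotations

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import ParcelEpochs, TimeFreqRep, SpectralSeries

__all__ = [
    "default_freqs",
    "morlet_transform",
    "cross_spectral_series",
    "baseline_correct",
]


def default_freqs(f_lo: float = 4.0, f_hi: float = 40.0, df: float = 1.0) -> np.ndarray:
    return np.arange(f_lo, f_hi + 0.5 * df, df)


def morlet_transform(
    epochs: ParcelEpochs,
    freqs: np.ndarray | None = None,
    step_ms: float = 10.0,
    cycles_rule: str = "f/2",
) -> TimeFreqRep:
    """Complex Morlet coefficients per trial, channel, frequency, time step.

    The number of cycles at frequency f is f/2 (``cycles_rule="f/2"``) or a
    fixed count (e.g. ``"7"``). Wavelets are L2-normalized (unit energy), so
    power is comparable across frequencies. The analysis grid is the epoch
    time axis decimated to ``step_ms``; ``valid_mask`` flags points at least
    half a wavelet support away from both epoch edges.
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, float)
    nyq = epochs.sfreq / 2.0
    if np.any(freqs >= nyq) or np.any(freqs <= 0):
        bad = freqs[(freqs >= nyq) | (freqs <= 0)]
        raise ValueError(f"frequencies {bad} outside (0, Nyquist={nyq} Hz)")

    if cycles_rule == "f/2":
        n_cycles = freqs / 2.0
    else:
        n_cycles = float(cycles_rule) * np.ones_like(freqs)

    # wavelet support n_cycles/f must fit in the epoch
    support_s = n_cycles / freqs
    epoch_s = (epochs.times[-1] - epochs.times[0]) / 1000.0
    too_long = support_s > epoch_s
    if np.any(too_long):
        f_bad = freqs[too_long][0]
        raise ValueError(
            f"epoch ({epoch_s:.3f} s) shorter than wavelet support at {f_bad} Hz"
        )

    decim_f = step_ms * epochs.sfreq / 1000.0
    decim = int(round(decim_f))
    if decim < 1 or abs(decim - decim_f) > 1e-9:
        raise ValueError(
            f"step_ms={step_ms} is not an integer multiple of the sample "
            f"period ({1000.0 / epochs.sfreq:.6g} ms)"
        )

    coeffs = tfr_array_morlet(
        epochs.data,
        sfreq=epochs.sfreq,
        freqs=freqs,
        n_cycles=n_cycles,
        output="complex",
        decim=decim,
        zero_mean=True,
    )
    times = epochs.times[::decim]
    half_support_ms = 500.0 * float(np.max(support_s))
    valid = (times >= epochs.times[0] + half_support_ms) & (
        times <= epochs.times[-1] - half_support_ms
    )
    return TimeFreqRep(coeffs, freqs, times, epochs.sfreq,
                       cycles_rule=cycles_rule, valid_mask=valid)


def cross_spectral_series(tfr_x: TimeFreqRep, tfr_y: TimeFreqRep) -> SpectralSeries:
    """Trial-averaged Hermitian block cross-spectral matrices S(tau, f).

    Channels of x and y are stacked into one block vector W(tau, f) and
    S(tau, f) = <W W^H> is averaged across trials only, so the time axis is
    preserved. Includes the auto-blocks Sxx, Syy on the diagonal.
    """
    if tfr_x.n_trials != tfr_y.n_trials:
        raise ValueError(
            f"trial counts differ: {tfr_x.n_trials} vs {tfr_y.n_trials}"
        )
    if not np.array_equal(tfr_x.freqs, tfr_y.freqs):
        raise ValueError("frequency grids differ between the two TFRs")
    if not np.array_equal(tfr_x.times, tfr_y.times):
        raise ValueError("time grids differ between the two TFRs")

    W = np.concatenate([tfr_x.coeffs, tfr_y.coeffs], axis=1)
    # S[tau, f] = mean_trials W W^H  -> (times, freqs, d, d)
    S = np.einsum("tcfn,tdfn->nfcd", W, np.conj(W)) / W.shape[0]
    S = 0.5 * (S + np.conj(np.swapaxes(S, 2, 3)))  # exact Hermitian symmetry
    return SpectralSeries(
        S, tfr_x.freqs, tfr_x.times, tfr_x.sfreq,
        n_trials=tfr_x.n_trials,
        block_sizes=(tfr_x.n_channels, tfr_y.n_channels),
    )


def baseline_correct(
    values: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
) -> np.ndarray:
    """Subtract the mean over the baseline time points (time = last axis).

    Applied independently per leading axis (frequency, band, subject, ...).
    """
    times = np.asarray(times, float)
    lo, hi = baseline_window
    mask = (times >= lo) & (times <= hi)
    if not np.any(mask):
        raise ValueError(
            f"baseline window {baseline_window} does not overlap the time axis "
            f"({times[0]:.0f}..{times[-1]:.0f} ms)"
        )
    values = np.asarray(values, float)
    return values - values[..., mask].mean(axis=-1, keepdims=True)
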