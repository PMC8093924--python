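"""Event-related spectral perturbation (ERSP) maps and band summaries.

ERSP quantifies stimulus-locked changes in oscillatory power: Morlet
wavelet power is computed per trial, averaged across trials, then
expressed in dB relative to the mean pre-stimulus baseline power of each
frequency:

    ERSP(t, f) = 10 log10( P(t, f) / mean_{t in baseline} P(t, f) )

The time grid follows a sliding-window convention: a 1-s analysis window
advanced in 25-ms steps across the 4-s epoch, each map column stamped at
the window center, with the final endpoint dropped so the position count
is (T_epoch - T_window) / step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .synthio import SourceEpochs

__all__ = [
    "TimeFreqMap",
    "BandWindowSpec",
    "ErspConfig",
    "compute_ersp",
    "baseline_normalize",
    "band_window_mean",
    "DEFAULT_BASELINE_MS",
]

#: pre-stimulus baseline window (ms) excluding the epoch edge and the
#: immediate pre-stimulus period
DEFAULT_BASELINE_MS = (-550.0, -50.0)


@dataclass
class TimeFreqMap:
    """A times x frequencies grid of power (linear) or dB values.

    ``values[t, f]`` corresponds to window center ``times[t]`` (ms) and
    frequency ``freqs[f]`` (Hz).  ``baseline_window`` is set once the map
    has been baseline-normalized (values then in dB).
    """

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("times and freqs must be strictly increasing")
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError("values must be times x freqs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in time-frequency map")


@dataclass(frozen=True)
class BandWindowSpec:
    """Named frequency bands (Hz) and analysis windows (ms).

    Defaults: theta 4-7, alpha 8-12, low beta 13-20, high beta 20-30 Hz;
    stimulus-presentation window 0-200 ms and conflict-resolution /
    response-preparation window 250-600 ms.  Band edges are inclusive, so
    a pixel centered exactly at 20 Hz contributes to both beta bands.
    """

    bands: dict = field(
        default_factory=lambda: {
            "theta": (4.0, 7.0),
            "alpha": (8.0, 12.0),
            "low_beta": (13.0, 20.0),
            "high_beta": (20.0, 30.0),
        }
    )
    windows: dict = field(
        default_factory=lambda: {
            "early": (0.0, 200.0),
            "late": (250.0, 600.0),
        }
    )

    def __post_init__(self):
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo <= hi):
                raise ValueError(f"band {name} edges must be positive, lo <= hi")
        for name, (lo, hi) in self.windows.items():
            if lo > hi:
                raise ValueError(f"window {name} is empty")


@dataclass(frozen=True)
class ErspConfig:
    """Time-frequency analysis settings.

    ``cycles`` = (c0, expansion): wavelet cycles grow linearly with
    frequency from c0 at the lowest frequency to
    c0 * expansion * (f_max / f_min) at the highest (EEGLAB-style
    [3, 0.5] default).  The frequency grid is linear 2-50 Hz at 1 Hz.
    """

    window_ms: float = 1000.0
    step_ms: float = 25.0
    freqs: tuple = tuple(np.arange(2.0, 51.0))
    cycles: tuple[float, float] = (3.0, 0.5)

    def n_cycles(self) -> np.ndarray:
        f = np.asarray(self.freqs, dtype=float)
        f0, f1 = f[0], f[-1]
        c0, expand = self.cycles
        if f1 == f0:
            return np.full_like(f, c0)
        c_hi = c0 * expand * (f1 / f0)
        return c0 + (f - f0) / (f1 - f0) * (c_hi - c0)


def compute_ersp(
    epochs: SourceEpochs,
    source: int,
    condition: np.ndarray | None = None,
    config: ErspConfig | None = None,
) -> TimeFreqMap:
    """Trial-averaged Morlet power for one source on the sliding grid.

    ``condition`` is an optional boolean trial filter (e.g. correct
    incongruent trials).  Power is averaged across trials *before* any
    baseline normalization; the returned map is linear power (call
    :func:`baseline_normalize` for dB).
    """
    cfg = config if config is not None else ErspConfig()
    freqs = np.asarray(cfg.freqs, dtype=float)
    if np.max(freqs) > epochs.fs / 2:
        raise ValueError("max frequency exceeds Nyquist")
    data = epochs.activations[source]
    if condition is not None:
        data = data[:, np.asarray(condition)]
    n_trials = data.shape[1]
    if n_trials < 8:
        raise ValueError(f"need at least 8 trials after filtering, got {n_trials}")

    # (n_epochs, n_channels=1, n_times) layout for the wavelet transform
    x = data.T[:, None, :]
    power = tfr_array_morlet(
        x, sfreq=epochs.fs, freqs=freqs, n_cycles=cfg.n_cycles(), output="power"
    )  # (n_trials, 1, F, T)
    mean_power = power[:, 0].mean(axis=0)  # (F, T)

    fs = epochs.fs
    epoch_ms = epochs.n_samples * 1000.0 / fs
    # position count in ms arithmetic, final endpoint dropped
    n_positions = int((epoch_ms - cfg.window_ms) / cfg.step_ms)
    if n_positions < 1:
        raise ValueError("epoch shorter than one analysis window")
    center_offsets_ms = np.arange(n_positions) * cfg.step_ms + cfg.window_ms / 2.0
    centers = np.round(center_offsets_ms * fs / 1000.0).astype(int)
    t0 = epochs.epoch_window[0]
    times_ms = t0 + center_offsets_ms

    values = mean_power[:, centers].T  # (T_positions, F)
    return TimeFreqMap(times=times_ms, freqs=freqs, values=values)


def baseline_normalize(
    tf: TimeFreqMap, baseline: tuple[float, float] = DEFAULT_BASELINE_MS
) -> TimeFreqMap:
    """Convert a linear-power map to dB relative to its baseline mean.

    Per frequency: value(t, f) <- 10 log10( power(t, f) / mean baseline
    power(f) ), the mean taken over map columns whose center time lies in
    ``baseline`` (inclusive).
    """
    lo, hi = baseline
    sel = (tf.times >= lo) & (tf.times <= hi)
    if not np.any(sel):
        raise ValueError("baseline window not covered by the map's time grid")
    base = tf.values[sel].mean(axis=0)  # (F,)
    if np.any(base <= 0):
        raise ValueError("zero or negative baseline power: degenerate input")
    db = 10.0 * np.log10(tf.values / base[None, :])
    return replace(tf, values=db, baseline_window=(float(lo), float(hi)))


def band_window_mean(
    tf: TimeFreqMap, band: tuple[float, float], window: tuple[float, float]
) -> float:
    """Unweighted mean over pixels inside a band x window box (inclusive)."""
    fsel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    tsel = (tf.times >= window[0]) & (tf.times <= window[1])
    if not (np.any(fsel) and np.any(tsel)):
        raise ValueError("band/window box contains no pixels")
    return float(tf.values[np.ix_(tsel, fsel)].mean())
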