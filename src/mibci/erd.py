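"""ERD/ERS time-frequency maps: percent band-power change from baseline.

For one channel and one class, each frequency row is obtained by
narrowband-filtering the epochs (2-Hz band centered on f, zero-phase),
squaring, averaging across the class's trials, and smoothing with a 250-ms
moving average; the value is the percent change relative to the mean power
over the pre-cue baseline interval,

    value(t, f) = 100 (P(t, f) - R(f)) / R(f),  R(f) = mean_{t in baseline} P(t, f).

Negative values are event-related desynchronization (contralateral mu
suppression during imagery), positive values synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epoching import EpochSet
from .recording import Label

#: Moving-average smoothing window (s) applied to instantaneous power.
SMOOTH_S = 0.25
#: Half-width (Hz) of the per-frequency analysis band.
BAND_HALFWIDTH = 1.0

DEFAULT_FREQS = tuple(float(f) for f in range(8, 31, 2))

__all__ = ["ERDSMap", "erds_map", "erds_summary", "DEFAULT_FREQS"]


@dataclass(frozen=True)
class ERDSMap:
    """Percent power change, time x frequency, for one channel and class."""

    channel: str
    times: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)  # (n_times, n_freqs)
    label: Label | None = None

    def to_frame(self) -> pd.DataFrame:
        """Grid as a DataFrame (index: time s, columns: frequency Hz)."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(np.round(self.times, 4), name="time_s"),
            columns=pd.Index(self.freqs, name="freq_hz"),
        )


def erds_map(
    epochs: EpochSet,
    channel: str,
    freqs: tuple[float, ...] = DEFAULT_FREQS,
    baseline: tuple[float, float] = (-2.0, 0.0),
    label: Label | str | None = None,
) -> ERDSMap:
    """ERD/ERS map of one channel for one class's trials.

    ``label`` selects the class when the epoch set contains both; epochs
    already restricted to one class may omit it.  The baseline interval
    must lie within the epoch span and carry nonzero power.
    """
    if label is not None:
        epochs = epochs.restrict(Label(label))
    elif len(set(epochs.labels)) > 1:
        raise ValueError("epochs contain both classes; pass label=...")
    if epochs.n_trials == 0:
        raise ValueError("no trials for the requested class")
    if not epochs.channel_names:
        raise ValueError("epoch set carries no channel names")
    ci = list(epochs.channel_names).index(channel) if channel in epochs.channel_names else -1
    if ci < 0:
        raise KeyError(f"channel {channel!r} not in the epoch set")

    fs = epochs.fs
    times = epochs.time0 + np.arange(epochs.n_samples) / fs
    b_lo, b_hi = baseline
    bmask = (times >= b_lo) & (times < b_hi)
    if not np.any(bmask):
        raise ValueError("baseline interval lies outside the epoch span")

    x = epochs.data[:, ci, :]  # trials x samples
    smooth_n = max(1, int(round(SMOOTH_S * fs)))
    kernel = np.ones(smooth_n) / smooth_n
    values = np.empty((epochs.n_samples, len(freqs)))
    for fi, f0 in enumerate(freqs):
        sos = signal.butter(
            4,
            [f0 - BAND_HALFWIDTH, f0 + BAND_HALFWIDTH],
            btype="bandpass",
            fs=fs,
            output="sos",
        )
        # generous reflect padding: the 2-Hz band's ring-down is ~0.5 s,
        # far beyond sosfiltfilt's default pad length
        padlen = min(x.shape[1] - 1, int(3 * fs))
        power = signal.sosfiltfilt(sos, x, axis=1, padlen=padlen) ** 2
        mean_power = power.mean(axis=0)
        smoothed = np.convolve(mean_power, kernel, mode="same")
        ref = smoothed[bmask].mean()
        if ref <= 0:
            raise ValueError(f"zero baseline power at {f0:g} Hz")
        values[:, fi] = 100 * (smoothed - ref) / ref
    return ERDSMap(
        channel=channel,
        times=times,
        freqs=np.asarray(freqs, dtype=float),
        values=values,
        label=Label(label) if label is not None else epochs.labels[0],
    )


def erds_summary(
    emap: ERDSMap, band: tuple[float, float], interval: tuple[float, float]
) -> float:
    """Mean percent power change over a time-frequency box."""
    tmask = (emap.times >= interval[0]) & (emap.times < interval[1])
    fmask = (emap.freqs >= band[0]) & (emap.freqs <= band[1])
    if not np.any(tmask) or not np.any(fmask):
        raise ValueError("requested time-frequency box is empty")
    return float(emap.values[np.ix_(tmask, fmask)].mean())
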