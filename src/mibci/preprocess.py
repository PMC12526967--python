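"""Temporal filtering and common-average referencing.

The processing chain for each continuous recording is: 8-30 Hz 4th-order
Butterworth band-pass -> 3rd-order Butterworth band-stop notches at the
50/60 Hz power lines -> common average reference (CAR).  All filters are
applied zero-phase (forward-backward), so the effective magnitude response
is the square of the single-pass response; filtering happens on the
continuous signal before epoching so no startup transient lands inside an
analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import RawRecording

__all__ = ["FilterSpec", "bandpass", "notch", "car", "preprocess"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass and notch parameters.

    ``band_low``/``band_high`` bound the mu-beta pass band in Hz,
    ``band_order`` the Butterworth order of the band-pass.  Each frequency
    in ``notch_freqs`` gets an order-``notch_order`` Butterworth band-stop
    of half-width ``notch_halfwidth`` Hz.
    """

    band_low: float = 8.0
    band_high: float = 30.0
    band_order: int = 4
    notch_freqs: tuple[float, ...] = (50.0, 60.0)
    notch_order: int = 3
    notch_halfwidth: float = 2.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        if not 0 < self.band_low < self.band_high < nyq:
            raise ValueError(
                f"band edges ({self.band_low}, {self.band_high}) must satisfy "
                f"0 < low < high < Nyquist ({nyq:g} Hz)"
            )
        for f in self.notch_freqs:
            if f + self.notch_halfwidth >= nyq:
                raise ValueError(f"notch at {f:g} Hz exceeds Nyquist ({nyq:g} Hz)")


def _sos_filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase Butterworth band-pass of each channel independently."""
    spec.validate(rec.fs)
    sos = signal.butter(
        spec.band_order,
        [spec.band_low, spec.band_high],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    return rec.with_data(_sos_filtfilt(sos, rec.data))


def notch(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase band-stop at each power-line frequency, cascaded."""
    spec.validate(rec.fs)
    data = rec.data
    for f in spec.notch_freqs:
        sos = signal.butter(
            spec.notch_order,
            [f - spec.notch_halfwidth, f + spec.notch_halfwidth],
            btype="bandstop",
            fs=rec.fs,
            output="sos",
        )
        data = _sos_filtfilt(sos, data)
    return rec.with_data(data)


def car(rec: RawRecording) -> RawRecording:
    """Common average reference: subtract the instantaneous mean over channels.

    At every sample the mean across all N electrodes is removed from each
    electrode, leaving a zero channel-sum.  Requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def preprocess(
    rec: RawRecording, spec: FilterSpec = FilterSpec(), apply_car: bool = True
) -> RawRecording:
    """Full chain: band-pass -> notch -> (optionally) CAR."""
    out = notch(bandpass(rec, spec), spec)
    return car(out) if apply_car else out
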