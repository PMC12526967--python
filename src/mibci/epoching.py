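"""Epoch extraction and the sliding analysis-window grid.

Each trial spans [-2, +7) s around the MI cue (2 s pre-cue baseline, 5 s
imagery, 2 s post interval; 2250 samples at 250 Hz).  Analysis windows of
length T (2 or 3 s) slide across the trial in 0.2-s steps; the grid is
computed in integer samples so window positions are exact at fs = 250.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import (
    EPOCH_LEN_S,
    EPOCH_START_S,
    EPOCH_STOP_S,
    Label,
    Paradigm,
    RawRecording,
)

__all__ = ["EpochSet", "WindowGrid", "extract_epochs", "window_grid", "slice_window"]


@dataclass(frozen=True)
class EpochSet:
    """Trials x channels x samples with class labels.

    ``time0`` is the cue-relative time of the first sample (-2 s for full
    trials; window slices carry their own offset).  ``paradigm`` is a
    per-trial tag.
    """

    data: np.ndarray = field(repr=False)
    labels: tuple[Label, ...]
    fs: float
    time0: float = EPOCH_START_S
    paradigm: tuple[Paradigm, ...] = ()
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", tuple(Label(x) for x in self.labels))
        object.__setattr__(self, "paradigm", tuple(Paradigm(x) for x in self.paradigm))
        if data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.labels) != data.shape[0]:
            raise ValueError("one label per trial required")
        if self.paradigm and len(self.paradigm) != data.shape[0]:
            raise ValueError("paradigm tags must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def label_array(self) -> np.ndarray:
        """Boolean array: True where the trial is RIGHT-hand imagery."""
        return np.array([lbl is Label.RIGHT for lbl in self.labels])

    def class_counts(self) -> dict[Label, int]:
        return {
            lbl: sum(1 for x in self.labels if x is lbl)
            for lbl in (Label.LEFT, Label.RIGHT)
        }

    def select(self, idx: np.ndarray) -> "EpochSet":
        """Subset of trials (labels and tags follow)."""
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            labels=tuple(self.labels[i] for i in np.atleast_1d(idx)),
            paradigm=tuple(self.paradigm[i] for i in np.atleast_1d(idx))
            if self.paradigm
            else (),
        )

    def restrict(self, label: Label | str) -> "EpochSet":
        """Trials of one class only."""
        label = Label(label)
        idx = np.flatnonzero([x is label for x in self.labels])
        return self.select(idx)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window start times (cue-relative seconds) for one length T."""

    T: float
    step: float
    starts: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.starts)


def extract_epochs(rec: RawRecording) -> EpochSet:
    """Cut the continuous recording into one 9-s trial per event.

    Sample window per event: ``[onset - 2 fs, onset + 7 fs)`` (half-open).
    Labels and paradigm tags are copied from the event table in event order.
    Trials containing non-finite samples are rejected with a warning.
    """
    if rec.events is None or len(rec.events) == 0:
        return EpochSet(
            data=np.empty((0, rec.n_channels, int(round(EPOCH_LEN_S * rec.fs)))),
            labels=(),
            fs=rec.fs,
            channel_names=rec.montage.channel_names,
        )
    pre = int(round(-EPOCH_START_S * rec.fs))
    post = int(round(EPOCH_STOP_S * rec.fs))
    trials, labels, paradigms = [], [], []
    for i, onset in enumerate(rec.events.onsets):
        lo, hi = int(onset) - pre, int(onset) + post
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"event {i} (sample {int(onset)}) does not fit the epoch span"
            )
        seg = rec.data[:, lo:hi]
        if not np.all(np.isfinite(seg)):
            warnings.warn(f"dropping trial {i}: non-finite samples", stacklevel=2)
            continue
        trials.append(seg)
        labels.append(rec.events.labels[i])
        paradigms.append(rec.events.paradigm[i])
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.n_channels, pre + post))
    )
    return EpochSet(
        data=data,
        labels=tuple(labels),
        fs=rec.fs,
        paradigm=tuple(paradigms),
        channel_names=rec.montage.channel_names,
    )


def window_grid(
    T: float,
    step: float = 0.2,
    span: tuple[float, float] = (EPOCH_START_S, EPOCH_STOP_S),
    fs: float = 250.0,
) -> WindowGrid:
    """Enumerate window start times: span start, stepping until start + T > span end.

    Computed in integer samples (``step_samples = round(step * fs)``) to keep
    positions exact; at fs = 250 a 0.2-s step is exactly 50 samples.
    """
    lo, hi = span
    if T > hi - lo:
        raise ValueError(f"window length {T} s exceeds the epoch span {hi - lo} s")
    if step <= 0:
        raise ValueError("step must be positive")
    step_n = int(round(step * fs))
    T_n = int(round(T * fs))
    span_n = int(round((hi - lo) * fs))
    starts = [lo + k * step_n / fs for k in range(0, (span_n - T_n) // step_n + 1)]
    return WindowGrid(T=T, step=step, starts=tuple(starts))


def slice_window(epochs: EpochSet, start: float, T: float) -> EpochSet:
    """View of all trials restricted to the window [start, start + T) s."""
    lo = int(round((start - epochs.time0) * epochs.fs))
    hi = lo + int(round(T * epochs.fs))
    if lo < 0 or hi > epochs.n_samples:
        raise ValueError(
            f"window [{start:g}, {start + T:g}) s lies outside the epoch span"
        )
    return replace(epochs, data=epochs.data[:, :, lo:hi], time0=start)
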