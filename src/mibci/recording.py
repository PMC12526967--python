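"""Continuous multichannel EEG recordings and their event tables."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .montage import Montage, default_montage

#: Cue-relative epoch span in seconds: 2 s pre-cue baseline, 5 s motor
#: imagery, 2 s post interval.
EPOCH_START_S = -2.0
EPOCH_STOP_S = 7.0
EPOCH_LEN_S = EPOCH_STOP_S - EPOCH_START_S  # 9 s trials


class Label(str, Enum):
    """Imagined hand."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Paradigm(str, Enum):
    """Cue presentation style during acquisition."""

    ARROW = "ARROW"
    PICTURE = "PICTURE"
    VIDEO = "VIDEO"


@dataclass(frozen=True)
class EventTable:
    """Cue events of one session.

    ``onsets`` are 0-based sample indices of the MI cue trigger (the instant
    the arrow/picture/video appears), strictly increasing.  ``labels`` holds
    the imagined hand per event; ``paradigm`` tags each event with its
    acquisition paradigm. ``run_id`` identifies the session/run.
    """

    onsets: np.ndarray = field(repr=False)
    labels: tuple[Label, ...]
    paradigm: tuple[Paradigm, ...]
    run_id: str = "run1"

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=np.int64)
        object.__setattr__(self, "onsets", onsets)
        labels = tuple(Label(lbl) for lbl in self.labels)
        object.__setattr__(self, "labels", labels)
        paradigm = tuple(Paradigm(p) for p in self.paradigm)
        object.__setattr__(self, "paradigm", paradigm)
        if onsets.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if len(labels) != onsets.size or len(paradigm) != onsets.size:
            raise ValueError("onsets, labels and paradigm must have equal length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class RawRecording:
    """Continuous EEG: channels x samples potentials in microvolts.

    Invariants: the data row count equals the montage channel count, the
    sampling rate is positive, and every event leaves room for the full
    9-s epoch (2 s before the cue to 7 s after) inside the recording.
    """

    data: np.ndarray = field(repr=False)
    fs: float = 250.0
    montage: Montage = field(default_factory=default_montage)
    events: EventTable | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.events is not None:
            self._check_events(self.events)

    def _check_events(self, events: EventTable) -> None:
        pre = int(round(-EPOCH_START_S * self.fs))
        post = int(round(EPOCH_STOP_S * self.fs))
        for i, onset in enumerate(events.onsets):
            if onset - pre < 0 or onset + post > self.n_samples:
                raise ValueError(
                    f"event {i} at sample {int(onset)} leaves no room for the "
                    f"[{EPOCH_START_S:g}, {EPOCH_STOP_S:g}) s epoch"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "RawRecording":
        """Copy of the recording with ``data`` replaced (same shape)."""
        return replace(self, data=data)
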