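"""Electrode montage for the 16-channel motor-cortex recording layout.

The default montage covers the sensorimotor strip of the international 10/20
system (frontocentral, central and centroparietal rows plus Pz).  Positions
are unitless 2-D scalp coordinates under the head-circle convention (vertex
Cz at the origin, unit-radius head outline), sufficient for topographic
export; they are not a volume-conduction model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel order of the study montage (left-to-right within each row).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FC3", "FCz", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "Pz",
)

# Approximate 10/20 head-circle coordinates (x: left negative, y: front positive).
_DEFAULT_POSITIONS: dict[str, tuple[float, float]] = {
    "FC3": (-0.30, 0.25), "FCz": (0.0, 0.25), "FC4": (0.30, 0.25),
    "C5": (-0.50, 0.0), "C3": (-0.30, 0.0), "C1": (-0.10, 0.0),
    "Cz": (0.0, 0.0), "C2": (0.10, 0.0), "C4": (0.30, 0.0), "C6": (0.50, 0.0),
    "CP3": (-0.30, -0.25), "CP1": (-0.10, -0.25), "CPz": (0.0, -0.25),
    "CP2": (0.10, -0.25), "CP4": (0.30, -0.25),
    "Pz": (0.0, -0.50),
}


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with 2-D scalp positions.

    Parameters
    ----------
    channel_names
        Unique channel labels, in recording order.
    positions
        ``(n_channels, 2)`` array of head-circle coordinates; every position
        must lie within the unit circle.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions must have shape ({len(names)}, 2), got {pos.shape}"
            )
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(radii > 1.0 + 1e-12):
            bad = names[int(np.argmax(radii))]
            raise ValueError(f"channel {bad} lies outside the unit head circle")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        """Return the row index of channel ``name``."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]


def default_montage() -> Montage:
    """The 16-channel sensorimotor montage used throughout the package."""
    pos = np.array([_DEFAULT_POSITIONS[ch] for ch in DEFAULT_CHANNELS])
    return Montage(DEFAULT_CHANNELS, pos)
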