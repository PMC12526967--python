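"""Synthetic motor-imagery EEG sessions with planted contralateral ERD.

The generator emulates the study protocol: a continuous 16-channel, 250 Hz
recording containing 40 trials per class in randomized order, each trial a
9-s structure (2 s pre-cue baseline, cue at t = 0, 5 s imagery interval,
2 s post interval) separated by a 2-3 s inter-trial gap.  The signal model
is

    x(t) = M s(t) + pink noise + line noise,

with two amplitude-modulated narrowband sources (a mu oscillation near
10 Hz plus a weaker beta harmonic) located over the left and right hand
areas (near C3 and C4) and mixed onto the montage through a
Gaussian-distance gain matrix M.  During the imagery interval the source
contralateral to the imagined hand is attenuated by a factor (1 - depth)
— the event-related desynchronization — with 200-ms raised-cosine ramps at
the interval edges so the gating itself adds no broadband transient.  The
ipsilateral source is unmodulated by default (an optional ERS gain is
available).  Pink (1/f power) background noise mimics the EEG spectrum and
a low-amplitude 50 Hz line component exercises the notch stage.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import Montage, default_montage
from .recording import EventTable, Label, Paradigm, RawRecording

__all__ = [
    "SimulationConfig",
    "SourceModel",
    "mixing_matrix",
    "simulate_session",
    "simulate_multirun",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic session.

    ``erd_depth_*`` are fractional amplitude attenuations in [0, 1] applied
    to the named source during contralateral imagery; ``snr`` is the ratio
    of oscillatory source power to pink-noise power at the source's nearest
    channel.  ``inter_trial_gap`` bounds the uniform gap (s) between the end
    of one trial and the pre-cue baseline of the next.
    """

    fs: float = 250.0
    n_trials_per_class: int = 40
    paradigm: str = "ARROW"
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    beta_amplitude: float = 0.4
    erd_depth_left_source: float = 0.7
    erd_depth_right_source: float = 0.7
    ers_gain_ipsilateral: float = 0.0
    snr: float = 2.0
    noise_rms_uv: float = 10.0
    line_noise_amplitude_uv: float = 1.0
    line_noise_freq: float = 50.0
    inter_trial_gap: tuple[float, float] = (2.0, 3.0)
    ramp_s: float = 0.2
    falloff: float = 0.3
    max_duration_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("erd_depth_left_source", "erd_depth_right_source"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        Paradigm(self.paradigm.upper())  # validates the tag

    def save(self, path: str | Path) -> None:
        """Serialize as a flat key=value file."""
        with open(path, "w") as fh:
            for f_ in dataclasses.fields(self):
                v = getattr(self, f_.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f_.name}={v}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs: dict = {}
        for f_ in dataclasses.fields(cls):
            if f_.name not in kv:
                continue
            raw = kv[f_.name]
            if f_.name == "inter_trial_gap":
                lo, hi = raw.split(",")
                kwargs[f_.name] = (float(lo), float(hi))
            elif f_.name == "paradigm":
                kwargs[f_.name] = raw
            elif f_.name in ("n_trials_per_class", "seed"):
                kwargs[f_.name] = int(raw)
            else:
                kwargs[f_.name] = float(raw)
        return cls(**kwargs)


@dataclass(frozen=True)
class SourceModel:
    """Source coordinates and the sources -> channels gain matrix."""

    source_positions: np.ndarray
    mixing: np.ndarray = field(repr=False)


def mixing_matrix(
    montage: Montage, source_positions: np.ndarray, falloff: float
) -> np.ndarray:
    """Gaussian-distance gain matrix, channels x sources.

    ``gain[c, s] = exp(-d(c, s)^2 / (2 falloff^2))``: nonnegative, maximal at
    the channel nearest each source, and monotonically decaying with
    distance.  Deterministic.
    """
    if falloff <= 0:
        raise ValueError("falloff length scale must be positive")
    pos = np.asarray(source_positions, dtype=float).reshape(-1, 2)
    if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.0 + 1e-12):
        raise ValueError("source positions must lie inside the unit head circle")
    d2 = ((montage.positions[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2 * falloff**2))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-power noise, unit RMS per channel (FFT amplitude shaping)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    return pink / pink.std(axis=1, keepdims=True)


def _narrowband(
    rng: np.random.Generator, n_samples: int, fs: float, f0: float, halfwidth: float = 1.0
) -> np.ndarray:
    """Unit-variance narrowband Gaussian oscillation centered on f0."""
    sos = signal.butter(
        4, [f0 - halfwidth, f0 + halfwidth], btype="bandpass", fs=fs, output="sos"
    )
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def _raised_cosine_gate(
    n_samples: int,
    fs: float,
    intervals: list[tuple[float, float, float]],
    ramp_s: float,
) -> np.ndarray:
    """Unity envelope with smooth excursions to ``1 - depth`` per interval.

    Each entry of ``intervals`` is (t_on, t_off, depth) in seconds; the gate
    descends/ascends with raised-cosine ramps of length ``ramp_s`` placed
    inside the interval.
    """
    env = np.ones(n_samples)
    t = np.arange(n_samples) / fs
    for t_on, t_off, depth in intervals:
        if depth == 0:
            continue
        core = (t >= t_on + ramp_s) & (t < t_off - ramp_s)
        env[core] *= 1 - depth
        down = (t >= t_on) & (t < t_on + ramp_s)
        phase = (t[down] - t_on) / ramp_s
        env[down] *= 1 - depth * (1 - np.cos(np.pi * phase)) / 2
        up = (t >= t_off - ramp_s) & (t < t_off)
        phase = (t[up] - (t_off - ramp_s)) / ramp_s
        env[up] *= 1 - depth * (1 + np.cos(np.pi * phase)) / 2
    return env


@dataclass(frozen=True)
class SimulationInternals:
    """Pre-mixing pieces of a simulated session, for inspection and tests."""

    source_model: SourceModel
    sources_raw: np.ndarray  # 2 x samples, before ERD gating, unit scale
    envelopes: np.ndarray  # 2 x samples amplitude gates
    amplitudes: np.ndarray  # per-source scale factors (uV)
    cue_times: np.ndarray  # seconds


def _schedule(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Cue times (s): trials back to back with uniform inter-trial gaps."""
    n = 2 * config.n_trials_per_class
    gaps = rng.uniform(*config.inter_trial_gap, size=n - 1)
    cues = np.empty(n)
    cues[0] = 2.0  # leave the pre-cue baseline of the first trial
    for k in range(1, n):
        cues[k] = cues[k - 1] + 9.0 + gaps[k - 1]
    return cues


def _simulate(
    config: SimulationConfig, montage: Montage, rng: np.random.Generator, run_id: str
) -> tuple[RawRecording, SimulationInternals]:
    n = 2 * config.n_trials_per_class
    labels = [Label.LEFT] * config.n_trials_per_class + [
        Label.RIGHT
    ] * config.n_trials_per_class
    labels = [labels[i] for i in rng.permutation(n)]
    cues = _schedule(config, rng)
    duration = cues[-1] + 7.0 + 1.0
    if duration > config.max_duration_s:
        raise ValueError(
            f"session of {duration:.0f} s exceeds max_duration_s="
            f"{config.max_duration_s:.0f}; reduce n_trials_per_class"
        )
    n_samples = int(round(duration * config.fs))

    src_pos = np.array([montage.position("C3"), montage.position("C4")])
    mixing = mixing_matrix(montage, src_pos, config.falloff)
    source_model = SourceModel(source_positions=src_pos, mixing=mixing)

    sources = np.stack(
        [
            _narrowband(rng, n_samples, config.fs, config.mu_freq)
            + config.beta_amplitude
            * _narrowband(rng, n_samples, config.fs, config.beta_freq)
            for _ in range(2)
        ]
    )

    # ERD gating: right-hand imagery attenuates the left (C3-side) source,
    # left-hand imagery the right source.  Optional ipsilateral ERS gain.
    depths = (config.erd_depth_left_source, config.erd_depth_right_source)
    envelopes = np.ones_like(sources)
    for s, (attenuating_label, depth) in enumerate(
        zip((Label.RIGHT, Label.LEFT), depths)
    ):
        intervals = [
            (cue, cue + 5.0, depth)
            for cue, lbl in zip(cues, labels)
            if lbl is attenuating_label
        ]
        if config.ers_gain_ipsilateral:
            intervals += [
                (cue, cue + 5.0, -config.ers_gain_ipsilateral)
                for cue, lbl in zip(cues, labels)
                if lbl is not attenuating_label
            ]
        envelopes[s] = _raised_cosine_gate(
            n_samples, config.fs, intervals, config.ramp_s
        )

    # Scale each source so its power at the nearest channel is snr x noise power.
    gain_max = mixing.max(axis=0)
    src_var = sources.var(axis=1)
    amplitudes = np.sqrt(config.snr * config.noise_rms_uv**2 / (gain_max**2 * src_var))

    noise = config.noise_rms_uv * _pink_noise(rng, montage.n_channels, n_samples)
    t = np.arange(n_samples) / config.fs
    line = config.line_noise_amplitude_uv * np.sin(
        2 * np.pi * config.line_noise_freq * t + rng.uniform(0, 2 * np.pi)
    )
    data = mixing @ (amplitudes[:, None] * envelopes * sources) + noise + line

    events = EventTable(
        onsets=np.round(cues * config.fs).astype(np.int64),
        labels=tuple(labels),
        paradigm=(Paradigm(config.paradigm.upper()),) * n,
        run_id=run_id,
    )
    rec = RawRecording(data=data, fs=config.fs, montage=montage, events=events)
    internals = SimulationInternals(
        source_model=source_model,
        sources_raw=sources,
        envelopes=envelopes,
        amplitudes=amplitudes,
        cue_times=cues,
    )
    return rec, internals


def simulate_session(
    config: SimulationConfig,
    montage: Montage | None = None,
    return_internals: bool = False,
    run_id: str = "run1",
):
    """Generate one continuous session; bit-reproducible from ``config.seed``."""
    montage = montage or default_montage()
    rng = np.random.default_rng(config.seed)
    rec, internals = _simulate(config, montage, rng, run_id)
    return (rec, internals) if return_internals else rec


def simulate_multirun(
    config: SimulationConfig, n_runs: int, montage: Montage | None = None
) -> list[RawRecording]:
    """Independent runs sharing the generative parameters.

    Sub-seeds are derived deterministically from ``config.seed`` (seed
    sequence spawning), so runs differ in noise realization but share
    montage, timing structure, and ERD parameters.
    """
    if n_runs < 2:
        raise ValueError("simulate_multirun expects n_runs >= 2")
    montage = montage or default_montage()
    children = np.random.SeedSequence(config.seed).spawn(n_runs)
    out = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        rec, _ = _simulate(config, montage, rng, run_id=f"run{k + 1}")
        out.append(rec)
    return out
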