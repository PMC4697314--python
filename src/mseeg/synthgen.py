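"""Synthetic multichannel EEG with known ground truth.

No public EEG cohort accompanies the clinical study this package models, so
every downstream stage is validated on simulated recordings in which the
quantities of interest are known by construction:

* a 1/f (power-law) background noise floor per channel;
* a small set of orthonormal scalp topographies ("microstate" templates)
  switching on a configurable ~50-150 ms timescale via a first-order Markov
  chain with uniform transition targets;
* optional band-limited oscillations added per channel;
* pairwise phase-lagged coupling: a band-limited source duplicated into two
  channels with a fixed sample delay matching the requested phase lag at
  band centre, optionally active only while the state sequence is in a
  given subset of microstate classes.

The signal-to-noise ratio is defined as RMS(template signal)/RMS(1/f noise)
over the whole matrix.  All randomness flows from a single integer seed;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .preproc import BANDS, Recording
from .stats_model import GroupStudy

__all__ = [
    "SynthConfig",
    "CouplingSpec",
    "GroundTruth",
    "generate_recording",
    "generate_group_study",
    "DOMAIN_SCORE_NAMES",
]

#: The six neuropsychological domain z-scores consumed by the statistics stage.
DOMAIN_SCORE_NAMES = (
    "verbal_attention",
    "visual_attention",
    "verbal_learning_memory",
    "visual_learning_memory",
    "verbal_language_production",
    "executive_motor_ability",
)

#: Noise RMS in microvolts; everything else is scaled relative to this.
_NOISE_RMS_UV = 10.0

#: Band (Hz) of the template activation waveform.  Kept inside the alpha
#: range and away from theta so that planted theta coupling is not masked.
_ACTIVATION_BAND = (9.0, 11.0)

#: In-band amplitude of a strength-1 coupled source, as a multiple of the
#: broadband noise RMS.  At 1 the source would only tie with the in-band
#: background (1/f noise plus template-switching sidebands); 3 makes a
#: strength-1 coupling the dominant rhythm of its band, which is what
#: "fully coupled" is meant to emulate.
_COUPLING_GAIN = 3.0


@dataclass(frozen=True)
class CouplingSpec:
    """A planted constant-phase-lag coupling between two channels.

    ``active_states`` is ``"all"`` or a collection of microstate indices;
    the coupled source is silenced outside those states, which is the
    ground truth against which microstate-segmented connectivity is tested.
    """

    pair: tuple[int, int]
    band: str = "theta"
    phase_lag: float = np.pi / 2
    strength: float = 1.0
    active_states: str | tuple[int, ...] = "all"

    def __post_init__(self):
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; known: {sorted(BANDS)}")
        if not (-np.pi < self.phase_lag <= np.pi):
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.active_states != "all" and len(tuple(self.active_states)) == 0:
            raise ValueError("active_states must be non-empty")

    def states(self, n_states: int) -> tuple[int, ...]:
        if self.active_states == "all":
            return tuple(range(n_states))
        return tuple(int(s) for s in self.active_states)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of one synthetic resting-state recording.

    Defaults mirror the acquisition the package targets where that is
    computationally sensible: 1000 Hz sampling, 180 s of retained signal,
    five microstate classes with ~100 ms mean dwell time.  The channel
    count defaults to 24 (a reduced montage; the method is channel-count
    agnostic).
    """

    n_channels: int = 24
    sampling_rate: float = 1000.0
    duration: float = 180.0
    n_states: int = 5
    mean_state_duration: float = 100.0  # ms
    band_oscillations: tuple[tuple[str, float], ...] = ()
    coupling_specs: tuple[CouplingSpec, ...] = ()
    noise_exponent: float = 1.0
    snr: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.n_channels < self.n_states:
            raise ValueError(
                f"n_channels ({self.n_channels}) < n_states ({self.n_states}): "
                "templates cannot be orthogonalized"
            )
        if self.mean_state_duration <= 0:
            raise ValueError("mean_state_duration must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer sample count")
        for band, _amp in self.band_oscillations:
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}")
        for spec in self.coupling_specs:
            if max(spec.pair) >= self.n_channels:
                raise ValueError(f"coupling pair {spec.pair} outside channel range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """What the generator planted: state sequence, templates, coupling graph."""

    state_sequence: np.ndarray  # per-sample state index
    templates: np.ndarray       # (n_states, n_channels), unit rows
    coupling_graph: dict        # band -> state -> set of channel pairs


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, exponent: float) -> np.ndarray:
    """Per-channel 1/f^exponent noise, unit RMS."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shaping, n=n, axis=1)
    rms = np.sqrt(np.mean(out ** 2, axis=1, keepdims=True))
    return out / rms


def _band_noise(rng: np.random.Generator, shape, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS along the last axis."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / rms


def _fm_source(rng: np.random.Generator, n: int, band: tuple[float, float],
               fs: float) -> np.ndarray:
    """Constant-envelope band-limited oscillation (slow frequency modulation).

    A coupled rhythm is emulated as a unit-RMS cosine whose instantaneous
    frequency wanders smoothly inside the band.  The constant envelope
    avoids the amplitude fading of Gaussian band noise, during which a
    planted phase lag would be masked by background noise.
    """
    lo, hi = band
    fc, dev = 0.5 * (lo + hi), 0.4 * (hi - lo)
    drift = sps.sosfiltfilt(
        sps.butter(2, (hi - lo) / 4.0, btype="lowpass", fs=fs, output="sos"),
        rng.standard_normal(n),
    )
    drift /= np.sqrt(np.mean(drift ** 2))
    freq = fc + dev * np.tanh(drift)
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.cos(phase)


def _markov_states(rng: np.random.Generator, n_states: int, n: int,
                   mean_dwell_samples: float) -> np.ndarray:
    """First-order Markov chain with geometric dwell and uniform targets."""
    p_switch = min(1.0, 1.0 / mean_dwell_samples)
    seq = np.empty(n, dtype=np.int64)
    pos = 0
    state = int(rng.integers(n_states))
    while pos < n:
        dwell = int(rng.geometric(p_switch))
        seq[pos:pos + dwell] = state
        pos += dwell
        step = int(rng.integers(n_states - 1))
        state = step if step < state else step + 1
    return seq


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one recording; returns the data and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ch, n, fs = config.n_channels, config.n_samples, config.sampling_rate

    # Orthonormal templates: QR of a seeded Gaussian matrix.
    gauss = rng.standard_normal((n_ch, config.n_states))
    q, _ = np.linalg.qr(gauss)
    templates = q.T[: config.n_states]  # rows unit-norm, mutually orthogonal

    dwell = config.mean_state_duration / 1000.0 * fs
    states = _markov_states(rng, config.n_states, n, dwell)

    # Template signal: the active template driven by an alpha-band waveform.
    activation = _band_noise(rng, n, _ACTIVATION_BAND, fs)
    template_signal = templates[states].T * activation  # (n_ch, n)
    # Unit-norm rows => matrix RMS of template_signal is RMS(activation)/sqrt(n_ch).
    template_rms = np.sqrt(np.mean(template_signal ** 2))
    data = template_signal * (config.snr * _NOISE_RMS_UV / template_rms)

    noise = _pink_noise(rng, n_ch, n, config.noise_exponent)
    data = data + noise * _NOISE_RMS_UV

    for band_name, amplitude in config.band_oscillations:
        data += amplitude * _band_noise(rng, (n_ch, n), BANDS[band_name], fs)

    coupling_graph: dict = {}
    for spec in config.coupling_specs:
        lo, hi = BANDS[spec.band]
        f_center = 0.5 * (lo + hi)
        source = _fm_source(rng, n, (lo, hi), fs) * (
            spec.strength * _COUPLING_GAIN * _NOISE_RMS_UV
        )
        delay = int(round(spec.phase_lag / (2 * np.pi * f_center) * fs))
        lagged = np.roll(source, delay)
        active = spec.states(config.n_states)
        mask = np.isin(states, active).astype(float)
        i, j = spec.pair
        data[i] += source * mask
        data[j] += lagged * mask
        pair = (min(i, j), max(i, j))
        for s in active:
            coupling_graph.setdefault(spec.band, {}).setdefault(s, set()).add(pair)

    rec = Recording(data=data, sampling_rate=fs,
                    channel_labels=[f"ch{i:02d}" for i in range(n_ch)])
    truth = GroundTruth(state_sequence=states, templates=templates,
                        coupling_graph=coupling_graph)
    return rec, truth


# ---------------------------------------------------------------------------
# Group studies


def generate_group_study(
    n_per_group: dict[str, int] | Sequence[int],
    effect_spec: dict[str, dict] | None = None,
    seed: int = 0,
    base_config: SynthConfig | None = None,
) -> GroupStudy:
    """Simulate a multi-group cohort of recordings plus domain scores.

    ``effect_spec`` maps group name to a dict with optional keys
    ``coupling_strength`` (added to every coupling spec's strength, clipped
    to [0, 1]) and ``domain_shift`` (scalar or length-6 vector added to the
    standard-normal domain z-scores).  A zero/absent effect_spec makes the
    groups exchangeable.
    """
    if not isinstance(n_per_group, dict):
        n_per_group = {f"group{i}": n for i, n in enumerate(n_per_group)}
    if len(n_per_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 2 for n in n_per_group.values()):
        raise ValueError("need n >= 2 per group (statistics impossible otherwise)")
    effect_spec = effect_spec or {}
    base = base_config or SynthConfig()

    seeds = np.random.SeedSequence(seed).spawn(sum(n_per_group.values()) + 1)
    score_rng = np.random.default_rng(seeds[-1])

    recordings, truths, groups, scores = [], [], [], []
    k = 0
    for gname, n_subj in n_per_group.items():
        eff = effect_spec.get(gname, {})
        dstrength = float(eff.get("coupling_strength", 0.0))
        dshift = np.broadcast_to(np.asarray(eff.get("domain_shift", 0.0), dtype=float), (6,))
        for _ in range(n_subj):
            specs = tuple(
                replace(s, strength=float(np.clip(s.strength + dstrength, 0.0, 1.0)))
                for s in base.coupling_specs
            )
            cfg = replace(base, coupling_specs=specs,
                          seed=int(seeds[k].generate_state(1)[0] % (2 ** 31)))
            rec, truth = generate_recording(cfg)
            recordings.append(rec)
            truths.append(truth)
            groups.append(gname)
            scores.append(score_rng.standard_normal(6) + dshift)
            k += 1
    import pandas as pd

    return GroupStudy(
        groups=groups,
        domain_scores=pd.DataFrame(np.asarray(scores), columns=list(DOMAIN_SCORE_NAMES)),
        recordings=recordings,
        ground_truths=truths,
    )
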