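"""Synthetic sEEG task schedules and recordings with planted ground truth.

Emulates a passive number-recognition task: each trial shows a fixation
cross (0.5-1.5 s, uniform), then a 1-s number stimulus in one of four
modalities (arabic numerals, dot assortments, spoken numbers, beep
sequences), followed by a 1.5-3.5 s inter-trial interval (uniform).  Forty
presentations per modality by default, with ~10% additional catch trials
requiring a parity judgement (flagged only; responses are not modeled).

Recordings are 1/f ("pink") background noise per contact, optionally with
mains interference, on which band-limited amplitude changes (high-frequency
broadband increases, alpha/beta desynchronization, theta increases, ...)
and event-related potentials are planted on stimulus trials of chosen
modalities.  Every planted effect is returned in a ground-truth manifest so
downstream stages can be validated against what was actually injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import Recording

MODALITIES = ("arabic", "dots", "spoken", "beeps")
STIMULUS_DUR_S = 1.0
FIXATION_RANGE_S = (0.5, 1.5)
ITI_RANGE_S = (1.5, 3.5)
RAMP_S = 0.05  # cosine on/off ramp of planted effect gains


class ConfigurationError(ValueError):
    """Raised for invalid synthesis configurations."""


@dataclass(frozen=True)
class Trial:
    onset_s: float
    modality: str
    quantity: int
    is_catch: bool
    fixation_dur_s: float
    iti_dur_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + STIMULUS_DUR_S


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered trial list; onsets are seconds from recording start."""

    trials: tuple[Trial, ...]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials])

    @property
    def end_s(self) -> float:
        last = self.trials[-1]
        return last.offset_s + last.iti_dur_s

    def modality_counts(self, include_catch: bool = False) -> dict[str, int]:
        counts = {m: 0 for m in MODALITIES}
        for t in self.trials:
            if include_catch or not t.is_catch:
                counts[t.modality] += 1
        return counts

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset/duration/trial_type/quantity/is_catch
        plus the jitter durations needed to reconstruct baseline placement)."""
        return pd.DataFrame(
            {
                "onset": [t.onset_s for t in self.trials],
                "duration": [STIMULUS_DUR_S] * len(self.trials),
                "trial_type": [t.modality for t in self.trials],
                "quantity": [t.quantity for t in self.trials],
                "is_catch": [int(t.is_catch) for t in self.trials],
                "fixation_dur": [t.fixation_dur_s for t in self.trials],
                "iti_dur": [t.iti_dur_s for t in self.trials],
            }
        )

    @classmethod
    def from_events_frame(cls, df: pd.DataFrame) -> "TaskSchedule":
        required = ["onset", "duration", "trial_type", "quantity", "is_catch"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"events table is missing required columns: {missing}")
        have_jitter = "iti_dur" in df.columns
        trials = []
        onsets = df["onset"].to_numpy(dtype=float)
        for i, row in enumerate(df.itertuples(index=False)):
            if have_jitter:
                iti = float(row.iti_dur)
                fix = float(getattr(row, "fixation_dur", 1.0))
            else:
                # conservative reconstruction: assume the longest fixation
                fix = FIXATION_RANGE_S[1]
                if i + 1 < len(onsets):
                    iti = onsets[i + 1] - fix - (onsets[i] + STIMULUS_DUR_S)
                else:
                    iti = ITI_RANGE_S[0]
            trials.append(
                Trial(
                    onset_s=float(row.onset),
                    modality=str(row.trial_type),
                    quantity=int(row.quantity),
                    is_catch=bool(int(row.is_catch)),
                    fixation_dur_s=fix,
                    iti_dur_s=iti,
                )
            )
        return cls(trials=tuple(trials))


@dataclass(frozen=True)
class EffectSpec:
    """Planted spectral/evoked ground-truth effect on one contact.

    ``magnitude`` multiplies the baseline band amplitude inside the window
    (``direction="decrease"`` divides instead); ``erp_amplitude`` (microvolts)
    adds a fixed biphasic evoked potential at stimulus onset.
    """

    contact: str
    modalities: tuple[str, ...]
    band_hz: tuple[float, float]
    window_s: tuple[float, float]
    direction: str = "increase"
    magnitude: float = 1.0
    erp_amplitude: float = 0.0

    def validate(self, sfreq: float) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigurationError(f"invalid band {self.band_hz}")
        if hi > sfreq / 2:
            raise ConfigurationError(
                f"effect band {self.band_hz} exceeds Nyquist ({sfreq / 2} Hz)"
            )
        if not (-1.0 <= self.window_s[0] < self.window_s[1] <= 1.0):
            raise ConfigurationError(f"invalid window {self.window_s}")
        if self.magnitude <= 0:
            raise ConfigurationError("magnitude must be positive")
        if self.direction not in ("increase", "decrease"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        bad = set(self.modalities) - set(MODALITIES)
        if bad or not self.modalities:
            raise ConfigurationError(f"invalid modalities {self.modalities}")

    @property
    def gain(self) -> float:
        return self.magnitude if self.direction == "increase" else 1.0 / self.magnitude


@dataclass(frozen=True)
class NoiseModel:
    """1/f^exponent background noise, scaled to an RMS amplitude in uV."""

    one_over_f_exponent: float = 1.0
    amplitude_uv: float = 20.0
    line_freq_hz: float | None = None
    line_amplitude_uv: float = 0.0

    def validate(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ConfigurationError("1/f exponent must be >= 0")
        if self.amplitude_uv < 0:
            raise ConfigurationError("noise amplitude must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    n_contacts: int = 8
    sfreq_hz: float = 1000.0
    presentations_per_modality: int = 40
    catch_rate: float = 0.10
    effects: tuple[EffectSpec, ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    region_labels: Mapping[str, str] | None = None
    pad_s: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_contacts < 1:
            raise ConfigurationError("n_contacts must be >= 1")
        if self.presentations_per_modality < 1:
            raise ConfigurationError("presentations_per_modality must be >= 1")
        if not (0.0 <= self.catch_rate < 1.0):
            raise ConfigurationError("catch_rate must be in [0, 1)")
        if self.sfreq_hz <= 0:
            raise ConfigurationError("sfreq_hz must be positive")
        self.noise.validate()
        names = set(self.contact_names())
        for eff in self.effects:
            eff.validate(self.sfreq_hz)
            if eff.contact not in names:
                raise ConfigurationError(f"effect contact {eff.contact!r} not in cohort")

    def contact_names(self) -> list[str]:
        if self.region_labels is not None:
            names = list(self.region_labels)
            if len(names) != self.n_contacts:
                raise ConfigurationError(
                    "region_labels must cover exactly n_contacts contacts"
                )
            return names
        return [f"C{i:03d}" for i in range(self.n_contacts)]


def build_schedule(config: SynthConfig, seed: int | None = None) -> TaskSchedule:
    """Draw a randomized task schedule honoring the task's timing.

    Exactly ``presentations_per_modality`` non-catch trials per modality,
    plus extra catch trials so the catch fraction of all trials matches
    ``catch_rate``; fixation and ITI jitters drawn uniformly from their
    declared ranges; the trial order is a uniform shuffle.  Deterministic
    given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_stim = len(MODALITIES) * config.presentations_per_modality
    n_catch = int(round(config.catch_rate / (1.0 - config.catch_rate) * n_stim))
    slots = [(m, False) for m in MODALITIES for _ in range(config.presentations_per_modality)]
    slots += [(rng.choice(MODALITIES), True) for _ in range(n_catch)]
    order = rng.permutation(len(slots))
    cursor = config.pad_s
    trials = []
    for i in order:
        modality, is_catch = slots[i]
        fix = rng.uniform(*FIXATION_RANGE_S)
        iti = rng.uniform(*ITI_RANGE_S)
        onset = cursor + fix
        trials.append(
            Trial(
                onset_s=onset,
                modality=str(modality),
                quantity=int(rng.integers(1, 10)),
                is_catch=is_catch,
                fixation_dur_s=fix,
                iti_dur_s=iti,
            )
        )
        cursor = onset + STIMULUS_DUR_S + iti
    return TaskSchedule(trials=tuple(trials))


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, rms: float,
                sfreq: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum and given RMS."""
    white = rng.standard_normal(n)
    if exponent == 0 or rms == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * shaping, n=n)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur if cur > 0 else 0.0)


def _erp_template(sfreq: float, amplitude_uv: float) -> np.ndarray:
    """Fixed biphasic evoked-potential template, 0-600 ms post onset."""
    t = np.arange(0.0, 0.6, 1.0 / sfreq)
    wave = np.exp(-((t - 0.15) ** 2) / (2 * 0.04**2)) - 0.6 * np.exp(
        -((t - 0.30) ** 2) / (2 * 0.06**2)
    )
    return amplitude_uv * wave


def _gain_envelope(
    n: int, sfreq: float, spans: Iterable[tuple[float, float]], gain: float
) -> np.ndarray:
    """Multiplicative envelope: 1 outside spans, ``gain`` inside, with 50-ms
    raised-cosine ramps at the span edges (ramps lie inside the span)."""
    g = np.ones(n)
    ramp_n = max(int(round(RAMP_S * sfreq)), 1)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    for start_s, end_s in spans:
        i0, i1 = int(round(start_s * sfreq)), int(round(end_s * sfreq))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        w = np.ones(i1 - i0)
        m = min(ramp_n, len(w) // 2)
        w[:m] = ramp[:m]
        w[len(w) - m :] = ramp[:m][::-1]
        g[i0:i1] = 1.0 + (gain - 1.0) * w
    return g


def simulate_recording(
    schedule: TaskSchedule,
    config: SynthConfig,
    seed: int | None = None,
) -> tuple[Recording, dict]:
    """Synthesize a continuous recording realizing the planted effects.

    Background is per-contact 1/f^exponent noise.  Each band-limited effect
    is realized by gain-modulating the background's own band-passed
    component inside the effect window on stimulus trials of the target
    modalities (gain = magnitude for increases, 1/magnitude for decreases),
    so the band amplitude is multiplied by exactly the configured factor up
    to ramping.  ERPs add a fixed biphasic template at stimulus onset.

    Returns the recording and a ground-truth manifest (JSON-serializable)
    listing every planted effect.
    """
    config.validate()
    if not schedule.trials:
        raise ConfigurationError("schedule is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sfreq = config.sfreq_hz
    duration = math.ceil(schedule.end_s + config.pad_s)
    n = int(round(duration * sfreq))
    names = config.contact_names()

    data = np.empty((config.n_contacts, n))
    for ci in range(config.n_contacts):
        data[ci] = _pink_noise(
            rng, n, config.noise.one_over_f_exponent, config.noise.amplitude_uv, sfreq
        )
    if config.noise.line_freq_hz and config.noise.line_amplitude_uv > 0:
        t = np.arange(n) / sfreq
        data += config.noise.line_amplitude_uv * np.sin(
            2 * np.pi * config.noise.line_freq_hz * t
        )[None, :]

    for eff in config.effects:
        ci = names.index(eff.contact)
        spans = [
            (tr.onset_s + eff.window_s[0], tr.onset_s + eff.window_s[1])
            for tr in schedule.trials
            if not tr.is_catch and tr.modality in eff.modalities
        ]
        if eff.magnitude != 1.0:
            sos = signal.butter(
                4, eff.band_hz, btype="bandpass", fs=sfreq, output="sos"
            )
            band = signal.sosfiltfilt(sos, data[ci])
            g = _gain_envelope(n, sfreq, spans, eff.gain)
            data[ci] += (g - 1.0) * band
        if eff.erp_amplitude != 0.0:
            erp = _erp_template(sfreq, eff.erp_amplitude)
            for tr in schedule.trials:
                if not tr.is_catch and tr.modality in eff.modalities:
                    i0 = int(round(tr.onset_s * sfreq))
                    data[ci, i0 : i0 + len(erp)] += erp[: max(n - i0, 0)]

    manifest = {
        "seed": int(config.seed if seed is None else seed),
        "sfreq_hz": sfreq,
        "n_contacts": config.n_contacts,
        "duration_s": duration,
        "effects": [
            {**asdict(e), "modalities": list(e.modalities)} for e in config.effects
        ],
    }
    return Recording(data=data, sfreq=sfreq, ch_names=names), manifest


def make_electrode_table(config: SynthConfig) -> pd.DataFrame:
    """Contact -> anatomical region table (columns ``name``, ``region``)."""
    if not config.region_labels:
        raise ConfigurationError("region_labels must be provided and non-empty")
    names = list(config.region_labels)
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate contact names in region_labels")
    if len(names) != config.n_contacts:
        raise ConfigurationError("region_labels must cover all contacts")
    return pd.DataFrame(
        {"name": names, "region": [config.region_labels[n] for n in names]}
    )
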