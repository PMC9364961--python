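"""Synthetic stage-labelled polysomnography (EEG + EOG) generator.

Real overnight recordings are scored in 30-s epochs whose EEG rhythm content
differs by stage: wake shows sustained alpha (8-13 Hz, 20-100 uV), N1 is
theta-dominant (4-8 Hz, 20-150 uV) with reduced alpha, N2 adds sleep
spindles (12-14 Hz) and K-complexes (biphasic, > 0.5 s) on a theta/delta
background, N3 is dominated by slow delta waves (0.5-2 Hz, up to 200 uV),
and REM pairs a theta/irregular-alpha EEG with sawtooth waves (2-7 Hz) and
bursts of rapid eye movement on the EOG channel.

This module renders those descriptions as a generative model: each stage is
a mixture of randomized-phase narrowband oscillations plus transient events
plus broadband Gaussian noise, and whole nights are laid out by a
run-length-structured hypnogram model.  The generator targets statistical
separability of the five stages, not physiological realism, so every
downstream module (decomposition, model, training, evaluation) is testable
without an external dataset.

All sampling is driven by ``numpy.random.Generator`` instances; identical
(configuration, seed) pairs reproduce identical signals bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stages import N_STAGES, STAGE_ORDER, StageLabel

__all__ = [
    "OscillatoryComponent",
    "TransientEvent",
    "StageSpec",
    "EpochRecord",
    "HypnogramModel",
    "default_stage_specs",
    "default_hypnogram_model",
    "generate_epoch",
    "generate_hypnogram",
    "generate_dataset",
]

EPOCH_SECONDS = 30.0

#: Channel order is fixed package-wide.
CHANNEL_NAMES = ("EEG", "EOG")

#: Transient kinds rendered as enveloped oscillatory bursts (the rest are
#: biphasic pulses).
_BURST_KINDS = frozenset({"spindle", "sawtooth"})
_PULSE_KINDS = frozenset({"k_complex", "blink", "rapid_eye_movement"})

# Fraction of the [amp_low, amp_high] range by which per-component amplitude
# draws may deviate from the shared per-epoch amplitude level.  A common
# level keeps the *relative* band structure stage-determined while the
# overall EEG amplitude still varies between epochs.
_AMP_JITTER = 0.10


@dataclass(frozen=True)
class OscillatoryComponent:
    """One narrowband background rhythm of a stage (EEG channel)."""

    band_low_hz: float
    band_high_hz: float
    amp_low_uv: float
    amp_high_uv: float
    weight: float

    def __post_init__(self) -> None:
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError(
                f"band_low_hz ({self.band_low_hz}) must be < band_high_hz "
                f"({self.band_high_hz})"
            )
        if self.amp_low_uv > self.amp_high_uv:
            raise ValueError("amp_low_uv must be <= amp_high_uv")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class TransientEvent:
    """A transient waveform injected at Poisson-distributed counts.

    ``spindle`` and ``sawtooth`` are Gaussian-enveloped oscillatory bursts
    (and require a carrier frequency range); ``k_complex``, ``blink`` and
    ``rapid_eye_movement`` are biphasic negative-then-positive pulses.
    ``amp_uv=None`` defaults the peak amplitude to 1.5x the stage's mean
    background amplitude at synthesis time.
    """

    kind: str
    duration_s: float
    rate_per_epoch: float
    target_channel: str = "EEG"
    freq_low_hz: float | None = None
    freq_high_hz: float | None = None
    amp_uv: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _BURST_KINDS | _PULSE_KINDS:
            raise ValueError(f"unknown transient kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.rate_per_epoch < 0:
            raise ValueError("rate_per_epoch must be >= 0")
        if self.target_channel not in CHANNEL_NAMES:
            raise ValueError(f"target_channel must be one of {CHANNEL_NAMES}")
        if self.kind in _BURST_KINDS:
            if self.freq_low_hz is None or self.freq_high_hz is None:
                raise ValueError(f"{self.kind} events need a carrier frequency range")
            if not 0 < self.freq_low_hz < self.freq_high_hz:
                raise ValueError("need 0 < freq_low_hz < freq_high_hz")
        if self.kind == "k_complex" and self.duration_s <= 0.5:
            # K-complex transient time exceeds half a second by definition.
            raise ValueError("k_complex duration_s must be > 0.5 s")


@dataclass(frozen=True)
class StageSpec:
    """Generative recipe for one sleep stage."""

    stage: StageLabel
    components: tuple[OscillatoryComponent, ...]
    events: tuple[TransientEvent, ...] = ()
    noise_sd_uv: float = 0.0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("a StageSpec needs at least one oscillatory component")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def max_frequency_hz(self) -> float:
        """Highest frequency any component or burst event can contain."""
        top = max(c.band_high_hz for c in self.components)
        for ev in self.events:
            if ev.freq_high_hz is not None:
                top = max(top, ev.freq_high_hz)
        return top

    def mean_background_amp_uv(self) -> float:
        """Weight-averaged mean component amplitude (event amplitude anchor)."""
        total_w = sum(c.weight for c in self.components)
        if total_w == 0:
            return 0.0
        return (
            sum(c.weight * 0.5 * (c.amp_low_uv + c.amp_high_uv) for c in self.components)
            / total_w
        )


@dataclass
class EpochRecord:
    """One 30-s two-channel (EEG, EOG) epoch in microvolts.

    ``stage`` is ``None`` for epochs read from an unscored recording until
    a hypnogram is attached.
    """

    samples: np.ndarray  # (n_samples, n_channels)
    fs_hz: float
    stage: StageLabel | None
    subject_id: str
    night_id: str
    epoch_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        expected = int(round(self.fs_hz * EPOCH_SECONDS))
        if self.samples.shape[0] != expected:
            raise ValueError(
                f"epoch has {self.samples.shape[0]} samples but fs_hz={self.fs_hz} "
                f"requires exactly {expected} for a 30-s epoch"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class HypnogramModel:
    """Run-length-structured model of a night's stage sequence.

    Stages are visited in bouts with geometric run lengths; bout entry
    probabilities are chosen so the long-run per-stage fractions converge
    to ``proportions``.  ``transition_bias[s]`` optionally reweights the
    successors of stage ``s`` (uniform when omitted).
    """

    proportions: Mapping[StageLabel, float]
    mean_bout_epochs: Mapping[StageLabel, float]
    transition_bias: Mapping[StageLabel, Mapping[StageLabel, float]] | None = None

    def __post_init__(self) -> None:
        total = float(sum(self.proportions.get(s, 0.0) for s in STAGE_ORDER))
        if total <= 0:
            raise ValueError("stage proportions are all zero; cannot normalize")
        for s, p in self.proportions.items():
            if p < 0:
                raise ValueError(f"proportion of {s.name} is negative")
        for s in STAGE_ORDER:
            if self.mean_bout_epochs.get(s, 1.0) < 1.0:
                raise ValueError(f"mean_bout_epochs[{s.name}] must be >= 1")

    def normalized_proportions(self) -> np.ndarray:
        p = np.array([self.proportions.get(s, 0.0) for s in STAGE_ORDER], float)
        return p / p.sum()


def default_stage_specs() -> dict[StageLabel, StageSpec]:
    """Per-stage generative defaults following the AASM stage descriptions.

    Band edges and amplitude ranges are the textbook values: delta 0.5-4 Hz
    at 20-200 uV (0.5-2 Hz for the N3 slow waves), theta 4-8 Hz at
    20-150 uV, alpha 8-13 Hz at 20-100 uV, beta 13-30 Hz at 5-20 uV,
    spindles 12-14 Hz, sawtooth 2-7 Hz, K-complex biphasic and longer than
    0.5 s.  Mixture weights make each stage's hallmark band dominant.
    """
    alpha = (8.0, 13.0, 20.0, 100.0)
    theta = (4.0, 8.0, 20.0, 150.0)
    delta = (0.5, 4.0, 20.0, 200.0)
    slow_delta = (0.5, 2.0, 20.0, 200.0)
    beta = (13.0, 30.0, 5.0, 20.0)

    def comp(band: tuple[float, float, float, float], w: float) -> OscillatoryComponent:
        lo, hi, a_lo, a_hi = band
        return OscillatoryComponent(lo, hi, a_lo, a_hi, w)

    specs = {
        StageLabel.W: StageSpec(
            stage=StageLabel.W,
            components=(comp(alpha, 0.80), comp(theta, 0.15), comp(beta, 0.05)),
            events=(
                TransientEvent("blink", duration_s=0.4, rate_per_epoch=3.0,
                               target_channel="EOG"),
            ),
            noise_sd_uv=6.0,
        ),
        StageLabel.N1: StageSpec(
            stage=StageLabel.N1,
            components=(comp(theta, 0.65), comp(alpha, 0.25), comp(beta, 0.10)),
            events=(),
            noise_sd_uv=8.5,
        ),
        StageLabel.N2: StageSpec(
            stage=StageLabel.N2,
            components=(comp(theta, 0.60), comp(delta, 0.15), comp(alpha, 0.15),
                        comp(beta, 0.10)),
            events=(
                TransientEvent("spindle", duration_s=1.0, rate_per_epoch=2.0,
                               target_channel="EEG", freq_low_hz=12.0,
                               freq_high_hz=14.0),
                TransientEvent("k_complex", duration_s=0.8, rate_per_epoch=1.5,
                               target_channel="EEG"),
            ),
            noise_sd_uv=8.5,
        ),
        StageLabel.N3: StageSpec(
            stage=StageLabel.N3,
            components=(comp(slow_delta, 0.75), comp(theta, 0.25)),
            events=(),
            noise_sd_uv=11.0,
        ),
        StageLabel.REM: StageSpec(
            stage=StageLabel.REM,
            components=(comp(theta, 0.60), comp(alpha, 0.25), comp(beta, 0.15)),
            events=(
                TransientEvent("sawtooth", duration_s=1.5, rate_per_epoch=2.0,
                               target_channel="EEG", freq_low_hz=2.0,
                               freq_high_hz=7.0),
                TransientEvent("rapid_eye_movement", duration_s=0.3,
                               rate_per_epoch=8.0, target_channel="EOG"),
            ),
            noise_sd_uv=8.5,
        ),
    }
    return specs


def default_hypnogram_model() -> HypnogramModel:
    """Stage-fraction targets at the midpoints of the reported clinical
    ranges (N1 5-10% -> 7.5%, N2 44-55% -> 49.5%, N3 10-20% -> 15%), REM at
    the low end of its wide 20-50% range (22%), wake absorbing the rest."""
    return HypnogramModel(
        proportions={
            StageLabel.W: 0.06,
            StageLabel.N1: 0.075,
            StageLabel.N2: 0.495,
            StageLabel.N3: 0.15,
            StageLabel.REM: 0.22,
        },
        mean_bout_epochs={
            StageLabel.W: 4.0,
            StageLabel.N1: 3.0,
            StageLabel.N2: 15.0,
            StageLabel.N3: 10.0,
            StageLabel.REM: 12.0,
        },
    )


def _narrowband(rng: np.random.Generator, n: int, fs_hz: float,
                f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-RMS randomized-phase narrowband oscillation on [f_lo, f_hi] Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():  # band narrower than one bin: take the nearest bin
        mask[np.argmin(np.abs(freqs - 0.5 * (f_lo + f_hi)))] = True
    spectrum = np.zeros(freqs.size, dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, int(mask.sum()))
    spectrum[mask] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    rms = float(np.sqrt(np.mean(x * x)))
    return x / rms if rms > 0 else x


def _pulse(n_dur: int) -> np.ndarray:
    """Unit-peak biphasic (negative-then-positive) smooth pulse."""
    tau = np.linspace(0.0, 1.0, n_dur, endpoint=False)
    window = np.hanning(n_dur) if n_dur > 1 else np.ones(1)
    return -np.sin(2.0 * np.pi * tau) * window


def _add_windowed(signal: np.ndarray, waveform: np.ndarray, start: int) -> None:
    """Add ``waveform`` into ``signal`` starting at ``start``, clipping edges."""
    lo = max(start, 0)
    hi = min(start + waveform.size, signal.size)
    if hi > lo:
        signal[lo:hi] += waveform[lo - start: hi - start]


def generate_epoch(
    spec: StageSpec,
    fs_hz: float,
    rng: np.random.Generator,
    *,
    stage: StageLabel | None = None,
    subject_id: str = "S00",
    night_id: str = "S00_n1",
    epoch_index: int = 0,
) -> EpochRecord:
    """Synthesize one 30-s two-channel epoch from a stage recipe.

    Oscillatory components go to the EEG channel as weight-mixed narrowband
    oscillations; transient events go to their target channel; both channels
    receive independent broadband Gaussian noise.  Raises ``ValueError`` if
    ``fs_hz`` violates the Nyquist bound for any configured frequency.
    """
    top = spec.max_frequency_hz
    if fs_hz < 2.0 * top:
        raise ValueError(
            f"sampling rate {fs_hz} Hz is below the Nyquist rate for the "
            f"highest configured frequency ({top} Hz); need fs >= {2 * top} Hz"
        )
    n = int(round(fs_hz * EPOCH_SECONDS))
    samples = np.zeros((n, 2))
    eeg = samples[:, 0]
    eog = samples[:, 1]

    # Shared per-epoch amplitude level with a small per-component jitter:
    # overall EEG amplitude varies, relative band structure stays
    # stage-determined.
    level = rng.uniform(0.0, 1.0)
    total_w = sum(c.weight for c in spec.components)
    for compo in spec.components:
        u = np.clip(level + _AMP_JITTER * rng.uniform(-1.0, 1.0), 0.0, 1.0)
        amp = compo.amp_low_uv + u * (compo.amp_high_uv - compo.amp_low_uv)
        wave = _narrowband(rng, n, fs_hz, compo.band_low_hz, compo.band_high_hz)
        if total_w > 0 and compo.weight > 0:
            # RMS of the component equals (weight-share * amp) / sqrt(2),
            # i.e. a sinusoid of that effective peak amplitude.
            eeg += (compo.weight / total_w) * (amp / np.sqrt(2.0)) * wave

    # Event amplitudes track the epoch's realized background level, so
    # transients stay in proportion to the rhythms they ride on.
    if total_w > 0:
        mean_bg = sum(
            (c.weight / total_w)
            * (c.amp_low_uv + level * (c.amp_high_uv - c.amp_low_uv))
            for c in spec.components
        )
    else:
        mean_bg = 0.0
    for ev in spec.events:
        channel = eeg if ev.target_channel == "EEG" else eog
        count = int(rng.poisson(ev.rate_per_epoch))
        for _ in range(count):
            dur = ev.duration_s * rng.uniform(0.75, 1.25)
            n_dur = max(int(round(dur * fs_hz)), 2)
            amp = ev.amp_uv if ev.amp_uv is not None else 1.5 * mean_bg
            start = int(rng.uniform(0.0, max(n - n_dur, 1)))
            if ev.kind in _BURST_KINDS:
                carrier_f = rng.uniform(ev.freq_low_hz, ev.freq_high_hz)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                t = np.arange(n_dur) / fs_hz
                envelope = np.exp(-0.5 * ((t - dur / 2.0) / (dur / 6.0)) ** 2)
                waveform = amp * envelope * np.sin(2 * np.pi * carrier_f * t + phase)
            else:
                waveform = amp * _pulse(n_dur)
            _add_windowed(channel, waveform, start)

    if spec.noise_sd_uv > 0:
        samples += rng.normal(0.0, spec.noise_sd_uv, size=samples.shape)

    return EpochRecord(
        samples=samples,
        fs_hz=fs_hz,
        stage=spec.stage if stage is None else stage,
        subject_id=subject_id,
        night_id=night_id,
        epoch_index=epoch_index,
    )


def generate_hypnogram(
    n_epochs: int,
    model: HypnogramModel,
    rng: np.random.Generator,
) -> list[StageLabel]:
    """Sample a run-length-structured stage sequence for one night.

    Bout lengths are geometric with the configured per-stage means; bout
    entry weights are proportions / mean-bout-length (so long-run stage
    fractions converge to the configured proportions under uniform
    transition bias).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    p = model.normalized_proportions()
    means = np.array(
        [model.mean_bout_epochs.get(s, 1.0) for s in STAGE_ORDER], float
    )
    entry = p / means
    if model.transition_bias is None:
        bias = np.ones((N_STAGES, N_STAGES))
    else:
        bias = np.array(
            [
                [
                    model.transition_bias.get(s, {}).get(t, 1.0)
                    for t in STAGE_ORDER
                ]
                for s in STAGE_ORDER
            ],
            float,
        )

    labels: list[StageLabel] = []
    current = int(rng.choice(N_STAGES, p=p))
    while len(labels) < n_epochs:
        bout = int(rng.geometric(1.0 / means[current]))
        labels.extend([STAGE_ORDER[current]] * min(bout, n_epochs - len(labels)))
        weights = entry * bias[current]
        weights[current] = 0.0  # a bout ends by switching stage
        total = weights.sum()
        if total <= 0:  # degenerate model (single permitted stage): stay
            continue
        current = int(rng.choice(N_STAGES, p=weights / total))
    return labels


def generate_dataset(
    n_subjects: int,
    nights_per_subject: int,
    epochs_per_night: int,
    fs_hz: float = 100.0,
    seed: int = 0,
    *,
    specs: Mapping[StageLabel, StageSpec] | None = None,
    hypnogram_model: HypnogramModel | None = None,
) -> list[EpochRecord]:
    """Generate a subject/night/epoch-indexed synthetic cohort.

    Each subject's signal stream is seeded independently from
    ``(seed, subject_index)``, so any single subject regenerates identically
    in isolation.
    """
    if min(n_subjects, nights_per_subject, epochs_per_night) < 1:
        raise ValueError("all counts must be >= 1")
    specs = default_stage_specs() if specs is None else dict(specs)
    hyp_model = default_hypnogram_model() if hypnogram_model is None else hypnogram_model

    records: list[EpochRecord] = []
    for si in range(n_subjects):
        subject_id = f"S{si + 1:02d}"
        for ni in range(nights_per_subject):
            night_id = f"{subject_id}_n{ni + 1}"
            rng = np.random.default_rng(np.random.SeedSequence([seed, si, ni]))
            hypnogram = generate_hypnogram(epochs_per_night, hyp_model, rng)
            for ei, stage in enumerate(hypnogram):
                records.append(
                    generate_epoch(
                        specs[stage],
                        fs_hz,
                        rng,
                        subject_id=subject_id,
                        night_id=night_id,
                        epoch_index=ei,
                    )
                )
    return records


def hypnogram_of(records: Sequence[EpochRecord]) -> list[StageLabel]:
    """Stage labels of a record list in stored order."""
    return [r.stage for r in records]
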