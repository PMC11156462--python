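"""Synthetic sEMG generators with planted, recoverable ground truth.

The package's analyses are validated by parameter recovery on synthetic
cohorts that emulate the two study conditions:

* **Voluntary contraction** (dumbbell hold to exhaustion): zero-mean
  band-limited (20–450 Hz) Gaussian noise whose windowed-RMS envelope grows
  as a planted power law ``scale * t**exponent + noise_floor``.
* **FES session**: a periodic biphasic stimulation-artifact train (default
  24 Hz, 200 µs, 2–15 mA range) superimposed with evoked bursts time-locked
  after each pulse; the evoked RMS envelope follows the four-stage "M"
  shape, its stage-3 peak time planted per trial.  Across a cohort, peak
  times follow t(I) = k/(I − i0) with optional per-subject multiplicative
  log-normal jitter, plus additive slopes in frequency (≤ 0) and pulse
  width (≥ 0).

All randomness flows from one seeded generator per trial; identical spec +
seed reproduces bit-identical samples.  Amplitudes are arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .core import SignalRecord, StimulationProtocol
from .exceptions import InvalidSpecError

__all__ = ["VoluntaryTrialSpec", "StageShape", "FesTrialSpec",
           "PlantedGroundTruth", "generate_voluntary_semg", "FesSimulation",
           "simulate_fes_trial", "generate_fes_mixed_signal", "CohortTrial",
           "CohortSimulation", "generate_cohort", "generate_protocol_sweep"]

_BAND = (20.0, 450.0)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to the sEMG band (20–450 Hz)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, _BAND, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std()


# --------------------------------------------------------------------------
# voluntary contraction


@dataclass(frozen=True)
class VoluntaryTrialSpec:
    """Specification of one synthetic voluntary (dumbbell-hold) trial.

    The planted windowed-RMS envelope is
    ``envelope_scale * t**envelope_exponent + noise_floor`` (t in seconds).
    """

    duration: float = 90.0
    sampling_rate: float = 1000.0
    envelope_scale: float = 1.0
    envelope_exponent: float = 0.6
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.duration < 60.0:
            raise InvalidSpecError(
                f"duration must be >= 60 s (got {self.duration}) so the "
                "60 s terminal segment exists"
            )
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")
        if self.envelope_scale < 0 or self.noise_floor < 0:
            raise InvalidSpecError("envelope_scale and noise_floor must be >= 0")
        if self.envelope_scale > 0 and self.envelope_exponent <= 0:
            raise InvalidSpecError(
                "envelope_exponent must be > 0 for a growing fatigue envelope"
            )

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Planted RMS envelope evaluated at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=np.float64)
        if self.envelope_scale == 0:
            return np.full_like(t, self.noise_floor)
        return self.envelope_scale * t ** self.envelope_exponent + self.noise_floor


def generate_voluntary_semg(spec: VoluntaryTrialSpec,
                            subject_id: str | None = None) -> SignalRecord:
    """Zero-mean stochastic sEMG whose windowed RMS tracks the planted envelope."""
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    env = spec.envelope(t)
    rng = np.random.default_rng(spec.seed)
    if np.all(env == 0):
        samples = np.zeros(n)
    else:
        samples = env * _bandlimited_noise(rng, n, fs)
    return SignalRecord(samples=samples, sampling_rate=fs,
                        channel_label="sEMG(voluntary,synthetic)",
                        subject_id=subject_id)


# --------------------------------------------------------------------------
# FES session


@dataclass(frozen=True)
class StageShape:
    """Knot description of the four-stage evoked RMS envelope.

    ``durations`` are the four stage lengths (seconds); the amplitude knots
    are baseline → first_peak (end of activation) → trough (end of
    recovery) → peak (end of fatigue; the global maximum) → tail.  The
    envelope interpolates the knots monotonically (PCHIP), so its interior
    critical points sit exactly at the knots.
    """

    durations: tuple[float, float, float, float] = (5.0, 10.0, 25.0, 20.0)
    baseline: float = 0.10
    first_peak: float = 0.60
    trough: float = 0.35
    peak: float = 1.00
    tail: float = 0.70

    def __post_init__(self):
        if len(self.durations) != 4 or any(d <= 0 for d in self.durations):
            raise InvalidSpecError("need 4 positive stage durations")
        if not (self.baseline < self.first_peak and
                self.trough < self.first_peak and
                self.trough < self.peak and self.tail < self.peak and
                self.peak > self.first_peak):
            raise InvalidSpecError(
                "stage amplitudes must satisfy baseline < first_peak, "
                "trough < first_peak, and peak > first_peak > ... (global "
                "maximum in stage 3)"
            )
        if min(self.baseline, self.trough, self.tail) < 0:
            raise InvalidSpecError("stage amplitudes must be non-negative")

    @property
    def t_peak(self) -> float:
        """Planted stage-3 peak time: d1 + d2 + d3."""
        return float(sum(self.durations[:3]))

    @property
    def total_duration(self) -> float:
        return float(sum(self.durations))

    def scaled_to_peak(self, t_peak: float) -> "StageShape":
        """Same shape with stage durations rescaled so the peak falls at t_peak."""
        if t_peak <= 0:
            raise InvalidSpecError(f"t_peak must be positive, got {t_peak}")
        f = t_peak / self.t_peak
        return StageShape(durations=tuple(d * f for d in self.durations),
                          baseline=self.baseline, first_peak=self.first_peak,
                          trough=self.trough, peak=self.peak, tail=self.tail)

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Evoked RMS envelope at times ``t``; constant at ``tail`` beyond the stages."""
        d1, d2, d3, d4 = self.durations
        knots_x = np.array([0.0, d1, d1 + d2, d1 + d2 + d3, d1 + d2 + d3 + d4])
        knots_y = np.array([self.baseline, self.first_peak, self.trough,
                            self.peak, self.tail])
        interp = PchipInterpolator(knots_x, knots_y, extrapolate=False)
        t = np.asarray(t, dtype=np.float64)
        out = interp(np.clip(t, 0.0, knots_x[-1]))
        return np.asarray(out)


@dataclass(frozen=True)
class FesTrialSpec:
    """Specification of one synthetic FES trial.

    ``carrier`` selects the evoked-burst carrier: ``"noise"`` (band-limited
    Gaussian noise, the default study condition) or ``"tone"`` (a
    deterministic unit-RMS 150 Hz sinusoid — the fully noiseless variant).
    """

    protocol: StimulationProtocol = StimulationProtocol(current_amplitude=12.0)
    stage_shape: StageShape = field(default_factory=StageShape)
    duration: float | None = None
    sampling_rate: float = 1000.0
    artifact_amplitude: float = 60.0
    evoked_amplitude: float = 1.0
    noise_floor: float = 0.02
    carrier: str = "noise"
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")
        if self.carrier not in ("noise", "tone"):
            raise InvalidSpecError(f"unknown carrier {self.carrier!r}")
        if min(self.artifact_amplitude, self.evoked_amplitude,
               self.noise_floor) < 0:
            raise InvalidSpecError("amplitudes must be non-negative")
        if self.duration is not None:
            if self.duration < self.stage_shape.total_duration:
                raise InvalidSpecError(
                    "stage durations must sum to at most the trial duration"
                )
        if self.protocol.frequency * self.effective_duration < 4:
            raise InvalidSpecError(
                "trial must contain at least 4 stimulation pulses"
            )

    @property
    def effective_duration(self) -> float:
        return (self.duration if self.duration is not None
                else self.stage_shape.total_duration)


@dataclass
class FesSimulation:
    """One simulated FES trial with its ground-truth decomposition."""

    spec: FesTrialSpec
    mixed: SignalRecord
    evoked: np.ndarray
    artifact: np.ndarray
    noise: np.ndarray
    envelope: np.ndarray
    planted_t_max: float

    @property
    def evoked_record(self) -> SignalRecord:
        return SignalRecord(samples=self.evoked,
                            sampling_rate=self.mixed.sampling_rate,
                            channel_label="sEMG(evoked,ground-truth)",
                            protocol=self.spec.protocol,
                            subject_id=self.mixed.subject_id)


def _burst_gate(n: int, fs: float, pulse_indices: np.ndarray,
                frequency: float) -> np.ndarray:
    """Hann-profiled evoked-response gate time-locked ~5 ms after each pulse."""
    gate = np.zeros(n)
    latency = int(round(0.005 * fs))
    burst_len = max(4, int(round(min(0.7 / frequency, 0.025) * fs)))
    profile = np.sin(np.pi * (np.arange(burst_len) + 0.5) / burst_len) ** 2
    for idx in pulse_indices:
        s = idx + latency
        e = min(s + burst_len, n)
        if s < n:
            gate[s:e] = np.maximum(gate[s:e], profile[: e - s])
    return gate


def simulate_fes_trial(spec: FesTrialSpec,
                       subject_id: str | None = None) -> FesSimulation:
    """Simulate one FES trial: artifact train + evoked component + noise.

    The biphasic artifact (total width = the protocol pulse width) is
    shorter than one sample at 1 kHz; each phase's charge is integrated
    into adjacent sample bins, giving a ±``artifact_amplitude * (w/2) / dt``
    two-sample transient per pulse — the aliased spike a real recording
    shows.  The evoked component is ``evoked_amplitude * envelope(t) *
    gate(t) * carrier(t)`` and is returned separately as ground truth.
    """
    fs = spec.sampling_rate
    dur = spec.effective_duration
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    f = spec.protocol.frequency
    rng = np.random.default_rng(spec.seed)

    n_pulses = int(np.floor(dur * f))
    pulse_times = (np.arange(n_pulses) + 0.5) / f
    pulse_idx = np.round(pulse_times * fs).astype(int)
    pulse_idx = pulse_idx[pulse_idx < n - 1]

    artifact = np.zeros(n)
    if spec.artifact_amplitude > 0:
        w_s = spec.protocol.pulse_width * 1e-6
        amp = spec.artifact_amplitude * (w_s / 2.0) * fs
        artifact[pulse_idx] += amp
        artifact[pulse_idx + 1] -= amp

    envelope = spec.stage_shape.envelope(t)
    evoked = np.zeros(n)
    if spec.evoked_amplitude > 0:
        gate = _burst_gate(n, fs, pulse_idx, f)
        if spec.carrier == "tone":
            carrier = np.sqrt(2.0) * np.sin(2.0 * np.pi * 150.0 * t)
        else:
            carrier = _bandlimited_noise(rng, n, fs)
        evoked = spec.evoked_amplitude * envelope * gate * carrier

    noise = (spec.noise_floor * rng.standard_normal(n)
             if spec.noise_floor > 0 else np.zeros(n))

    mixed = SignalRecord(samples=artifact + evoked + noise, sampling_rate=fs,
                         channel_label="sEMG(FES,mixed,synthetic)",
                         protocol=spec.protocol, subject_id=subject_id)
    return FesSimulation(spec=spec, mixed=mixed, evoked=evoked,
                         artifact=artifact, noise=noise, envelope=envelope,
                         planted_t_max=spec.stage_shape.t_peak)


def generate_fes_mixed_signal(spec: FesTrialSpec,
                              subject_id: str | None = None) -> SignalRecord:
    """Mixed FES recording (artifact + evoked + noise) for one trial."""
    return simulate_fes_trial(spec, subject_id=subject_id).mixed


# --------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class PlantedGroundTruth:
    """Planted dose–duration law for cohort simulation.

    Maximum stimulation time at protocol (I, f, w):

        t = k / (I - i0) + freq_slope * (f - f_ref) + pw_slope * (w - w_ref)

    with ``freq_slope <= 0`` (raising frequency shortens stimulation time)
    and ``pw_slope >= 0`` (widening the pulse prolongs it).
    """

    k: float = 120.0
    i0: float = 0.0
    freq_slope: float = -0.15
    pw_slope: float = 0.02
    f_ref: float = 24.0
    w_ref: float = 200.0

    def __post_init__(self):
        if self.k <= 0:
            raise InvalidSpecError("k must be positive")
        if self.i0 < 0:
            raise InvalidSpecError("i0 must be >= 0")
        if self.freq_slope > 0:
            raise InvalidSpecError("freq_slope must be <= 0")
        if self.pw_slope < 0:
            raise InvalidSpecError("pw_slope must be >= 0")

    def t_max(self, current: float, frequency: float | None = None,
              pulse_width: float | None = None) -> float:
        """Planted maximum stimulation time (seconds) for a protocol."""
        if current <= self.i0:
            raise InvalidSpecError(
                f"current {current} mA must exceed i0 = {self.i0} mA"
            )
        f = self.f_ref if frequency is None else frequency
        w = self.w_ref if pulse_width is None else pulse_width
        t = (self.k / (current - self.i0)
             + self.freq_slope * (f - self.f_ref)
             + self.pw_slope * (w - self.w_ref))
        if t <= 0:
            raise InvalidSpecError(
                f"planted t_max is non-positive ({t:.3g} s) at "
                f"I={current}, f={f}, w={w}"
            )
        return float(t)


@dataclass
class CohortTrial:
    subject_id: str
    spec: FesTrialSpec
    record: SignalRecord
    planted_t_max: float


@dataclass
class CohortSimulation:
    """A simulated multi-subject FES cohort plus its ground-truth table."""

    trials: list[CohortTrial]
    truth_table: pd.DataFrame
    truth: PlantedGroundTruth
    jitter: float

    def __iter__(self):
        return iter(self.trials)


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2 ** 31))


def generate_cohort(n_subjects: int, currents, truth: PlantedGroundTruth,
                    seed: int, jitter: float = 0.05,
                    frequency: float = 24.0, pulse_width: float = 200.0,
                    template: StageShape | None = None,
                    sampling_rate: float = 1000.0,
                    carrier: str = "noise",
                    artifact_amplitude: float = 60.0,
                    evoked_amplitude: float = 1.0,
                    noise_floor: float = 0.02) -> CohortSimulation:
    """Simulate n_subjects × len(currents) FES trials with planted peak times.

    Each subject carries one multiplicative log-normal factor
    ``exp(jitter * z)`` applied to every planted peak time, so the
    jitter-free cohort maps current to exactly ``k / (I - i0)``.
    """
    if n_subjects < 1:
        raise InvalidSpecError(f"n_subjects must be >= 1, got {n_subjects}")
    currents = [float(c) for c in currents]
    for c in currents:
        if c <= truth.i0:
            raise InvalidSpecError(
                f"current {c} mA must exceed i0 = {truth.i0} mA"
            )
    if jitter < 0:
        raise InvalidSpecError("jitter must be >= 0")
    template = template or StageShape()

    root = np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(root.spawn(1)[0])
    multipliers = np.exp(jitter * subj_rng.standard_normal(n_subjects))
    trial_seqs = root.spawn(n_subjects * len(currents) + 1)[1:]

    trials: list[CohortTrial] = []
    rows = []
    idx = 0
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for c in currents:
            t_planted = truth.t_max(c, frequency, pulse_width) * multipliers[s]
            spec = FesTrialSpec(
                protocol=StimulationProtocol(current_amplitude=c,
                                             frequency=frequency,
                                             pulse_width=pulse_width),
                stage_shape=template.scaled_to_peak(t_planted),
                sampling_rate=sampling_rate, carrier=carrier,
                artifact_amplitude=artifact_amplitude,
                evoked_amplitude=evoked_amplitude, noise_floor=noise_floor,
                seed=_child_seed(trial_seqs[idx]),
            )
            sim = simulate_fes_trial(spec, subject_id=subject)
            trials.append(CohortTrial(subject_id=subject, spec=spec,
                                      record=sim.mixed,
                                      planted_t_max=sim.planted_t_max))
            rows.append({"subject": subject, "current_mA": c,
                         "frequency_Hz": frequency,
                         "pulse_width_us": pulse_width,
                         "planted_t_max_s": sim.planted_t_max,
                         "seed": spec.seed})
            idx += 1
    table = pd.DataFrame(rows, columns=["subject", "current_mA", "frequency_Hz",
                                        "pulse_width_us", "planted_t_max_s",
                                        "seed"])
    return CohortSimulation(trials=trials, truth_table=table, truth=truth,
                            jitter=jitter)


def generate_protocol_sweep(truth: PlantedGroundTruth, seed: int,
                            currents=(8.0, 10.0, 12.0, 14.0),
                            frequencies=(16.0, 24.0, 32.0, 40.0),
                            pulse_widths=(100.0, 200.0, 300.0, 400.0),
                            reference_current: float = 12.0,
                            template: StageShape | None = None,
                            carrier: str = "noise",
                            **trial_kwargs) -> list[tuple[StimulationProtocol, FesTrialSpec, SignalRecord]]:
    """One-factor-at-a-time protocol sweep around the 12 mA / 24 Hz / 200 µs reference.

    Returns (protocol, spec, mixed record) triples suitable for end-to-end
    effect-sign recovery with :func:`~fesfatigue.stages.parameter_effect_summary`.
    """
    template = template or StageShape()
    protocols = [StimulationProtocol(c, truth.f_ref, truth.w_ref)
                 for c in currents]
    protocols += [StimulationProtocol(reference_current, f, truth.w_ref)
                  for f in frequencies]
    protocols += [StimulationProtocol(reference_current, truth.f_ref, w)
                  for w in pulse_widths]
    seqs = np.random.SeedSequence(seed).spawn(len(protocols))
    out = []
    for proto, seq in zip(protocols, seqs):
        t_planted = truth.t_max(proto.current_amplitude, proto.frequency,
                                proto.pulse_width)
        spec = FesTrialSpec(protocol=proto,
                            stage_shape=template.scaled_to_peak(t_planted),
                            carrier=carrier, seed=_child_seed(seq),
                            **trial_kwargs)
        out.append((proto, spec, generate_fes_mixed_signal(spec)))
    return out
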