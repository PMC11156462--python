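"""Core in-memory containers: stimulation protocols and sampled signals.

A :class:`SignalRecord` is the package's single signal container: a uniformly
sampled single-channel sEMG trace with its sampling rate and optional trial
metadata.  Sample ``i`` maps to time ``i / sampling_rate`` seconds (0-based);
windows elsewhere in the package are half-open ``[start, start + n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidSpecError

__all__ = ["StimulationProtocol", "SignalRecord"]


@dataclass(frozen=True)
class StimulationProtocol:
    """FES pulse-train settings for one trial.

    Parameters
    ----------
    current_amplitude : float
        Pulse amplitude in milliamperes.  Study protocols sweep 2–15 mA;
        values outside that range are allowed but unusual.
    frequency : float
        Pulse repetition rate in hertz (default 24).
    pulse_width : float
        Single-pulse width in microseconds (default 200).
    """

    current_amplitude: float
    frequency: float = 24.0
    pulse_width: float = 200.0

    def __post_init__(self):
        if not np.isfinite(self.current_amplitude) or self.current_amplitude <= 0:
            raise InvalidSpecError(
                f"current_amplitude must be positive, got {self.current_amplitude}"
            )
        if not np.isfinite(self.frequency) or self.frequency <= 0:
            raise InvalidSpecError(f"frequency must be positive, got {self.frequency}")
        if not np.isfinite(self.pulse_width) or self.pulse_width <= 0:
            raise InvalidSpecError(
                f"pulse_width must be positive, got {self.pulse_width}"
            )


@dataclass(eq=False)
class SignalRecord:
    """Uniformly sampled single-channel signal with trial metadata."""

    samples: np.ndarray
    sampling_rate: float
    channel_label: str = "EMG"
    protocol: StimulationProtocol | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidSpecError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise InvalidSpecError("samples must be non-empty")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise InvalidSpecError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0-based."""
        return np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "SignalRecord":
        """Copy of this record carrying new samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    def equals(self, other: "SignalRecord") -> bool:
        """Field-wise equality with bit-exact sample comparison."""
        return (
            isinstance(other, SignalRecord)
            and np.array_equal(self.samples, other.samples)
            and self.sampling_rate == other.sampling_rate
            and self.channel_label == other.channel_label
            and self.protocol == other.protocol
            and self.subject_id == other.subject_id
        )
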