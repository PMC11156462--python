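"""End-to-end per-trial analysis chains.

These helpers wire the module stages together in the canonical order so the
CLI, the test-suite and downstream scripts all run the identical pipeline:

voluntary:  band-pass -> terminal 60 s -> windowed RMS -> min-max
            normalization -> power-law fit
FES:        band-pass -> single-scale CWT separation -> windowed RMS ->
            min-max normalization -> polynomial fit -> four-stage
            segmentation -> maximum stimulation time
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import SignalRecord
from .features import (FittedCurve, RMSCurve, fit_polynomial_curve,
                       fit_power_curve, minmax_normalize, windowed_rms)
from .preprocess import bandpass_filter, extract_terminal_segment
from .stages import StageSegmentation, segment_mwave_stages
from .wavelet import WaveletSpec, separate_evoked

__all__ = ["VoluntaryTrialResult", "FesTrialResult",
           "analyze_voluntary_trial", "analyze_fes_trial"]


@dataclass
class VoluntaryTrialResult:
    rms: RMSCurve
    normalized: RMSCurve
    fit: FittedCurve


@dataclass
class FesTrialResult:
    rms: RMSCurve
    normalized: RMSCurve
    fit: FittedCurve
    segmentation: StageSegmentation

    @property
    def t_max(self) -> float:
        return self.segmentation.t_max


def analyze_voluntary_trial(record: SignalRecord, *, low: float = 20.0,
                            high: float = 450.0, order: int = 4,
                            terminal_window: float = 60.0,
                            window_samples: int = 1000) -> VoluntaryTrialResult:
    """Fatigue characteristic curve of a voluntary contraction trial."""
    filtered = bandpass_filter(record, low=low, high=high, order=order)
    terminal = extract_terminal_segment(filtered, window=terminal_window)
    rms = windowed_rms(terminal, window_samples=window_samples)
    norm = minmax_normalize(rms)
    fit = fit_power_curve(norm)
    return VoluntaryTrialResult(rms=rms, normalized=norm, fit=fit)


def analyze_fes_trial(record: SignalRecord, *, low: float = 20.0,
                      high: float = 450.0, order: int = 4,
                      wavelet: WaveletSpec | None = None,
                      window_samples: int = 1000,
                      degree: int = 6) -> FesTrialResult:
    """Evoked fatigue curve, stage decomposition and t_max of one FES trial."""
    filtered = bandpass_filter(record, low=low, high=high, order=order)
    evoked = separate_evoked(filtered, wavelet)
    rms = windowed_rms(evoked, window_samples=window_samples)
    norm = minmax_normalize(rms)
    fit = fit_polynomial_curve(norm, degree=degree)
    seg = segment_mwave_stages(fit, norm)
    return FesTrialResult(rms=rms, normalized=norm, fit=fit, segmentation=seg)
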