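"""Band-pass filtering and terminal-segment extraction.

sEMG energy of interest lives in the 20–450 Hz band; everything below is
motion artifact and baseline drift, everything above is amplifier noise.
The filter is a Butterworth band-pass applied forward–backward
(zero-phase), so RMS windows downstream are never time-shifted relative to
stimulation events.  Fatigue analysis of voluntary contractions uses only
the final 60 s of a trial, when the muscle is approaching exhaustion.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import SignalRecord
from .exceptions import LengthError, ParameterError

__all__ = ["bandpass_filter", "extract_terminal_segment"]


def _design_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ParameterError(
            f"high corner {high} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(record: SignalRecord, low: float = 20.0, high: float = 450.0,
                    order: int = 4) -> SignalRecord:
    """Zero-phase Butterworth band-pass of a signal record.

    Parameters
    ----------
    record : SignalRecord
        Input signal; length and sampling rate are preserved.
    low, high : float
        Passband corners in hertz (defaults 20 and 450, the conventional
        sEMG band).  ``high`` must lie below Nyquist.
    order : int
        Butterworth order of the one-way filter (default 4); the effective
        roll-off doubles because the filter runs forward and backward.
    """
    sos = _design_sos(low, high, order, record.sampling_rate)
    n = record.n_samples
    # sosfiltfilt's default edge padding; also a proxy for the effective
    # impulse-response length used in the too-short warning below.
    default_padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                                     (sos[:, 5] == 0).sum()))
    if n <= 3 * default_padlen:
        warnings.warn(
            f"record of {n} samples is short relative to the filter's edge "
            f"response ({default_padlen} samples); boundary distortion likely",
            stacklevel=2,
        )
    padlen = min(default_padlen, n - 1)
    filtered = sps.sosfiltfilt(sos, record.samples, padlen=padlen)
    return record.with_samples(filtered)


def extract_terminal_segment(record: SignalRecord, window: float = 60.0) -> SignalRecord:
    """Return the trailing ``window`` seconds of a record.

    Raises :class:`LengthError` when the record is shorter than ``window``.
    """
    if window <= 0:
        raise ParameterError(f"window must be positive, got {window}")
    n_keep = int(round(window * record.sampling_rate))
    if record.n_samples < n_keep:
        raise LengthError(
            f"record of {record.duration:.3f} s is shorter than the "
            f"{window} s terminal window"
        )
    return record.with_samples(record.samples[record.n_samples - n_keep:])
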