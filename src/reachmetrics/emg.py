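"""Surface-EMG preprocessing and the peak-latency statistic.

The preprocessing chain is a zero-phase Butterworth band-pass
(20-400 Hz) followed by a zero-phase notch at the mains frequency
(50 Hz).  Both stages run forward-backward so they introduce no group
delay — essential here because the statistic of interest IS a latency.

Peak latency is the time from target appearance to the maximum of the
muscle's processed signal within the first movement segment of a block
(initial hand position to the fixed first target, the only segment
geometrically comparable across conditions).  "Maximum of the signal"
is read as the peak of the rectified, smoothed amplitude envelope
(moving RMS over 50 ms, then a zero-phase 1.5 Hz low-pass): the argmax of the
raw band-passed waveform is a single noisy sample, whereas the envelope
peak estimates the underlying activation maximum.  A raw
absolute-value mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .segmentation import first_segment
from .session_io import EmgRecording, EventLog, TrialEvent

__all__ = [
    "FilterSpec",
    "PeakLatencyResult",
    "preprocess",
    "envelope",
    "peak_latency",
]


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing parameters: band-pass edges, notch, orders."""

    bandpass_low: float = 20.0
    bandpass_high: float = 400.0
    notch_freq: float = 50.0
    order: int = 4
    notch_quality: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.notch_freq <= 0 or self.notch_quality <= 0 or self.order < 1:
            raise ValueError("notch_freq, notch_quality, order must be positive")


@dataclass(frozen=True)
class PeakLatencyResult:
    """Peak latency of one muscle on one first segment."""

    muscle: str
    latency: float
    peak_time: float
    segment: TrialEvent

    def __post_init__(self) -> None:
        if not 0.0 <= self.latency <= self.segment.duration + 1e-9:
            raise ValueError(
                f"{self.muscle}: latency {self.latency:.3f}s outside segment "
                f"duration {self.segment.duration:.3f}s"
            )


def preprocess(emg: EmgRecording, spec: FilterSpec = FilterSpec()) -> EmgRecording:
    """Zero-phase band-pass then zero-phase notch, per channel.

    Grid and channel labels are preserved.  The upper band edge must
    stay below Nyquist.
    """
    fs = emg.sample_rate
    if fs <= 2.0 * spec.bandpass_high:
        raise ValueError(
            f"bandpass_high={spec.bandpass_high} Hz violates Nyquist for "
            f"sample rate {fs} Hz"
        )
    sos = butter(
        spec.order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    b_notch, a_notch = iirnotch(spec.notch_freq, spec.notch_quality, fs=fs)
    out = sosfiltfilt(sos, emg.samples, axis=0)
    out = filtfilt(b_notch, a_notch, out, axis=0)
    return EmgRecording(
        times=emg.times, channels=emg.channels, samples=out, sample_rate=fs
    )


def envelope(
    signal: np.ndarray,
    sample_rate: float,
    window: float = 0.050,
    smoothing_cutoff: float | None = 1.5,
) -> np.ndarray:
    """Amplitude envelope: centered moving RMS, optionally low-passed.

    ``window`` is the RMS window length in seconds (must span at least
    2 samples and fit inside the signal).  ``smoothing_cutoff`` applies
    a zero-phase 2nd-order low-pass to the RMS trace, stabilizing the
    argmax of flat-topped bursts; ``None`` disables it.
    """
    signal = np.asarray(signal, dtype=float)
    n_win = int(round(window * sample_rate))
    if n_win < 2:
        raise ValueError(f"window {window}s spans {n_win} samples; need >= 2")
    if n_win > signal.shape[0]:
        raise ValueError(
            f"window {window}s ({n_win} samples) longer than signal "
            f"({signal.shape[0]} samples)"
        )
    power = np.clip(uniform_filter1d(signal**2, size=n_win, mode="nearest"), 0.0, None)
    env = np.sqrt(power)
    if smoothing_cutoff is not None and smoothing_cutoff < sample_rate / 2:
        sos = butter(2, smoothing_cutoff, btype="lowpass", fs=sample_rate, output="sos")
        env = np.maximum(sosfiltfilt(sos, env), 0.0)
    return env


def peak_latency(
    emg: EmgRecording,
    events: EventLog,
    spec: FilterSpec = FilterSpec(),
    ball_mode: str = "big",
    phase: str | None = None,
    feedback: str | None = None,
    window: float = 0.050,
    smoothing_cutoff: float | None = 1.5,
    mode: str = "envelope",
) -> list[PeakLatencyResult]:
    """Per-muscle peak latency on the first segment of the selected cell.

    Pipeline per muscle: preprocess -> envelope (or rectify when
    ``mode='abs'``) -> restrict to the segment's closed interval ->
    latency = argmax time minus appearance (earliest sample on
    plateaus).
    """
    if mode not in ("envelope", "abs"):
        raise ValueError(f"mode must be 'envelope' or 'abs', got {mode!r}")
    trial = first_segment(events, ball_mode, phase=phase, feedback=feedback)
    if trial.appear < emg.times[0] - 1e-9 or trial.disappear > emg.times[-1] + 1e-9:
        raise ValueError(
            f"EMG does not cover trial {trial.index} "
            f"[{trial.appear:.3f}, {trial.disappear:.3f}] s"
        )
    clean = preprocess(emg, spec)
    lo = np.searchsorted(clean.times, trial.appear - 1e-9, side="left")
    hi = np.searchsorted(clean.times, trial.disappear + 1e-9, side="right")
    results = []
    for muscle in clean.channels:
        sig = clean.channel(muscle)
        if mode == "envelope":
            env = envelope(sig, clean.sample_rate, window, smoothing_cutoff)
        else:
            env = np.abs(sig)
        seg_env = env[lo:hi]
        i = int(np.argmax(seg_env))
        peak_time = float(clean.times[lo + i])
        results.append(
            PeakLatencyResult(
                muscle=muscle,
                latency=peak_time - trial.appear,
                peak_time=peak_time,
                segment=trial,
            )
        )
    return results
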