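"""Preprocessing: continuous recordings -> clean, cue-locked epoch sets.

The stage order is fixed and mirrors standard practice for this kind of
cueing-paradigm EEG analysis:

    band-pass filter -> bad-channel removal -> common average reference
    -> resample -> epoch segmentation -> artifact rejection
    -> minimum-trial gate

Artifact rejection is a configurable amplitude criterion (epochs with any
sample beyond a threshold on a retained channel are dropped). Every removal
(channel or epoch) is logged with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import firwin, fftconvolve, resample_poly

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "design_bandpass_fir",
    "bandpass_filter",
    "detect_bad_channels",
    "drop_channels",
    "rereference_average",
    "resample",
    "segment_epochs",
    "reject_artifact_epochs",
    "enforce_min_trials",
    "preprocess_recording",
]


@dataclass
class ContinuousRecording:
    """Multi-channel continuous time series with event markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_times)
        Signal in uV.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
    events : list of (int, str)
        (sample index, marker string) pairs, e.g. ``(12345, "cueL")``.
    info : dict
        Free-form metadata (subject, session, condition, ...).
    """

    data: np.ndarray
    fs: float
    ch_names: list
    events: list
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, time)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel label count mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        n = self.data.shape[1]
        for samp, _ in self.events:
            if not 0 <= samp < n:
                raise ValueError(f"event sample {samp} outside recording")

    @property
    def n_times(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Cue-locked trials x channels x time, with per-trial metadata.

    ``times`` is in ms relative to cue onset. ``metadata`` has one row per
    epoch with at least a ``side`` column ("L"/"R"); ``rejection_log`` is a
    list of dicts recording every dropped epoch and the reason.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: list
    metadata: pd.DataFrame
    rejection_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata row count mismatch")
        if "side" in self.metadata.columns:
            bad = set(self.metadata["side"]) - {"L", "R"}
            if bad:
                raise ValueError(f"invalid cue sides: {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def design_bandpass_fir(
    fs: float, low: float = 1.0, high: float = 30.0
) -> np.ndarray:
    """Linear-phase FIR band-pass kernel (odd length, symmetric).

    The transition width is ``low / 2`` on both edges, which places one
    octave below the low edge (and far more than an octave above the high
    edge) well inside the Hamming-window stopband (>= 50 dB attenuation),
    with passband ripple far below 1 dB.
    """
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={fs} Hz")
    trans = low / 2.0
    numtaps = int(np.ceil(6.6 * fs / trans))
    if numtaps % 2 == 0:
        numtaps += 1
    return firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass_filter(
    rec: ContinuousRecording, low: float = 1.0, high: float = 30.0
) -> ContinuousRecording:
    """Zero-phase FIR band-pass filter of a continuous recording.

    A symmetric (linear-phase) kernel applied in a single pass with centered
    convolution has exactly zero phase, so alpha dynamics are not shifted in
    time.
    """
    kern = design_bandpass_fir(rec.fs, low, high)
    filtered = fftconvolve(rec.data, kern[np.newaxis, :], mode="same", axes=-1)
    return ContinuousRecording(
        data=filtered,
        fs=rec.fs,
        ch_names=list(rec.ch_names),
        events=list(rec.events),
        info=dict(rec.info),
    )


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale <= 0:
        # all values (nearly) identical; nothing deviates
        return np.zeros_like(x)
    return (x - med) / scale


def detect_bad_channels(
    rec: ContinuousRecording, z_threshold: float = 5.0
) -> list:
    """Flag channels with outlying kurtosis or log-variance.

    Both statistics are converted to robust z-scores (median/MAD) across
    channels; a channel whose absolute z exceeds ``z_threshold`` on either
    criterion is flagged. This mirrors common automated bad-channel
    detection based on kurtosis and amplitude-probability criteria.
    """
    if rec.data.shape[0] < 4:
        raise ValueError("need at least 4 channels for bad-channel detection")
    kurt = stats.kurtosis(rec.data, axis=1, fisher=True, bias=True)
    logvar = np.log(np.var(rec.data, axis=1) + np.finfo(float).tiny)
    zk = _robust_z(kurt)
    zv = _robust_z(logvar)
    flagged = np.abs(zk) > z_threshold
    flagged |= np.abs(zv) > z_threshold
    return [name for name, bad in zip(rec.ch_names, flagged) if bad]


def drop_channels(rec: ContinuousRecording, labels) -> ContinuousRecording:
    """Remove the given channels from a recording."""
    labels = set(labels)
    keep = [i for i, name in enumerate(rec.ch_names) if name not in labels]
    return ContinuousRecording(
        data=rec.data[keep],
        fs=rec.fs,
        ch_names=[rec.ch_names[i] for i in keep],
        events=list(rec.events),
        info=dict(rec.info),
    )


def rereference_average(obj):
    """Re-reference to the common average of all retained channels.

    Works on a :class:`ContinuousRecording` or an :class:`EpochSet`; at
    every sample the mean over channels becomes zero. Idempotent.
    """
    if isinstance(obj, ContinuousRecording):
        if obj.data.shape[0] < 2:
            raise ValueError("need at least 2 channels to average-reference")
        data = obj.data - obj.data.mean(axis=0, keepdims=True)
        return ContinuousRecording(
            data=data, fs=obj.fs, ch_names=list(obj.ch_names),
            events=list(obj.events), info=dict(obj.info),
        )
    if isinstance(obj, EpochSet):
        if obj.data.shape[1] < 2:
            raise ValueError("need at least 2 channels to average-reference")
        data = obj.data - obj.data.mean(axis=1, keepdims=True)
        return EpochSet(
            data=data, times=obj.times, fs=obj.fs, ch_names=list(obj.ch_names),
            metadata=obj.metadata.copy(), rejection_log=list(obj.rejection_log),
        )
    raise TypeError(f"cannot re-reference object of type {type(obj)!r}")


def resample(rec: ContinuousRecording, target_fs: float = 200.0) -> ContinuousRecording:
    """Downsample a recording with polyphase anti-alias filtering.

    Event sample indices are rescaled to the new rate. Upsampling is
    rejected (the pipeline only ever decimates).
    """
    if target_fs >= rec.fs:
        raise ValueError(
            f"target rate {target_fs} Hz must be below the current rate {rec.fs} Hz"
        )
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = resample_poly(rec.data, up, down, axis=-1)
    ratio = target_fs / rec.fs
    events = [(int(round(samp * ratio)), label) for samp, label in rec.events]
    n = data.shape[1]
    events = [(s, lab) for s, lab in events if 0 <= s < n]
    return ContinuousRecording(
        data=data, fs=float(target_fs), ch_names=list(rec.ch_names),
        events=events, info=dict(rec.info),
    )


def segment_epochs(
    rec: ContinuousRecording,
    window: tuple[float, float] = (-1500.0, 4000.0),
    markers: tuple = ("cueL", "cueR"),
) -> EpochSet:
    """Cut cue-locked epochs around every cue marker.

    The epoch time axis includes both window endpoints; the sample at the
    cue marker has time exactly 0 ms. Epochs truncated by the recording
    edges are dropped and logged.
    """
    side_of = {"cueL": "L", "cueR": "R"}
    lo = int(round(window[0] * rec.fs / 1000.0))
    hi = int(round(window[1] * rec.fs / 1000.0))
    times = np.arange(lo, hi + 1) / rec.fs * 1000.0
    epochs, rows, log = [], [], []
    cue_events = [(s, lab) for s, lab in rec.events if lab in markers]
    if not cue_events:
        raise ValueError(f"no cue markers {markers} found in recording")
    for idx, (samp, label) in enumerate(cue_events):
        start, stop = samp + lo, samp + hi
        if start < 0 or stop >= rec.n_times:
            log.append({"epoch": idx, "reason": "truncated_by_edge",
                        "marker_sample": samp})
            continue
        epochs.append(rec.data[:, start : stop + 1])
        rows.append({
            "epoch": idx,
            "side": side_of.get(label, label),
            "marker_sample": samp,
            "condition": rec.info.get("condition"),
            "subject": rec.info.get("subject"),
            "session": rec.info.get("session"),
        })
    data = (np.stack(epochs) if epochs
            else np.empty((0, rec.data.shape[0], len(times))))
    return EpochSet(
        data=data, times=times, fs=rec.fs, ch_names=list(rec.ch_names),
        metadata=pd.DataFrame(rows, columns=[
            "epoch", "side", "marker_sample", "condition", "subject", "session"
        ]),
        rejection_log=log,
    )


def reject_artifact_epochs(ep: EpochSet, amp_threshold: float = 100.0) -> EpochSet:
    """Drop epochs with any sample beyond ``amp_threshold`` uV (absolute).

    Stand-in for classifier-based artifact removal; the threshold is fully
    configurable and each removed epoch is logged with its peak amplitude.
    """
    if not amp_threshold > 0:
        raise ValueError("amplitude threshold must be positive")
    peaks = np.max(np.abs(ep.data), axis=(1, 2)) if ep.n_trials else np.empty(0)
    keep = peaks <= amp_threshold
    log = list(ep.rejection_log)
    for i in np.flatnonzero(~keep):
        log.append({
            "epoch": int(ep.metadata.iloc[i]["epoch"]),
            "reason": "amplitude",
            "peak_uV": float(peaks[i]),
        })
    return EpochSet(
        data=ep.data[keep],
        times=ep.times,
        fs=ep.fs,
        ch_names=list(ep.ch_names),
        metadata=ep.metadata.iloc[keep].reset_index(drop=True),
        rejection_log=log,
    )


def enforce_min_trials(ep: EpochSet, min_trials: int = 100) -> bool:
    """Session inclusion flag: True iff at least ``min_trials`` epochs remain.

    The gate is strict below the threshold: a session with exactly
    ``min_trials`` valid epochs is included, one fewer is excluded.
    """
    return ep.n_trials >= min_trials


def preprocess_recording(
    rec: ContinuousRecording,
    low: float = 1.0,
    high: float = 30.0,
    bad_z_threshold: float = 5.0,
    target_fs: float = 200.0,
    window: tuple[float, float] = (-1500.0, 4000.0),
    amp_threshold: float = 100.0,
    min_trials: int = 100,
) -> tuple[EpochSet, dict]:
    """Run the full fixed-order preprocessing chain on one recording.

    Returns the epoch set and a log dict with the removed channels, the
    epoch rejection log, and the inclusion flag from the minimum-trial gate.
    """
    filtered = bandpass_filter(rec, low, high)
    bads = detect_bad_channels(filtered, bad_z_threshold)
    cleaned = drop_channels(filtered, bads) if bads else filtered
    reref = rereference_average(cleaned)
    down = resample(reref, target_fs)
    epochs = segment_epochs(down, window)
    epochs = reject_artifact_epochs(epochs, amp_threshold)
    included = enforce_min_trials(epochs, min_trials)
    log = {
        "bad_channels": bads,
        "n_epochs": epochs.n_trials,
        "rejection_log": epochs.rejection_log,
        "included": included,
    }
    return epochs, log
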