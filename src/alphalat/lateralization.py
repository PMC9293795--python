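"""Cue-dependent lateralization index (LI) over time-frequency space.

For each lateralized posterior electrode pair, every trial's channels are
relabeled contralateral/ipsilateral according to the cued hemifield; power
is averaged over trials *first* and the LI is the normalized difference of
those trial-averaged powers,

    LI = (pow_ipsi - pow_contra) / (pow_contra + pow_ipsi),

bounded in [-1, 1]. Positive LI means higher ipsilateral alpha power - the
signature of covertly attending the contralateral hemifield. Pair-level LI
maps are averaged over the three posterior pairs, temporally smoothed with
a 50-frame moving average (250 ms at 200 Hz), and only then enter any
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .timefreq import TFPower

__all__ = [
    "DEFAULT_PAIRS",
    "hemisphere",
    "assign_contra_ipsi",
    "lateralization_index",
    "trial_pair_power",
    "subject_li_map",
    "smooth_time",
    "bin_tests",
    "LateralizationMap",
]

#: The three posterior electrode pairs entering the analysis.
DEFAULT_PAIRS = (("P7", "P8"), ("P3", "P4"), ("CP5", "CP6"))


def hemisphere(label: str) -> str:
    """Hemisphere of a 10-20 electrode label: odd index left, even right."""
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        raise ValueError(f"midline or unparseable electrode label: {label!r}")
    return "L" if int(digits) % 2 == 1 else "R"


def assign_contra_ipsi(pair: tuple, cue_side: str) -> tuple:
    """Map an electrode pair to (contralateral, ipsilateral) for a cue side.

    The contralateral electrode lies in the hemisphere opposite the cued
    hemifield: cue left -> right-hemisphere member is contralateral.
    """
    if cue_side not in ("L", "R"):
        raise ValueError(f"unknown cue side {cue_side!r}; expected 'L' or 'R'")
    hemis = {hemisphere(lab): lab for lab in pair}
    if set(hemis) != {"L", "R"}:
        raise ValueError(f"pair {pair} must have one electrode per hemisphere")
    contra_hemi = "R" if cue_side == "L" else "L"
    return hemis[contra_hemi], hemis["L" if contra_hemi == "R" else "R"]


def lateralization_index(pow_contra, pow_ipsi):
    """LI = (pow_ipsi - pow_contra) / (pow_contra + pow_ipsi).

    Accepts scalars or arrays of nonnegative power. Points where the
    denominator is zero are undefined and returned as NaN (flagged missing,
    excluded from averages downstream).
    """
    pc = np.asarray(pow_contra, dtype=float)
    pi = np.asarray(pow_ipsi, dtype=float)
    if np.any(pc < 0) or np.any(pi < 0):
        raise ValueError("power must be nonnegative")
    denom = pc + pi
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(denom > 0, (pi - pc) / np.where(denom > 0, denom, 1.0), np.nan)
    if li.ndim == 0:
        return float(li)
    return li


@dataclass
class LateralizationMap:
    """Per-subject (x condition) LI over frequency x time.

    Houses the trial-averaged contralateral and ipsilateral power (averaged
    over pairs) alongside the pair-averaged LI itself.
    """

    li: np.ndarray
    pow_contra: np.ndarray
    pow_ipsi: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    pairs_used: tuple
    dropped_pairs: tuple = ()
    info: dict = field(default_factory=dict)


def trial_pair_power(
    tf: TFPower, sides, pairs: tuple = DEFAULT_PAIRS
) -> tuple[np.ndarray, np.ndarray, tuple, tuple]:
    """Trial-level contralateral/ipsilateral power for each electrode pair.

    Returns ``(pow_contra, pow_ipsi, pairs_used, pairs_dropped)`` with power
    arrays of shape (n_trials, n_pairs, n_freqs, n_times). A pair with a
    removed channel is dropped (and reported) rather than interpolated.
    """
    sides = np.asarray(sides)
    if len(sides) != tf.power.shape[0]:
        raise ValueError("one cue side per trial required")
    bad_sides = set(sides) - {"L", "R"}
    if bad_sides:
        raise ValueError(f"invalid cue sides: {bad_sides}")
    index = {name: i for i, name in enumerate(tf.ch_names)}
    used, dropped, contra_all, ipsi_all = [], [], [], []
    for pair in pairs:
        if pair[0] not in index or pair[1] not in index:
            dropped.append(pair)
            continue
        used.append(pair)
        contra = np.empty(tf.power.shape[0:1] + tf.power.shape[2:])
        ipsi = np.empty_like(contra)
        for side in ("L", "R"):
            mask = sides == side
            if not mask.any():
                continue
            c_lab, i_lab = assign_contra_ipsi(pair, side)
            contra[mask] = tf.power[mask, index[c_lab]]
            ipsi[mask] = tf.power[mask, index[i_lab]]
        contra_all.append(contra)
        ipsi_all.append(ipsi)
    if not used:
        raise ValueError("no analysis pair has both channels retained")
    pow_contra = np.stack(contra_all, axis=1)
    pow_ipsi = np.stack(ipsi_all, axis=1)
    return pow_contra, pow_ipsi, tuple(used), tuple(dropped)


def subject_li_map(
    tf: TFPower,
    sides,
    pairs: tuple = DEFAULT_PAIRS,
    smooth_window: int | None = None,
    info: dict | None = None,
) -> LateralizationMap:
    """Subject-level LI map: average power over trials, LI, mean over pairs.

    Requires at least one valid trial per cue side present in ``sides``.
    Optionally applies the temporal moving-average smoothing at the end.
    """
    sides = np.asarray(sides)
    for side in np.unique(sides):
        if side not in ("L", "R"):
            raise ValueError(f"invalid cue side {side!r}")
    pc, pi, used, dropped = trial_pair_power(tf, sides, pairs)
    mean_c = pc.mean(axis=0)  # (pairs, freqs, times)
    mean_i = pi.mean(axis=0)
    li_pairs = lateralization_index(mean_c, mean_i)
    li = np.nanmean(li_pairs, axis=0)
    if smooth_window:
        li = smooth_time(li, smooth_window)
    return LateralizationMap(
        li=li,
        pow_contra=mean_c.mean(axis=0),
        pow_ipsi=mean_i.mean(axis=0),
        freqs=tf.freqs,
        times=tf.times,
        pairs_used=used,
        dropped_pairs=dropped,
        info=info or {},
    )


def smooth_time(x: np.ndarray, window: int = 50, axis: int = -1) -> np.ndarray:
    """Centered moving average along ``axis`` with truncated edge windows.

    For an even ``window`` w the average at index i covers
    ``[i - (w//2 - 1), i + w//2]`` (numpy 'same' convention); at the edges
    the window shrinks to what is covered and the divisor shrinks with it,
    so a constant input is exactly unchanged. 50 frames at 200 Hz = 250 ms.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds axis length {n}")
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.moveaxis(x, axis, -1)
    left = (window - 1) // 2
    right = window // 2
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    out = (cs[..., hi] - cs[..., lo]) / (hi - lo)
    return np.moveaxis(out, -1, axis)


def bin_tests(
    maps: dict,
    freqs: np.ndarray,
    times: np.ndarray,
    bins: tuple = ((0.0, 800.0), (800.0, 1600.0), (1600.0, 2400.0)),
    band: tuple[float, float] = (8.0, 14.0),
) -> pd.DataFrame:
    """Per-condition, per-bin mean LI with a one-sample t-test against 0.

    ``maps`` maps condition name -> array (n_subjects, n_freqs, n_times) of
    smoothed subject LI maps. Bins are half-open [a, b) on the time axis
    (a frame at exactly 800 ms belongs to the 800-1600 ms bin); the band is
    inclusive. Zero-variance cells are flagged (t = NaN, p = 1).
    """
    freqs = np.asarray(freqs)
    times = np.asarray(times)
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    if not band_mask.any():
        raise ValueError(f"band {band} Hz contains no frequency samples")
    rows = []
    for cond, arr in maps.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] < 2:
            raise ValueError("bin tests require at least 2 subjects")
        for lo, hi in bins:
            tmask = (times >= lo) & (times < hi)
            if not tmask.any():
                rows.append({
                    "condition": cond, "bin_start_ms": lo, "bin_end_ms": hi,
                    "mean_li": np.nan, "t": np.nan, "df": arr.shape[0] - 1,
                    "p": np.nan,
                })
                continue
            vals = np.nanmean(arr[:, band_mask][:, :, tmask], axis=(1, 2))
            n = len(vals)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1))
            if sd == 0.0:
                t, p = (np.nan, 1.0)
            else:
                t = mean / (sd / np.sqrt(n))
                p = float(2.0 * sstats.t.sf(abs(t), df=n - 1))
            rows.append({
                "condition": cond, "bin_start_ms": lo, "bin_end_ms": hi,
                "mean_li": mean, "t": t, "df": n - 1, "p": p,
            })
    return pd.DataFrame(rows)
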