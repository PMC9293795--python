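"""Cluster-based permutation inference in time-frequency space.

Three null constructions are implemented, one per scientific question:

* **Cue lateralization** - is there any cue-dependent lateralization at
  all? The null is built by shuffling the contralateral/ipsilateral channel
  assignment independently per trial (p = 0.5), which destroys cue-locked
  lateralization while preserving everything else.
* **Condition contrast** - does the stress condition lateralize more than
  control? The null flips the stress/control label independently per
  subject (sign flips of the paired differences).
* **Cortisol coupling** - does the between-session LI difference covary
  with the cortisol response difference (dAUCi)? The null permutes the
  dAUCi values across subjects.

All three share the same cluster machinery: pointwise statistics are
thresholded at a two-sided pointwise p < alpha, suprathreshold points are
grouped into 4-connected clusters separately by sign, each cluster's mass
is the summed statistic, and observed masses are referred to the null
distribution of the maximum absolute cluster mass over iterations. Cluster
p-values use the add-one estimator p = (1 + #{null >= obs}) / (1 + n_perm),
so the attainable floor is exactly 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .lateralization import smooth_time

__all__ = [
    "TFStatMap",
    "Cluster",
    "ClusterResult",
    "pointwise_t",
    "t_threshold",
    "find_clusters",
    "permtest_cue_lateralization",
    "permtest_condition",
    "corr_map",
    "permtest_correlation",
    "fisher_z",
    "fisher_window_test",
    "FisherWindowResult",
]


@dataclass
class TFStatMap:
    """Pointwise statistic map (t or Pearson r) over frequencies x time."""

    values: np.ndarray
    df: int
    kind: str = "t"
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None


@dataclass
class Cluster:
    """One suprathreshold cluster: boolean t-f mask, summed stat, sign, p."""

    mask: np.ndarray
    stat: float
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    """Observed clusters plus the max-cluster null distribution."""

    clusters: list
    null_max_stats: np.ndarray
    threshold: float
    n_perm: int
    seed: int | None = None
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None
    stat_name: str = "summed_t"
    extra: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p < alpha]

    @property
    def min_p(self) -> float:
        if not self.clusters:
            return 1.0
        return min(c.p for c in self.clusters)


def pointwise_t(values: np.ndarray, mode: str = "one-sample",
                values_b: np.ndarray | None = None) -> TFStatMap:
    """Pointwise t-statistics over the subject axis (axis 0).

    ``mode='one-sample'`` tests against 0; ``mode='paired'`` takes the
    one-sample t of ``values - values_b`` for matched subjects. Points with
    zero variance are flagged NaN and treated as subthreshold downstream.
    """
    x = np.asarray(values, dtype=float)
    if mode == "paired":
        if values_b is None:
            raise ValueError("paired mode requires a second array")
        b = np.asarray(values_b, dtype=float)
        if b.shape != x.shape:
            raise ValueError("paired arrays must have matching subjects/shape")
        x = x - b
    elif mode != "one-sample":
        raise ValueError(f"unknown mode {mode!r}")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0) * np.sqrt(n), np.nan)
    return TFStatMap(values=t, df=n - 1, kind="t")


def t_threshold(df: int, alpha_point: float = 0.05) -> float:
    """Two-sided critical t at pointwise level ``alpha_point``."""
    return float(sstats.t.ppf(1.0 - alpha_point / 2.0, df))


def _label_clusters(values: np.ndarray, threshold: float) -> list:
    """4-connected suprathreshold clusters, positive and negative separately."""
    vals = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    clusters = []
    for sign in (1, -1):
        mask = (sign * vals) > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)  # default structure = 4-connectivity
        for k in range(1, n + 1):
            cmask = labels == k
            clusters.append(
                Cluster(mask=cmask, stat=float(vals[cmask].sum()), sign=sign)
            )
    clusters.sort(key=lambda c: abs(c.stat), reverse=True)
    return clusters


def find_clusters(stat_map, threshold: float | None = None,
                  alpha_point: float = 0.05) -> list:
    """Cluster a statistic map at a two-sided pointwise threshold.

    ``stat_map`` is a :class:`TFStatMap` (threshold derived from its df for
    t maps unless given explicitly) or a bare array with an explicit
    ``threshold``. NaN points are subthreshold by definition.
    """
    if isinstance(stat_map, TFStatMap):
        values = stat_map.values
        if threshold is None:
            if stat_map.kind != "t":
                raise ValueError("explicit threshold required for non-t maps")
            threshold = t_threshold(stat_map.df, alpha_point)
    else:
        values = np.asarray(stat_map)
        if threshold is None:
            raise ValueError("threshold required when passing a bare array")
    return _label_clusters(values, threshold)


def _max_cluster_stat(values: np.ndarray, threshold: float) -> float:
    """Maximum absolute cluster mass of a map (0.0 if nothing suprathreshold)."""
    vals = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    best = 0.0
    for sign in (1, -1):
        mask = (sign * vals) > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)
        sums = ndimage.sum_labels(vals, labels, np.arange(1, n + 1))
        best = max(best, float(np.max(np.abs(sums))))
    return best


def _add_one_p(obs: float, null: np.ndarray) -> float:
    return float((1 + np.sum(null >= abs(obs))) / (1 + len(null)))


def _attach_p(clusters: list, null: np.ndarray) -> None:
    for c in clusters:
        c.p = _add_one_p(c.stat, null)


def _rows_t(sum_x: np.ndarray, sum_x2: np.ndarray, n: int) -> np.ndarray:
    """Row-wise one-sample t from accumulated sums over subjects."""
    mean = sum_x / n
    var = (sum_x2 - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var > 0, mean / np.sqrt(np.where(var > 0, var, 1.0) / n), np.nan)
    return t


def permtest_cue_lateralization(
    pow_contra: list,
    pow_ipsi: list,
    freqs: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_point: float = 0.05,
    smooth_window: int | None = 50,
) -> ClusterResult:
    """Cue-lateralization cluster test against trial-shuffled surrogates.

    Parameters
    ----------
    pow_contra, pow_ipsi : list of ndarray
        Per subject, trial-level power with shape
        (n_trials, n_pairs, n_freqs, n_times) under the *observed*
        contra/ipsi assignment.
    n_perm : int
        Number of permutation iterations (must be >= 1).
    smooth_window : int or None
        Temporal moving-average width applied to each subject-level
        difference map before the group t.

    Notes
    -----
    The observed statistic is the one-sample t over subjects of
    (LI_observed - LI_surrogate), where each subject's surrogate LI is
    built by swapping the contra/ipsi assignment independently per trial
    with p = 0.5 (one fixed draw per subject). Each null iteration
    replaces LI_observed by a freshly re-shuffled LI, keeping the same
    fixed surrogate, which destroys cue-locked lateralization while
    preserving exchangeability. Because the contra+ipsi power *sum* is
    invariant under per-trial swaps, every re-shuffled LI is an exactly
    linear function of the swap indicators, so all iterations reduce to
    one matrix product per subject.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_subj = len(pow_contra)
    if n_subj < 2 or len(pow_ipsi) != n_subj:
        raise ValueError("need matched contra/ipsi data for >= 2 subjects")
    rng = np.random.default_rng(seed)
    nf, nt = len(freqs), len(times)
    n_rows = n_perm + 1  # row 0 = observed (vs the fixed surrogate)
    sum_x = np.zeros((n_rows, nf * nt))
    sum_x2 = np.zeros((n_rows, nf * nt))
    for pc, pi in zip(pow_contra, pow_ipsi):
        pc = np.asarray(pc, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if pc.ndim == 3:  # single implicit pair
            pc, pi = pc[:, None], pi[:, None]
        if pc.shape != pi.shape or pc.ndim != 4:
            raise ValueError("per-subject power must be (trials, pairs, f, t)")
        n_tr, n_pairs = pc.shape[:2]
        if n_tr < 1:
            raise ValueError("subject with no trials")
        mean_c = pc.mean(axis=0)
        mean_i = pi.mean(axis=0)
        total = mean_c + mean_i  # invariant under per-trial swaps
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(total > 0, 1.0 / np.where(total > 0, total, 1.0), np.nan)
        # LI(swaps s) = LI_obs - s @ G, per pair; G_t = 2 (ipsi_t - contra_t) / (n * total)
        g = 2.0 * (pi - pc) * inv[None] / n_tr  # (trials, pairs, f, t)
        g = np.nan_to_num(g, nan=0.0).mean(axis=1).reshape(n_tr, nf * nt)
        # LI under swap vector s is LI_obs - s @ G; with the fixed
        # surrogate s_fix, row 0 (observed) is LI_obs - LI(s_fix)
        # = s_fix @ G and null row i is LI(s_i) - LI(s_fix)
        # = (s_fix - s_i) @ G.
        s_fix = (rng.random(n_tr) < 0.5).astype(np.float32)
        s_perm = (rng.random((n_perm, n_tr)) < 0.5).astype(np.float32)
        coeff = np.vstack([s_fix[None], s_fix[None] - s_perm])
        x = (coeff @ g.astype(np.float32)).astype(np.float64)
        if smooth_window:
            x = smooth_time(x.reshape(n_rows, nf, nt), smooth_window).reshape(
                n_rows, nf * nt
            )
        sum_x += x
        sum_x2 += x**2
    t_rows = _rows_t(sum_x, sum_x2, n_subj).reshape(n_rows, nf, nt)
    thresh = t_threshold(n_subj - 1, alpha_point)
    clusters = _label_clusters(t_rows[0], thresh)
    null = np.array([_max_cluster_stat(t_rows[i], thresh) for i in range(1, n_rows)])
    _attach_p(clusters, null)
    return ClusterResult(
        clusters=clusters, null_max_stats=null, threshold=thresh,
        n_perm=n_perm, seed=seed, freqs=np.asarray(freqs),
        times=np.asarray(times), stat_name="summed_t",
        extra={"observed_map": t_rows[0]},
    )


def permtest_condition(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_point: float = 0.05,
    exact: bool = False,
) -> ClusterResult:
    """Paired condition-contrast cluster test with subject-level sign flips.

    ``maps_a``/``maps_b`` are (n_subjects, n_freqs, n_times) smoothed LI
    maps for the two conditions (matched subject order). The observed map
    is the paired t of (a - b); each null iteration flips each subject's
    condition label independently with p = 0.5. With ``exact=True`` all
    2**n sign patterns are enumerated instead of sampled (n <= 16).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition maps must be matched per subject")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1 and not exact:
        raise ValueError("n_perm must be >= 1")
    d = (a - b).reshape(n, -1)
    nf, nt = len(freqs), len(times)
    if exact:
        if n > 16:
            raise ValueError("exact enumeration limited to n <= 16 subjects")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        n_perm = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    ssq = (d**2).sum(axis=0)  # invariant under sign flips
    obs_t = _rows_t(d.sum(axis=0)[None], ssq[None], n)[0].reshape(nf, nt)
    thresh = t_threshold(n - 1, alpha_point)
    clusters = _label_clusters(obs_t, thresh)
    t_rows = _rows_t(signs @ d, ssq[None], n)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _max_cluster_stat(t_rows[i].reshape(nf, nt), thresh)
    _attach_p(clusters, null)
    return ClusterResult(
        clusters=clusters, null_max_stats=null, threshold=thresh,
        n_perm=n_perm, seed=seed, freqs=np.asarray(freqs),
        times=np.asarray(times), stat_name="summed_t",
        extra={"observed_map": obs_t, "exact": exact},
    )


def corr_map(delta_li: np.ndarray, delta_auci: np.ndarray) -> TFStatMap:
    """Pointwise Pearson r between per-subject dLI maps and dAUCi values."""
    x = np.asarray(delta_li, dtype=float)
    y = np.asarray(delta_auci, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 subjects")
    if len(y) != n:
        raise ValueError("one dAUCi value per subject required")
    if np.std(y) == 0:
        raise ValueError("dAUCi has zero variance across subjects")
    xc = x.reshape(n, -1) - x.reshape(n, -1).mean(axis=0)
    yc = y - y.mean()
    xnorm = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (np.sqrt((yc**2).sum()) * np.where(xnorm > 0, xnorm, np.nan))
    return TFStatMap(values=r.reshape(x.shape[1:]), df=n - 2, kind="r")


def r_threshold(df: int, alpha_point: float = 0.05) -> float:
    """Critical |r| whose t-transform hits the two-sided pointwise level."""
    tc = t_threshold(df, alpha_point)
    return float(tc / np.sqrt(df + tc**2))


def permtest_correlation(
    delta_li: np.ndarray,
    delta_auci: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_point: float = 0.05,
) -> ClusterResult:
    """Cluster test of the dLI ~ dAUCi correlation map.

    Pointwise r values are thresholded through the t-transform of r
    (df = n - 2); cluster mass is the summed r. The null permutes the
    dAUCi values across subjects, breaking the systematic relation while
    preserving both marginals.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(delta_li, dtype=float)
    y = np.asarray(delta_auci, dtype=float)
    obs = corr_map(x, y)  # validates inputs
    n = x.shape[0]
    nf, nt = len(freqs), len(times)
    thresh = r_threshold(n - 2, alpha_point)
    clusters = _label_clusters(obs.values, thresh)
    rng = np.random.default_rng(seed)
    xc = x.reshape(n, -1) - x.reshape(n, -1).mean(axis=0)
    xnorm = np.sqrt((xc**2).sum(axis=0))
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    with np.errstate(invalid="ignore", divide="ignore"):
        r_rows = (perms @ xc) / (ynorm * np.where(xnorm > 0, xnorm, np.nan))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _max_cluster_stat(r_rows[i].reshape(nf, nt), thresh)
    _attach_p(clusters, null)
    return ClusterResult(
        clusters=clusters, null_max_stats=null, threshold=thresh,
        n_perm=n_perm, seed=seed, freqs=np.asarray(freqs),
        times=np.asarray(times), stat_name="summed_r",
        extra={"observed_map": obs.values},
    )


def fisher_z(r):
    """Fisher's variance-stabilizing Z transform, atanh(r)."""
    return np.arctanh(r)


@dataclass
class FisherWindowResult:
    """In-window vs out-of-window averaged Fisher-Z correlations per pair."""

    z_in: np.ndarray
    z_out: np.ndarray
    t: float
    df: int
    p: float
    flagged: bool = False


def fisher_window_test(
    r_maps: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (870.0, 1535.0),
    band: tuple[float, float] = (8.0, 14.0),
    cue_target_interval: tuple[float, float] = (0.0, 2610.0),
) -> FisherWindowResult:
    """Dependent t-test of in-window vs out-of-window mean Fisher-Z.

    ``r_maps`` holds one correlation map per channel pair, shape
    (n_pairs, n_freqs, n_times). For each pair, correlations within the
    alpha band are Fisher-Z transformed and averaged over the cluster
    window and over the remaining time points of the cue-target interval;
    the paired t across pairs (df = n_pairs - 1) is one-sided for
    in-window > out-of-window. Points with |r| = 1 (infinite Z) are
    flagged and excluded from the averages.
    """
    r = np.asarray(r_maps, dtype=float)
    if r.ndim != 3:
        raise ValueError("r_maps must be (pairs, freqs, times)")
    freqs = np.asarray(freqs)
    times = np.asarray(times)
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    in_t = (times >= window[0]) & (times <= window[1])
    interval_t = (times >= cue_target_interval[0]) & (times <= cue_target_interval[1])
    out_t = interval_t & ~in_t
    if not (band_mask.any() and in_t.any() and out_t.any()):
        raise ValueError("window/band selects no time-frequency points")
    flagged = bool(np.any(np.abs(r) >= 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.abs(r) < 1.0, np.arctanh(np.clip(r, -1, 1)), np.nan)
    z_in = np.nanmean(z[:, band_mask][:, :, in_t], axis=(1, 2))
    z_out = np.nanmean(z[:, band_mask][:, :, out_t], axis=(1, 2))
    diff = z_in - z_out
    n = len(diff)
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        t, p = 0.0, np.nan
        flagged = True
    else:
        t = float(np.mean(diff) / (sd / np.sqrt(n)))
        p = float(sstats.t.sf(t, df=n - 1))  # one-sided: in > out
    return FisherWindowResult(z_in=z_in, z_out=z_out, t=t, df=n - 1, p=p,
                              flagged=flagged)
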