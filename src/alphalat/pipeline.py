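"""End-to-end orchestration: synthesis -> preprocessing -> time-frequency
-> lateralization -> permutation statistics -> cortisol coupling.

A run is fully determined by its :class:`RunConfig`: one master seed
spawns independent per-stage streams (so changing the number of
permutations never alters the synthetic data), and rerunning the same
config reproduces the report hash exactly. Each stage failure aborts with
the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .cortisol import auc_increase
from .lateralization import (
    DEFAULT_PAIRS,
    lateralization_index,
    smooth_time,
    bin_tests,
    trial_pair_power,
)
from .permstats import (
    ClusterResult,
    corr_map,
    fisher_window_test,
    permtest_condition,
    permtest_correlation,
    permtest_cue_lateralization,
)
from .preprocess import EpochSet, preprocess_recording
from .synth import StudyConfig, iter_sessions
from .timefreq import WaveletFamily, build_wavelet_family, tf_power, prune_edges

__all__ = ["RunConfig", "RunReport", "run", "analyze_epoch_sets",
           "summarize_clusters"]


@dataclass
class RunConfig:
    """Everything that determines a pipeline run.

    ``study`` configures the synthetic study; the remaining fields are the
    analysis-stage parameters. ``seed`` is the master seed; the synthetic
    study and the three permutation tests each get an independent stream
    derived from it, so e.g. changing ``n_perm`` never changes the data.
    """

    study: StudyConfig = field(default_factory=StudyConfig)
    pairs: tuple = DEFAULT_PAIRS
    filter_band: tuple = (1.0, 30.0)
    bad_z_threshold: float = 5.0
    resample_fs: float = 200.0
    amp_threshold: float = 100.0
    min_trials: int = 100
    n_wavelets: int = 50
    wavelet_f_range: tuple = (2.0, 20.0)
    wavelet_fwhm_range: tuple = (400.0, 100.0)
    prune_window: tuple = (-500.0, 3200.0)
    smooth_window: int = 50
    band: tuple = (8.0, 14.0)
    bins: tuple = ((0.0, 800.0), (800.0, 1600.0), (1600.0, 2400.0))
    cluster_window: tuple = (870.0, 1535.0)
    n_perm: int = 1000
    alpha_point: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """The self-describing result of one pipeline run."""

    config: RunConfig
    cue_result: ClusterResult
    condition_result: ClusterResult
    correlation_result: ClusterResult
    bin_table: pd.DataFrame
    auci_table: pd.DataFrame
    fisher_result: object
    subject_maps: dict
    grand_average: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    logs: dict
    provenance: dict

    def summary_dict(self) -> dict:
        from .io import cluster_result_to_dict

        return {
            "provenance": self.provenance,
            "cue_test": cluster_result_to_dict(self.cue_result),
            "condition_test": cluster_result_to_dict(self.condition_result),
            "correlation_test": cluster_result_to_dict(self.correlation_result),
            "bin_tests": self.bin_table.to_dict(orient="records"),
            "auci": self.auci_table.to_dict(orient="records"),
            "fisher_window": {
                "t": self.fisher_result.t,
                "df": self.fisher_result.df,
                "p": self.fisher_result.p,
                "z_in": list(map(float, self.fisher_result.z_in)),
                "z_out": list(map(float, self.fisher_result.z_out)),
            },
            "n_subjects_analyzed": len(self.subject_maps),
            "excluded_subjects": self.logs.get("excluded_subjects", []),
        }

    def report_hash(self) -> str:
        blob = json.dumps(self.summary_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def to_json(self, path=None) -> str:
        text = json.dumps(self.summary_dict(), indent=2, default=str)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text, encoding="utf-8")
        return text


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class _stage:
    """Context guard attaching the stage name to any failure."""

    def __init__(self, label):
        self.label = label

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(
                f"pipeline stage '{self.label}' failed: {exc}"
            ) from exc
        return False


def _entry_from_epochs(epochs: EpochSet, family: WaveletFamily, pairs,
                       prune_window) -> dict:
    """Per-session trial-level pair power from a clean epoch set."""
    pair_labels = sorted({lab for pair in pairs for lab in pair})
    keep = [c for c in pair_labels if c in epochs.ch_names]
    idx = [epochs.ch_names.index(c) for c in keep]
    tf = tf_power(epochs.data[:, idx], epochs.times, epochs.fs, family,
                  ch_names=keep, dtype=np.float32)
    tf = prune_edges(tf, prune_window)
    sides = epochs.metadata["side"].to_numpy()
    pc, pi, used, _dropped = trial_pair_power(tf, sides, pairs)
    return {"pow_contra": pc, "pow_ipsi": pi, "pairs": used,
            "freqs": tf.freqs, "times": tf.times}


def _run_statistics(per_subject: dict, auci_df: pd.DataFrame,
                    config: RunConfig, stage_seeds, logs: dict) -> RunReport:
    """Shared statistics backend for run() and analyze_epoch_sets()."""
    with _stage("lateralization"):
        freqs = times = None
        subject_maps: dict = {}
        pair_maps: dict = {}
        excluded = []
        for subj, entry in per_subject.items():
            if len(entry) < 2 or any(v is None for v in entry.values()):
                excluded.append(subj)
                continue
            common = [p for p in entry["stress"]["pairs"]
                      if p in entry["control"]["pairs"]]
            if not common:
                excluded.append(subj)
                continue
            maps, pmaps = {}, {}
            for cond in ("stress", "control"):
                d = entry[cond]
                sel = [d["pairs"].index(p) for p in common]
                mean_c = d["pow_contra"][:, sel].mean(axis=0, dtype=np.float64)
                mean_i = d["pow_ipsi"][:, sel].mean(axis=0, dtype=np.float64)
                li_pairs = smooth_time(
                    lateralization_index(mean_c, mean_i), config.smooth_window
                )
                pmaps[cond] = li_pairs
                maps[cond] = li_pairs.mean(axis=0)
                freqs, times = d["freqs"], d["times"]
            subject_maps[subj] = maps
            pair_maps[subj] = {"pairs": common, **pmaps}
        logs["excluded_subjects"] = excluded
        if len(subject_maps) < 3:
            raise ValueError(
                f"only {len(subject_maps)} subjects usable after the trial "
                "gate; need >= 3 for the analyses"
            )
        subjects = sorted(subject_maps)
        maps_by_cond = {
            cond: np.stack([subject_maps[s][cond] for s in subjects])
            for cond in ("stress", "control")
        }
        grand = np.mean(
            [maps_by_cond["stress"], maps_by_cond["control"]], axis=0
        ).mean(axis=0)
        bin_table = bin_tests(maps_by_cond, freqs, times,
                              bins=config.bins, band=config.band)

    with _stage("cue permutation test"):
        pc_list, pi_list = [], []
        for s in subjects:
            entry = per_subject[s]
            common = pair_maps[s]["pairs"]
            pcs, pis = [], []
            for cond in ("stress", "control"):
                d = entry[cond]
                sel = [d["pairs"].index(p) for p in common]
                pcs.append(d["pow_contra"][:, sel])
                pis.append(d["pow_ipsi"][:, sel])
            pc_list.append(np.concatenate(pcs, axis=0))
            pi_list.append(np.concatenate(pis, axis=0))
        cue_result = permtest_cue_lateralization(
            pc_list, pi_list, freqs, times, n_perm=config.n_perm,
            seed=stage_seeds[0], alpha_point=config.alpha_point,
            smooth_window=config.smooth_window,
        )

    with _stage("condition permutation test"):
        condition_result = permtest_condition(
            maps_by_cond["stress"], maps_by_cond["control"], freqs, times,
            n_perm=config.n_perm, seed=stage_seeds[1],
            alpha_point=config.alpha_point,
        )

    with _stage("cortisol coupling"):
        piv = auci_df.pivot_table(index="subject", columns="condition",
                                  values="auci")
        dauc = (piv["stress"] - piv["control"]).reindex(subjects)
        auci_df = auci_df.merge(
            dauc.rename("delta_auci"), left_on="subject", right_index=True,
            how="left",
        )
        delta_li = maps_by_cond["stress"] - maps_by_cond["control"]
        correlation_result = permtest_correlation(
            delta_li, dauc.to_numpy(), freqs, times, n_perm=config.n_perm,
            seed=stage_seeds[2], alpha_point=config.alpha_point,
        )
        all_pairs = [p for p in config.pairs
                     if all(p in pair_maps[s]["pairs"] for s in subjects)]
        r_maps = []
        for pair in all_pairs:
            dmaps = np.stack([
                pair_maps[s]["stress"][pair_maps[s]["pairs"].index(pair)]
                - pair_maps[s]["control"][pair_maps[s]["pairs"].index(pair)]
                for s in subjects
            ])
            r_maps.append(corr_map(dmaps, dauc.to_numpy()).values)
        fisher_result = fisher_window_test(
            np.stack(r_maps), freqs, times, window=config.cluster_window,
            band=config.band,
            cue_target_interval=(0.0, config.study.target_onset),
        )

    provenance = {
        "package": "alphalat",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "numpy": np.__version__,
    }
    return RunReport(
        config=config, cue_result=cue_result,
        condition_result=condition_result,
        correlation_result=correlation_result, bin_table=bin_table,
        auci_table=auci_df, fisher_result=fisher_result,
        subject_maps=subject_maps, grand_average=grand,
        freqs=np.asarray(freqs), times=np.asarray(times), logs=logs,
        provenance=provenance,
    )


def _stage_seeds(master_seed: int):
    seeds = np.random.SeedSequence(master_seed).spawn(4)
    ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    return ints[0], ints[1:]


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline on a synthetic study.

    Produces per-subject (and per-pair) LI maps, the grand-average map,
    the three cluster-based permutation tests (cue lateralization against
    trial-shuffled surrogates; stress-vs-control condition contrast;
    dLI ~ dAUCi correlation), the per-condition bin-test table, the AUCi
    table and the in-window vs out-of-window Fisher-Z test.
    """
    if config.study.n_subjects < 2:
        raise ValueError("pipeline requires at least 2 subjects")
    synth_seed, stage_seeds = _stage_seeds(config.seed)
    study_cfg = StudyConfig(**{**asdict(config.study), "seed": synth_seed})

    family = build_wavelet_family(
        config.resample_fs, n=config.n_wavelets,
        f_range=config.wavelet_f_range, fwhm_range=config.wavelet_fwhm_range,
    )
    per_subject: dict = {}
    cortisol_rows = []
    logs: dict = {"sessions": {}, "excluded_subjects": []}
    with _stage("synthesis+preprocessing+timefreq"):
        for sess in iter_sessions(study_cfg):
            epochs, log = preprocess_recording(
                sess.recording,
                low=config.filter_band[0], high=config.filter_band[1],
                bad_z_threshold=config.bad_z_threshold,
                target_fs=config.resample_fs,
                window=study_cfg.epoch_window,
                amp_threshold=config.amp_threshold,
                min_trials=config.min_trials,
            )
            logs["sessions"][f"{sess.subject}/{sess.session}"] = {
                "condition": sess.condition,
                "bad_channels": log["bad_channels"],
                "n_epochs": log["n_epochs"],
                "included": log["included"],
            }
            cortisol_rows.append({
                "subject": sess.subject, "session": sess.session,
                "condition": sess.condition,
                "auci": auc_increase(sess.cortisol),
            })
            entry = per_subject.setdefault(sess.subject, {})
            if not log["included"]:
                entry[sess.condition] = None
                continue
            entry[sess.condition] = _entry_from_epochs(
                epochs, family, config.pairs, config.prune_window
            )
    return _run_statistics(per_subject, pd.DataFrame(cortisol_rows), config,
                           stage_seeds, logs)


def analyze_epoch_sets(epoch_sets, cortisol: pd.DataFrame,
                       config: RunConfig | None = None,
                       n_perm: int | None = None,
                       seed: int | None = None) -> dict:
    """Statistics on already-preprocessed epoch sets + a tidy cortisol table.

    ``epoch_sets`` carry subject/session/condition in their metadata (as
    written by the preprocessing CLI); returns the JSON-ready report
    summary.
    """
    config = config or RunConfig()
    if n_perm is not None:
        config.n_perm = n_perm
    if seed is not None:
        config.seed = seed
    _, stage_seeds = _stage_seeds(config.seed)
    family = build_wavelet_family(
        config.resample_fs, n=config.n_wavelets,
        f_range=config.wavelet_f_range, fwhm_range=config.wavelet_fwhm_range,
    )
    per_subject: dict = {}
    logs: dict = {"sessions": {}, "excluded_subjects": []}
    for ep in epoch_sets:
        meta = ep.metadata.iloc[0]
        subj, cond = meta["subject"], meta["condition"]
        entry = per_subject.setdefault(subj, {})
        if ep.n_trials < config.min_trials:
            entry[cond] = None
            continue
        entry[cond] = _entry_from_epochs(ep, family, config.pairs,
                                         config.prune_window)
    from .cortisol import auci_table

    auci_df = auci_table(cortisol)
    report = _run_statistics(per_subject, auci_df, config, stage_seeds, logs)
    return report.summary_dict()


def summarize_clusters(result: ClusterResult, alpha: float | None = 0.05,
                       ) -> pd.DataFrame:
    """Tabulate clusters: time/frequency extents (ms/Hz, closed), mass, p.

    With ``alpha`` set, only clusters significant at that level are
    reported; pass ``alpha=None`` for all clusters.
    """
    freqs = np.asarray(result.freqs)
    times = np.asarray(result.times)
    rows = []
    for c in result.clusters:
        if alpha is not None and not (c.p < alpha):
            continue
        fi, ti = np.nonzero(c.mask)
        rows.append({
            "time_min_ms": float(times[ti.min()]),
            "time_max_ms": float(times[ti.max()]),
            "freq_min_hz": float(freqs[fi.min()]),
            "freq_max_hz": float(freqs[fi.max()]),
            "stat": c.stat,
            "sign": c.sign,
            "p": c.p,
        })
    return pd.DataFrame(rows, columns=[
        "time_min_ms", "time_max_ms", "freq_min_hz", "freq_max_hz",
        "stat", "sign", "p",
    ])
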