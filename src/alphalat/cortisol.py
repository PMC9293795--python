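"""Salivary cortisol summaries: AUC with respect to increase (AUCi).

AUCi is the trapezoidal area under the concentration-time curve minus the
area of the rectangle at the baseline (first-sample) concentration -- i.e.
the area of the response *above* baseline. A flat profile has AUCi = 0 and
adding a constant to every sample leaves it unchanged. The between-session
delta (stress minus control) per subject is the endocrine covariate for
the lateralization coupling analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SAMPLE_TIMES",
    "CortisolSeries",
    "auc_increase",
    "auci_table",
    "delta_auci",
]

#: Saliva sampling times in minutes relative to stressor onset.
DEFAULT_SAMPLE_TIMES = (-10.0, 0.0, 15.0, 20.0, 35.0, 50.0, 65.0)


@dataclass
class CortisolSeries:
    """One session's cortisol profile: sample times (min) and nmol/L values."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.concentrations[np.isfinite(self.concentrations)] < 0):
            raise ValueError("concentrations must be nonnegative")


def auc_increase(series: CortisolSeries) -> float:
    """AUCi in nmol/L * min: trapezoid minus baseline * total duration.

    Baseline is the first sample's concentration. Missing (NaN) samples are
    dropped before integration; at least 2 finite samples are required.
    """
    finite = np.isfinite(series.concentrations)
    t = series.times[finite]
    c = series.concentrations[finite]
    if len(t) < 2:
        raise ValueError("need at least 2 finite samples for AUCi")
    total = float(np.trapezoid(c, t))
    return total - float(c[0]) * float(t[-1] - t[0])


def auci_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session AUCi from a tidy cortisol table.

    ``samples`` has columns subject, session, condition, time_min, nmolL
    (the TSV layout written by the synthetic generator).
    """
    rows = []
    for (subj, sess), grp in samples.groupby(["subject", "session"]):
        grp = grp.sort_values("time_min")
        series = CortisolSeries(grp["time_min"].to_numpy(),
                                grp["nmolL"].to_numpy())
        rows.append({
            "subject": subj,
            "session": sess,
            "condition": grp["condition"].iloc[0],
            "auci": auc_increase(series),
        })
    return pd.DataFrame(rows)


def delta_auci(auci: pd.DataFrame) -> tuple[pd.Series, list]:
    """dAUCi = AUCi(stress) - AUCi(control) per subject.

    Subjects missing either session are excluded and returned in the
    dropped list.
    """
    deltas, dropped = {}, []
    for subj, grp in auci.groupby("subject"):
        by_cond = grp.set_index("condition")["auci"]
        if "stress" in by_cond.index and "control" in by_cond.index:
            deltas[subj] = float(by_cond["stress"]) - float(by_cond["control"])
        else:
            dropped.append(subj)
    return pd.Series(deltas, name="delta_auci"), dropped
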