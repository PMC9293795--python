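"""File formats: BrainVision EEG, HDF5 epoch containers, TSV tables.

Continuous synthetic recordings are written as BrainVision triplets
(text .vhdr/.vmrk headers + IEEE float32 multiplexed .eeg in uV) so they
can be read back by any standard EEG stack; reading goes through
``mne.io.read_raw_brainvision``. Epoch sets and LI maps use an HDF5
container with explicit axes; cortisol tables, rejection logs, cluster
masks and null distributions are plain TSV; ground truth and cluster
summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cortisol import CortisolSeries
from .preprocess import ContinuousRecording, EpochSet

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_cortisol_tsv",
    "read_cortisol_tsv",
    "save_epochs",
    "load_epochs",
    "write_li_map_tsv",
    "cluster_result_to_dict",
    "save_cluster_result",
]


def write_brainvision(rec: ContinuousRecording, basename) -> Path:
    """Write a recording as a BrainVision triplet; returns the .vhdr path.

    Data are stored as multiplexed little-endian IEEE float32 in uV
    (resolution 1). Events become Stimulus markers with the marker string
    as description; a session-level info JSON sidecar carries subject,
    session and condition tags.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = len(rec.ch_names)
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.fs:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.ch_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (samp, label) in enumerate(rec.events, start=2):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{k}=Stimulus,{label},{samp + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    info_path = base.with_suffix(".json")
    info_path.write_text(json.dumps(rec.info, default=str), encoding="utf-8")
    return vhdr


def read_brainvision(vhdr_path) -> ContinuousRecording:
    """Read a BrainVision recording into a :class:`ContinuousRecording`.

    Uses mne's reader; data are converted back to uV and Stimulus
    annotations back to (sample, marker) events. An info JSON sidecar, if
    present, restores the session metadata.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    fs = float(raw.info["sfreq"])
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("Stimulus/"):
            desc = desc.split("/", 1)[1]
        elif desc.startswith("New Segment"):
            continue
        samp = int(round(ann["onset"] * fs))
        events.append((samp, desc))
    info = {}
    sidecar = Path(vhdr_path).with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text(encoding="utf-8"))
    return ContinuousRecording(
        data=data, fs=fs, ch_names=list(raw.ch_names), events=events, info=info
    )


def write_cortisol_tsv(series_map: dict, conditions: dict, path) -> Path:
    """Write cortisol profiles as a tidy TSV.

    ``series_map`` maps (subject, session) -> :class:`CortisolSeries`;
    ``conditions`` maps the same keys to condition names. Columns:
    subject, session, condition, time_min, nmolL.
    """
    rows = []
    for (subj, sess), series in series_map.items():
        for t, c in zip(series.times, series.concentrations):
            rows.append({
                "subject": subj, "session": sess,
                "condition": conditions[(subj, sess)],
                "time_min": t, "nmolL": c,
            })
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cortisol_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "session", "condition", "time_min", "nmolL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cortisol table missing columns: {missing}")
    return df


def cortisol_df_to_series(df: pd.DataFrame) -> tuple[dict, dict]:
    """Tidy cortisol table -> ((subject, session) -> series, -> condition)."""
    series_map, conditions = {}, {}
    for (subj, sess), grp in df.groupby(["subject", "session"]):
        grp = grp.sort_values("time_min")
        series_map[(subj, sess)] = CortisolSeries(
            grp["time_min"].to_numpy(), grp["nmolL"].to_numpy()
        )
        conditions[(subj, sess)] = grp["condition"].iloc[0]
    return series_map, conditions


def save_epochs(ep: EpochSet, path) -> Path:
    """Persist an epoch set as HDF5: data + axes + JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip")
        f.create_dataset("times_ms", data=ep.times)
        f.attrs["fs"] = ep.fs
        f.attrs["ch_names"] = json.dumps(list(ep.ch_names))
        f.attrs["metadata"] = ep.metadata.to_json(orient="records")
        f.attrs["rejection_log"] = json.dumps(ep.rejection_log, default=str)
    return path


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times_ms"][()]
        fs = float(f.attrs["fs"])
        ch_names = json.loads(f.attrs["ch_names"])
        from io import StringIO

        metadata = pd.read_json(StringIO(f.attrs["metadata"]),
                                orient="records")
        log = json.loads(f.attrs["rejection_log"])
    return EpochSet(data=data, times=times, fs=fs, ch_names=ch_names,
                    metadata=metadata, rejection_log=log)


def write_li_map_tsv(li: np.ndarray, freqs, times, path) -> Path:
    """LI map as TSV: rows = frequencies, columns = time frames.

    Axes are stored in comment header lines (Hz / ms).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as f:
        f.write("# rows: frequency (Hz); columns: time (ms)\n")
        f.write("# freqs_hz\t" + "\t".join(f"{v:g}" for v in freqs) + "\n")
        f.write("# times_ms\t" + "\t".join(f"{v:g}" for v in times) + "\n")
        np.savetxt(f, np.asarray(li), delimiter="\t", fmt="%.6g")
    return path


def cluster_result_to_dict(result) -> dict:
    """JSON-ready summary of a ClusterResult (bounding boxes in ms/Hz)."""
    freqs = np.asarray(result.freqs)
    times = np.asarray(result.times)
    clusters = []
    for c in result.clusters:
        fi, ti = np.nonzero(c.mask)
        clusters.append({
            "stat": c.stat,
            "sign": c.sign,
            "p": c.p,
            "n_points": int(c.mask.sum()),
            "freq_min_hz": float(freqs[fi.min()]),
            "freq_max_hz": float(freqs[fi.max()]),
            "time_min_ms": float(times[ti.min()]),
            "time_max_ms": float(times[ti.max()]),
        })
    return {
        "stat_name": result.stat_name,
        "threshold": result.threshold,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "clusters": clusters,
    }


def save_cluster_result(result, basepath) -> Path:
    """Write a ClusterResult as JSON + TSV masks + TSV null distribution."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    json_path = base.with_suffix(".json")
    json_path.write_text(
        json.dumps(cluster_result_to_dict(result), indent=2), encoding="utf-8"
    )
    np.savetxt(base.parent / (base.name + "_null.tsv"),
               result.null_max_stats, delimiter="\t", fmt="%.6g")
    for i, c in enumerate(result.clusters):
        np.savetxt(base.parent / (base.name + f"_cluster{i}_mask.tsv"),
                   c.mask.astype(int), delimiter="\t", fmt="%d")
    return json_path
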