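"""File formats and the end-to-end pipeline runner.

Native on-disk format for recordings is a plain delimited numeric matrix
(TSV, channels as columns) with a JSON sidecar holding the sampling rate,
montage and events; EDF files are read through MNE when given. Cohort
tables travel as CSV, derived metrics as long-format CSV
(subject, timepoint, metric, value), and every run writes a provenance
manifest (config echo, seed, inputs consumed, per-stage counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import spectral, tep
from .containers import RestingRecording, TepEpochs
from .montage import Montage
from .responder import (SubjectRecord, extract_features, nested_cv_classify,
                        group_difference_tests)
from .cohort_stats import between_group_change, change_table, correlate_changes

log = logging.getLogger("tmsreact")


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: RestingRecording, base: str | Path,
                    events_s: list[float] | None = None) -> tuple[Path, Path]:
    """Write a recording as ``<base>.tsv`` + ``<base>.json`` sidecar."""
    base = Path(base)
    tsv = base.with_suffix(".tsv")
    sidecar = base.with_suffix(".json")
    df = pd.DataFrame(rec.data.T, columns=list(rec.montage.names))
    df.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    meta = {
        "fs": rec.fs,
        "channels": list(rec.montage.names),
        "clusters": {k: list(v) for k, v in rec.montage.clusters.items()},
        "units": "uV",
        "events_s": list(events_s) if events_s is not None else [],
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return tsv, sidecar


def read_recording(path: str | Path, montage: Montage | None = None,
                   expected_fs: float | None = None) -> RestingRecording:
    """Read a recording from TSV+sidecar or EDF; amplitudes in microvolts."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path, montage)
    elif path.suffix.lower() in (".tsv", ".csv", ".txt"):
        rec = _read_delimited(path, montage)
    else:
        raise ValueError(f"unknown recording format {path.suffix!r} "
                         f"(expected .edf, .tsv, .csv or .txt)")
    if expected_fs is not None and not np.isclose(rec.fs, expected_fs):
        raise ValueError(f"{path.name}: sampling rate {rec.fs} Hz does not "
                         f"match the configured {expected_fs} Hz")
    return rec


def _read_delimited(path: Path, montage: Montage | None) -> RestingRecording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if montage is None:
        clusters = {k: tuple(v) for k, v in meta.get("clusters", {}).items()}
        montage = Montage(names=tuple(meta["channels"]), clusters=clusters)
    missing = [c for c in montage.names if c not in df.columns]
    if missing:
        raise KeyError(f"{path.name}: montage channel(s) missing from file: "
                       f"{missing}")
    data = df[list(montage.names)].to_numpy().T
    return RestingRecording(data=data, fs=float(meta["fs"]), montage=montage,
                            meta={"events_s": meta.get("events_s", []),
                                  "source": str(path)})


def _read_edf(path: Path, montage: Montage | None) -> RestingRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = tuple(raw.ch_names)
    montage = montage or Montage(names=names, clusters={})
    missing = [c for c in montage.names if c not in names]
    if missing:
        raise KeyError(f"{path.name}: montage channel(s) missing from EDF: "
                       f"{missing}")
    picks = [names.index(c) for c in montage.names]
    data = raw.get_data()[picks] * 1e6  # MNE returns volts
    return RestingRecording(data=data, fs=float(raw.info["sfreq"]),
                            montage=montage, meta={"source": str(path)})


def write_epochs(epochs: TepEpochs, base: str | Path) -> tuple[Path, Path]:
    """Write epochs as ``<base>.tsv`` (trials*time rows) + JSON sidecar."""
    base = Path(base)
    tsv = base.with_suffix(".tsv")
    sidecar = base.with_suffix(".json")
    n_tr, n_ch, n_t = epochs.data.shape
    flat = epochs.data.transpose(0, 2, 1).reshape(n_tr * n_t, n_ch)
    df = pd.DataFrame(flat, columns=list(epochs.montage.names))
    df.insert(0, "trial", np.repeat(np.arange(n_tr), n_t))
    df.insert(1, "time_ms", np.tile(epochs.times, n_tr))
    df.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    meta = {
        "fs": epochs.fs, "n_trials": n_tr,
        "channels": list(epochs.montage.names),
        "clusters": {k: list(v) for k, v in epochs.montage.clusters.items()},
        "stim_side": epochs.stim_side, "stim_role": epochs.stim_role,
        "units": "uV",
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return tsv, sidecar


def read_epochs(path: str | Path) -> TepEpochs:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t")
    montage = Montage(names=tuple(meta["channels"]),
                      clusters={k: tuple(v) for k, v in meta["clusters"].items()})
    n_tr = int(meta["n_trials"])
    times = df.loc[df["trial"] == 0, "time_ms"].to_numpy()
    data = (df[list(montage.names)].to_numpy()
            .reshape(n_tr, times.size, montage.n_channels)
            .transpose(0, 2, 1))
    return TepEpochs(data=data, times=times, montage=montage,
                     fs=float(meta["fs"]), stim_side=meta.get("stim_side"),
                     stim_role=meta.get("stim_role"))


# ---------------------------------------------------------------------------
# cohort tables


COHORT_COLUMNS = ["id", "group", "affected_side", "updrs_t0", "updrs_t10",
                  "updrs_t1m", "tug_seconds", "frontal_delta_rel",
                  "f2f7_delta_pli", "true_responder"]


def cohort_to_csv(subjects: list[SubjectRecord], path: str | Path) -> Path:
    rows = []
    for s in subjects:
        rows.append({c: getattr(s, c) for c in COHORT_COLUMNS})
        tremor = s.subscores.get("tremor", {})
        rows[-1]["tremor_t0"] = tremor.get("t0")
        rows[-1]["tremor_t10"] = tremor.get("t10")
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def cohort_from_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    subjects = []
    for _, r in df.iterrows():
        sub = {}
        for name in ("tremor_t0", "tremor_t10"):
            if name in r and pd.notna(r[name]):
                sub.setdefault("tremor", {})[name.split("_")[1]] = float(r[name])
        subjects.append(SubjectRecord(
            id=str(r["id"]), group=str(r["group"]),
            affected_side=str(r["affected_side"]),
            updrs_t0=float(r["updrs_t0"]),
            updrs_t10=None if pd.isna(r.get("updrs_t10")) else float(r["updrs_t10"]),
            updrs_t1m=None if pd.isna(r.get("updrs_t1m")) else float(r["updrs_t1m"]),
            subscores=sub,
            tug_seconds=None if pd.isna(r.get("tug_seconds")) else float(r["tug_seconds"]),
            frontal_delta_rel=None if pd.isna(r.get("frontal_delta_rel"))
            else float(r["frontal_delta_rel"]),
            f2f7_delta_pli=None if pd.isna(r.get("f2f7_delta_pli"))
            else float(r["f2f7_delta_pli"]),
            true_responder=None if pd.isna(r.get("true_responder"))
            else bool(r["true_responder"]),
        ))
    return subjects


# ---------------------------------------------------------------------------
# pipeline


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    for key in ("tep_windows", "baseline_ms", "interpolation_ms"):
        win = cfg.get(key)
        if isinstance(win, (list, tuple)) and not win[0] < win[1]:
            raise ValueError(f"config window {key} must be ordered: {win}")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run rest -> connectivity -> tep -> responder stages per the config.

    The config lists input files per stage (see README for the schema);
    stages whose inputs are absent are skipped with a log entry. Returns
    the manifest dict, which is also written to ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    fs = config.get("fs")
    manifest: dict = {"seed": seed, "inputs": [], "stages": {},
                      "config_hash": hashlib.sha256(
                          json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()}

    band = tuple(config.get("pli_band", (1.0, 4.0)))
    metric_rows = []

    for entry in config.get("rest", []):
        rec = read_recording(entry["path"], expected_fs=fs)
        manifest["inputs"].append(str(entry["path"]))
        summary = spectral.spectral_summary(rec)
        frontal_delta = spectral.region_average(
            summary.rel_power["delta"], rec.montage, "frontal")
        mat = conn.band_pli(rec, band)
        pli_f2f7 = mat.pair("F2", "F7")
        sid, tp = entry["subject"], entry.get("timepoint", "t0")
        for bname, vals in summary.rel_power.items():
            metric_rows.append((sid, tp, f"rel_power_{bname}_mean",
                                float(np.mean(vals))))
        metric_rows.append((sid, tp, "ratio1_mean", float(np.mean(summary.ratio1))))
        metric_rows.append((sid, tp, "frontal_delta_rel", frontal_delta))
        metric_rows.append((sid, tp, "f2f7_delta_pli", pli_f2f7))
        log.info("rest %s/%s: frontal delta rel %.3f, F2-F7 PLI %.3f",
                 sid, tp, frontal_delta, pli_f2f7)
    manifest["stages"]["rest"] = {"n_recordings": len(config.get("rest", []))}

    if not config.get("tep"):
        log.info("tep stage skipped: no TEP inputs in config")
        manifest["stages"]["tep"] = {"skipped": True}
    else:
        peak_rows = []
        for entry in config["tep"]:
            epo = read_epochs(entry["path"])
            manifest["inputs"].append(str(entry["path"]))
            epo = tep.interpolate_artifact(
                epo, tuple(config.get("interpolation_ms", (-5.0, 15.0))))
            epo = tep.reject_epochs(
                epo, float(config.get("rejection_uv", 100.0)))
            evoked = tep.average_tep(
                epo, tuple(config.get("baseline_ms", (-500.0, -50.0))))
            roles = tep.map_m1_sides(entry["affected_side"])
            role = ("M1plus" if roles["M1plus"] == entry["stim_side"]
                    else "M1minus")
            cluster = "m1_left" if entry["stim_side"] == "left" else "m1_right"
            g = tep.gmfa(evoked, epo.times, epo.n_trials)
            loc = tep.local_tep(evoked, epo.times, epo.montage, cluster,
                                epo.n_trials)
            sid, tp = entry["subject"], entry.get("timepoint", "t0")
            for trace, label in ((g, "gmfa"), (loc, "local")):
                for name, pk in tep.extract_peaks(trace).items():
                    if pk.found:
                        peak_rows.append({
                            "subject": sid, "timepoint": tp, "role": role,
                            "trace": label, "component": name,
                            "latency_ms": pk.latency_ms,
                            "amplitude_uv": pk.amplitude_uv,
                        })
            log.info("tep %s/%s: %d trials kept, %d rejected", sid, tp,
                     epo.n_trials, len(epo.rejected_trials))
        pd.DataFrame(peak_rows).to_csv(out / "tep_peaks.csv", index=False)
        manifest["stages"]["tep"] = {"n_sets": len(config["tep"])}

    if metric_rows:
        pd.DataFrame(metric_rows,
                     columns=["subject", "timepoint", "metric", "value"]
                     ).to_csv(out / "rest_metrics.csv", index=False)

    if not config.get("cohort"):
        log.info("responder stage skipped: no cohort table in config")
        manifest["stages"]["responder"] = {"skipped": True}
    else:
        subjects = cohort_from_csv(config["cohort"])
        manifest["inputs"].append(str(config["cohort"]))
        ct = change_table(subjects)
        ct.to_csv(out / "change_table.csv", index=False)
        itbs = [s for s in subjects if s.group == "iTBS" and s.responder is not None]
        X, y = extract_features(itbs)
        stats_out: dict = {}
        if len(np.unique(y)) == 2 and np.bincount(y).min() >= 2:
            report = nested_cv_classify(
                X, y, repetitions=int(config.get("cv_repetitions", 100)),
                seed=seed)
            stats_out["classifier"] = {
                "balanced_accuracy": report.balanced_accuracy,
                "auc": report.auc,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
            }
            resp = X[y == 1]
            nonresp = X[y == 0]
            stats_out["group_differences"] = group_difference_tests({
                "frontal_delta_rel": (resp[:, 0], nonresp[:, 0]),
                "f2f7_delta_pli": (resp[:, 1], nonresp[:, 1]),
            })
        else:
            log.info("classifier skipped: need two classes with n >= 2 each")
        groups = ct.dropna(subset=["d_updrs_t10"]).groupby("group")["d_updrs_t10"]
        if len(groups) == 2:
            (ga, a), (gb, b) = list(groups)
            stats_out["between_group_d_updrs_t10"] = {
                "groups": [ga, gb], **between_group_change(a.values, b.values)}
        sub = ct.dropna(subset=["improvement_rate", "frontal_delta_rel"])
        if len(sub) >= 5:
            stats_out["improvement_vs_frontal_delta"] = correlate_changes(
                sub["frontal_delta_rel"].values, sub["improvement_rate"].values)
        (out / "stats.json").write_text(json.dumps(_jsonable(stats_out), indent=2))
        manifest["stages"]["responder"] = {"n_subjects": len(subjects)}

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
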