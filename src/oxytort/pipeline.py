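"""Pipeline orchestration: simulate -> oximetry -> tortuosity -> stats.

Each stage is a pure function of (inputs, config); `run_all` chains them,
writes all tables with fixed float formatting and records a manifest
(config hash, seed, row counts), so re-running with the same configuration
reproduces every CSV/JSON output byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import stats as cohort_stats
from .config import PipelineConfig, config_hash
from .errors import JoinError, OxytortError
from .oximetry import FundusImagePair, analyze_pair
from .synthetic import generate_cohort
from .tortuosity import analyze_tortuosity

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def load_pair(data_dir: str | Path, eye_entry: dict, annotations: dict) -> FundusImagePair:
    data_dir = Path(data_dir)
    img532 = tifffile.imread(data_dir / eye_entry["file_532"]).astype(float) / 65535.0
    img633 = tifffile.imread(data_dir / eye_entry["file_633"]).astype(float) / 65535.0
    return FundusImagePair(
        image_532=img532,
        image_633=img633,
        onh_center=tuple(annotations["onh_center"]),
        onh_radius=float(annotations["onh_radius"]),
        um_per_px=float(annotations["um_per_px"]),
    )


def _load_annotations(data_dir: str | Path) -> dict:
    path = Path(data_dir) / "annotations.json"
    if not path.exists():
        raise JoinError(f"missing annotations file: {path}")
    with open(path) as fh:
        return json.load(fh)


def match_segments(
    segments: pd.DataFrame,
    ground_truth_eye: pd.DataFrame,
    max_angle_deg: float = 15.0,
) -> pd.DataFrame:
    """Attach ground-truth vessel ids/types to measured segments by angular
    position around the ONH (labels play the role of the manual artery/vein
    identification on real images).  Unmatched segments are dropped with a
    warning."""
    if segments.empty:
        return segments.assign(vessel_id=pd.Series(dtype=str), vessel_type=pd.Series(dtype=str))
    gt_ang = ground_truth_eye["angle_deg"].to_numpy()
    rows = []
    for _, seg in segments.iterrows():
        delta = np.abs((gt_ang - seg["angle_deg"] + 180.0) % 360.0 - 180.0)
        j = int(np.argmin(delta))
        if delta[j] > max_angle_deg:
            log.warning(
                "segment %s at %.1f deg matched no vessel (nearest %.1f deg away)",
                seg["segment_id"], seg["angle_deg"], delta[j],
            )
            continue
        row = seg.to_dict()
        row["vessel_id"] = ground_truth_eye.iloc[j]["vessel_id"]
        row["vessel_type"] = ground_truth_eye.iloc[j]["vessel_type"]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(segments.columns) + ["vessel_id", "vessel_type"])


def run_simulate(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    paths = generate_cohort(out_dir, cfg)
    return Path(paths["dir"])


def _iter_eyes(data_dir: str | Path):
    annotations = _load_annotations(data_dir)
    for entry in annotations["eyes"]:
        yield entry, annotations


def run_oximetry(data_dir: str | Path, cfg: PipelineConfig, out_csv: str | Path) -> pd.DataFrame:
    data_dir = Path(data_dir)
    subjects = pd.read_csv(data_dir / "subjects.csv").set_index("subject_id", drop=False)
    gt = pd.read_csv(data_dir / "ground_truth.csv")
    frames = []
    for entry, annotations in _iter_eyes(data_dir):
        pair = load_pair(data_dir, entry, annotations)
        sid, eye = entry["subject_id"], entry["eye"]
        hct = float(subjects.loc[sid, "hct"])
        seg = analyze_pair(pair, cfg, hct=hct)
        gt_eye = gt[(gt["subject_id"] == sid) & (gt["eye"] == eye)]
        seg = match_segments(seg, gt_eye)
        seg.insert(0, "subject_id", sid)
        seg.insert(1, "eye", eye)
        seg["segment_id"] = [f"{sid}_{eye}_{s}" for s in seg["segment_id"]]
        frames.append(seg)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table.to_csv(out_csv, index=False, float_format=_FLOAT_FMT)
    return table


def run_tortuosity(data_dir: str | Path, cfg: PipelineConfig, out_csv: str | Path) -> pd.DataFrame:
    data_dir = Path(data_dir)
    gt = pd.read_csv(data_dir / "ground_truth.csv")
    frames = []
    for entry, annotations in _iter_eyes(data_dir):
        pair = load_pair(data_dir, entry, annotations)
        sid, eye = entry["subject_id"], entry["eye"]
        seg = analyze_tortuosity(pair, cfg)
        gt_eye = gt[(gt["subject_id"] == sid) & (gt["eye"] == eye)]
        seg = match_segments(seg, gt_eye)
        seg.insert(0, "subject_id", sid)
        seg.insert(1, "eye", eye)
        seg["segment_id"] = [f"{sid}_{eye}_{s}" for s in seg["segment_id"]]
        frames.append(seg)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table.to_csv(out_csv, index=False, float_format=_FLOAT_FMT)
    return table


def _summary_table(cohort: pd.DataFrame) -> str:
    """Mean +/- SD of each metric by diagnosis x eye, one block per vessel
    type (the layout of the cohort summary tables)."""
    lines = []
    for vtype, title in (("artery", "Arteries"), ("vein", "Veins")):
        sub = cohort[cohort["vessel_type"] == vtype]
        if sub.empty:
            continue
        lines.append(title)
        header = f"{'metric':<12}" + "".join(
            f"{diag + ' ' + eye:>16}" for diag in ("NC", "SCR") for eye in ("OD", "OS")
        )
        lines.append(header)
        for metric in ("o2_content", "vti", "vii"):
            cells = []
            for diag in ("NC", "SCR"):
                for eye in ("OD", "OS"):
                    vals = sub[(sub["diagnosis"] == diag) & (sub["eye"] == eye)][metric].dropna()
                    cells.append(
                        f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}" if len(vals) else "-"
                    )
            lines.append(f"{metric:<12}" + "".join(f"{c:>16}" for c in cells))
        lines.append("")
    return "\n".join(lines)


def run_stats(data_dir: str | Path, results_dir: str | Path, cfg: PipelineConfig) -> dict:
    data_dir, results_dir = Path(data_dir), Path(results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    oximetry = pd.read_csv(results_dir / "oximetry.csv")
    tortuosity = pd.read_csv(results_dir / "tortuosity.csv")
    subjects = pd.read_csv(data_dir / "subjects.csv")

    cohort = cohort_stats.aggregate(oximetry, tortuosity, subjects)
    cohort, removal_log = cohort_stats.remove_outliers(
        cohort, n_sd=cfg.stats.outlier_n_sd, min_rows=cfg.stats.outlier_min_rows
    )
    cohort.to_csv(results_dir / "cohort.csv", index=False, float_format=_FLOAT_FMT)
    with open(results_dir / "outlier_log.txt", "w") as fh:
        if removal_log.empty:
            fh.write("no outliers removed\n")
        else:
            fh.write(removal_log.to_string(index=False) + "\n")

    lmm_out: dict = {}
    for response in ("o2_content", "vti", "vii"):
        try:
            lmm_out[f"group_{response}"] = cohort_stats.fit_group_lmm(
                cohort, response, reml=cfg.stats.reml
            ).to_dict()
        except OxytortError as exc:
            log.warning("group model for %s not fit: %s", response, exc)
            lmm_out[f"group_{response}"] = {"error": str(exc)}
    for metric in ("vti", "vii"):
        try:
            lmm_out[f"o2_vs_{metric}"] = cohort_stats.relate_o2_tortuosity(
                cohort, metric, reml=cfg.stats.reml
            ).to_dict()
        except OxytortError as exc:
            log.warning("o2-%s model not fit: %s", metric, exc)
            lmm_out[f"o2_vs_{metric}"] = {"error": str(exc)}
    with open(results_dir / "lmm_results.json", "w") as fh:
        json.dump(lmm_out, fh, sort_keys=True, indent=1)

    ent_mi = {
        "entropy_vti_bits": cohort_stats.shannon_entropy(
            cohort["vti"].dropna(), n_bins=cfg.stats.entropy_bins
        ),
        "entropy_vii_bits": cohort_stats.shannon_entropy(
            cohort["vii"].dropna(), n_bins=cfg.stats.entropy_bins
        ),
        "mi_vti_vii_bits": cohort_stats.mutual_information(
            cohort["vti"], cohort["vii"], n_bins=cfg.stats.entropy_bins
        ),
    }
    with open(results_dir / "entropy_mi.json", "w") as fh:
        json.dump(ent_mi, fh, sort_keys=True, indent=1)

    with open(results_dir / "summary.txt", "w") as fh:
        fh.write(_summary_table(cohort) + "\n")
    return {"cohort": cohort, "lmm": lmm_out, "entropy_mi": ent_mi}


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage under ``out_dir`` (images in ``data/``, tables in
    ``results/``) and write a manifest; deterministic for a fixed config."""
    out_dir = Path(out_dir)
    data_dir = out_dir / "data"
    results_dir = out_dir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)

    run_simulate(cfg, data_dir)
    ox = run_oximetry(data_dir, cfg, results_dir / "oximetry.csv")
    tt = run_tortuosity(data_dir, cfg, results_dir / "tortuosity.csv")
    out = run_stats(data_dir, results_dir, cfg)

    manifest = {
        "config_sha256": config_hash(cfg),
        "seed": cfg.seed,
        "n_subjects": int(pd.read_csv(data_dir / "subjects.csv").shape[0]),
        "n_oximetry_segments": int(len(ox)),
        "n_tortuosity_segments": int(len(tt)),
        "n_cohort_rows": int(len(out["cohort"])),
    }
    with open(results_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return out_dir
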