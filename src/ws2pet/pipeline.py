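"""Subject- and cohort-level orchestration of masks -> SUVR -> wS2 -> stats.

One voxel-pair sample is drawn per (subject, timepoint) — with a seed
derived deterministically from the run seed — and reused across all
normalization schemes: the gray-matter mask does not depend on the
scheme, so sharing the sample removes between-scheme Monte-Carlo noise
from scheme comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortResult, correlation_table, evaluate_cohort
from .io import Volume, load_volume
from .masks import (DEFAULT_GM_LEVEL, TissueProbabilityMap, exclusion_mask,
                    reference_mask, target_gm_mask)
from .suvr import compute_suvr
from .ws2 import WS2Config, sample_pairs, subject_seed, ws2_from_pairs

DEFAULT_SCHEMES = ("cereb_gm", "wm10", "wm100", "brainstem", "corpus_callosum")


@dataclass
class RunSettings:
    """Everything besides the input volumes that shapes a run."""

    schemes: tuple[str, ...] = DEFAULT_SCHEMES
    ws2: WS2Config = field(default_factory=WS2Config)
    gm_level: float = DEFAULT_GM_LEVEL
    region_ids: dict | None = None
    ref_statistic: str = "mean"


def run_subject(
    pet: Volume,
    tpm: TissueProbabilityMap,
    labels: Volume,
    *,
    subject_id: str,
    timepoint: str,
    settings: RunSettings | None = None,
    splenium: np.ndarray | None = None,
) -> list[dict]:
    """All scheme x metric outcomes for one scan.

    Per-scheme failures are isolated: a failing scheme yields a row whose
    ``error`` column carries the message while the other schemes complete.
    """
    settings = settings or RunSettings()
    target = target_gm_mask(
        tpm, settings.gm_level,
        exclude=exclusion_mask(labels, settings.region_ids),
    )

    cfg = settings.ws2
    seed = subject_seed(cfg.seed, subject_id, timepoint)
    rng = np.random.default_rng(seed)
    work = target & np.isfinite(pet.data)
    idx1, idx2, dist = sample_pairs(work, pet.spacing, cfg, rng=rng)

    rows: list[dict] = []
    for scheme in settings.schemes:
        row = {
            "subject_id": subject_id, "timepoint": timepoint,
            "scheme": scheme, "suvr_mean": np.nan, "suvr_median": np.nan,
            "ref_mean": np.nan, "n_ref_voxels": 0,
            "ws2_auc": np.nan, "ws2_slope": np.nan,
            "lambda": cfg.lambda_diff, "n_pairs": cfg.n_pairs,
            "pair_seed": seed, "error": "",
        }
        try:
            ref = reference_mask(scheme, tpm, labels,
                                 region_ids=settings.region_ids,
                                 splenium=splenium)
            res = compute_suvr(pet, target, ref, scheme,
                               statistic=settings.ref_statistic)
            curve = ws2_from_pairs(res.suvr_volume, idx1, idx2, dist, cfg)
            row.update(
                suvr_mean=res.suvr_mean, suvr_median=res.suvr_median,
                ref_mean=res.ref_mean, n_ref_voxels=res.n_ref_voxels,
                ws2_auc=curve.auc, ws2_slope=curve.slope,
            )
        except Exception as exc:  # isolate the scheme, keep the run going
            row["error"] = str(exc)
            warnings.warn(
                f"{subject_id}/{timepoint}/{scheme} failed: {exc}",
                stacklevel=2,
            )
        rows.append(row)
    return rows


def run_cohort(
    scans,
    biomarker: pd.DataFrame,
    settings: RunSettings | None = None,
) -> tuple[pd.DataFrame, CohortResult]:
    """Run every scan and evaluate the cohort.

    ``scans`` yields ``(subject_id, timepoint, pet, tpm, labels)`` (with an
    optional sixth splenium-mask element); ``biomarker`` has columns
    subject_id, timepoint, biomarker.
    """
    settings = settings or RunSettings()
    rows: list[dict] = []
    for item in scans:
        sid, tp, pet, tpm, labels, *rest = item
        splenium = rest[0] if rest else None
        rows.extend(run_subject(
            pet, tpm, labels, subject_id=sid, timepoint=tp,
            settings=settings, splenium=splenium,
        ))
    records = pd.DataFrame(rows)
    records = records.merge(biomarker, on=["subject_id", "timepoint"],
                            how="left")
    result = evaluate_cohort(records)
    return records, result


def _to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def write_cohort_outputs(out_dir: str | Path, records: pd.DataFrame,
                         result: CohortResult,
                         settings: RunSettings) -> dict[str, Path]:
    """Write records/scatter, correlation, CV tables and a JSON manifest.

    Output is deterministic for a fixed input (fixed float formatting, no
    timestamps), so reruns with identical config and seed are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out_dir / "records.tsv",
        "spearman": out_dir / "spearman.tsv",
        "correlation_table": out_dir / "correlation_table.tsv",
        "cv": out_dir / "cv.tsv",
        "manifest": out_dir / "manifest.json",
    }
    _to_tsv(records, paths["records"])
    _to_tsv(result.spearman, paths["spearman"])
    _to_tsv(correlation_table(result), paths["correlation_table"])
    cv = result.cv_cells.copy()
    pooled = result.cv_pooled.reset_index()
    pooled.columns = ["metric", "cv"]
    pooled.insert(0, "scheme", "ALL")
    pooled.insert(1, "timepoint", "ALL")
    pooled["n"] = np.nan
    cv = pd.concat([cv, pooled[cv.columns]], ignore_index=True)
    _to_tsv(cv, paths["cv"])
    manifest = {
        "ws2pet_version": __version__,
        "schemes": list(settings.schemes),
        "ws2": asdict(settings.ws2),
        "gm_level": settings.gm_level,
        "region_ids": settings.region_ids,
        "ref_statistic": settings.ref_statistic,
        "cv_convention": "across-subject CV per cell, pooled as the mean "
                         "over timepoints and schemes",
        "rho_sign": "signed rho; negative = inverse PET-biomarker "
                    "association (expected direction)",
        "n_records": int(len(records)),
        "warnings": result.warnings,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                 + "\n")
    return paths


# ---------------------------------------------------------------------------
# file-based runs driven by a YAML config


def load_run_config(path: str | Path) -> dict:
    """Parse and validate a YAML run config; all referenced files must exist."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "subjects" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with 'subjects'")
    base = path.parent
    for sub in cfg["subjects"]:
        for tp in ("baseline", "followup"):
            if tp not in sub:
                continue
            for key, rel in list(sub[tp].items()):
                p = (base / rel).resolve()
                if not p.exists():
                    raise FileNotFoundError(
                        f"config references missing file: {p}"
                    )
                sub[tp][key] = str(p)
    if "biomarker_table" in cfg:
        p = (base / cfg["biomarker_table"]).resolve()
        if not p.exists():
            raise FileNotFoundError(f"config references missing file: {p}")
        cfg["biomarker_table"] = str(p)
    return cfg


def settings_from_config(cfg: dict) -> RunSettings:
    ws2_cfg = WS2Config(**cfg.get("ws2", {}))
    return RunSettings(
        schemes=tuple(cfg.get("schemes", DEFAULT_SCHEMES)),
        ws2=ws2_cfg,
        gm_level=float(cfg.get("gm_level", DEFAULT_GM_LEVEL)),
        region_ids=cfg.get("region_ids"),
        ref_statistic=cfg.get("ref_statistic", "mean"),
    )


def _iter_config_scans(cfg: dict):
    for sub in cfg["subjects"]:
        sid = str(sub["id"])
        for tp in ("baseline", "followup"):
            if tp not in sub:
                continue
            entry = sub[tp]
            pet = load_volume(entry["pet"])
            tpm = TissueProbabilityMap(
                gm_prob=load_volume(entry["gm_prob"]).data,
                wm_prob=load_volume(entry["wm_prob"]).data,
            )
            labels = load_volume(entry["labels"])
            splenium = None
            if "splenium" in entry:
                splenium = load_volume(entry["splenium"]).data.astype(bool)
            yield sid, tp, pet, tpm, labels, splenium


def run_from_config(config_path: str | Path,
                    out_dir: str | Path) -> dict[str, Path]:
    """End-to-end cohort run from a YAML config of file paths."""
    cfg = load_run_config(config_path)
    settings = settings_from_config(cfg)
    biomarker = pd.read_csv(cfg["biomarker_table"], sep="\t")
    records, result = run_cohort(_iter_config_scans(cfg), biomarker, settings)
    return write_cohort_outputs(out_dir, records, result, settings)
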