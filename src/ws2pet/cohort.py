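"""Cohort-level evaluation: rank correlations and coefficients of variation.

Given a tidy table of per-subject, per-timepoint, per-scheme PET outcomes
(SUVR mean, SUVR median, wS2 AUC) plus a fluid biomarker (CSF-Ab1-42-like,
pg/ml), compute Spearman's rank correlation for every
(scheme, timepoint, metric) cell and coefficients of variation per metric
pooled across timepoints and normalization schemes.

Sign convention: amyloid accumulation raises PET outcomes and lowers CSF
Ab1-42, so a *negative* rho is the expected direction; outputs carry both
the signed rho and |rho|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

METRICS: tuple[str, ...] = ("suvr_mean", "suvr_median", "ws2_auc")

REQUIRED_COLUMNS = ("subject_id", "timepoint", "scheme", "biomarker") + METRICS


class CohortError(ValueError):
    """Raised for malformed cohort tables or undefined statistics."""


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with average ranks for ties.

    Equals the Pearson correlation of the two rank vectors.  Requires at
    least 3 paired finite observations and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CohortError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise CohortError(f"need >= 3 paired observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise CohortError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CohortError("rank correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def spearman_permutation_pvalue(x, y, n_perm: int = 10_000,
                                seed: int = 0) -> float:
    """Two-sided Monte-Carlo permutation p-value for Spearman's rho.

    Optional companion to :func:`spearman_rho` for small cohorts; not
    emitted by default.
    """
    rho = abs(spearman_rho(x, y))
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_perm):
        if abs(spearman_rho(x, rng.permutation(y))) >= rho - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean; scale-invariant."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise CohortError(f"need >= 2 values for a CV, got {values.size}")
    if not np.isfinite(values).all():
        raise CohortError("CV inputs must be finite")
    mean = values.mean()
    if mean == 0:
        raise CohortError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


@dataclass
class CohortResult:
    """Spearman grid + CV summaries for one cohort.

    ``spearman`` is long-form with columns scheme, timepoint, metric, n,
    rho, abs_rho.  ``cv_cells`` holds the across-subject CV for every
    (scheme, timepoint, metric) cell; ``cv_pooled`` averages those cells
    per metric (the pooled across-subject convention, labelled as such in
    outputs).
    """

    spearman: pd.DataFrame
    cv_cells: pd.DataFrame
    cv_pooled: pd.Series
    warnings: list[str] = field(default_factory=list)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise CohortError(f"records table missing columns {missing}")
    dup = records.duplicated(subset=["subject_id", "timepoint", "scheme"])
    if dup.any():
        rows = records.loc[dup, ["subject_id", "timepoint", "scheme"]]
        raise CohortError(
            "duplicate (subject, timepoint, scheme) rows:\n"
            f"{rows.to_string(index=False)}"
        )
    return records


def evaluate_cohort(records: pd.DataFrame,
                    metrics: tuple[str, ...] = METRICS) -> CohortResult:
    """Full cohort evaluation over every scheme x timepoint x metric cell.

    Subjects with missing values in a cell are excluded pairwise with a
    recorded warning; cells whose correlation or CV is undefined
    (too few subjects, constant values) are reported as NaN with a
    warning rather than silently dropped.
    """
    records = _validate_records(records)
    schemes = sorted(records["scheme"].unique())
    timepoints = sorted(records["timepoint"].unique())
    notes: list[str] = []

    sp_rows = []
    cv_rows = []
    for scheme in schemes:
        for tp in timepoints:
            cell = records[(records["scheme"] == scheme)
                           & (records["timepoint"] == tp)]
            for metric in metrics:
                sub = cell[[metric, "biomarker"]].dropna()
                n = len(sub)
                n_dropped = len(cell) - n
                if n_dropped:
                    notes.append(
                        f"{scheme}/{tp}/{metric}: {n_dropped} subjects "
                        "excluded pairwise (missing values)"
                    )
                rho = np.nan
                try:
                    rho = spearman_rho(sub[metric], sub["biomarker"])
                except CohortError as exc:
                    notes.append(f"{scheme}/{tp}/{metric}: rho undefined ({exc})")
                sp_rows.append({
                    "scheme": scheme, "timepoint": tp, "metric": metric,
                    "n": n, "rho": rho,
                    "abs_rho": abs(rho) if np.isfinite(rho) else np.nan,
                })
                cv = np.nan
                try:
                    cv = coefficient_of_variation(sub[metric].to_numpy())
                except CohortError as exc:
                    notes.append(f"{scheme}/{tp}/{metric}: CV undefined ({exc})")
                cv_rows.append({
                    "scheme": scheme, "timepoint": tp, "metric": metric,
                    "n": n, "cv": cv,
                })
    for note in notes:
        warnings.warn(note, stacklevel=2)
    spearman = pd.DataFrame(sp_rows)
    cv_cells = pd.DataFrame(cv_rows)
    cv_pooled = cv_cells.groupby("metric")["cv"].mean().rename("cv_pooled")
    return CohortResult(spearman=spearman, cv_cells=cv_cells,
                        cv_pooled=cv_pooled, warnings=notes)


def correlation_table(result: CohortResult) -> pd.DataFrame:
    """Wide correlation table: rows = scheme, columns = timepoint x metric.

    The layout used for reporting (signed rho; negative = expected
    inverse PET-CSF direction).
    """
    wide = result.spearman.pivot_table(
        index="scheme", columns=["timepoint", "metric"], values="rho",
        sort=True,
    )
    wide.columns = [f"{tp}:{metric}" for tp, metric in wide.columns]
    return wide.reset_index()
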