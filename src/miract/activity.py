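"""Per-sample miRNA activity inference from target-gene expression.

Three steps per miRNA: (1) baseline expression of its targets, estimated
over the samples where the miRNA reads lowest; (2) per-sample degradation =
observed minus baseline; (3) a weighted through-origin regression of
degradation on baseline whose per-sample slope, sign-flipped, is the
activity. Weights are refined iteratively: genes more anti-correlated with
the current activity estimate count more (they are more plausibly
functional targets).

The mRNA-only variant replaces step (1)'s miRNA readout with a summed
z-score over known negatively-associated functional targets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from miract import stats
from miract.io import zscore_rows

logger = logging.getLogger(__name__)

MIN_SAMPLES = 20  # below this the per-sample fits are unreliable


class InsufficientSamplesError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityParams:
    baseline_fraction: float = 0.05
    min_baseline_samples: int = 3
    tol: float = 1e-6
    max_iter: int = 500
    weight_floor: float = 1e-6
    fit_intercept: bool = False


@dataclass
class ActivityProfile:
    mirna_id: str
    activity: pd.Series  # per sample; larger = more target degradation
    weights: pd.Series  # per target gene, sums to 1
    correlations: pd.Series  # Pearson(activity, gene expression)
    baseline: pd.Series  # per target gene b_g
    baseline_samples: list[str]
    n_iter: int
    converged: bool
    variant: str  # "standard" | "mrna_only"


def filter_mirnas(
    mirna: pd.DataFrame,
    targets: dict[str, list[str]],
    gene_universe,
    *,
    zero_fraction_max: float = 0.85,
    min_targets: int = 10,
) -> tuple[list[str], dict[str, str]]:
    """Retain miRNAs expressed often enough and with enough usable targets.

    A miRNA is dropped when its (log-scale) expression is exactly 0 — i.e.
    raw RPM 0 — in more than `zero_fraction_max` of samples, or when fewer
    than `min_targets` of its predicted targets appear in the expression
    matrix.
    """
    universe = set(gene_universe)
    retained: list[str] = []
    reasons: dict[str, str] = {}
    for mir in mirna.index:
        if mir not in targets:
            reasons[mir] = "no_targets"
            continue
        zero_frac = float((mirna.loc[mir] == 0).mean())
        if zero_frac > zero_fraction_max:
            reasons[mir] = "zero_fraction"
            continue
        n_in_universe = len(universe.intersection(targets[mir]))
        if n_in_universe < min_targets:
            reasons[mir] = "min_targets"
            continue
        retained.append(mir)
    return retained, reasons


def select_baseline_samples(
    mirna_row: pd.Series,
    *,
    fraction: float = 0.05,
    min_baseline_samples: int = 3,
) -> list[str]:
    """The max(ceil(fraction*n), floor) lowest-expression samples.

    Ties at the cut are resolved by ascending sample ID.
    """
    n = mirna_row.size
    if n < MIN_SAMPLES:
        raise InsufficientSamplesError(
            f"insufficient_samples: need >= {MIN_SAMPLES}, got {n}"
        )
    k = max(math.ceil(fraction * n), min_baseline_samples)
    order = sorted(mirna_row.index, key=lambda s: (mirna_row[s], s))
    chosen = order[:k]
    if mirna_row[order[0]] == mirna_row[order[-1]]:
        warnings.warn(
            "all expression values tied; baseline selection is degenerate",
            stacklevel=2,
        )
    return chosen


def estimate_baseline(
    expr: pd.DataFrame, baseline_samples, target_genes
) -> pd.Series:
    """Mean expression of each target gene over the baseline samples."""
    genes = [g for g in target_genes if g in expr.index]
    if not genes:
        raise ValueError("no target genes present in the expression matrix")
    missing = [s for s in baseline_samples if s not in expr.columns]
    if missing:
        raise ValueError(f"baseline samples absent from expression matrix: {missing[:3]}")
    return expr.loc[genes, list(baseline_samples)].mean(axis=1)


def compute_degradation(expr: pd.DataFrame, baseline: pd.Series) -> pd.DataFrame:
    """Observed expression minus per-gene baseline (genes x samples)."""
    return expr.loc[baseline.index].sub(baseline, axis=0)


def fit_activity_one_sample(d_column, b, w) -> float:
    """Weighted least-squares slope through the origin of d on b."""
    d = np.asarray(d_column, float)
    bb = np.asarray(b, float)
    ww = np.asarray(w, float)
    denom = float(ww @ (bb * bb))
    if denom <= 0:
        raise DegenerateFitError("degenerate_fit: sum w*b^2 is not positive")
    return float((ww * bb) @ d) / denom


def _irls(
    x: np.ndarray,
    b: np.ndarray,
    params: ActivityParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """IRLS loop shared by both variants.

    x: targets x samples expression; b: per-target baseline.
    Returns (activity, weights, correlations, n_iter, converged).
    """
    n_targets, n_samples = x.shape
    d = x - b[:, None]
    w = np.full(n_targets, 1.0 / n_targets)
    a_prev = np.full(n_samples, np.inf)
    a = np.zeros(n_samples)
    r = np.zeros(n_targets)
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        denom = float(w @ (b * b))
        if denom <= 0:
            raise DegenerateFitError("degenerate_fit: sum w*b^2 is not positive")
        slopes = (w * b) @ d / denom
        a = -slopes
        if np.max(np.abs(a - a_prev)) < params.tol:
            converged = True
            break
        a_prev = a
        r = stats.pearson_rows(x, a)
        r = np.nan_to_num(r, nan=0.0)  # constant gene rows: no signal
        w = np.maximum(params.weight_floor, -r)
        w = w / w.sum()
    r = np.nan_to_num(stats.pearson_rows(x, a), nan=0.0)
    if not converged:
        warnings.warn("IRLS did not converge within max_iter", stacklevel=2)
    return a, w, r, n_iter, converged


def infer_activity(
    expr: pd.DataFrame,
    mirna_row: pd.Series,
    targets,
    params: ActivityParams = ActivityParams(),
    *,
    mirna_id: str | None = None,
) -> ActivityProfile:
    """Standard variant: baseline from samples with low miRNA expression."""
    if expr.shape[1] < MIN_SAMPLES:
        raise InsufficientSamplesError(
            f"insufficient_samples: need >= {MIN_SAMPLES}, got {expr.shape[1]}"
        )
    mirna_row = mirna_row.loc[expr.columns]
    baseline_samples = select_baseline_samples(
        mirna_row,
        fraction=params.baseline_fraction,
        min_baseline_samples=params.min_baseline_samples,
    )
    return _finish(
        expr, baseline_samples, targets, params, "standard", mirna_id or str(mirna_row.name)
    )


def infer_activity_mrna_only(
    expr: pd.DataFrame,
    functional_targets_negative,
    params: ActivityParams = ActivityParams(),
    *,
    mirna_id: str = "",
    baseline_extreme: str = "high_target_sum",
) -> ActivityProfile:
    """mRNA-only variant: baseline from the summed z-score of known
    negatively-associated functional targets.

    With `baseline_extreme="high_target_sum"` (default) the baseline is the
    5% of samples with the HIGHEST target-z sum — the least-degraded, hence
    lowest-implied-activity samples. `"low_target_sum"` selects the other
    extreme.
    """
    if expr.shape[1] < MIN_SAMPLES:
        raise InsufficientSamplesError(
            f"insufficient_samples: need >= {MIN_SAMPLES}, got {expr.shape[1]}"
        )
    if baseline_extreme not in ("high_target_sum", "low_target_sum"):
        raise ValueError(f"unknown baseline_extreme: {baseline_extreme!r}")
    genes = [g for g in functional_targets_negative if g in expr.index]
    if not genes:
        raise ValueError("no functional target genes present in the expression matrix")
    z, dropped = zscore_rows(expr.loc[genes])
    if dropped:
        logger.warning("dropped %d constant gene rows from target-z score", len(dropped))
    if z.empty:
        raise ValueError("all functional target rows are constant")
    score = z.sum(axis=0)
    ranking = score if baseline_extreme == "low_target_sum" else -score
    baseline_samples = select_baseline_samples(
        ranking,
        fraction=params.baseline_fraction,
        min_baseline_samples=params.min_baseline_samples,
    )
    return _finish(expr, baseline_samples, genes, params, "mrna_only", mirna_id)


def _finish(
    expr: pd.DataFrame,
    baseline_samples: list[str],
    targets,
    params: ActivityParams,
    variant: str,
    mirna_id: str,
) -> ActivityProfile:
    baseline = estimate_baseline(expr, baseline_samples, targets)
    x = expr.loc[baseline.index].to_numpy(float)
    a, w, r, n_iter, converged = _irls(x, baseline.to_numpy(float), params)
    return ActivityProfile(
        mirna_id=mirna_id,
        activity=pd.Series(a, index=expr.columns, name=mirna_id),
        weights=pd.Series(w, index=baseline.index, name="weight"),
        correlations=pd.Series(r, index=baseline.index, name="r"),
        baseline=baseline,
        baseline_samples=list(baseline_samples),
        n_iter=n_iter,
        converged=converged,
        variant=variant,
    )


def infer_all_activities(
    expr: pd.DataFrame,
    mirna: pd.DataFrame,
    targets: dict[str, list[str]],
    params: ActivityParams = ActivityParams(),
    *,
    mirna_ids=None,
) -> tuple[pd.DataFrame, dict[str, ActivityProfile]]:
    """Run the standard variant for each miRNA; returns (matrix, profiles)."""
    ids = list(mirna_ids) if mirna_ids is not None else list(mirna.index)
    profiles: dict[str, ActivityProfile] = {}
    rows = []
    for mir in ids:
        prof = infer_activity(
            expr, mirna.loc[mir], targets[mir], params, mirna_id=mir
        )
        profiles[mir] = prof
        rows.append(prof.activity)
    matrix = pd.DataFrame(rows, index=ids, columns=expr.columns)
    return matrix, profiles
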