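"""The miRNA selection cascade.

A miRNA survives the screen when it is simultaneously (1) functionally
active — its inferred activity correlates positively with its own
expression and its activity-correlated genes are enriched for its predicted
targets; (2) key — it has many functional (negatively associated) targets;
and (3) differentially expressed against matched normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from miract import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    n_perm: int = 1000  # null size for the activity-expression correlation
    correlation_fdr: float = 0.05
    enrichment_fdr: float = 0.05
    correlated_gene_fdr: float = 0.05
    correlated_gene_perms: int = 200
    functional_target_fdr: float = 0.01
    key_min_targets: int = 10
    de_p_threshold: float = 1e-5
    seed: int = 0


def correlate_activity_expression(activity, mirna_row) -> tuple[float, float]:
    """Pearson r (with t p-value) between inferred activity and expression."""
    return stats.pearson(activity, mirna_row)


def permutation_fdr(observed, null, n_perm: int) -> np.ndarray:
    """Pooled-null empirical FDR; see :func:`miract.stats.permutation_fdr`."""
    return stats.permutation_fdr(observed, null, n_perm)


def _permuted_matrix(rng: np.random.Generator, vec: np.ndarray, n_perm: int) -> np.ndarray:
    idx = np.argsort(rng.random((n_perm, vec.size)), axis=1)
    return vec[idx]


def correlation_screen(
    activities: pd.DataFrame,
    mirna: pd.DataFrame,
    *,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-miRNA activity-expression correlation with permutation FDR.

    Statistic is r oriented positively (larger r = more significant, per
    the positive-skew expectation for genuinely active miRNAs). The null
    pools r values from `n_perm` permutations of every miRNA's activity.
    """
    rng = np.random.default_rng(seed)
    obs_r = np.empty(len(activities.index))
    obs_p = np.empty_like(obs_r)
    null_chunks = []
    mirna = mirna.loc[:, activities.columns]
    for i, mir in enumerate(activities.index):
        a = activities.loc[mir].to_numpy(float)
        e = mirna.loc[mir].to_numpy(float)
        r, p = stats.pearson(a, e)
        obs_r[i], obs_p[i] = r, p
        perm = _permuted_matrix(rng, a, n_perm)
        null_chunks.append(stats.pearson_rows(perm, e))
    observed = np.nan_to_num(obs_r, nan=-np.inf)  # constant rows: never significant
    null = np.concatenate(null_chunks)
    null = null[~np.isnan(null)]
    fdr = stats.permutation_fdr(observed, null, n_perm)
    return pd.DataFrame(
        {
            "r_activity_expression": obs_r,
            "r_p": obs_p,
            "r_fdr": fdr,
        },
        index=activities.index,
    )


def correlated_genes(
    activity,
    expr: pd.DataFrame,
    *,
    fdr: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
) -> list[str]:
    """Genes whose |r| with the activity clears a pooled permutation FDR."""
    a = np.asarray(activity, float)
    x = expr.to_numpy(float)
    obs = np.abs(np.nan_to_num(stats.pearson_rows(x, a), nan=0.0))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, x.shape[0]))
    for p in range(n_perm):
        null[p] = np.abs(
            np.nan_to_num(stats.pearson_rows(x, rng.permutation(a)), nan=0.0)
        )
    gene_fdr = stats.permutation_fdr(obs, null.ravel(), n_perm)
    return [g for g, f in zip(expr.index, gene_fdr) if f <= fdr]


def target_enrichment(
    activity,
    expr: pd.DataFrame,
    targets,
    universe=None,
    *,
    correlated_gene_fdr: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """One-sided FET p for predicted-target over-representation among
    activity-correlated genes."""
    if universe is None:
        universe = list(expr.index)
    universe = [g for g in universe if g in expr.index]
    sub = expr.loc[universe]
    corr = set(
        correlated_genes(
            activity, sub, fdr=correlated_gene_fdr, n_perm=n_perm, seed=seed
        )
    )
    target_set = set(targets) & set(universe)
    if not corr:
        return 1.0
    overlap = len(corr & target_set)
    return stats.fet_overrep(overlap, len(corr), len(target_set), len(universe))


def loo_correlations(profile, expr: pd.DataFrame) -> pd.Series:
    """Per-target-gene correlation with the leave-one-gene-out activity.

    The inferred activity is a weighted combination of the target genes'
    own expression, so correlating it directly with each target is
    circular — under a no-effect null the most up-weighted noise genes
    look strongly anti-correlated. Recomputing each sample's slope without
    gene g before correlating against gene g removes the direct
    circularity while leaving genuine shared-signal correlation intact.
    """
    genes = list(profile.weights.index)
    x = expr.loc[genes].to_numpy(float)
    b = profile.baseline.loc[genes].to_numpy(float)
    w = profile.weights.to_numpy(float)
    d = x - b[:, None]
    num = (w * b) @ d
    den = float(w @ (b * b))
    r = np.empty(len(genes))
    for g in range(len(genes)):
        den_g = den - w[g] * b[g] ** 2
        if den_g <= 0:
            r[g] = np.nan
            continue
        a_g = -(num - w[g] * b[g] * d[g]) / den_g
        rg = stats.pearson_rows(x[g][None, :], a_g)[0]
        r[g] = rg
    return pd.Series(r, index=genes)


def functional_targets(
    activity,
    expr: pd.DataFrame,
    targets,
    *,
    fdr_threshold: float = 0.01,
    profile=None,
) -> pd.DataFrame:
    """Predicted targets whose expression correlates with the activity at
    the BH FDR threshold; rows carry gene, r, p, fdr, sign.

    The "functional (negative) targets" used by the key-miRNA criterion are
    the rows with sign == -1. When an :class:`ActivityProfile` is supplied
    the correlation is computed against the leave-one-gene-out activity
    (see :func:`loo_correlations`), which keeps the no-effect null
    calibrated at the stated FDR.
    """
    genes = [g for g in targets if g in expr.index]
    if not genes:
        logger.warning("functional_targets: empty target/expression intersection")
        return pd.DataFrame(columns=["gene_id", "r", "p", "fdr", "sign"])
    a = np.asarray(activity, float)
    if profile is not None:
        loo = loo_correlations(profile, expr)
        in_profile = [g for g in genes if g in loo.index]
        x = expr.loc[genes].to_numpy(float)
        r = stats.pearson_rows(x, a)
        r_series = pd.Series(r, index=genes)
        r_series.loc[in_profile] = loo.loc[in_profile]
        r = r_series.to_numpy(float)
    else:
        x = expr.loc[genes].to_numpy(float)
        r = stats.pearson_rows(x, a)
    p = stats.pearson_p_from_r(r, a.size)
    p = np.where(np.isnan(r), np.nan, p)
    fdr = stats.bh_fdr(p)
    keep = ~np.isnan(fdr) & (fdr <= fdr_threshold)
    out = pd.DataFrame(
        {
            "gene_id": np.asarray(genes)[keep],
            "r": r[keep],
            "p": p[keep],
            "fdr": fdr[keep],
            "sign": np.where(r[keep] < 0, -1, 1),
        }
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def flag_key(counts, min_count: int = 10) -> np.ndarray:
    """Key miRNA = at least `min_count` functional negative targets."""
    return np.asarray(counts) >= min_count


def diff_expression_vs_normal(
    tumor_mirna: pd.DataFrame,
    normal_mirna: pd.DataFrame,
    *,
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Per-miRNA two-sided WMW of tumor vs normal expression."""
    if normal_mirna.shape[1] < 1:
        raise ValueError("need at least one normal sample")
    rows = {}
    for mir in tumor_mirna.index:
        if mir not in normal_mirna.index:
            rows[mir] = (np.nan, False)
            continue
        _, p = stats.wmw_test(
            tumor_mirna.loc[mir].to_numpy(float),
            normal_mirna.loc[mir].to_numpy(float),
        )
        rows[mir] = (p, p < p_threshold)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["wmw_p_vs_normal", "diff_expressed"]
    )
    out.index.name = "mirna_id"
    return out


def intersect_functional_key(screen: pd.DataFrame) -> list[str]:
    """miRNAs with all three flags set."""
    mask = (
        screen["functionally_active"] & screen["key"] & screen["diff_expressed"]
    )
    return list(screen.index[mask])


def build_screen_table(
    activities: pd.DataFrame,
    expr: pd.DataFrame,
    mirna: pd.DataFrame,
    targets: dict[str, list[str]],
    normal_mirna: pd.DataFrame | None = None,
    params: ScreenParams = ScreenParams(),
    profiles: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Assemble the full screen: one row per miRNA, all flags.

    The enrichment criterion's FDR is Benjamini–Hochberg across miRNAs on
    the one-sided FET p-values (a full permutation null there would nest
    one permutation FDR inside another).
    """
    corr = correlation_screen(
        activities, mirna, n_perm=params.n_perm, seed=params.seed
    )
    enrich_p = []
    n_func = []
    target_tables: dict[str, pd.DataFrame] = {}
    for i, mir in enumerate(activities.index):
        a = activities.loc[mir].to_numpy(float)
        enrich_p.append(
            target_enrichment(
                a,
                expr,
                targets.get(mir, []),
                correlated_gene_fdr=params.correlated_gene_fdr,
                n_perm=params.correlated_gene_perms,
                seed=params.seed + 1 + i,
            )
        )
        ft = functional_targets(
            a,
            expr,
            targets.get(mir, []),
            fdr_threshold=params.functional_target_fdr,
            profile=profiles.get(mir) if profiles else None,
        )
        target_tables[mir] = ft
        n_func.append(int((ft["sign"] == -1).sum()) if len(ft) else 0)
    table = corr.copy()
    table["enrichment_p"] = enrich_p
    table["enrichment_fdr"] = stats.bh_fdr(np.asarray(enrich_p))
    table["n_functional_targets"] = n_func
    table["functionally_active"] = (
        (table["r_activity_expression"] > 0)
        & (table["r_fdr"] <= params.correlation_fdr)
        & (table["enrichment_fdr"] <= params.enrichment_fdr)
    )
    table["key"] = flag_key(table["n_functional_targets"], params.key_min_targets)
    if normal_mirna is not None:
        de = diff_expression_vs_normal(
            mirna.loc[activities.index],
            normal_mirna,
            p_threshold=params.de_p_threshold,
        )
        table = table.join(de)
    else:
        table["wmw_p_vs_normal"] = np.nan
        table["diff_expressed"] = False
    table["diff_expressed"] = table["diff_expressed"].fillna(False).astype(bool)
    table["functional_key"] = (
        table["functionally_active"] & table["key"] & table["diff_expressed"]
    )
    table.index.name = "mirna_id"
    return table, target_tables
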