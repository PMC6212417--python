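"""Post-screen association analyses.

Everything enrichment-shaped routes through the hypergeometric kernel in
:mod:`miract.stats`; the activity-group differential-expression step uses a
rank-sum statistic with a label-permutation null pooled across genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from miract import stats
from miract.survival import GroupAssignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene-set enrichment


def pathway_enrichment(
    functional_targets,
    collection: dict[str, list[str]],
    universe,
    *,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """One-sided FET of the functional-target set against each pathway,
    restricted to the declared gene universe."""
    universe = set(universe)
    target_set = set(functional_targets) & universe
    rows = {}
    for name, members in collection.items():
        pathway = set(members) & universe
        if not pathway:
            rows[name] = (0, len(pathway), 1.0, False, "empty_in_universe")
            continue
        overlap = len(target_set & pathway)
        p = stats.fet_overrep(overlap, len(target_set), len(pathway), len(universe))
        rows[name] = (overlap, len(pathway), p, p < p_threshold, "")
    out = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["overlap", "pathway_size_in_universe", "p", "significant", "note"],
    )
    out.index.name = "pathway"
    return out.sort_values("p", kind="mergesort")


def geneset_overlap_fet(direct_targets, gene_set, universe) -> float:
    """One-sided FET between a target set and a single gene set."""
    universe = set(universe)
    a = set(direct_targets) & universe
    b = set(gene_set) & universe
    if not a or not b:
        return 1.0
    return stats.fet_overrep(len(a & b), len(a), len(b), len(universe))


def geneset_correlation_ks(
    activity, expr: pd.DataFrame, gene_set, universe=None
) -> tuple[float, float, int]:
    """Two-sample KS between activity-expression correlations of set genes
    and the rest of the universe.

    Returns (statistic, p, sign of median difference: -1 when the set's
    correlations sit lower, i.e. the set is enriched for negatively
    correlated genes).
    """
    if universe is None:
        universe = list(expr.index)
    universe = [g for g in universe if g in expr.index]
    in_set = [g for g in universe if g in set(gene_set)]
    out_set = [g for g in universe if g not in set(gene_set)]
    if len(in_set) < 3:
        raise ValueError("gene set has fewer than 3 genes in the universe")
    if len(out_set) < 3:
        raise ValueError("complement has fewer than 3 genes in the universe")
    a = np.asarray(activity, float)
    r_all = stats.pearson_rows(expr.loc[universe].to_numpy(float), a)
    r = pd.Series(r_all, index=universe).dropna()
    rs, rb = r.loc[[g for g in in_set if g in r.index]], r.loc[[g for g in out_set if g in r.index]]
    res = stats.ks_two_sample(rs.to_numpy(), rb.to_numpy())
    sign = int(np.sign(rs.median() - rb.median()))
    return res.statistic, res.pvalue, sign


# ---------------------------------------------------------------------------
# Activity-group differential expression


@dataclass
class DESignature:
    mirna_id: str
    up_genes: list[str]  # higher in the overactive group
    down_genes: list[str]
    table: pd.DataFrame = field(repr=False)  # per-gene p, direction, significant
    p_cutoff: float = float("nan")

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down lists overlap")


def de_by_activity_group(
    expr: pd.DataFrame,
    groups: GroupAssignment,
    *,
    n_perm: int = 500,
    seed: int = 0,
    empirical_fdr: float = 0.05,
    mirna_id: str = "",
) -> DESignature:
    """Rank-sum DE between over- and under-active samples.

    Per-gene two-sided WMW p (tie-corrected normal approximation — the
    groups here are half-cohorts); the significance cutoff is the largest
    observed p at which the pooled label-permutation null keeps the
    empirical FDR at or below `empirical_fdr`. Direction comes from the
    median difference.
    """
    over = [s for s in groups.overactive if s in expr.columns]
    under = [s for s in groups.underactive if s in expr.columns]
    if len(over) < 3 or len(under) < 3:
        raise ValueError("both activity groups need >= 3 samples")
    cols = over + under
    m = expr.loc[:, cols].to_numpy(float)
    mask = np.zeros(len(cols), bool)
    mask[: len(over)] = True
    n1, n2 = len(over), len(under)
    n = n1 + n2

    # ranks are label-invariant: compute once, reuse for every permutation
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    tie_term = np.array(
        [(c**3 - c).sum() for c in (np.unique(row, return_counts=True)[1] for row in m)],
        dtype=float,
    )
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0

    def pvals(col_mask: np.ndarray) -> np.ndarray:
        r1 = ranks[:, col_mask].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (np.abs(u - mu) - 0.5) / np.sqrt(sigma2)
        p = 2.0 * sps.norm.sf(np.maximum(z, 0.0))
        return np.where(sigma2 <= 0, 1.0, np.minimum(p, 1.0))

    obs_p = pvals(mask)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, m.shape[0]))
    for i in range(n_perm):
        null[i] = pvals(rng.permutation(mask))
    # empirical FDR over candidate cutoffs = observed p values (smaller = better)
    null_sorted = np.sort(null.ravel())
    obs_sorted = np.sort(obs_p)
    cutoffs = np.unique(obs_sorted)
    n_null_le = np.searchsorted(null_sorted, cutoffs, side="right") / n_perm
    n_obs_le = np.searchsorted(obs_sorted, cutoffs, side="right")
    fdr_at = n_null_le / np.maximum(n_obs_le, 1)
    ok = cutoffs[fdr_at <= empirical_fdr]
    p_cutoff = float(ok.max()) if ok.size else -1.0

    constant = sigma2 <= 0
    significant = (obs_p <= p_cutoff) & ~constant
    med_diff = np.median(m[:, mask], axis=1) - np.median(m[:, ~mask], axis=1)
    direction = np.sign(med_diff)
    table = pd.DataFrame(
        {
            "p": obs_p,
            "direction": direction,
            "significant": significant,
        },
        index=expr.index,
    )
    up = list(table.index[significant & (direction > 0)])
    down = list(table.index[significant & (direction < 0)])
    return DESignature(
        mirna_id=mirna_id, up_genes=up, down_genes=down, table=table, p_cutoff=p_cutoff
    )


def export_cmap_signature(
    signature: DESignature,
    directory: str | Path,
    *,
    probe_map: dict[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write up.grp / down.grp: one uppercase identifier per line, no header."""
    if not signature.up_genes and not signature.down_genes:
        raise ValueError("both gene lists are empty; nothing to export")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def render(genes: list[str]) -> list[str]:
        mapped = [probe_map.get(g, g) if probe_map else g for g in genes]
        seen: dict[str, None] = {}
        for g in mapped:
            gu = g.upper()
            if gu in seen:
                warnings.warn(f"duplicate identifier {gu} deduplicated", stacklevel=3)
            seen[gu] = None
        return list(seen)

    up_path = directory / "up.grp"
    down_path = directory / "down.grp"
    up_path.write_text("".join(g + "\n" for g in render(signature.up_genes)))
    down_path.write_text("".join(g + "\n" for g in render(signature.down_genes)))
    return up_path, down_path


# ---------------------------------------------------------------------------
# Mutation and immune associations


def mutation_activity_association(
    mutations: pd.DataFrame,
    activity: pd.Series,
    *,
    p_threshold: float = 0.003,
) -> pd.DataFrame:
    """Per-gene association between mutation status and activity.

    WMW on the continuous activity by mutation status, plus a two-sided FET
    on the 2x2 of mutation x median-split activity; flagged when either p
    falls below `p_threshold`. Genes mutated in none or all samples are
    skipped.
    """
    shared = [s for s in mutations.columns if s in activity.index]
    act = activity.loc[shared]
    med = float(act.median())
    high = (act > med).to_numpy()
    rows = {}
    for gene in mutations.index:
        status = mutations.loc[gene, shared].to_numpy(int).astype(bool)
        n_mut = int(status.sum())
        if n_mut == 0 or n_mut == len(shared):
            rows[gene] = (n_mut, np.nan, np.nan, False, "all_or_none_mutated")
            continue
        _, wmw_p = stats.wmw_test(act[status].to_numpy(), act[~status].to_numpy())
        table = [
            [int((status & high).sum()), int((status & ~high).sum())],
            [int((~status & high).sum()), int((~status & ~high).sum())],
        ]
        fet_p = stats.fet_two_sided(table)
        flag = min(wmw_p, fet_p) < p_threshold
        rows[gene] = (n_mut, wmw_p, fet_p, flag, "")
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_mutated", "wmw_p", "fet_p", "significant", "note"]
    )
    out.index.name = "gene_id"
    return out


def immune_score_association(
    expr: pd.DataFrame,
    marker_genes,
    groups: GroupAssignment,
) -> tuple[pd.Series, float, float]:
    """Immune-infiltration score = summed marker-gene expression per sample;
    Welch t-test between over- and under-active groups."""
    markers = [g for g in marker_genes if g in expr.index]
    n_missing = len(list(marker_genes)) - len(markers)
    if not markers:
        raise ValueError("no marker genes present in the expression matrix")
    if n_missing:
        logger.info("immune score: %d marker genes absent from expression", n_missing)
    score = expr.loc[markers].sum(axis=0)
    score.name = "immune_score"
    over = [s for s in groups.overactive if s in score.index]
    under = [s for s in groups.underactive if s in score.index]
    t, p = stats.welch_t(score[over].to_numpy(), score[under].to_numpy())
    return score, t, p
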