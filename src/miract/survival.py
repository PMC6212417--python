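"""Median-split survival screening.

Each miRNA's per-sample activity is dichotomized at its median, the two
Kaplan–Meier curves are compared by the log-rank test, and significance is
calibrated by permuting the activity vector (1000 times by default) to
build a pooled empirical null for the FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from miract import stats

logger = logging.getLogger(__name__)


class DegenerateSplitError(ValueError):
    pass


@dataclass
class GroupAssignment:
    labels: pd.Series  # per-sample {"overactive", "underactive"}
    split_value: float

    @property
    def overactive(self) -> pd.Index:
        return self.labels.index[self.labels == "overactive"]

    @property
    def underactive(self) -> pd.Index:
        return self.labels.index[self.labels == "underactive"]


def dichotomize_by_median(values: pd.Series) -> GroupAssignment:
    """Above the median -> overactive; at or below -> underactive."""
    if values.size < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(values.median())
    if float(values.max()) == float(values.min()):
        raise DegenerateSplitError("degenerate_split: all values equal")
    labels = pd.Series(
        np.where(values > med, "overactive", "underactive"),
        index=values.index,
        name="group",
    )
    if (labels == "overactive").sum() == 0:
        raise DegenerateSplitError("degenerate_split: overactive group empty")
    return GroupAssignment(labels=labels, split_value=med)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit estimator evaluated at each distinct event time.

    Returns columns time, n_at_risk, n_events, survival. Censored-only data
    yields an empty frame (the curve stays at 1).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    rows = []
    s = 1.0
    for et in event_times:
        n_at_risk = int((t >= et).sum())
        n_events = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - n_events / n_at_risk
        rows.append((et, n_at_risk, n_events, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _logrank_terms(t: np.ndarray, e: np.ndarray):
    """Precompute per-distinct-event-time matrices for bulk log-rank.

    Returns (at_risk A [n x J], deaths D [n x J], d_j, n_j).
    """
    event_times = np.unique(t[e == 1])
    A = t[:, None] >= event_times[None, :]
    D = (t[:, None] == event_times[None, :]) & (e[:, None] == 1)
    d = D.sum(axis=0).astype(float)
    n = A.sum(axis=0).astype(float)
    return A.astype(float), D.astype(float), d, n


def _logrank_bulk(G: np.ndarray, A, D, d, n) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square for each row of group matrix G (rows x samples).

    Returns (chi2, O1 - E1) per row; group 1 = True entries of G.
    """
    n1 = G @ A  # at-risk in group 1 per event time
    d1 = G @ D  # deaths in group 1 per event time
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = d * n1 / n
        var = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / np.maximum(n - 1.0, 1.0)
        var = np.where(n <= 1.0, 0.0, var)
    o_minus_e = (d1 - e1).sum(axis=1)
    v = var.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v > 0, o_minus_e**2 / v, 0.0)
    return chi2, o_minus_e


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    `groups` is boolean (True = group 1) or any two-valued labeling.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    if g.dtype != bool:
        levels = pd.unique(g)
        if levels.size != 2:
            raise ValueError("log-rank requires exactly two groups")
        g = g == levels[0]
    if g.all() or (~g).all():
        raise ValueError("log-rank requires two non-empty groups")
    if e.sum() == 0:
        warnings.warn("no events at all; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    A, D, d, n = _logrank_terms(t, e)
    chi2, _ = _logrank_bulk(g[None, :].astype(float), A, D, d, n)
    chi2 = float(chi2[0])
    return chi2, float(sps.chi2.sf(chi2, 1))


def survival_screen(
    activities: pd.DataFrame,
    survival: pd.DataFrame,
    *,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median-split log-rank screen over all miRNAs with permutation FDR.

    The null permutes each miRNA's activity vector `n_perm` times (median
    splitting a permuted vector permutes the group labels), pooling the
    chi-square statistics across miRNAs. Output columns: n_over, n_under,
    chi2, p, fdr, direction (+1 = overactive group has better survival),
    skipped_reason.
    """
    shared = [s for s in activities.columns if s in survival.index]
    dropped = activities.shape[1] - len(shared)
    if dropped:
        logger.info("survival screen: dropped %d samples without survival records", dropped)
    if len(shared) < 20:
        raise ValueError(f"insufficient_samples: need >= 20, got {len(shared)}")
    surv = survival.loc[shared]
    t = surv["time"].to_numpy(float)
    e = surv["event"].to_numpy(int)
    A, D, d, n = _logrank_terms(t, e)
    rng = np.random.default_rng(seed)

    rows = {}
    null_chunks = []
    for mir in activities.index:
        a = activities.loc[mir, shared]
        try:
            groups = dichotomize_by_median(a)
        except DegenerateSplitError as exc:
            rows[mir] = (0, 0, np.nan, np.nan, np.nan, 0, str(exc))
            continue
        g = (groups.labels == "overactive").to_numpy()
        if e.sum() == 0:
            rows[mir] = (int(g.sum()), int((~g).sum()), 0.0, 1.0, np.nan, 0, "no_events")
            continue
        chi2, ome = _logrank_bulk(g[None, :].astype(float), A, D, d, n)
        chi2 = float(chi2[0])
        p = float(sps.chi2.sf(chi2, 1))
        direction = int(np.sign(-ome[0]))  # fewer deaths than expected -> +1
        perm_idx = np.argsort(rng.random((n_perm, g.size)), axis=1)
        G = g[perm_idx].astype(float)
        null_chi2, _ = _logrank_bulk(G, A, D, d, n)
        null_chunks.append(null_chi2)
        rows[mir] = (int(g.sum()), int((~g).sum()), chi2, p, np.nan, direction, "")
    out = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["n_over", "n_under", "chi2", "p", "fdr", "direction", "skipped_reason"],
    )
    out.index.name = "mirna_id"
    tested = out.index[out["skipped_reason"] == ""]
    if len(tested) and null_chunks:
        null = np.concatenate(null_chunks)
        observed = out.loc[tested, "chi2"].to_numpy(float)
        out.loc[tested, "fdr"] = stats.permutation_fdr(observed, null, n_perm)
    return out


def km_curves_by_group(times, events, groups: GroupAssignment) -> pd.DataFrame:
    """KM coordinates per group, for plotting; columns group/time/survival."""
    t = pd.Series(np.asarray(times, float), index=groups.labels.index)
    e = pd.Series(np.asarray(events, int), index=groups.labels.index)
    frames = []
    for name in ("overactive", "underactive"):
        members = groups.labels.index[groups.labels == name]
        km = km_estimate(t[members], e[members])
        km.insert(0, "group", name)
        frames.append(km)
    return pd.concat(frames, ignore_index=True)
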