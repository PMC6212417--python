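"""Two-step correlation classifier for tumor molecular subtypes.

Step 1 assigns each sample the class (I–IV) whose signature-gene centroid
it correlates with best. Step 2 splits class I/II samples into p53-like
(positive correlation with the p53 signature values) and Luminal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from miract import stats

logger = logging.getLogger(__name__)

STEP1_CLASSES = ("I", "II", "III", "IV")
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class SignatureCentroids:
    """Per-class mean expression over the signature genes, plus the p53 signature."""

    centroids: pd.DataFrame  # signature genes x 4 class columns
    p53_signature: pd.Series  # gene -> signature value

    def __post_init__(self) -> None:
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate genes in signature centroid table")
        if self.p53_signature.index.has_duplicates:
            raise ValueError("duplicate genes in p53 signature")
        if self.centroids.shape[1] != 4:
            raise ValueError("centroid table must have 4 class columns")
        if self.centroids.shape[0] < 2:
            raise ValueError("need at least 2 signature genes")
        if not np.isfinite(self.centroids.to_numpy()).all():
            raise ValueError("non-finite centroid value")


def build_centroids(
    expr: pd.DataFrame,
    reference_labels: pd.Series,
    signature_genes,
) -> pd.DataFrame:
    """Class centroid = mean expression over that class's samples, on the
    signature genes. `reference_labels` maps sample -> class I–IV."""
    genes = [g for g in signature_genes if g in expr.index]
    missing = len(list(signature_genes)) - len(genes)
    if missing:
        logger.warning("dropped %d signature genes absent from expression", missing)
    if len(genes) < 2:
        raise ValueError("fewer than 2 signature genes survive intersection")
    cols = {}
    for cls in STEP1_CLASSES:
        members = reference_labels.index[reference_labels == cls]
        members = [s for s in members if s in expr.columns]
        if not members:
            raise ValueError(f"reference class {cls!r} has no samples")
        cols[f"class{cls}"] = expr.loc[genes, members].mean(axis=1)
    return pd.DataFrame(cols)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def assign_step1(expr: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """Correlate each sample with the 4 centroids; argmax class wins.

    Ties break toward the earlier class (I < II < III < IV), with a logged
    warning. Samples constant on the signature genes are flagged
    `unclassifiable`. Returns a frame with step1_class and r_I..r_IV.
    """
    genes = [g for g in centroids.index if g in expr.index]
    if len(genes) < 2:
        raise ValueError("fewer than 2 signature genes shared with expression")
    if len(genes) < len(centroids.index):
        logger.warning(
            "step 1 using %d of %d signature genes", len(genes), len(centroids.index)
        )
    cent = centroids.loc[genes].to_numpy(float)
    sub = expr.loc[genes]
    records = {}
    for sample in expr.columns:
        vec = sub[sample].to_numpy(float)
        rs = np.array([_safe_corr(vec, cent[:, c]) for c in range(4)])
        if np.isnan(rs).all() or np.std(vec) == 0:
            records[sample] = (UNCLASSIFIABLE, *rs)
            continue
        best = np.nanmax(rs)
        winners = np.flatnonzero(rs == best)
        if winners.size > 1:
            logger.warning(
                "sample %s tied between classes %s; taking the first",
                sample,
                [STEP1_CLASSES[i] for i in winners],
            )
        records[sample] = (STEP1_CLASSES[int(winners[0])], *rs)
    out = pd.DataFrame.from_dict(
        records, orient="index", columns=["step1_class", "r_I", "r_II", "r_III", "r_IV"]
    )
    out.index.name = "sample_id"
    return out


def assign_step2(
    expr: pd.DataFrame,
    luminal_like_samples,
    p53_signature: pd.Series,
) -> pd.DataFrame:
    """Split class I/II samples on the p53 signature: r > 0 -> p53-like."""
    genes = [g for g in p53_signature.index if g in expr.index]
    if len(genes) < 2:
        raise ValueError("fewer than 2 p53-signature genes shared with expression")
    sig = p53_signature.loc[genes].to_numpy(float)
    records = {}
    for sample in luminal_like_samples:
        vec = expr.loc[genes, sample].to_numpy(float)
        r = _safe_corr(vec, sig)
        if np.isnan(r):
            records[sample] = (UNCLASSIFIABLE, r)
        else:
            records[sample] = ("p53-like" if r > 0 else "Luminal", r)
    out = pd.DataFrame.from_dict(records, orient="index", columns=["label", "r_p53"])
    out.index.name = "sample_id"
    return out


def classify(
    expr: pd.DataFrame,
    centroids: pd.DataFrame | SignatureCentroids,
    p53_signature: pd.Series | None = None,
) -> pd.DataFrame:
    """Both steps composed: class III -> Basal, IV -> ClassIV, I/II -> step 2.

    Returns one row per sample: step1_class, label, r_I..r_IV, r_p53.
    """
    if isinstance(centroids, SignatureCentroids):
        p53_signature = centroids.p53_signature
        centroids = centroids.centroids
    if p53_signature is None:
        raise ValueError("p53 signature required")
    step1 = assign_step1(expr, centroids)
    labels = pd.Series(index=step1.index, dtype=object, name="label")
    labels[step1["step1_class"] == "III"] = "Basal"
    labels[step1["step1_class"] == "IV"] = "ClassIV"
    labels[step1["step1_class"] == UNCLASSIFIABLE] = UNCLASSIFIABLE
    luminal_like = step1.index[step1["step1_class"].isin(["I", "II"])]
    r_p53 = pd.Series(np.nan, index=step1.index, name="r_p53")
    if len(luminal_like):
        step2 = assign_step2(expr, luminal_like, p53_signature)
        labels[step2.index] = step2["label"]
        r_p53[step2.index] = step2["r_p53"]
    out = step1.copy()
    out.insert(1, "label", labels)
    out["r_p53"] = r_p53
    return out
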