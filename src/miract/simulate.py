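"""Synthetic cohorts with the statistical structure the pipeline assumes.

A cohort couples: half-normal latent per-sample miRNA activities, target
genes degraded proportionally to activity for a configurable functional
fraction, miRNA readouts correlated with activity, additive subtype
centroid structure on a signature-gene block disjoint from all targets,
survival times whose log-hazard is linear in one designated miRNA's
activity, matched zero-activity normal samples, and a binary mutation table
with one gene linked to low activity of the designated miRNA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from miract import io

STEP1_CLASSES = ("I", "II", "III", "IV")
SUBTYPE_LABELS = ("Luminal", "p53-like", "Basal", "ClassIV")
# truth subtype -> step-1 class it must fall into
SUBTYPE_TO_CLASS = {"Luminal": "I", "p53-like": "II", "Basal": "III", "ClassIV": "IV"}

_MIRNA_OFFSET = 4.0  # additive offset of the miRNA readout (log2 RPM scale)
_MIRNA_GAIN = 2.0  # activity -> readout gain before coupling


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of :func:`generate_cohort`. Defaults give the standard cohort."""

    n_samples: int = 120
    n_normals: int = 20
    n_genes: int = 1500
    n_mirnas: int = 20
    targets_per_mirna: int = 60
    functional_fraction: float = 0.7
    activity_scale: float = 0.8
    degradation_effect: float = 0.4
    mirna_coupling: float = 0.8
    noise_sd_mrna: float = 0.5
    noise_sd_mirna: float = 0.3
    n_subtypes: int = 4
    centroid_shift: float = 2.0
    signature_genes_per_class: int = 25
    prognostic_mirna_index: int = 0
    log_hazard_per_activity: float = -0.5
    censoring_rate: float = 0.3
    mutation_gene_count: int = 5
    mutation_background_rate: float = 0.2
    base_hazard: float = 0.1
    simulate_subtypes: bool = True
    # optional per-miRNA override of functional_fraction (len n_mirnas)
    functional_fraction_per_mirna: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "targets_per_mirna": self.targets_per_mirna,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_normals < 0 or self.mutation_gene_count < 0:
            raise ValueError("n_normals and mutation_gene_count must be >= 0")
        for name in ("functional_fraction", "censoring_rate", "mirna_coupling"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("activity_scale", "degradation_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.functional_fraction_per_mirna is not None:
            if len(self.functional_fraction_per_mirna) != self.n_mirnas:
                raise ValueError("functional_fraction_per_mirna length != n_mirnas")
        if self.simulate_subtypes and self.n_samples < 20 * self.n_subtypes:
            raise ValueError(
                "need at least 20 samples per subtype when subtyping is simulated"
            )
        n_signature = self.n_signature_genes if self.simulate_subtypes else 0
        needed = n_signature + self.n_mirnas * self.targets_per_mirna
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small: need {needed} for disjoint "
                "signature block and per-miRNA target blocks"
            )
        if not 0 <= self.prognostic_mirna_index < self.n_mirnas:
            raise ValueError("prognostic_mirna_index out of range")

    @property
    def n_signature_genes(self) -> int:
        # one block per step-1 class plus the p53-signature block
        return self.signature_genes_per_class * (self.n_subtypes + 1)

    def fraction_for(self, mirna_index: int) -> float:
        if self.functional_fraction_per_mirna is not None:
            return self.functional_fraction_per_mirna[mirna_index]
        return self.functional_fraction


@dataclass
class SyntheticCohort:
    """Ground truth plus observable matrices for one simulated cohort."""

    config: SimulationConfig
    mrna: pd.DataFrame  # genes x (tumors + normals), log2 scale
    mirna: pd.DataFrame  # miRNAs x (tumors + normals), >= 0
    targets: dict[str, list[str]]
    true_activity: pd.DataFrame  # miRNAs x (tumors + normals); normals 0
    functional_flags: pd.DataFrame  # columns mirna_id, gene_id, functional
    subtype_truth: pd.Series  # tumor samples -> label
    survival: pd.DataFrame  # index tumor sample, columns time/event
    mutations: pd.DataFrame  # mutation genes x tumor samples, 0/1
    normal_sample_ids: list[str]
    baseline_truth: pd.Series  # per-gene generating baseline b_g
    signature_genes: dict[str, list[str]]  # class blocks + "p53"
    p53_signature: pd.Series  # per-gene signature value (delta_g)

    @property
    def tumor_sample_ids(self) -> list[str]:
        normals = set(self.normal_sample_ids)
        return [s for s in self.mrna.columns if s not in normals]

    def reference_centroids(self) -> pd.DataFrame:
        """Step-1 centroids rebuilt from truth labels over the class blocks."""
        genes = [g for c in STEP1_CLASSES for g in self.signature_genes[c]]
        cols = {}
        for label, cls in SUBTYPE_TO_CLASS.items():
            members = self.subtype_truth.index[self.subtype_truth == label]
            cols[f"class{cls}"] = self.mrna.loc[genes, members].mean(axis=1)
        return pd.DataFrame(cols)


def _calibrate_censoring(times: np.ndarray, rate: float) -> float:
    """Uniform(0, C) upper bound giving an expected censored fraction ≈ rate.

    With U ~ Uniform(0, C), P(censor sample i) = min(t_i, C)/C; the mean of
    that over samples is decreasing in C, so bisect.
    """

    def frac(c: float) -> float:
        return float(np.minimum(times, c).mean() / c)

    lo, hi = 1e-9, float(times.max()) * 2
    while frac(hi) > rate:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Deterministically generate one cohort from `config` (seed included)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    mirnas = [f"mir-{i:03d}" for i in range(1, cfg.n_mirnas + 1)]
    tumors = [f"T{i:04d}" for i in range(1, cfg.n_samples + 1)]
    normals = [f"N{i:04d}" for i in range(1, cfg.n_normals + 1)]
    samples = tumors + normals
    n_total = len(samples)

    b = rng.uniform(4.0, 12.0, size=cfg.n_genes)  # per-gene baseline, log2 scale

    # --- gene bookkeeping: signature blocks first, then disjoint target blocks
    cursor = 0
    signature_genes: dict[str, list[str]] = {}
    if cfg.simulate_subtypes:
        for cls in STEP1_CLASSES[: cfg.n_subtypes]:
            signature_genes[cls] = genes[cursor : cursor + cfg.signature_genes_per_class]
            cursor += cfg.signature_genes_per_class
        signature_genes["p53"] = genes[cursor : cursor + cfg.signature_genes_per_class]
        cursor += cfg.signature_genes_per_class
    pool = genes[cursor:]
    perm = rng.permutation(len(pool))
    targets: dict[str, list[str]] = {}
    for k, mir in enumerate(mirnas):
        idx = perm[k * cfg.targets_per_mirna : (k + 1) * cfg.targets_per_mirna]
        targets[mir] = [pool[i] for i in idx]

    # --- latent activities: half-normal for tumors, exactly 0 for normals
    alpha = np.zeros((cfg.n_mirnas, n_total))
    alpha[:, : cfg.n_samples] = cfg.activity_scale * np.abs(
        rng.standard_normal((cfg.n_mirnas, cfg.n_samples))
    )
    beta = cfg.degradation_effect
    if beta > 0:
        bad = np.mean(beta * alpha[:, : cfg.n_samples] >= 1.0)
        if bad > 0.01:
            raise ValueError(
                f"ill-posed simulation: degradation_effect * activity >= 1 for "
                f"{bad:.1%} of draws (> 1%); expression would go negative"
            )

    # --- functional flags (deterministic count per miRNA)
    flag_rows = []
    functional_lookup: dict[str, np.ndarray] = {}
    for k, mir in enumerate(mirnas):
        n_func = int(round(cfg.fraction_for(k) * cfg.targets_per_mirna))
        flags = np.zeros(cfg.targets_per_mirna, dtype=bool)
        flags[:n_func] = True
        functional_lookup[mir] = flags
        for gene, fl in zip(targets[mir], flags):
            flag_rows.append((mir, gene, bool(fl)))
    functional_flags = pd.DataFrame(
        flag_rows, columns=["mirna_id", "gene_id", "functional"]
    )

    # --- mRNA matrix
    x = np.tile(b[:, None], (1, n_total)).astype(float)
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, mir in enumerate(mirnas):
        t_idx = np.array([gene_index[g] for g in targets[mir]])
        func = functional_lookup[mir]
        fi = t_idx[func]
        if fi.size:
            x[fi, :] = b[fi, None] * (1.0 - beta * alpha[k][None, :])

    # --- subtype truth and centroid shifts (tumors only)
    if cfg.simulate_subtypes:
        labels_cycle = np.array(SUBTYPE_LABELS[: cfg.n_subtypes])
        assignment = labels_cycle[np.arange(cfg.n_samples) % cfg.n_subtypes]
        assignment = assignment[rng.permutation(cfg.n_samples)]
        subtype_truth = pd.Series(assignment, index=tumors, name="subtype")
        for label in labels_cycle:
            cls = SUBTYPE_TO_CLASS[label]
            block = np.array([gene_index[g] for g in signature_genes[cls]])
            cols = np.flatnonzero(assignment == label)
            x[np.ix_(block, cols)] += cfg.centroid_shift
        # p53 block: signed delta separates Luminal (-) from p53-like (+)
        p53_block = np.array([gene_index[g] for g in signature_genes["p53"]])
        delta = rng.normal(0.0, cfg.centroid_shift, size=p53_block.size)
        p53_signature = pd.Series(delta, index=signature_genes["p53"], name="value")
        plus = np.flatnonzero(assignment == "p53-like")
        minus = np.flatnonzero(assignment == "Luminal")
        if plus.size:
            x[np.ix_(p53_block, plus)] += delta[:, None]
        if minus.size:
            x[np.ix_(p53_block, minus)] -= delta[:, None]
    else:
        subtype_truth = pd.Series(dtype=object, name="subtype")
        p53_signature = pd.Series(dtype=float, name="value")

    if cfg.noise_sd_mrna > 0:
        x += rng.normal(0.0, cfg.noise_sd_mrna, size=x.shape)

    # --- miRNA readout
    m = (
        cfg.mirna_coupling * alpha * _MIRNA_GAIN
        + _MIRNA_OFFSET
        + (rng.normal(0.0, cfg.noise_sd_mirna, size=alpha.shape) if cfg.noise_sd_mirna > 0 else 0.0)
    )
    m = np.maximum(m, 0.0)

    # --- survival (tumors only), exponential with log-linear hazard
    a_star = alpha[cfg.prognostic_mirna_index, : cfg.n_samples]
    hazard = cfg.base_hazard * np.exp(cfg.log_hazard_per_activity * a_star)
    raw_times = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_upper = _calibrate_censoring(raw_times, cfg.censoring_rate)
        censor_times = rng.uniform(0.0, c_upper, size=cfg.n_samples)
        time = np.minimum(raw_times, censor_times)
        event = (raw_times <= censor_times).astype(int)
    else:
        time = raw_times
        event = np.ones(cfg.n_samples, dtype=int)
    survival = pd.DataFrame({"time": time, "event": event}, index=pd.Index(tumors, name="sample_id"))

    # --- mutations (tumors only); gene 1 linked to low prognostic activity
    mut_genes = [f"MUTG{i:03d}" for i in range(1, cfg.mutation_gene_count + 1)]
    mut = np.zeros((cfg.mutation_gene_count, cfg.n_samples), dtype=int)
    if cfg.mutation_gene_count > 0:
        logit = -0.5 + 3.0 * (-a_star)  # mutated tumors skew to low activity
        p_linked = 1.0 / (1.0 + np.exp(-logit))
        mut[0] = rng.random(cfg.n_samples) < p_linked
        for j in range(1, cfg.mutation_gene_count):
            mut[j] = rng.random(cfg.n_samples) < cfg.mutation_background_rate
    mutations = pd.DataFrame(mut, index=mut_genes, columns=tumors)

    return SyntheticCohort(
        config=cfg,
        mrna=pd.DataFrame(x, index=genes, columns=samples),
        mirna=pd.DataFrame(m, index=mirnas, columns=samples),
        targets=targets,
        true_activity=pd.DataFrame(alpha, index=mirnas, columns=samples),
        functional_flags=functional_flags,
        subtype_truth=subtype_truth,
        survival=survival,
        mutations=mutations,
        normal_sample_ids=normals,
        baseline_truth=pd.Series(b, index=genes, name="baseline"),
        signature_genes=signature_genes,
        p53_signature=p53_signature,
    )


_FIXTURE_FILES = (
    "mrna.tsv",
    "mirna.tsv",
    "targets.gmt",
    "survival.tsv",
    "mutations.tsv",
    "truth.tsv",
)


def write_fixtures(
    cohort: SyntheticCohort, directory: str | Path, *, overwrite: bool = False
) -> dict:
    """Write the cohort as plain-text fixtures; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"fixture manifest already exists: {manifest_path}")

    paths: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = directory / name
        writer(path)
        paths[name] = path

    emit("mrna.tsv", lambda p: io.write_matrix(cohort.mrna, p, index_label="gene_id"))
    emit("mirna.tsv", lambda p: io.write_matrix(cohort.mirna, p, index_label="mirna_id"))
    emit("targets.gmt", lambda p: io.write_gmt(cohort.targets, p))
    emit("survival.tsv", lambda p: io.write_survival(cohort.survival, p))
    emit(
        "mutations.tsv",
        lambda p: cohort.mutations.to_csv(p, sep="\t", index_label="gene_id"),
    )
    emit(
        "truth.tsv",
        lambda p: io.write_matrix(cohort.true_activity, p, index_label="mirna_id"),
    )
    emit(
        "functional_flags.tsv",
        lambda p: cohort.functional_flags.to_csv(p, sep="\t", index=False),
    )
    emit(
        "normals.txt",
        lambda p: p.write_text("".join(s + "\n" for s in cohort.normal_sample_ids)),
    )
    if not cohort.subtype_truth.empty:
        emit(
            "subtypes_truth.tsv",
            lambda p: cohort.subtype_truth.to_frame().to_csv(
                p, sep="\t", index_label="sample_id"
            ),
        )
        emit(
            "centroids.tsv",
            lambda p: io.write_matrix(
                cohort.reference_centroids(), p, index_label="gene_id"
            ),
        )
        emit(
            "p53_signature.tsv",
            lambda p: cohort.p53_signature.to_frame().to_csv(
                p, sep="\t", index_label="gene_id", float_format=io.FLOAT_FMT
            ),
        )
    config_lines = [
        f"{f.name} = {getattr(cohort.config, f.name)}"
        for f in dataclasses.fields(cohort.config)
        if f.name != "functional_fraction_per_mirna"
    ]
    emit("config.txt", lambda p: p.write_text("\n".join(config_lines) + "\n"))

    return io.write_manifest(paths, manifest_path)
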