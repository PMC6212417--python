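"""End-to-end orchestration: classify, filter, infer, screen, survive,
and the downstream associations, all driven by one config and one seed.

Data outputs are a pure function of (inputs, config, seed); wall-clock
information lives only in report.json so reruns are byte-identical
elsewhere.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from miract import __version__, activity, downstream, io, screen, subtyping, survival

logger = logging.getLogger(__name__)

MIN_SUBTYPE_SAMPLES = 20


@dataclass
class RunConfig:
    mrna: Path
    targets: Path
    centroids: Path
    p53_signature: Path
    survival: Path
    out_dir: Path
    mirna: Path | None = None  # absent -> mRNA-only mode
    functional_targets: Path | None = None  # GMT, required for mRNA-only mode
    mutations: Path | None = None
    normals: Path | None = None  # one normal sample ID per line
    gene_sets: Path | None = None  # GMT of pathways
    immune_markers: Path | None = None  # one marker gene per line
    subtype: str = "p53-like"
    zero_fraction_max: float = 0.85
    min_targets: int = 10
    key_min_targets: int = 10
    functional_target_fdr: float = 0.01
    n_perm: int = 1000
    de_n_perm: int = 500
    baseline_extreme: str = "high_target_sum"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = io.read_config(path)
        kwargs: dict = {}
        for key, value in raw.items():
            if key in (
                "mrna", "mirna", "targets", "centroids", "p53_signature",
                "survival", "mutations", "normals", "gene_sets",
                "immune_markers", "functional_targets", "out_dir",
            ):
                kwargs[key] = Path(value)
            elif key in ("zero_fraction_max", "functional_target_fdr"):
                kwargs[key] = float(value)
            elif key in ("min_targets", "key_min_targets", "n_perm", "de_n_perm", "seed"):
                kwargs[key] = int(value)
            elif key in ("subtype", "baseline_extreme"):
                kwargs[key] = value
            else:
                raise io.InputError(f"unknown config key: {key}")
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise io.InputError(f"incomplete run config: {exc}") from exc


def stage_seeds(master: int) -> dict[str, int]:
    """Deterministic per-stage seeds fanned out from the master seed."""
    ss = np.random.SeedSequence(master)
    names = ("screen", "survival", "de", "extra")
    states = [int(child.generate_state(1)[0]) for child in ss.spawn(len(names))]
    return dict(zip(names, states))


def validate_inputs(config: RunConfig) -> list[str]:
    """Fatal diagnostics for the input files; empty list = clean."""
    findings: list[str] = []
    try:
        mrna = io.read_matrix(config.mrna, name="mrna")
    except Exception as exc:  # surface as a finding, not a crash
        return [f"mrna: {exc}"]
    if config.mirna is not None:
        try:
            mirna = io.read_matrix(config.mirna, name="mirna")
        except Exception as exc:
            findings.append(f"mirna: {exc}")
        else:
            try:
                io.check_sample_agreement(mrna, mirna)
            except io.InputError as exc:
                findings.append(str(exc))
    for label, path, reader in (
        ("targets", config.targets, io.read_gmt),
        ("centroids", config.centroids, io.read_centroids),
        ("p53_signature", config.p53_signature, io.read_signature_values),
        ("survival", config.survival, io.read_survival),
    ):
        try:
            reader(path)
        except Exception as exc:
            findings.append(f"{label}: {exc}")
    if config.mutations is not None:
        try:
            io.read_mutations(config.mutations)
        except Exception as exc:
            findings.append(f"mutations: {exc}")
    if config.mirna is None and config.functional_targets is None:
        findings.append("mRNA-only mode requires a functional_targets GMT")
    return findings


def _read_lines(path: Path) -> list[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written to report.json)."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "mode": "standard" if config.mirna is not None else "mrna_only",
        "subtype": config.subtype,
        "stages": {},
        "exclusions": {},
    }

    findings = validate_inputs(config)
    if findings:
        raise io.InputError("; ".join(findings))

    mrna = io.read_matrix(config.mrna, name="mrna")
    mirna = io.read_matrix(config.mirna, name="mirna") if config.mirna else None
    targets = io.read_gmt(config.targets)
    centroids = io.read_centroids(config.centroids)
    p53_sig = io.read_signature_values(config.p53_signature)
    surv = io.read_survival(config.survival)
    normal_ids = _read_lines(config.normals) if config.normals else []
    tumor_ids = [s for s in mrna.columns if s not in set(normal_ids)]

    # --- classification (tumors only)
    labels = subtyping.classify(mrna[tumor_ids], centroids, p53_sig)
    labels.to_csv(out / "subtype_labels.tsv", sep="\t", float_format=io.FLOAT_FMT)
    counts = labels["label"].value_counts().to_dict()
    report["stages"]["classify"] = {"n_samples": len(tumor_ids), "label_counts": counts}
    members = list(labels.index[labels["label"] == config.subtype])
    if len(members) < MIN_SUBTYPE_SAMPLES:
        raise ValueError(
            f"subtype {config.subtype!r} has {len(members)} samples; "
            f"at least {MIN_SUBTYPE_SAMPLES} samples are required"
        )
    expr_sub = mrna[members]

    # --- miRNA filtering + activity inference
    params = activity.ActivityParams()
    if mirna is not None:
        mirna_sub = mirna[members]
        retained, reasons = activity.filter_mirnas(
            mirna_sub,
            targets,
            mrna.index,
            zero_fraction_max=config.zero_fraction_max,
            min_targets=config.min_targets,
        )
        report["exclusions"]["mirna_filter"] = reasons
        report["stages"]["filter"] = {
            "n_input": int(mirna_sub.shape[0]),
            "n_retained": len(retained),
        }
        if not retained:
            raise ValueError("no miRNA survives filtering")
        activities, profiles = activity.infer_all_activities(
            expr_sub, mirna_sub, targets, params, mirna_ids=retained
        )
    else:
        func_sets = io.read_gmt(config.functional_targets)
        profiles = {}
        rows = []
        for mir, genes in func_sets.items():
            prof = activity.infer_activity_mrna_only(
                expr_sub,
                genes,
                params,
                mirna_id=mir,
                baseline_extreme=config.baseline_extreme,
            )
            profiles[mir] = prof
            rows.append(prof.activity)
        activities = pd.DataFrame(rows, index=list(func_sets), columns=expr_sub.columns)
        report["stages"]["filter"] = {"n_input": len(func_sets), "n_retained": len(func_sets)}
    io.write_matrix(activities, out / "activities.tsv", index_label="mirna_id")
    sidecar_dir = out / "profiles"
    sidecar_dir.mkdir(exist_ok=True)
    for mir, prof in profiles.items():
        side = pd.DataFrame(
            {"weight": prof.weights, "r": prof.correlations, "baseline": prof.baseline}
        )
        io.write_matrix(side, sidecar_dir / f"{mir}.tsv", index_label="gene_id")
    report["stages"]["activity"] = {
        "n_mirnas": int(activities.shape[0]),
        "n_samples": int(activities.shape[1]),
        "converged": {m: bool(p.converged) for m, p in profiles.items()},
        "baseline_samples": {m: p.baseline_samples for m, p in profiles.items()},
    }

    # --- screen
    sc_params = screen.ScreenParams(
        n_perm=config.n_perm,
        key_min_targets=config.key_min_targets,
        functional_target_fdr=config.functional_target_fdr,
        seed=seeds["screen"],
    )
    if mirna is not None:
        normal_mirna = mirna[[s for s in normal_ids if s in mirna.columns]] if normal_ids else None
        table, target_tables = screen.build_screen_table(
            activities, expr_sub, mirna_sub, targets, normal_mirna, sc_params,
            profiles=profiles,
        )
    else:
        # without a miRNA matrix only the functional-target half of the
        # screen is computable
        rows, target_tables = [], {}
        for mir in activities.index:
            ft = screen.functional_targets(
                activities.loc[mir].to_numpy(float),
                expr_sub,
                targets.get(mir, []),
                fdr_threshold=config.functional_target_fdr,
                profile=profiles.get(mir),
            )
            target_tables[mir] = ft
            rows.append(int((ft["sign"] == -1).sum()) if len(ft) else 0)
        table = pd.DataFrame({"n_functional_targets": rows}, index=activities.index)
        table["key"] = screen.flag_key(table["n_functional_targets"], config.key_min_targets)
        table.index.name = "mirna_id"
    table.to_csv(out / "screen.tsv", sep="\t", float_format=io.FLOAT_FMT)
    ft_dir = out / "functional_targets"
    ft_dir.mkdir(exist_ok=True)
    for mir, ft in target_tables.items():
        ft.to_csv(ft_dir / f"{mir}.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    report["stages"]["screen"] = {
        "n_key": int(table["key"].sum()),
        "n_functional_key": int(table["functional_key"].sum())
        if "functional_key" in table
        else None,
    }

    # --- survival screens (activity; expression too when available)
    surv_table = survival.survival_screen(
        activities, surv, n_perm=config.n_perm, seed=seeds["survival"]
    )
    surv_table.to_csv(out / "survival_screen.tsv", sep="\t", float_format=io.FLOAT_FMT)
    if mirna is not None:
        expr_screen = survival.survival_screen(
            mirna_sub.loc[activities.index],
            surv,
            n_perm=config.n_perm,
            seed=seeds["survival"],
        )
        expr_screen.to_csv(
            out / "survival_screen_expression.tsv", sep="\t", float_format=io.FLOAT_FMT
        )
    tested = surv_table[surv_table["skipped_reason"] == ""]
    report["stages"]["survival"] = {
        "n_tested": int(len(tested)),
        "n_fdr_05": int((tested["fdr"] <= 0.05).sum()),
    }

    # --- downstream, focused on the best surviving miRNA
    focus = None
    if len(tested):
        focus = tested["p"].idxmin()
    report["focus_mirna"] = focus
    if focus is not None:
        act_row = activities.loc[focus]
        shared = [s for s in act_row.index if s in surv.index]
        groups = survival.dichotomize_by_median(act_row)
        km = survival.km_curves_by_group(
            surv.loc[shared, "time"],
            surv.loc[shared, "event"],
            survival.dichotomize_by_median(act_row[shared]),
        )
        km.to_csv(out / f"km_{focus}.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
        ft = target_tables.get(focus)
        func_genes = (
            list(ft.loc[ft["sign"] == -1, "gene_id"]) if ft is not None and len(ft) else []
        )
        if config.gene_sets is not None and func_genes:
            collection = io.read_gmt(config.gene_sets)
            enr = downstream.pathway_enrichment(func_genes, collection, expr_sub.index)
            enr.to_csv(out / f"pathways_{focus}.tsv", sep="\t", float_format=io.FLOAT_FMT)
            report["stages"]["pathways"] = {"n_significant": int(enr["significant"].sum())}
        sig = downstream.de_by_activity_group(
            expr_sub,
            groups,
            n_perm=config.de_n_perm,
            seed=seeds["de"],
            mirna_id=focus,
        )
        sig.table.to_csv(out / f"de_{focus}.tsv", sep="\t", float_format=io.FLOAT_FMT)
        if sig.up_genes or sig.down_genes:
            downstream.export_cmap_signature(sig, out / "cmap")
        report["stages"]["de"] = {
            "n_up": len(sig.up_genes),
            "n_down": len(sig.down_genes),
            "p_cutoff": sig.p_cutoff,
        }
        if config.mutations is not None:
            mutations = io.read_mutations(config.mutations)
            assoc = downstream.mutation_activity_association(mutations, act_row)
            assoc.to_csv(out / f"mutations_{focus}.tsv", sep="\t", float_format=io.FLOAT_FMT)
            report["stages"]["mutations"] = {"n_significant": int(assoc["significant"].sum())}
        if config.immune_markers is not None:
            markers = _read_lines(config.immune_markers)
            score, t_stat, p = downstream.immune_score_association(expr_sub, markers, groups)
            score.to_frame().to_csv(
                out / "immune_scores.tsv", sep="\t", index_label="sample_id",
                float_format=io.FLOAT_FMT,
            )
            report["stages"]["immune"] = {"t": t_stat, "p": p}

    report["elapsed_seconds"] = round(time.monotonic() - t0, 3)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
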