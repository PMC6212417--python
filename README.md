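# miract

Infer per-sample **miRNA activities** from target-gene expression, classify
tumors into molecular subtypes, and screen for functionally active, key, and
prognostic miRNAs — with a synthetic-cohort generator so the whole pipeline
is testable offline.

## What it does

The central quantity is a per-sample *activity* for each miRNA, estimated in
three steps:

1. **Baseline** — each target gene's expression averaged over the samples
   where the miRNA reads lowest (the state where it has no impact).
2. **Degradation** — observed expression minus baseline, per sample.
3. **Per-sample fit** — a weighted through-origin regression of degradation
   on baseline; the sign-flipped slope is the activity. Weights are refined
   by iteratively reweighted least squares: genes more anti-correlated with
   the current activity estimate (more plausibly functional targets) count
   more.

A variant infers activity from mRNA expression alone, seeding the baseline
from the summed z-score of known negatively-associated functional targets.

Around the core sit:

- `miract.simulate` — synthetic cohorts: half-normal latent activities,
  proportional target degradation with a configurable functional fraction,
  expression-coupled miRNA readouts, subtype centroid structure,
  activity-dependent survival, matched normals, and linked mutations.
- `miract.subtyping` — two-step correlation classifier
  (Luminal / p53-like / Basal / ClassIV).
- `miract.screen` — the selection cascade: activity–expression correlation
  with permutation FDR, predicted-target enrichment (Fisher), functional
  targets at BH FDR 1 % (with a leave-one-gene-out correlation to avoid the
  activity-is-built-from-these-genes circularity), key-miRNA counting, and
  tumor-vs-normal differential expression (exact WMW for small groups).
- `miract.survival` — median-split Kaplan–Meier / log-rank screening with a
  vectorized 1000-permutation FDR.
- `miract.downstream` — pathway enrichment, gene-set overlap (FET) and
  correlation-distribution (KS) tests, activity-group DE signatures with a
  permutation significance cutoff and CMAP-style `.grp` export,
  mutation–activity association (WMW + FET), immune-infiltration scoring.

## CLI

All stages are subcommands of `miract`:

```bash
# generate a synthetic cohort with fixture files
miract simulate --out fixtures/ --seed 1

# classify samples into subtypes
miract classify --expr fixtures/mrna.tsv --centroids fixtures/centroids.tsv \
    --p53-signature fixtures/p53_signature.tsv --out labels.tsv

# infer activities (standard; add --mrna-only --functional-targets f.gmt
# for the expression-free variant)
miract activity --expr fixtures/mrna.tsv --mirna fixtures/mirna.tsv \
    --targets fixtures/targets.gmt --out activities.tsv

# screening cascade and survival screen
miract screen --activities activities.tsv --expr fixtures/mrna.tsv \
    --mirna fixtures/mirna.tsv --targets fixtures/targets.gmt --out screen.tsv
miract survive --activities activities.tsv --survival fixtures/survival.tsv \
    --n-perm 1000 --seed 1 --out survival.tsv

# everything, from one flat key = value config
miract validate --config run.cfg
miract run-all --config run.cfg
```

A run config lists the input paths and stage parameters, e.g.:

```
mrna = fixtures/mrna.tsv
mirna = fixtures/mirna.tsv
targets = fixtures/targets.gmt
centroids = fixtures/centroids.tsv
p53_signature = fixtures/p53_signature.tsv
survival = fixtures/survival.tsv
normals = fixtures/normals.txt
out_dir = out
subtype = p53-like
n_perm = 1000
seed = 1
```

Exit codes: 0 ok, 1 user/input error, 2 internal error. Outputs are a pure
function of (inputs, config, seed); only `report.json` carries timings.

## File formats

TSV matrices (first column = feature ID, header = sample IDs), GMT gene
sets, survival tables (`sample_id`, `time`, `event`), binary mutation
matrices, flat `key = value` configs — all plain text, written with 12
significant digits so fixtures round-trip.
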