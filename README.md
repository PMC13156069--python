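# ssep — substrate-specific effect prediction for drug transporter variants

Genetic variants in solute-carrier drug transporters (OCT1/*SLC22A1*,
MATE1/2, CNT3, the OATP family) often change uptake of one drug while
leaving another untouched: the common OCT1 deletion p.M420del impairs
metformin and morphine transport yet is near-neutral for sumatriptan, and
p.F244A ranges from 10 %WT to an 8-fold increase depending on the
substrate. Conventional variant effect predictors assign a single,
substrate-agnostic score and cannot represent this. `ssep` implements a
substrate-specific effect predictor: a quantitative model of a transporter
variant's activity toward a *specific* substrate, plus the profiling,
evaluation, feature-exploration and cohort-association machinery around it,
all testable offline on seeded synthetic fixtures with planted ground truth.

## The model

Activity is expressed as percent of wildtype uptake and regressed on the
log scale, `t = log10(uptake ratio)` (0 = wildtype, clipped at ratio 1e-3).
The regressor is a multi-input feed-forward network: each feature block —
sequence **embedding** of the mutant protein, **in-silico** predictor
scores, **mutation** physicochemical deltas (Kyte–Doolittle hydropathy,
residue volume, charge, BLOSUM62 log-odds), **ligand** descriptors
(molecular weight, Kier κ₂ shape index, small-ring count, topological-
symmetry atom count, via RDKit), and protein–ligand **interaction**
geometry (minimum heavy-atom distance, contact count, binding-site flag) —
passes through its own affine encoder; the encoded blocks are concatenated
and a fully connected trunk emits the scalar score. Training is Adam + MSE
on an 85/15 split with early stopping, optionally followed by
deep-mutational-scanning (DMS) fine-tuning at a 10× lower learning rate,
and grid-search hyperparameter selection on mean held-out Spearman ρ.
Two routes share the code: **SNV** for variants with complete annotation,
**UV** for partially annotated variants including indels. Per-structure
predictions for one variant–substrate pair are averaged into a single score.

Downstream, the package provides substrate-variability profiling
(Δ%WT span, span ratio, mixed directionality, per-transporter fractions),
rank-based evaluation (Spearman with exact small-n permutation p,
Jonckheere–Terpstra trend tests, tie-corrected Kruskal–Wallis, Mann–Whitney
ROC-AUC, per-substrate benchmarking), Kruskal–Wallis + BH-FDR feature
ranking with collinearity pruning, and a cohort layer (daily-dose
derivation, MAF < 0.05 filtering, weighted burden scores, covariate-adjusted
dose regression, burden and SKAT-style variance-component tests with a
permutation min-p omnibus).

## Worked example

```python
import numpy as np
from ssep import (simulate_activity, simulate_features, simulate_dms,
                  ModelConfig, build_model, pretrain, fine_tune,
                  stack_bundles, target_transform, summarize_transporter)

table, truth = simulate_activity(seed=7)          # 60 variants x 8 substrates
summary = summarize_transporter(table, "GENE1")
print(f"{summary.pct_high_variability:.1f}% high-variability")

bundles = simulate_features(truth, seed=7)        # planted feature loadings
ymap = {(r.variant, r.substrate): r.uptake_pct_wt for r in table.df.itertuples()}
y = target_transform([ymap[(b.variant, b.substrate)] for b in bundles])
names = ["embedding", "insilico", "mutation", "ligand", "interaction"]
X = stack_bundles(bundles, names)
dims = tuple((n, X[n].shape[1]) for n in names)

perm = np.random.default_rng(7).permutation(len(bundles))
tr, va = perm[:408], perm[408:]
model = build_model(ModelConfig(block_dims=dims, max_epochs=300,
                                learning_rate=3e-3, seed=7))
model = pretrain(model, {k: v[tr] for k, v in X.items()}, y[tr], seed=7)

dms = simulate_dms(truth, truth.substrates[0], seed=7)   # reporter-substrate DMS
```

With the held-out 15% as the evaluation set this prints:

```
95.0% high-variability
held-out Spearman rho before fine-tuning: 0.954, after: 0.952
  drug01: per-substrate held-out rho = 0.98 (n=8)
  drug02: per-substrate held-out rho = 0.95 (n=11)
  ...
```

i.e. the model recovers the planted variant×substrate interaction structure
(per-substrate ρ ≈ 0.9 against observed uptake), and reporter-substrate DMS
fine-tuning preserves that performance. The same pipeline is scriptable from
the shell:

```sh
ssep simulate --seed 7 --out fixtures/
ssep variability --table fixtures/activity.tsv --gene GENE1 --out summary.tsv
# -> GENE1: 60 variants profiled, 95.0% high-variability, 80.0% mixed-direction
ssep cohort --geno fixtures/genotypes.tsv --pheno fixtures/subjects.tsv \
            --n-perm 1000 --seed 1 --out assoc.json
# -> beta=40.58 mg/day (p=0.0359)
```

The cohort fixture plants a burden coefficient of 30 mg/day per unit
weighted burden (4000 subjects, dose noise SD 300 mg/day); the regression
recovers β = 40.6 mg/day with 95% CI [2.7, 78.5] — the planted value sits
inside the interval, and the substrate-specific weighting yields p < 0.05
where the variance-component omnibus is borderline, as expected for a pure
burden-type signal.

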