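# Methods

## Scales and conventions

Transport activity is stored as percent of wildtype uptake (%WT, 100 =
wildtype); sources quoting fold-change ratios are converted (×100) at
ingestion. The regression target is `t = log10(uptake ratio)`, so 0 is
wildtype-equivalent, −1 is a 10-fold loss, +1 a 10-fold gain; ratios are
clipped at 10⁻³ (t = −3) so that complete loss of function remains finite.
The log scale makes gains and losses symmetric and matches how uptake
ratios are usually displayed; display plots use `log10(1 + x)` at
presentation time only, never on stored data.

Replicates for one (gene, variant, substrate) key are aggregated by the
unweighted arithmetic mean. Variant labels are canonical one-letter
protein notation (`p.F244A`, `p.M420del`); three-letter input is accepted
and canonicalized, and labels round-trip through the parser.

## Substrate-variability profiling

For each variant measured on ≥ 2 substrates: span Δ%WT = max − min,
span ratio = max/min (undefined when the minimum is 0; such variants are
excluded from top-span rankings with a warning), sample (n−1) SD, and two
flags — *high variability* (span ≥ 50 %WT by default) and *mixed
directionality* (some substrate strictly above 100 %WT and some strictly
below; values exactly 100 count as neither). Per-transporter summaries
report the percentage of profiled variants carrying each flag and order
variants by median uptake. The n−1 SD is the statistical default; values at
the 100 %WT boundary are deliberately excluded from both directions so the
flag identifies genuine sign flips.

## Feature blocks

* **Ligand** (RDKit): average molecular weight; Kier second kappa shape
  index κ₂ computed from heavy-atom path counts — a topological stand-in
  for three-dimensional shape complexity, chosen because it is
  deterministic and conformer-free; count of SSSR rings of size ≤ 6
  ("small rings"); and the number of heavy atoms whose canonical
  topological rank is shared with ≥ 1 other atom (a graph-automorphism
  notion of molecular symmetry). All are invariant to atom order.
* **Mutation**: deltas (mutant − wildtype) of Kyte–Doolittle hydropathy,
  Zamyatnin residue volume (Å³), net side-chain charge at pH 7 (His
  counted +0.1), and BLOSUM62 log-odds relative to the self-substitution
  (so an identity exchange scores 0). Single-residue deletions use the
  wildtype-removal convention — deltas are the negated wildtype property —
  and set an indel flag; this avoids undefined mutant lookups.
* **Interaction**: minimum heavy-atom Euclidean distance between the
  mutated residue and the ligand, ligand heavy atoms within the contact
  cutoff (4.0 Å), and binding-site membership (minimum distance ≤ 5.0 Å).
  Both cutoffs are configurable; the defaults are conventional contact and
  first-shell distances. Coordinates come from standard PDB files (ligand
  as non-water HETATM records, 1-based residue numbering after a declared
  offset) or directly from arrays.
* **Embedding**: any provider satisfying the contract — deterministic,
  fixed output length — can be plugged in. The bundled provider is a
  seeded hash-projection of 3-mer counts (64 dimensions by default): each
  k-mer maps to a pseudo-random Gaussian vector derived from a stable hash
  of the k-mer and the provider seed, and the sequence embedding is their
  normalized sum. It is an offline, dependency-free provider that
  fulfils the contract and is sensitive to single-residue changes; it does
  not encode evolutionary information the way a pretrained protein
  language model would, and results obtained with it measure the
  pipeline, not protein biology.
* **In-silico**: substrate-agnostic predictor scores consumed from a
  user-supplied table keyed by variant; no external predictor is executed.

A bundle is *full* when all five blocks are present and finite, otherwise
*partial*. Full bundles are routed to the SNV model, partial ones
(including indels) to the UV model; a mixed set of per-structure bundles
for one pair is routed by majority completeness with ties going to SNV.

## The regressor

Per-block affine encoders (default width 32, ReLU) feed a concatenation
into a trunk (default 64→32, ReLU, dropout 0.1) ending in a scalar linear
output. Setting the encoder width to 0, the trunk to () and the activation
to identity degenerates the network to an affine map — the linear
reference mode used to validate the optimizer against closed-form least
squares (agreement to ‖β̂ − β_OLS‖∞ < 10⁻³ on well-conditioned data).

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) on mean-squared error,
mini-batches of 32, up to 500 epochs with early stopping on the 15%
validation split (patience 20, best weights restored). An optional final
stage retrains on the full dataset for the epoch budget the early-stopped
run selected. Fine-tuning on DMS-derived targets keeps all weights
trainable at a 10× lower learning rate for a fixed budget (default 100
epochs); DMS raw scores are first mapped onto the target scale by a
rank-quantile transform against the empirical pretraining-target
distribution, anchored so a wildtype-equivalent raw score lands at 0. The
transform is monotone by construction, which is all that rank-based
evaluation requires.

Grid search trains each candidate configuration across repeated
split/initialization seeds (default 5, seeds 0–4) and selects the highest
mean held-out Spearman ρ; ties break toward the smaller parameter count,
then lexicographic configuration order. All randomness flows through
explicit numpy generators; a fixed seed yields a bit-identical training
log and predictions on a single thread.

## Evaluation statistics

Spearman ρ uses average ranks; its two-sided p-value is an exact full
permutation enumeration for n ≤ 8 and the t-approximation above.
Jonckheere–Terpstra (ordered trend across activity bins, ties counted ½)
and Kruskal–Wallis (tie-corrected H) switch from exact permutation
enumeration (total n ≤ 10) to asymptotics — a continuity-corrected normal
approximation with tie correction for JT, χ²(k−1) for KW. ROC-AUC is the
Mann–Whitney identity with tied pairs counted ½. Activity bins follow
strict inequalities — decreased < 50 %WT, increased > 200 %WT — with an
inclusive variant available as an option; binary threshold schemes at
50/75 (reduced function positive below) and 125/150 %WT (gain of function
positive above) support the classification analyses. The per-pair rank
error is the normalized absolute rank difference |rank(pred) −
rank(obs)|/n. Benchmarks against substrate-agnostic predictor tables
compute per-substrate |ρ| (or AUC) over substrates with ≥ 10 scored
variants, compare methods by Kruskal–Wallis (or mean ± SEM), and join
substrate-agnostic tables on (gene, variant) so one score broadcasts
across substrates.

## Feature association

The importance workflow is a descriptive exploration, not model
attribution: greedy collinearity pruning in column order drops any feature
with |Spearman ρ| > 0.9 against an already-kept feature (the earlier
column wins; the kept set therefore depends on column order, which is the
input schema order); survivors are tested by Kruskal–Wallis across the
three activity bins, Benjamini–Hochberg adjusted, ranked by ascending q
(ties by descending H), and the top 4 flagged.

## Cohort association

Per-prescription daily dose is strength × quantity / duration-days;
a subject's maintenance dose is the median over their valid prescriptions
(median resists titration outliers; the mean is a config option). Variants
are restricted to MAF strictly < 0.05. The burden score is Σ_v dosage_v ×
weight_v with weights either substrate-specific predicted activities or
substrate-agnostic mean activities. Dose is regressed on burden by OLS
with covariates (age at prescription, sex, ethnic group one-hot against a
reference level, BMI); the burden coefficient is reported with its
normal-theory 95% CI and two-sided p. Note that a symmetric 95% CI
containing 0 is incompatible with p < 0.05 in this model; the
implementation reports internally consistent two-sided inference.

Gene-level tests: the burden test is a covariate-adjusted score test on
the unweighted carrier count (phenotype and burden both residualized on
the covariates); the SKAT-style test uses the variance-component statistic
Q = Σ_v w_v² (g_vᵀ r)² on covariate-adjusted residuals, with p-values for
both branches and their min-p omnibus calibrated by residual permutation
(default 1000 draws; fewer than 100 triggers a resolution warning).
The permutation omnibus replaces the analytic SKAT-O ρ-grid/Davies
machinery: it is exchangeability-valid, exact up to Monte-Carlo error, and
adequate at cohort sizes where permutation is cheap. Damaging-variant
classification ships direction-aware literature-default thresholds per
predictor (lower scores are more damaging for the substrate-specific
score, with the default cutoff at half of wildtype activity on the log
scale), all overrideable.

## Synthetic fixtures

The activity generator plants `log10(ratio) = variant effect + substrate
effect + variant×substrate interaction + noise`. Default scales — variant
N(−0.06, 0.21²), substrate N(0, 0.10²), interaction N(0, 0.15²), noise SD
0.05, 60 variants × 8 substrates — were chosen analytically so the total
spread (SD ≈ 0.28 around −0.06) populates the three activity bins at
roughly 20% decreased / 70% neutral / 10% increased, the regime in which
trend tests and threshold classifiers are all exercised. The feature
generator gives each block a planted linear loading on the corresponding
latent (embedding/mutation/in-silico ← variant effect, ligand ← substrate
effect, interaction ← interaction term) mixed with per-entity noise by a
signal fraction (default 0.9); substrate-specific structure is therefore
learnable only through blocks that see both variant and substrate, which
is what the ligand-ablation comparison tests. The DMS generator returns
dense per-variant scores of `variant effect + reporter-substrate
interaction + noise`, emulating a single-reporter near-saturation assay.
The cohort generator draws Hardy–Weinberg genotypes at given MAFs and
doses of `1000 + β·burden + covariate terms + N(0, 300²)` mg/day, matching
the scale of metformin maintenance dosing; the default planted β is
30 mg/day per unit weighted burden.

For the substrate-specific vs averaged weighting contrast, cohort variants
are generated in an interaction-dominated regime (within-variant substrate
SD 0.5 log units, shared main-effect SD 0.05, 11 variants, 9513 subjects):
this emulates an analysis that deliberately targets strongly
substrate-specific transporter variants, where averaging across substrates
washes out most of the dose-relevant signal — the setting in which
substrate-specific weighting is expected to matter at all. With
main-effect-dominated variants the two weightings are nearly collinear and
the contrast is uninformative by construction.

What the fixtures do *not* emulate: real protein structures or chemistry
(feature blocks are statistical, not physical), assay-specific error
structure, linkage disequilibrium between cohort variants, or confounding
between genotype and covariates. Passing tests therefore demonstrate that
the pipeline recovers planted statistical structure of the assumed form,
not that any particular biological prediction is accurate.

## Problem sizes and numerical choices

The end-to-end recovery analyses use the default fixture (480
variant–substrate pairs, 16-dimensional embeddings, 300-epoch budget) over
five seeds; association calibration uses 500 permuted-phenotype nulls at
500 subjects, CI coverage 100 cohorts at 5000 subjects, and the weighting
contrast 5 cohorts at 9513 subjects — sizes at which every check runs in
seconds to a few minutes on one CPU while leaving Monte-Carlo error well
inside the asserted bands. Degenerate inputs are handled explicitly:
constant vectors are an error for correlation, all-identical groups give
H = 0 / p = 1, zero carriers give p = 1 with a warning, all-zero SKAT
weights give p = 1, and empty DMS sets are a warning no-op.

## Known limitations

The bundled embedding provider carries no evolutionary signal; real
embeddings must come from an external provider satisfying the contract.
The κ₂ shape index and the symmetry count are topological stand-ins for
unspecified 3D descriptors. The SKAT-style omnibus is permutation-based
and hence has Monte-Carlo p-value granularity of 1/(n_perm + 1). SNV and
UV models are trained independently; no weight sharing is attempted.
Exact permutation branches are enumerative and restricted to the tiny-n
regimes where enumeration is feasible.
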