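"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here so that all stages
are testable offline. The activity generator plants an additive structure on
the log10 uptake-ratio scale,

    log10(activity ratio) = variant effect + substrate effect
                            + variant x substrate interaction + noise,

exported as %WT. The default scales are chosen so that the three-bin
activity scheme populates roughly 20% decreased / 70% neutral / 10%
increased: total SD ~0.28 around mean -0.06 on the log10 scale, partitioned
into variant SD 0.21, substrate SD 0.10, interaction SD 0.15 and noise SD
0.05. The feature generator plants linear loadings on those latent effects:
ligand blocks see only the substrate, embedding/mutation/in-silico blocks
only the variant, and interaction blocks see the variant x substrate
interaction — so substrate-specific structure is learnable only through
blocks that see both. The cohort generator plants a burden coefficient in
mg/day under Hardy-Weinberg genotypes.

All randomness flows from one explicit seed through spawned substreams; no
global state is touched, and regeneration with the same seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import ActivityRecord, ActivityTable, aggregate_measurements
from .features import FeatureBundle

__all__ = [
    "SimulationTruth",
    "simulate_activity",
    "simulate_features",
    "simulate_dms",
    "simulate_cohort",
    "DEFAULTS",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

# simple, valid SMILES reused cyclically for synthetic substrates
_SMILES_POOL = [
    "CC(C)O", "c1ccccc1", "CCN(CC)CC", "C1CCNCC1", "CC(=O)O", "c1ccncc1",
    "OCCO", "CC(N)C(=O)O", "C1CCCCC1", "CCOC(=O)C", "Cn1cncc1", "NCCc1ccccc1",
]

DEFAULTS = {
    "n_variants": 60,
    "n_substrates": 8,
    "variant_effect_mean": -0.06,
    "variant_effect_sd": 0.21,
    "substrate_effect_sd": 0.10,
    "interaction_sd": 0.15,
    "noise_sd": 0.05,
    "embedding_dim": 16,
    "signal_fraction": 0.9,
}


@dataclass
class SimulationTruth:
    """Planted parameters of a synthetic activity dataset."""

    genes: list[str]
    variant_labels: list[list[str]]       # per gene
    substrates: list[str]
    variant_effects: np.ndarray           # (n_genes, n_variants), log10 units
    substrate_effects: np.ndarray         # (n_substrates,)
    interaction: np.ndarray               # (n_genes, n_variants, n_substrates)
    noise_sd: float
    seed: int
    feature_loadings: dict = field(default_factory=dict)
    cohort_beta: float | None = None

    def pair_latents(self):
        """Flattened (gene, variant, substrate, v_eff, s_eff, interaction) rows."""
        rows = []
        for gi, gene in enumerate(self.genes):
            for vi, label in enumerate(self.variant_labels[gi]):
                for si, sub in enumerate(self.substrates):
                    rows.append((gene, label, sub,
                                 float(self.variant_effects[gi, vi]),
                                 float(self.substrate_effects[si]),
                                 float(self.interaction[gi, vi, si])))
        return rows


def _variant_labels(n: int, rng: np.random.Generator) -> list[str]:
    labels = []
    positions = rng.choice(np.arange(2, 2 + 10 * n), size=n, replace=False)
    positions.sort()
    for pos in positions:
        ref, alt = rng.choice(list(AA), size=2, replace=False)
        labels.append(f"p.{ref}{int(pos)}{alt}")
    return labels


def simulate_activity(
    n_genes: int = 1,
    n_variants: int = DEFAULTS["n_variants"],
    n_substrates: int = DEFAULTS["n_substrates"],
    interaction_sd: float = DEFAULTS["interaction_sd"],
    noise_sd: float = DEFAULTS["noise_sd"],
    seed: int = 0,
    variant_effect_mean: float = DEFAULTS["variant_effect_mean"],
    variant_effect_sd: float = DEFAULTS["variant_effect_sd"],
    substrate_effect_sd: float = DEFAULTS["substrate_effect_sd"],
) -> tuple[ActivityTable, SimulationTruth]:
    """Generate a synthetic aggregated activity table with planted truth."""
    if min(n_genes, n_variants, n_substrates) < 1:
        raise ValueError("counts must be >= 1")
    if min(interaction_sd, noise_sd) < 0:
        raise ValueError("SDs must be >= 0")
    ss = np.random.SeedSequence([seed, 101])
    rng_struct, rng_eff, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]
    genes = [f"GENE{g + 1}" for g in range(n_genes)]
    variant_labels = [_variant_labels(n_variants, rng_struct) for _ in genes]
    substrates = [f"drug{s + 1:02d}" for s in range(n_substrates)]
    V = rng_eff.normal(variant_effect_mean, variant_effect_sd, (n_genes, n_variants))
    S = rng_eff.normal(0.0, substrate_effect_sd, n_substrates)
    I = rng_eff.normal(0.0, interaction_sd, (n_genes, n_variants, n_substrates))
    truth = SimulationTruth(
        genes=genes, variant_labels=variant_labels, substrates=substrates,
        variant_effects=V, substrate_effects=S, interaction=I,
        noise_sd=noise_sd, seed=seed,
    )
    records = []
    for gi, gene in enumerate(genes):
        for vi, label in enumerate(variant_labels[gi]):
            for si, sub in enumerate(substrates):
                x = V[gi, vi] + S[si] + I[gi, vi, si] + rng_noise.normal(0.0, noise_sd)
                records.append(ActivityRecord(
                    gene=gene, variant=label, substrate=sub,
                    uptake_pct_wt=float(100.0 * 10.0 ** x),
                    smiles=_SMILES_POOL[si % len(_SMILES_POOL)],
                    source="synthetic",
                ))
    return aggregate_measurements(records), truth


_BLOCK_DIMS = {"insilico": 3, "mutation": 5, "ligand": 4, "interaction": 3}


def simulate_features(
    truth: SimulationTruth,
    embedding_dim: int = DEFAULTS["embedding_dim"],
    signal_fraction: float = DEFAULTS["signal_fraction"],
    seed: int = 0,
    n_structures: int = 1,
    partial_fraction: float = 0.0,
) -> list[FeatureBundle]:
    """Feature bundles whose blocks carry planted linear loadings.

    Each block equals ``signal_fraction * loading * latent`` plus
    ``(1 - signal_fraction)`` standard-normal entity noise: embedding,
    mutation and in-silico blocks load on the variant effect (noise drawn
    once per variant, shared across substrates), the ligand block on the
    substrate effect (noise per substrate), and the interaction block on the
    variant x substrate interaction (noise per pair and structure).
    ``partial_fraction`` drops the in-silico block for that share of
    variants, producing partial (UV-route) bundles. With ``n_structures > 1``
    each pair yields one bundle per structure template, differing only in
    the interaction block's entity noise.
    """
    if not (0.0 <= signal_fraction <= 1.0):
        raise ValueError("signal_fraction must be in [0, 1]")
    sf = signal_fraction
    ss = np.random.SeedSequence([seed, truth.seed, 202])
    rng_load, rng_ent, rng_route = [np.random.default_rng(s) for s in ss.spawn(3)]
    dims = dict(_BLOCK_DIMS, embedding=embedding_dim)
    loadings = {name: rng_load.standard_normal(d) for name, d in dims.items()}
    truth.feature_loadings = {k: v.copy() for k, v in loadings.items()}

    n_genes = len(truth.genes)
    n_var = truth.variant_effects.shape[1]
    n_sub = len(truth.substrates)
    emb_noise = rng_ent.standard_normal((n_genes, n_var, embedding_dim))
    mut_noise = rng_ent.standard_normal((n_genes, n_var, dims["mutation"]))
    ins_noise = rng_ent.standard_normal((n_genes, n_var, dims["insilico"]))
    lig_noise = rng_ent.standard_normal((n_sub, dims["ligand"]))
    int_noise = rng_ent.standard_normal(
        (n_genes, n_var, n_sub, n_structures, dims["interaction"]))
    is_partial = rng_route.random((n_genes, n_var)) < partial_fraction

    bundles = []
    for gi, gene in enumerate(truth.genes):
        for vi, label in enumerate(truth.variant_labels[gi]):
            v_eff = truth.variant_effects[gi, vi]
            emb = sf * v_eff * loadings["embedding"] + (1 - sf) * emb_noise[gi, vi]
            mut = sf * v_eff * loadings["mutation"] + (1 - sf) * mut_noise[gi, vi]
            ins = sf * v_eff * loadings["insilico"] + (1 - sf) * ins_noise[gi, vi]
            for si, sub in enumerate(truth.substrates):
                s_eff = truth.substrate_effects[si]
                lig = sf * s_eff * loadings["ligand"] + (1 - sf) * lig_noise[si]
                x_eff = truth.interaction[gi, vi, si]
                for st in range(n_structures):
                    inter = (sf * x_eff * loadings["interaction"]
                             + (1 - sf) * int_noise[gi, vi, si, st])
                    blocks = {
                        "embedding": emb.copy(),
                        "insilico": None if is_partial[gi, vi] else ins.copy(),
                        "mutation": mut.copy(),
                        "ligand": lig.copy(),
                        "interaction": inter,
                    }
                    bundles.append(FeatureBundle(
                        variant=label, substrate=sub, gene=gene,
                        structure_id=f"struct{st + 1}" if n_structures > 1 else "struct1",
                        blocks=blocks))
    return bundles


def simulate_dms(
    truth: SimulationTruth,
    reporter_substrate: str,
    coverage: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    gene: str | None = None,
) -> pd.DataFrame:
    """Dense per-variant DMS scores for one reporter substrate.

    score = variant effect + that substrate's interaction + noise, i.e. what
    a single-reporter near-saturation assay would see of the planted truth.
    ``coverage`` subsamples variants. Returns a table with columns gene,
    variant, score.
    """
    if reporter_substrate not in truth.substrates:
        raise ValueError(f"reporter substrate {reporter_substrate!r} not in truth")
    gene = gene or truth.genes[0]
    gi = truth.genes.index(gene)
    si = truth.substrates.index(reporter_substrate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, truth.seed, 303]))
    labels = truth.variant_labels[gi]
    n = len(labels)
    n_keep = int(round(coverage * n))
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    rows = []
    for vi in keep:
        score = (truth.variant_effects[gi, vi] + truth.interaction[gi, vi, si]
                 + rng.normal(0.0, noise_sd))
        rows.append({"gene": gene, "variant": labels[vi], "score": float(score)})
    return pd.DataFrame(rows)


def simulate_cohort(
    n_subjects: int,
    mafs: Sequence[float],
    weights: Sequence[float],
    beta: float = 30.0,
    covariate_effects: Mapping[str, float] | None = None,
    noise_sd: float = 300.0,
    seed: int = 0,
    intercept: float = 1000.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hardy-Weinberg genotypes plus a dose phenotype with a planted burden beta.

    Genotype dosages are Binomial(2, MAF) per variant. The daily dose is
    ``intercept + beta * sum_v dosage_v * weight_v + covariate terms +
    N(0, noise_sd)`` (mg/day). Covariates are age at prescription, sex,
    ethnic group and BMI with modest default effects. Returns the
    (n_subjects, n_variants) dosage matrix and the subject table.
    """
    mafs = np.asarray(mafs, dtype=float)
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if np.any(mafs <= 0) or np.any(mafs >= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5)")
    w = np.asarray(weights, dtype=float)
    if w.size != mafs.size:
        raise ValueError("weights and mafs must have equal length")
    eff = {"age_at_prescription": 2.0, "sex": 60.0, "bmi": 8.0, "ethnic_group": 25.0}
    if covariate_effects:
        eff.update(covariate_effects)
    ss = np.random.SeedSequence([seed, 404])
    rng_g, rng_c, rng_n = [np.random.default_rng(s) for s in ss.spawn(3)]
    G = rng_g.binomial(2, mafs, size=(n_subjects, mafs.size)).astype(float)
    age = rng_c.normal(60.0, 10.0, n_subjects)
    sex = rng_c.choice(["F", "M"], n_subjects)
    ethnic = rng_c.choice(["groupA", "groupB", "groupC"], n_subjects, p=[0.8, 0.15, 0.05])
    bmi = rng_c.normal(28.0, 5.0, n_subjects)
    burden = G @ w
    dose = (intercept
            + beta * burden
            + eff["age_at_prescription"] * (age - 60.0)
            + eff["sex"] * (sex == "M")
            + eff["ethnic_group"] * (ethnic == "groupB")
            + eff["bmi"] * (bmi - 28.0)
            + rng_n.normal(0.0, noise_sd, n_subjects))
    subjects = pd.DataFrame({
        "subject_id": [f"S{i + 1:06d}" for i in range(n_subjects)],
        "daily_dose": dose,
        "age_at_prescription": age,
        "sex": sex,
        "ethnic_group": ethnic,
        "bmi": bmi,
    })
    return G, subjects
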