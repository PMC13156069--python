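"""Blocked feature assembly for variant-substrate(-structure) triples.

A :class:`FeatureBundle` carries five named numeric blocks:

* ``embedding``   — fixed-length sequence embedding of the mutant protein,
  produced by any provider satisfying the deterministic fixed-length contract
  (a seeded k-mer hash-projection provider is bundled for offline use);
* ``insilico``    — scores from substrate-agnostic variant effect predictors,
  consumed from a user-supplied table;
* ``mutation``    — residue-level physicochemical deltas (hydropathy, volume,
  charge, substitution log-odds) of the amino-acid exchange;
* ``ligand``      — physicochemical descriptors of the substrate molecule
  (molecular weight, shape index, small-ring count, symmetric atom count);
* ``interaction`` — distance-based metrics between the mutated residue and the
  docked ligand in a structure template.

Bundles with every block present and finite are ``full`` (routed to the
SNV model); anything less is ``partial`` (routed to the UV model).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np

from .core_data import VariantKind, VariantSpec, parse_variant

logger = logging.getLogger(__name__)

__all__ = [
    "LigandDescriptors",
    "MutationDescriptors",
    "InteractionFeatures",
    "FeatureBundle",
    "FeatureResources",
    "DescriptorError",
    "StructureCoverageError",
    "ligand_descriptors",
    "mutation_descriptors",
    "interaction_features",
    "interaction_features_from_pdb",
    "HashKmerEmbedder",
    "embed_sequence",
    "apply_variant_to_sequence",
    "assemble",
    "KYTE_DOOLITTLE",
    "RESIDUE_VOLUME",
    "RESIDUE_CHARGE",
]


class DescriptorError(ValueError):
    """Raised when a molecular input cannot be parsed into descriptors."""


class StructureCoverageError(ValueError):
    """Raised when a structure lacks the mutated residue or the ligand."""


# Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Residue volumes (A^3), Zamyatnin
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# Net side-chain charge at pH 7 (His partially protonated)
RESIDUE_CHARGE = {aa: 0.0 for aa in KYTE_DOOLITTLE}
RESIDUE_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})

DEFAULT_BINDING_SITE_CUTOFF = 5.0  # A
DEFAULT_CONTACT_CUTOFF = 4.0  # A
SMALL_RING_MAX_SIZE = 6


@dataclass(frozen=True)
class LigandDescriptors:
    molecular_weight: float
    shape_index: float
    small_ring_count: int
    symmetric_atom_count: int
    extra: tuple[tuple[str, float], ...] = ()

    def to_vector(self) -> np.ndarray:
        base = [self.molecular_weight, self.shape_index,
                float(self.small_ring_count), float(self.symmetric_atom_count)]
        return np.array(base + [v for _, v in self.extra], dtype=float)

    @staticmethod
    def names() -> list[str]:
        return ["ligand_mw", "ligand_shape_index", "ligand_small_ring_count",
                "ligand_symmetric_atom_count"]


def ligand_descriptors(smiles: str) -> LigandDescriptors:
    """Physicochemical descriptors of a ligand given in SMILES line notation.

    * molecular weight: average-isotope molecular weight (g/mol);
    * shape index: Kier second kappa shape index from heavy-atom path counts
      (a documented stand-in for an unspecified 3D shape descriptor);
    * small_ring_count: SSSR rings of size <= 6;
    * symmetric_atom_count: heavy atoms whose canonical topological rank
      (automorphism class) is shared with at least one other atom.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, GraphDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(f"unparseable ligand SMILES: {smiles!r}")
    ri = mol.GetRingInfo()
    small_rings = sum(1 for ring in ri.AtomRings() if len(ring) <= SMALL_RING_MAX_SIZE)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    counts: dict[int, int] = {}
    for r in ranks:
        counts[r] = counts.get(r, 0) + 1
    symmetric = sum(1 for r in ranks if counts[r] > 1)
    try:
        kappa2 = float(GraphDescriptors.Kappa2(mol))
    except Exception:  # single-atom graphs
        kappa2 = 0.0
    return LigandDescriptors(
        molecular_weight=float(Descriptors.MolWt(mol)),
        shape_index=kappa2,
        small_ring_count=int(small_rings),
        symmetric_atom_count=int(symmetric),
    )


@dataclass(frozen=True)
class MutationDescriptors:
    delta_hydropathy: float
    delta_volume: float
    delta_charge: float
    substitution_score: float
    is_indel: bool

    def to_vector(self) -> np.ndarray:
        return np.array([self.delta_hydropathy, self.delta_volume,
                         self.delta_charge, self.substitution_score,
                         float(self.is_indel)], dtype=float)

    @staticmethod
    def names() -> list[str]:
        return ["delta_hydropathy", "delta_volume", "delta_charge",
                "substitution_score", "is_indel"]


_BLOSUM62 = None


def _blosum62(a: str, b: str) -> float:
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return float(_BLOSUM62[a, b])


def mutation_descriptors(wt_aa: str, alt_aa: str | None) -> MutationDescriptors:
    """Residue-level deltas (mutant - wildtype) of an amino-acid exchange.

    ``alt_aa=None`` denotes a single-residue deletion: deltas follow the
    wildtype-removal convention (negative of the wildtype property) and
    ``is_indel`` is set. The substitution score is BLOSUM62 log-odds relative
    to the self-substitution, so an identity exchange scores 0.
    """
    if wt_aa not in KYTE_DOOLITTLE:
        raise ValueError(f"unknown amino-acid code {wt_aa!r}")
    if alt_aa is None:
        return MutationDescriptors(
            delta_hydropathy=-KYTE_DOOLITTLE[wt_aa],
            delta_volume=-RESIDUE_VOLUME[wt_aa],
            delta_charge=-RESIDUE_CHARGE[wt_aa],
            substitution_score=-_blosum62(wt_aa, wt_aa),
            is_indel=True,
        )
    if alt_aa not in KYTE_DOOLITTLE:
        raise ValueError(f"unknown amino-acid code {alt_aa!r}")
    return MutationDescriptors(
        delta_hydropathy=KYTE_DOOLITTLE[alt_aa] - KYTE_DOOLITTLE[wt_aa],
        delta_volume=RESIDUE_VOLUME[alt_aa] - RESIDUE_VOLUME[wt_aa],
        delta_charge=RESIDUE_CHARGE[alt_aa] - RESIDUE_CHARGE[wt_aa],
        substitution_score=_blosum62(wt_aa, alt_aa) - _blosum62(wt_aa, wt_aa),
        is_indel=False,
    )


@dataclass(frozen=True)
class InteractionFeatures:
    min_heavy_atom_distance: float
    contact_count: int
    in_binding_site: bool
    structure_id: str = ""

    def to_vector(self) -> np.ndarray:
        return np.array([self.min_heavy_atom_distance, float(self.contact_count),
                         float(self.in_binding_site)], dtype=float)

    @staticmethod
    def names() -> list[str]:
        return ["min_heavy_atom_distance", "contact_count", "in_binding_site"]


def interaction_features(
    residue_coords,
    ligand_coords,
    structure_id: str = "",
    binding_site_cutoff: float = DEFAULT_BINDING_SITE_CUTOFF,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> InteractionFeatures:
    """Distance metrics between a mutated residue and the ligand.

    ``min_heavy_atom_distance`` is the minimum pairwise Euclidean distance;
    ``contact_count`` is the number of ligand heavy atoms within
    ``contact_cutoff`` of any residue heavy atom; the residue is in the
    binding site iff the minimum distance is <= ``binding_site_cutoff``.
    """
    res = np.atleast_2d(np.asarray(residue_coords, dtype=float))
    lig = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if res.size == 0 or lig.size == 0:
        raise StructureCoverageError("residue and ligand must each have >= 1 heavy atom")
    d = np.sqrt(((res[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2))
    min_d = float(d.min())
    contacts = int((d.min(axis=0) <= contact_cutoff).sum())
    return InteractionFeatures(
        min_heavy_atom_distance=min_d,
        contact_count=contacts,
        in_binding_site=min_d <= binding_site_cutoff,
        structure_id=structure_id,
    )


def interaction_features_from_pdb(
    path: str | Path,
    residue_position: int,
    residue_offset: int = 0,
    chain_id: str | None = None,
    structure_id: str | None = None,
    **cutoffs,
) -> InteractionFeatures:
    """Interaction features from a PDB coordinate file with a HETATM ligand.

    The mutated residue is located at ``residue_position + residue_offset`` in
    the structure's numbering; water is not treated as ligand.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    target = residue_position + residue_offset
    res_coords, lig_coords = [], []
    for model in structure:
        for chain in model:
            if chain_id is not None and chain.id != chain_id:
                continue
            for residue in chain:
                hetflag, seqid, _ = residue.id
                coords = [a.coord for a in residue if a.element != "H"]
                if hetflag.strip() and residue.resname not in ("HOH", "WAT"):
                    lig_coords.extend(coords)
                elif not hetflag.strip() and seqid == target:
                    res_coords.extend(coords)
        break  # first model only
    if not res_coords:
        raise StructureCoverageError(
            f"{path}: residue {target} not present in structure coordinates")
    if not lig_coords:
        raise StructureCoverageError(f"{path}: no ligand HETATM records found")
    return interaction_features(
        np.array(res_coords), np.array(lig_coords),
        structure_id=structure_id or path.stem, **cutoffs)


class EmbeddingProvider(Protocol):
    """Contract: deterministic fixed-length embedding of a protein sequence."""

    dim: int

    def __call__(self, sequence: str) -> np.ndarray: ...


def _stable_hash64(token: str) -> int:
    return int.from_bytes(hashlib.blake2b(token.encode(), digest_size=8).digest(), "big")


@dataclass
class HashKmerEmbedder:
    """Seeded hash-projection of k-mer counts: an offline embedding provider.

    Each k-mer is mapped to a pseudo-random ``dim``-vector derived from a
    stable hash of the k-mer and the provider seed; the sequence embedding is
    the count-weighted sum, scaled by 1/sqrt(n_kmers). Deterministic across
    processes, fixed output length, sensitive to single-residue changes.
    """

    dim: int = 64
    k: int = 3
    seed: int = 0

    def __call__(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        k = min(self.k, len(sequence))
        kmers = [sequence[i:i + k] for i in range(len(sequence) - k + 1)]
        out = np.zeros(self.dim)
        for kmer in kmers:
            rng = np.random.default_rng([self.seed, _stable_hash64(kmer)])
            out += rng.standard_normal(self.dim)
        return out / np.sqrt(len(kmers))


def embed_sequence(provider: EmbeddingProvider, mutant_sequence: str) -> np.ndarray:
    """Embed a mutant sequence through a provider; validates the contract."""
    vec = np.asarray(provider(mutant_sequence), dtype=float)
    if vec.ndim != 1 or vec.shape[0] != provider.dim:
        raise ValueError(
            f"provider returned shape {vec.shape}, expected ({provider.dim},)")
    if not np.all(np.isfinite(vec)):
        raise ValueError("provider returned non-finite values")
    return vec


def apply_variant_to_sequence(sequence: str, variant: VariantSpec) -> str:
    """Apply a missense or deletion variant to a 1-based wildtype sequence."""
    i = variant.position - 1
    if i >= len(sequence):
        raise ValueError(
            f"variant position {variant.position} beyond sequence length {len(sequence)}")
    if variant.ref_aa and sequence[i] != variant.ref_aa:
        raise ValueError(
            f"reference mismatch at {variant.position}: sequence has "
            f"{sequence[i]}, variant expects {variant.ref_aa}")
    if variant.kind is VariantKind.MISSENSE:
        return sequence[:i] + variant.alt_aa + sequence[i + 1:]
    if variant.kind is VariantKind.SINGLE_RESIDUE_DELETION:
        return sequence[:i] + sequence[i + 1:]
    end = variant.end_position or variant.position
    return sequence[:i] + sequence[end:]


BLOCK_NAMES = ["embedding", "insilico", "mutation", "ligand", "interaction"]


@dataclass
class FeatureBundle:
    """Blocked feature vector for one variant-substrate(-structure) triple."""

    variant: str
    substrate: str
    blocks: dict[str, np.ndarray]
    structure_id: str | None = None
    gene: str = ""

    @property
    def completeness(self) -> str:
        for name in BLOCK_NAMES:
            v = self.blocks.get(name)
            if v is None or not np.all(np.isfinite(np.asarray(v, dtype=float))):
                return "partial"
        return "full"

    def block_dims(self) -> dict[str, int]:
        return {k: int(np.asarray(v).size) for k, v in self.blocks.items() if v is not None}


@dataclass
class FeatureResources:
    """Everything :func:`assemble` may consult for one gene.

    ``structures`` maps structure_id to either a PDB file path or a pair of
    coordinate arrays ``(residue_lookup, ligand_coords)`` where
    ``residue_lookup`` maps residue position to an (n, 3) coordinate array.
    """

    embedder: EmbeddingProvider | None = None
    wt_sequence: str | None = None
    insilico_scores: Mapping[str, Mapping[str, float]] | None = None  # variant -> {predictor: score}
    insilico_predictors: Sequence[str] | None = None
    structures: Mapping[str, object] | None = None
    residue_offset: int = 0


def _insilico_block(resources: FeatureResources, variant_label: str) -> np.ndarray | None:
    if resources.insilico_scores is None:
        return None
    row = resources.insilico_scores.get(variant_label)
    if row is None:
        return None
    preds = list(resources.insilico_predictors or sorted(row))
    try:
        return np.array([float(row[p]) for p in preds])
    except KeyError:
        return None


def assemble(
    variant: str | VariantSpec,
    substrate: str,
    smiles: str,
    resources: FeatureResources,
) -> list[FeatureBundle]:
    """Assemble feature bundles for one variant-substrate pair.

    Returns one bundle per available structure template (one structure-free
    bundle when no structures are supplied). A bundle is ``full`` only when
    the embedding, in-silico, mutation, ligand, and interaction blocks are all
    present and finite; otherwise it is ``partial`` and will be routed to the
    UV model. A missing ligand SMILES is a hard error: without the substrate's
    chemistry no substrate-specific prediction is possible.
    """
    if not smiles:
        raise DescriptorError(f"no ligand SMILES for substrate {substrate!r}")
    spec = parse_variant(variant) if isinstance(variant, str) else variant

    ligand = ligand_descriptors(smiles).to_vector()
    mut = mutation_descriptors(
        spec.ref_aa,
        spec.alt_aa if spec.kind is VariantKind.MISSENSE else None,
    ).to_vector()

    embedding = None
    if resources.embedder is not None and resources.wt_sequence:
        try:
            mutant_seq = apply_variant_to_sequence(resources.wt_sequence, spec)
            embedding = embed_sequence(resources.embedder, mutant_seq)
        except Exception as exc:
            logger.warning("embedding failed for %s: %s", spec.label, exc)

    insilico = _insilico_block(resources, spec.label)

    base = {
        "embedding": embedding,
        "insilico": insilico,
        "mutation": mut,
        "ligand": ligand,
    }
    bundles: list[FeatureBundle] = []
    if resources.structures:
        for sid in sorted(resources.structures):
            entry = resources.structures[sid]
            interaction = None
            try:
                if isinstance(entry, (str, Path)):
                    feats = interaction_features_from_pdb(
                        entry, spec.position, residue_offset=resources.residue_offset,
                        structure_id=sid)
                else:
                    residue_lookup, lig_coords = entry
                    res_coords = residue_lookup[spec.position]
                    feats = interaction_features(res_coords, lig_coords, structure_id=sid)
                interaction = feats.to_vector()
            except (StructureCoverageError, KeyError) as exc:
                logger.warning("structure %s lacks coverage for %s: %s", sid, spec.label, exc)
            bundles.append(FeatureBundle(
                variant=spec.label, substrate=substrate, gene=spec.gene or "",
                structure_id=sid, blocks={**base, "interaction": interaction}))
    else:
        bundles.append(FeatureBundle(
            variant=spec.label, substrate=substrate, gene=spec.gene or "",
            structure_id=None, blocks={**base, "interaction": None}))
    return bundles
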