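"""Protofilament protocol: restraints, pcaRMSD symmetry score, contact energy,
two-stage model selection and reference-RMSD evaluation.

The protocol scores candidate protofilament models — stacks of M identical
peptide chains expected to adopt an in-register parallel architecture — on
two axes: an inter-chain interaction energy (lower = better packed) and the
peptide-chain-average RMSD (pcaRMSD), which measures the translational
symmetry of the stack:

    pcaRMSD = 1/(M² − M) · Σ_i Σ_j RMSD_fit(chain_i, chain_j)

where each chain pair is independently superposed before its Cα RMSD is
taken and the i == j diagonal contributes zero. Model selection filters a
pool of the best models on one score and ranks the pool on the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DomainCheckError, FormatError, ShapeError
from .structio import (
    STANDARD_AA,
    Ensemble,
    OligomerModel,
    PeptideChain,
    kabsch_superpose,
)

# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

DEFAULT_RESTRAINT_DISTANCE = 5.0  # Å between side-chain atoms of stacked residues

AtomRole = Literal["sidechain_center", "calpha"]


@dataclass(frozen=True)
class Restraint:
    """One inter-chain distance restraint between corresponding residues."""

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    atom_role: AtomRole = "sidechain_center"
    target_distance: float = DEFAULT_RESTRAINT_DISTANCE
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise FormatError("target_distance must be positive")
        if self.chain_a == self.chain_b:
            raise FormatError("restraints must join two different chains")


def _chain_ids(n: int) -> list[str]:
    import string

    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n > len(alphabet):
        raise FormatError(f"cannot label {n} chains with single characters")
    return list(alphabet[:n])


def generate_inregister_restraints(
    sequence: str,
    n_chains: int,
    target_distance: float = DEFAULT_RESTRAINT_DISTANCE,
    weight: float = 1.0,
    chain_ids: Sequence[str] | None = None,
) -> list[Restraint]:
    """In-register restraints between adjacent chains of an M-chain stack.

    One restraint per residue per adjacent chain pair — (M−1)·L records —
    between the side-chain centres of the *same* residue position (Cα for
    glycine, which has no side chain). These restraints fix the chain order
    and favour parallel in-register stacking without dictating the fold.
    """
    bad = sorted(set(sequence) - STANDARD_AA)
    if bad:
        raise FormatError(f"invalid residue letters {bad}")
    if n_chains < 1 or not sequence:
        raise FormatError("need n_chains >= 1 and a non-empty sequence")
    ids = list(chain_ids) if chain_ids is not None else _chain_ids(n_chains)
    restraints = []
    for pair in range(n_chains - 1):
        for pos, aa in enumerate(sequence, start=1):
            restraints.append(Restraint(
                chain_a=ids[pair], residue_a=pos,
                chain_b=ids[pair + 1], residue_b=pos,
                atom_role="calpha" if aa == "G" else "sidechain_center",
                target_distance=target_distance, weight=weight,
            ))
    return restraints


def write_restraints(restraints: Sequence[Restraint], path) -> None:
    """Plain-text restraint file: 'chain_a resid_a chain_b resid_b distance weight'."""
    with open(path, "w") as fh:
        fh.write("# chain_a resid_a chain_b resid_b distance weight\n")
        for r in restraints:
            fh.write(f"{r.chain_a} {r.residue_a} {r.chain_b} {r.residue_b} "
                     f"{r.target_distance:g} {r.weight:g}\n")


def read_restraints(path, sequence: str | None = None) -> list[Restraint]:
    """Read a restraint file; if ``sequence`` is given, re-derive the glycine rule."""
    restraints = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"bad restraint line: {line!r}")
            ca, ra, cb, rb, d, w = parts
            role: AtomRole = "sidechain_center"
            if sequence is not None and sequence[int(ra) - 1] == "G":
                role = "calpha"
            restraints.append(Restraint(ca, int(ra), cb, int(rb), role,
                                        float(d), float(w)))
    return restraints


# ---------------------------------------------------------------------------
# pcaRMSD
# ---------------------------------------------------------------------------

def pca_rmsd(model: OligomerModel) -> float:
    """Peptide-chain-average RMSD of an M-chain model (Å).

    Full double sum over ordered chain pairs of the independently fitted
    pairwise Cα RMSD, divided by M² − M; diagonal terms are zero, so this
    equals the mean over the M² − M ordered pairs i ≠ j, and — because the
    fitted RMSD is symmetric — twice the sum over unordered pairs. Zero iff
    all chains are mutually congruent; low values indicate high
    translational symmetry of the stack.
    """
    m = model.n_chains
    if m < 2:
        raise DomainCheckError("pcaRMSD needs at least two chains")
    model.require_uniform()
    total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            r = kabsch_superpose(model.chains[i].calpha, model.chains[j].calpha).rmsd
            total += 2.0 * r  # ordered pairs (i, j) and (j, i)
    return total / (m * m - m)


# ---------------------------------------------------------------------------
# side-chain reference points and contact energy
# ---------------------------------------------------------------------------

CB_OFFSET = 1.5  # Å from Cα toward the local curvature direction


def sidechain_centers(chain: PeptideChain) -> np.ndarray:
    """Per-residue side-chain reference points from a Cα trace.

    Each point is the Cα displaced by 1.5 Å along the local curvature
    vector (Cα_i minus the midpoint of its neighbours, orthogonalised
    against the chain tangent) — a Cβ-direction proxy that is exactly
    equivariant under rigid motion. Glycine, terminal residues and locally
    straight geometry (undefined curvature) fall back to the Cα itself.
    """
    ca = chain.calpha
    centers = ca.copy()
    for i in range(1, len(ca) - 1):
        if chain.sequence[i] == "G":
            continue
        prev_, next_ = ca[i - 1], ca[i + 1]
        tangent = next_ - prev_
        tn = np.linalg.norm(tangent)
        if tn < 1e-9:
            continue
        tangent /= tn
        bend = ca[i] - 0.5 * (prev_ + next_)
        bend -= (bend @ tangent) * tangent
        bn = np.linalg.norm(bend)
        if bn < 1e-6:
            continue  # locally straight: direction undefined
        centers[i] = ca[i] + CB_OFFSET * bend / bn
    return centers


AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Kyte–Doolittle hydropathy, the standard scale for hydrophobicity-driven
# contact models.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass
class ContactPotential:
    """Pairwise residue contact energies, indexed by one-letter code.

    Unknown residue types score a neutral 0 (with a warning at lookup
    encoding time). The shipped default is a hydrophobicity product; any
    20×20 table can be supplied.
    """

    matrix: np.ndarray  # (21, 21); row/col 20 is the unknown type
    name: str = "custom"

    @classmethod
    def from_table(cls, table: dict[str, dict[str, float]], name: str = "custom"):
        m = np.zeros((21, 21))
        for a, row in table.items():
            for b, e in row.items():
                m[_AA_INDEX[a], _AA_INDEX[b]] = e
        return cls(m, name)

    @classmethod
    def uniform(cls, value: float = -1.0) -> "ContactPotential":
        """Every contact scores ``value``; with −1 the energy is −(contact count)."""
        m = np.full((21, 21), value)
        m[20, :] = 0.0
        m[:, 20] = 0.0
        return cls(m, f"uniform({value:g})")

    @classmethod
    def hydrophobic(cls) -> "ContactPotential":
        """Default attractive potential: e(a,b) = −h_a·h_b with h the
        Kyte–Doolittle hydropathy rescaled to [0, 1]."""
        h = np.array([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in AA_ORDER])
        m = np.zeros((21, 21))
        m[:20, :20] = -np.outer(h, h)
        return cls(m, "hydrophobic")

    def encode(self, sequence: str) -> np.ndarray:
        idx = np.empty(len(sequence), dtype=int)
        for i, aa in enumerate(sequence):
            j = _AA_INDEX.get(aa)
            if j is None:
                warnings.warn(f"unknown residue type {aa!r}: scored as neutral 0",
                              stacklevel=2)
                j = 20
            idx[i] = j
        return idx


DEFAULT_CONTACT_CUTOFF = 6.5  # Å between side-chain reference points


def interaction_energy(model: OligomerModel,
                       potential: ContactPotential | None = None,
                       contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> float:
    """Inter-chain contact energy of a stack (arbitrary units, lower = better).

    Sums ``potential[aa_i][aa_j]`` over all residue pairs from *different*
    chains whose side-chain reference points lie within ``contact_cutoff``.
    Additive over chain pairs and invariant under rigid motion of the model.
    """
    if model.n_chains < 2:
        raise DomainCheckError("interaction energy needs at least two chains")
    pot = potential if potential is not None else ContactPotential.hydrophobic()
    centers = [sidechain_centers(c) for c in model.chains]
    codes = [pot.encode(c.sequence) for c in model.chains]
    energy = 0.0
    for i in range(model.n_chains):
        for j in range(i + 1, model.n_chains):
            d = cdist(centers[i], centers[j])
            mask = d <= contact_cutoff
            if mask.any():
                energy += pot.matrix[np.ix_(codes[i], codes[j])][mask].sum()
    return float(energy)


def contact_count_energy(model: OligomerModel,
                         contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> float:
    """Energy proxy: minus the number of inter-chain side-chain contacts."""
    return interaction_energy(model, ContactPotential.uniform(-1.0), contact_cutoff)


# ---------------------------------------------------------------------------
# two-stage selection
# ---------------------------------------------------------------------------

Variant = Literal["E_then_pcaRMSD", "pcaRMSD_then_E"]

_VARIANT_ALIASES = {
    "e_then_pcarmsd": "E_then_pcaRMSD",
    "e-then-pca": "E_then_pcaRMSD",
    "pcarmsd_then_e": "pcaRMSD_then_E",
    "pca-then-e": "pcaRMSD_then_E",
}


def normalize_variant(variant: str) -> Variant:
    v = _VARIANT_ALIASES.get(variant.lower().replace(" ", ""), variant)
    if v not in ("E_then_pcaRMSD", "pcaRMSD_then_E"):
        raise FormatError(f"unknown selection variant {variant!r}")
    return v  # type: ignore[return-value]


@dataclass
class ScoreRecord:
    model_index: int
    energy: float
    pca_rmsd: float
    ref_rmsd: float | None = None


@dataclass
class SelectionReport:
    """Outcome of the two-stage filter-then-rank selection."""

    variant: Variant
    pool_size: int
    best_model: int
    top10: list[int]
    records: list[ScoreRecord]
    pool: list[int] = field(default_factory=list)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.model_index, r.energy, r.pca_rmsd, r.ref_rmsd) for r in self.records],
            columns=["model_index", "energy", "pca_rmsd", "ref_rmsd"],
        )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "pool_size": self.pool_size,
            "best_model": self.best_model,
            "top10": list(self.top10),
            "pool_actual": len(self.pool),
        }


def score_ensemble(ensemble: Ensemble,
                   potential: ContactPotential | None = None,
                   reference: OligomerModel | None = None,
                   chain_mapping: str = "identity") -> list[ScoreRecord]:
    """Energy + pcaRMSD (and optionally reference RMSD) for every model.

    A model's stored energy (e.g. from a docking engine's sidecar table) is
    used when present; otherwise the contact energy is computed here.
    """
    records = []
    for model in ensemble:
        e = model.energy if model.energy is not None else \
            interaction_energy(model, potential)
        rec = ScoreRecord(model.model_index, float(e), pca_rmsd(model))
        if reference is not None:
            rec.ref_rmsd = reference_rmsd(model, reference, chain_mapping)
        records.append(rec)
    return records


def two_stage_select(ensemble: Ensemble, variant: str,
                     pool_size: int = 1000,
                     records: Sequence[ScoreRecord] | None = None,
                     potential: ContactPotential | None = None) -> SelectionReport:
    """Filter the ``pool_size`` best models on one score, rank them on the other.

    ``E_then_pcaRMSD``: pool = lowest-energy models, ranked by ascending
    pcaRMSD. ``pcaRMSD_then_E``: pool = lowest-pcaRMSD models, ranked by
    ascending energy. Ties always break toward the lower model_index, so the
    selection is fully deterministic; a pool smaller than ``pool_size``
    degenerates to the whole ensemble.
    """
    v = normalize_variant(variant)
    if len(ensemble) == 0:
        raise DomainCheckError("cannot select from an empty ensemble")
    recs = list(records) if records is not None else \
        score_ensemble(ensemble, potential)
    stage1 = (lambda r: r.energy) if v == "E_then_pcaRMSD" else (lambda r: r.pca_rmsd)
    stage2 = (lambda r: r.pca_rmsd) if v == "E_then_pcaRMSD" else (lambda r: r.energy)
    pool = sorted(recs, key=lambda r: (stage1(r), r.model_index))[:pool_size]
    ranked = sorted(pool, key=lambda r: (stage2(r), r.model_index))
    top10 = [r.model_index for r in ranked[:10]]
    return SelectionReport(
        variant=v, pool_size=pool_size, best_model=top10[0], top10=top10,
        records=recs, pool=[r.model_index for r in pool],
    )


# ---------------------------------------------------------------------------
# reference evaluation
# ---------------------------------------------------------------------------

def _mappings(m: int, chain_mapping: str):
    if chain_mapping == "identity":
        yield tuple(range(m))
    elif chain_mapping == "best_cyclic_or_reversed":
        base = list(range(m))
        for shift in range(m):
            yield tuple(base[(shift + i) % m] for i in range(m))
            yield tuple(base[(shift - i) % m] for i in range(m))
    else:
        raise FormatError(f"unknown chain_mapping {chain_mapping!r}")


def reference_rmsd(model: OligomerModel, reference: OligomerModel,
                   chain_mapping: str = "identity") -> float:
    """All-Cα RMSD to a reference after one whole-model superposition.

    ``identity`` keeps the stored chain order (restraint-defined setups fix
    it); ``best_cyclic_or_reversed`` minimises over the 2M cyclic shifts and
    order reversals of the model's chains, for references whose chain order
    may differ.
    """
    if model.n_chains != reference.n_chains:
        raise ShapeError("model and reference differ in chain count")
    ref = reference.all_calpha()
    best = np.inf
    for order in _mappings(model.n_chains, chain_mapping):
        mob = model.all_calpha(order)
        if mob.shape != ref.shape:
            raise ShapeError("model and reference differ in chain lengths")
        best = min(best, kabsch_superpose(mob, ref).rmsd)
    return float(best)
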