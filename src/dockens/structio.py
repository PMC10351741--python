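"""Structure and sequence I/O plus the superposition/RMSD kernels.

Everything downstream (protofilament scoring, cleavage-site calling, the
synthetic generators) works on the light-weight containers defined here:
a :class:`PeptideChain` is a Cα trace with optional backbone N/C/O atoms,
a :class:`OligomerModel` is an ordered stack of chains, a
:class:`ComplexModel` is receptor chains plus one peptide ligand, and an
:class:`Ensemble` is an ordered multi-model collection as produced by
coarse-grained docking engines (one PDB ``MODEL`` block per pose).

Residue addressing is sequential and 1-based within each chain; author
numbering from deposited PDB files is not preserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_1to3_extended
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, DataError, FormatError, ShapeError

ONE_TO_THREE = {aa: three.upper()
                for aa, three in protein_letters_1to3_extended.items()}
THREE_TO_ONE = {three: one for one, three in ONE_TO_THREE.items()}
#: the 20 standard residues (sequences the generators/restraints accept)
STANDARD_AA = frozenset(protein_letters_1to3)
#: standard plus extended/ambiguity codes (what annotated substrates may hold)
VALID_AA = frozenset(ONE_TO_THREE) | {"X"}

BACKBONE_ATOMS = ("N", "C", "O")

#: Cleavage-site separators accepted in annotated substrate strings.
SEPARATORS = ("—", "–", "--")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: name, 1-based residue index, 3-letter residue name, chain, Å coords."""

    atom_name: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ShapeError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        if self.residue_index < 1:
            raise FormatError(f"residue_index must be >= 1, got {self.residue_index}")


@dataclass
class PeptideChain:
    """A peptide chain as a Cα trace with optional backbone N/C/O coordinates.

    ``backbone`` maps atom name -> (L, 3) array; rows of NaN mark missing
    atoms (carbonyl oxygens are frequently absent from Cα-trace models).
    """

    chain_id: str
    sequence: str
    calpha: np.ndarray
    backbone: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.calpha = np.asarray(self.calpha, dtype=float)
        if self.calpha.ndim != 2 or self.calpha.shape[1] != 3:
            raise ShapeError("calpha must be an (L, 3) array")
        if len(self.sequence) != len(self.calpha):
            raise ShapeError(
                f"chain {self.chain_id}: sequence length {len(self.sequence)} "
                f"!= number of Cα records {len(self.calpha)}"
            )
        if self.backbone is not None:
            self.backbone = {
                name: np.asarray(xyz, dtype=float) for name, xyz in self.backbone.items()
            }
            for name, xyz in self.backbone.items():
                if xyz.shape != self.calpha.shape:
                    raise ShapeError(f"backbone {name} must match calpha shape")

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_geometry(self, lo: float = 2.7, hi: float = 4.3) -> None:
        """Check consecutive Cα–Cα distances fall in [lo, hi] Å.

        Off by default everywhere: decoy poses from lattice simulations may
        legitimately violate ideal virtual-bond geometry.
        """
        d = np.linalg.norm(np.diff(self.calpha, axis=0), axis=1)
        if len(d) and (d.min() < lo or d.max() > hi):
            raise FormatError(
                f"chain {self.chain_id}: consecutive Cα–Cα distance outside "
                f"[{lo}, {hi}] Å (range {d.min():.2f}–{d.max():.2f})"
            )

    def reversed(self) -> "PeptideChain":
        backbone = None
        if self.backbone is not None:
            backbone = {k: v[::-1].copy() for k, v in self.backbone.items()}
        return PeptideChain(self.chain_id, self.sequence[::-1],
                            self.calpha[::-1].copy(), backbone)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PeptideChain":
        """Return a rigidly moved copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        backbone = None
        if self.backbone is not None:
            backbone = {k: v @ R.T + t for k, v in self.backbone.items()}
        return PeptideChain(self.chain_id, self.sequence, self.calpha @ R.T + t, backbone)


@dataclass
class OligomerModel:
    """One multi-chain model (M chains); the scoring unit of the protofilament protocol."""

    model_index: int
    chains: list[PeptideChain]
    energy: float | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise FormatError(f"model {self.model_index}: zero chains")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def require_uniform(self) -> int:
        """Protofilament mode: all chains share one sequence/length. Returns N."""
        seqs = {c.sequence for c in self.chains}
        if len(seqs) != 1:
            raise ShapeError(
                f"model {self.model_index}: chains differ in sequence/length"
            )
        return len(self.chains[0])

    def all_calpha(self, order: Sequence[int] | None = None) -> np.ndarray:
        idx = range(self.n_chains) if order is None else order
        return np.concatenate([self.chains[i].calpha for i in idx], axis=0)

    def transformed(self, rotation, translation) -> "OligomerModel":
        return OligomerModel(
            self.model_index,
            [c.transformed(rotation, translation) for c in self.chains],
            self.energy,
        )


@dataclass
class ComplexModel:
    """Receptor chains plus one peptide ligand; the unit of the cleavage protocol."""

    model_index: int
    receptor_chains: list[PeptideChain]
    ligand: PeptideChain
    energy: float | None = None

    def __post_init__(self) -> None:
        if len(self.ligand) < 2:
            raise FormatError(
                f"model {self.model_index}: ligand must hold at least one peptide bond"
            )

    def receptor_calpha(self) -> np.ndarray:
        return np.concatenate([c.calpha for c in self.receptor_chains], axis=0)

    def find_residue_ca(self, chain_id: str, residue_index: int) -> np.ndarray:
        """Cα of a receptor residue addressed by (chain_id, 1-based position)."""
        for chain in self.receptor_chains:
            if chain.chain_id == chain_id:
                if not 1 <= residue_index <= len(chain):
                    raise DataError(
                        f"model {self.model_index}: residue {chain_id}:{residue_index} "
                        f"outside chain of length {len(chain)}"
                    )
                return chain.calpha[residue_index - 1]
        raise DataError(
            f"model {self.model_index}: receptor chain {chain_id!r} not found"
        )

    def transformed(self, rotation, translation) -> "ComplexModel":
        return ComplexModel(
            self.model_index,
            [c.transformed(rotation, translation) for c in self.receptor_chains],
            self.ligand.transformed(rotation, translation),
            self.energy,
        )


@dataclass
class Ensemble:
    """Ordered collection of models with provenance and optional per-model energies."""

    models: list
    source_tag: str = ""

    def __post_init__(self) -> None:
        idx = [m.model_index for m in self.models]
        if len(set(idx)) != len(idx):
            raise FormatError("model_index values must be unique within an ensemble")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator:
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def attach_energies(self, energies: dict[int, float]) -> None:
        """Attach a per-model energy table (model_index -> energy, lower = better)."""
        missing = [m.model_index for m in self.models if m.model_index not in energies]
        if missing:
            raise DataError(f"energy table missing model_index values: {missing[:5]}")
        for m in self.models:
            m.energy = float(energies[m.model_index])


# ---------------------------------------------------------------------------
# sequence parsing
# ---------------------------------------------------------------------------

def parse_annotated_substrate(annotation: str) -> tuple[str, int]:
    """Split an annotated substrate string into (sequence, 1-based scissile bond).

    The cleavage site is marked with an em-dash (e.g. ``KPAEF—IRL``); an
    en-dash or a double hyphen is accepted as a transcription-tolerant
    alternative. Bond *k* joins residues *k* and *k+1*, so the returned index
    equals the number of residues before the marker.
    """
    text = annotation.strip()
    # normalise all accepted separators to a single sentinel
    for sep in SEPARATORS:
        text = text.replace(sep, "|")
    n_sep = text.count("|")
    if n_sep != 1:
        raise FormatError(
            f"annotation {annotation!r}: expected exactly one cleavage separator, found {n_sep}"
        )
    left, right = text.split("|")
    if not left or not right:
        raise FormatError(
            f"annotation {annotation!r}: separator at a terminus; a bond needs "
            "residues on both sides"
        )
    sequence = left + right
    bad = sorted(set(sequence) - VALID_AA)
    if bad:
        raise FormatError(f"annotation {annotation!r}: invalid residue letters {bad}")
    return sequence, len(left)


def read_fasta(path) -> str:
    """Return the sequence of the first record of a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        return str(record.seq)
    raise FormatError(f"{path}: no FASTA records found")


# ---------------------------------------------------------------------------
# superposition / RMSD kernels
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid fit of ``mobile`` onto ``target`` (x -> R x + t)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def __iter__(self):  # allow  R, t, rmsd = kabsch_superpose(...)
        return iter((self.rotation, self.translation, self.rmsd))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (proper rotations only).

    Returns the rotation/translation minimising the coordinate RMSD of
    ``mobile`` against ``target`` under index-wise correspondence.
    Degenerate inputs (K < 3 points, or collinear point sets, for which the
    optimum is not unique) are flagged but still fitted best-effort.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ShapeError(f"coordinate shapes differ: {mob.shape} vs {tgt.shape}")
    k = len(mob)
    if k == 0:
        raise ShapeError("cannot superpose empty coordinate sets")
    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    a, b = mob - mc, tgt - tc

    degenerate = k < 3
    if not degenerate:
        s = np.linalg.svd(a, compute_uv=False)
        degenerate = bool(s[1] <= 1e-8 * max(s[0], 1.0))  # collinear mobile set

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    rmsd = float(rssd) / math.sqrt(k)
    t = tc - R @ mc
    return SuperpositionResult(R, t, rmsd, degenerate)


def _coords(obj) -> np.ndarray:
    return obj.calpha if isinstance(obj, PeptideChain) else np.asarray(obj, float)


def calpha_rmsd(a, b, fit: bool = True) -> float:
    """Cα RMSD between two equal-length chains (or (L, 3) arrays).

    With ``fit=True`` the chains are optimally superposed first; with
    ``fit=False`` the raw coordinate RMSD is returned.
    """
    xa, xb = _coords(a), _coords(b)
    if xa.shape != xb.shape:
        raise ShapeError(f"chain lengths differ: {len(xa)} vs {len(xb)}")
    if fit:
        return kabsch_superpose(xa, xb).rmsd
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


AtomMode = Literal["carbonyl_O", "calpha_midpoint"]


def bond_reference_point(chain: PeptideChain, bond: int,
                         atom_mode: AtomMode = "carbonyl_O") -> np.ndarray:
    """Reference point of peptide bond ``bond`` (1-based; joins residues k, k+1).

    ``carbonyl_O`` returns the carbonyl oxygen of residue *k* (the atom whose
    contacts with the protease active-site centre define the scissile-bond
    histogram); ``calpha_midpoint`` is the documented Cα-trace fallback.
    """
    if not 1 <= bond <= len(chain) - 1:
        raise ShapeError(
            f"bond {bond} outside 1..{len(chain) - 1} for chain {chain.chain_id}"
        )
    if atom_mode == "calpha_midpoint":
        return 0.5 * (chain.calpha[bond - 1] + chain.calpha[bond])
    if atom_mode == "carbonyl_O":
        if chain.backbone is None or "O" not in chain.backbone:
            raise DataError(
                f"chain {chain.chain_id} residue {bond}: no carbonyl O atoms present "
                "(use atom_mode='calpha_midpoint' for Cα traces)"
            )
        o = chain.backbone["O"][bond - 1]
        if not np.all(np.isfinite(o)):
            raise DataError(
                f"chain {chain.chain_id} residue {bond}: carbonyl O missing"
            )
        return o.copy()
    raise ConfigurationError(f"unknown atom_mode {atom_mode!r}")


def bond_reference_points(chain: PeptideChain,
                          atom_mode: AtomMode = "carbonyl_O") -> np.ndarray:
    """All L−1 bond reference points, stacked (vectorised convenience)."""
    return np.array([bond_reference_point(chain, k, atom_mode)
                     for k in range(1, len(chain))])


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------

def _chain_from_biopdb(bio_chain) -> PeptideChain | None:
    seq: list[str] = []
    ca: list[np.ndarray] = []
    bb: dict[str, list[np.ndarray]] = {name: [] for name in BACKBONE_ATOMS}
    for residue in bio_chain:
        het, _resseq, icode = residue.id
        if het.strip():
            continue  # skip waters / heteroatoms
        if icode.strip():
            raise FormatError(
                f"chain {bio_chain.id}: insertion code {icode!r} at residue "
                f"{_resseq} is not supported"
            )
        if "CA" not in residue:
            continue
        seq.append(THREE_TO_ONE.get(residue.get_resname().strip(), "X"))
        ca.append(residue["CA"].get_coord().astype(float))
        for name in BACKBONE_ATOMS:
            if name in residue:
                bb[name].append(residue[name].get_coord().astype(float))
            else:
                bb[name].append(np.full(3, np.nan))
    if not ca:
        return None
    backbone = None
    if any(np.isfinite(np.asarray(v)).any() for v in bb.values()):
        backbone = {name: np.asarray(v) for name, v in bb.items()}
    return PeptideChain(bio_chain.id, "".join(seq), np.asarray(ca), backbone)


def read_pdb_ensemble(path, mode: Literal["oligomer", "complex"] = "oligomer",
                      ligand_chain: str | None = None,
                      source_tag: str | None = None) -> Ensemble:
    """Read a (multi-)MODEL PDB file into an :class:`Ensemble`.

    ``mode='oligomer'`` yields one :class:`OligomerModel` per MODEL block;
    ``mode='complex'`` splits each model into receptor chains and the named
    ``ligand_chain``. Chain order follows the file; a file without
    MODEL/ENDMDL wrapping is treated as a one-model ensemble. altLoc
    conflicts keep the first location; insertion codes are rejected.
    """
    if mode == "complex" and ligand_chain is None:
        raise ConfigurationError("complex mode requires ligand_chain")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("ens", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted construction errors
        raise FormatError(f"{path}: unreadable PDB file ({exc})") from exc

    models = []
    for i, bio_model in enumerate(structure):
        chains = [c for c in (_chain_from_biopdb(ch) for ch in bio_model)
                  if c is not None]
        if not chains:
            raise FormatError(f"{path}: MODEL {i + 1} holds zero peptide chains")
        if mode == "oligomer":
            models.append(OligomerModel(model_index=i + 1, chains=chains))
        else:
            ligand = next((c for c in chains if c.chain_id == ligand_chain), None)
            if ligand is None:
                raise ConfigurationError(
                    f"{path}: MODEL {i + 1} has no ligand chain {ligand_chain!r} "
                    f"(chains: {[c.chain_id for c in chains]})"
                )
            receptor = [c for c in chains if c.chain_id != ligand_chain]
            if not receptor:
                raise FormatError(f"{path}: MODEL {i + 1} has no receptor chains")
            models.append(ComplexModel(model_index=i + 1,
                                       receptor_chains=receptor, ligand=ligand))
    return Ensemble(models, source_tag=source_tag or str(path))


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}{resseq:>4d}"
    "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def _write_chain(fh, chain: PeptideChain, serial: int) -> int:
    order = ("N", "CA", "C", "O")
    for i, aa in enumerate(chain.sequence):
        res3 = ONE_TO_THREE.get(aa, "UNK")
        for name in order:
            if name == "CA":
                xyz = chain.calpha[i]
            else:
                if chain.backbone is None or name not in chain.backbone:
                    continue
                xyz = chain.backbone[name][i]
                if not np.all(np.isfinite(xyz)):
                    continue
            fh.write(_ATOM_FMT.format(
                serial=serial, name=f" {name:<3s}"[:4], alt=" ", res=res3,
                chain=chain.chain_id[:1], resseq=i + 1, icode=" ",
                x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0, elem=name[0],
            ))
            serial += 1
    fh.write(f"TER   {serial:>5d}      {ONE_TO_THREE.get(chain.sequence[-1], 'UNK'):>3s} "
             f"{chain.chain_id[:1]}{len(chain):>4d}\n")
    return serial + 1


def write_pdb_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (Cα + available backbone)."""
    with open(path, "w") as fh:
        for model in ensemble:
            fh.write(f"MODEL     {model.model_index:>4d}\n")
            serial = 1
            if isinstance(model, ComplexModel):
                chains = list(model.receptor_chains) + [model.ligand]
            else:
                chains = model.chains
            for chain in chains:
                serial = _write_chain(fh, chain, serial)
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# per-model energy sidecar (TSV: model_index, energy)
# ---------------------------------------------------------------------------

def read_energies_tsv(path) -> dict[int, float]:
    """Read a per-model energy sidecar table (columns: model_index, energy)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("model_index", "energy"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["model_index"].astype(int), df["energy"].astype(float)))


def write_energies_tsv(ensemble: Ensemble, path) -> None:
    import pandas as pd

    rows = [(m.model_index, m.energy) for m in ensemble]
    pd.DataFrame(rows, columns=["model_index", "energy"]).to_csv(
        path, sep="\t", index=False
    )
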