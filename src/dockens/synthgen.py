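"""Synthetic fixtures with the statistical structure both protocols assume.

Two families of generators:

* idealised in-register parallel β-stacks of M identical chains with
  tunable i.i.d. Gaussian coordinate noise, for exercising the symmetry
  score and the two-stage selection; and
* enzyme–substrate pose ensembles around a compact model aspartate
  protease with a planted scissile bond, tunable bound fraction,
  binding-mode direction mix and (optionally) flap geometry coupled to the
  bound state, for exercising the cleavage-site protocol end to end.

Every generator is seed-deterministic and returns a ground-truth table
sufficient to score downstream calls without re-inspecting geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .cleavage import ActiveSiteSpec, FlapSpec
from .errors import ConfigurationError, FormatError
from .structio import (
    STANDARD_AA,
    ComplexModel,
    Ensemble,
    OligomerModel,
    PeptideChain,
)
from .protofil import contact_count_energy

# idealised trans-peptide backbone offsets (Å) relative to each Cα of an
# extended chain running along +x; chosen to keep N–Cα, C–Cα and C=O bond
# lengths near their canonical values
_N_OFFSET = np.array([-1.20, 0.80, 0.0])
_C_OFFSET = np.array([1.25, 0.85, 0.0])
_O_OFFSET = np.array([1.60, 2.03, 0.0])

DEFAULT_STRAND_RISE = 4.8   # Å, canonical cross-β inter-strand spacing
DEFAULT_CA_SPACING = 3.8    # Å, virtual Cα–Cα bond of an extended chain


def _chain_label(i: int) -> str:
    import string

    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    return alphabet[i % len(alphabet)]


def ideal_extended_chain(sequence: str, chain_id: str = "A",
                         ca_spacing: float = DEFAULT_CA_SPACING,
                         with_backbone: bool = True) -> PeptideChain:
    """An extended chain along +x with idealised backbone N/C/O placement."""
    L = len(sequence)
    ca = np.zeros((L, 3))
    ca[:, 0] = np.arange(L) * ca_spacing
    backbone = None
    if with_backbone:
        backbone = {"N": ca + _N_OFFSET, "C": ca + _C_OFFSET, "O": ca + _O_OFFSET}
    return PeptideChain(chain_id, sequence, ca, backbone)


# ---------------------------------------------------------------------------
# protofilament stacks
# ---------------------------------------------------------------------------

@dataclass
class StackParams:
    """Parameters of an idealised in-register parallel stack."""

    sequence: str
    n_chains: int = 5
    strand_rise: float = DEFAULT_STRAND_RISE
    ca_spacing: float = DEFAULT_CA_SPACING
    noise_sigma: float = 0.0
    seed: int = 0
    with_backbone: bool = True

    def __post_init__(self) -> None:
        if self.strand_rise <= 0 or self.ca_spacing <= 0 or self.noise_sigma < 0:
            raise ConfigurationError("rise/spacing must be > 0 and sigma >= 0")
        bad = sorted(set(self.sequence) - STANDARD_AA)
        if bad:
            raise FormatError(f"invalid residue letters {bad}")


def build_ideal_stack(params: StackParams, model_index: int = 1,
                      rng: np.random.Generator | None = None) -> OligomerModel:
    """M extended chains stacked along z at ``strand_rise`` intervals.

    At ``noise_sigma = 0`` the chains are exact translated copies, so every
    in-register atom pair across adjacent chains sits at ``strand_rise``
    exactly and the pcaRMSD is zero. Gaussian noise of sd ``noise_sigma`` is
    then added independently to every coordinate of every atom.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    base = ideal_extended_chain(params.sequence, "A", params.ca_spacing,
                                params.with_backbone)
    chains = []
    for m in range(params.n_chains):
        shift = np.array([0.0, 0.0, m * params.strand_rise])
        ca = base.calpha + shift
        backbone = None
        if base.backbone is not None:
            backbone = {k: v + shift for k, v in base.backbone.items()}
        if params.noise_sigma > 0:
            ca = ca + rng.normal(0.0, params.noise_sigma, ca.shape)
            if backbone is not None:
                backbone = {
                    k: v + rng.normal(0.0, params.noise_sigma, v.shape)
                    for k, v in backbone.items()
                }
        chains.append(PeptideChain(_chain_label(m), params.sequence, ca, backbone))
    return OligomerModel(model_index=model_index, chains=chains)


def make_protofil_ensemble(
    params: StackParams,
    n_models: int | None = None,
    sigma_schedule: Sequence[tuple[float, int]] | Sequence[float] | None = None,
) -> tuple[Ensemble, pd.DataFrame]:
    """Ensemble of perturbed stacks with a per-model noise truth table.

    ``sigma_schedule`` is either a list of (sigma, count) pairs or one sigma
    per model; omitted, every model uses ``params.noise_sigma``. Each model
    gets a contact-count energy proxy (minus the number of inter-chain
    side-chain contacts), so low-noise, well-packed stacks score lower.
    """
    if sigma_schedule is None:
        if n_models is None:
            raise ConfigurationError("give n_models or sigma_schedule")
        sigmas = [params.noise_sigma] * n_models
    elif sigma_schedule and isinstance(sigma_schedule[0], (tuple, list)):
        sigmas = [s for s, count in sigma_schedule for _ in range(int(count))]
    else:
        sigmas = [float(s) for s in sigma_schedule]
    if n_models is not None and len(sigmas) != n_models:
        raise ConfigurationError("sigma_schedule length does not match n_models")
    rng = np.random.default_rng(params.seed)
    models, rows = [], []
    for i, sigma in enumerate(sigmas, start=1):
        model = build_ideal_stack(replace(params, noise_sigma=float(sigma)),
                                  model_index=i, rng=rng)
        model.energy = contact_count_energy(model)
        models.append(model)
        rows.append((i, float(sigma), model.energy))
    truth = pd.DataFrame(rows, columns=["model_index", "sigma", "energy"])
    return Ensemble(models, source_tag=f"synthetic-stacks(seed={params.seed})"), truth


# ---------------------------------------------------------------------------
# model aspartate protease
# ---------------------------------------------------------------------------

#: residue addresses of the model protease built by :func:`build_model_protease`
MODEL_PROTEASE_CATALYTIC: tuple = (("A", 3), ("B", 3))
MODEL_PROTEASE_FLAP: tuple = (("A", 22), ("B", 22))


def build_model_protease(flap_separation: float = 8.0) -> list[PeptideChain]:
    """A compact two-chain model aspartate protease.

    Two mirror-symmetric 22-residue chains (A and B) form serpentine lobes
    flanking a cleft along the x axis. Residue 3 of each chain is the
    catalytic Asp (Cα at (0, ±3, 0), so the active-site centre is the
    origin) and residue 22 is the flap tip, hovering over the cleft at
    (0, ±flap_separation/2, 4). Geometry, not chemistry: virtual bonds are
    not idealised and only Cα atoms are placed.
    """
    rows, cols, spacing, row_step = 4, 5, 3.8, 4.0
    coords_a = []
    for r in range(rows):
        xs = [(c - 2) * spacing for c in range(cols)]
        if r % 2:
            xs = xs[::-1]  # serpentine
        for x in xs:
            coords_a.append((x, 3.0 + r * row_step, 0.0))
    coords_a.append((1.0, 3.0, 4.0))                      # residue 21: flap stem
    coords_a.append((0.0, flap_separation / 2.0, 4.0))    # residue 22: flap tip
    coords_a = np.asarray(coords_a)
    seq = list("A" * 22)
    seq[2] = "D"   # catalytic Asp at position 3
    seq[21] = "G"  # flap tip glycine
    seq = "".join(seq)
    mirror = np.array([1.0, -1.0, 1.0])
    chain_a = PeptideChain("A", seq, coords_a)
    chain_b = PeptideChain("B", seq, coords_a * mirror)
    return [chain_a, chain_b]


def model_protease_specs(planted_bond: int) -> tuple[ActiveSiteSpec, FlapSpec]:
    """ActiveSiteSpec/FlapSpec matching :func:`build_model_protease`."""
    site = ActiveSiteSpec(*MODEL_PROTEASE_CATALYTIC)
    flap = FlapSpec(*MODEL_PROTEASE_FLAP, scissile_bond=planted_bond)
    return site, flap


# ---------------------------------------------------------------------------
# cleavage-pose ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlantParams:
    """Parameters of a synthetic enzyme–substrate pose ensemble.

    ``bound_fraction`` of the poses place the planted bond's carbonyl
    oxygen within (cutoff − margin) Å of the active-site centre with
    Gaussian jitter of sd ``bound_noise_sigma``; the rest are decoys whose
    nearest atom lies at least ``decoy_radius`` from the centre.
    ``mode_mix`` is the fraction of bound poses running forward (+x).
    ``flap_coupling`` = (P(closed | bound), P(closed | unbound)) switches on
    per-model flap geometry; None leaves the flaps at a fixed separation.
    ``register_slip_p`` is the probability mass of the ±1 register offsets:
    a slipped pose centres a neighbouring bond on the active site, which
    reproduces the secondary histogram peaks seen in real docking
    ensembles while keeping the planted bond the strict argmax.
    """

    substrate_sequence: str
    planted_bond: int
    n_models: int = 500
    bound_fraction: float = 0.12
    bound_noise_sigma: float = 1.0
    decoy_radius: float = 25.0
    mode_mix: float = 0.5
    flap_coupling: tuple[float, float] | None = None
    seed: int = 0
    cutoff: float = 7.0
    margin: float = 1.0
    register_slip_p: float = 0.2
    ligand_chain_id: str = "P"

    def __post_init__(self) -> None:
        L = len(self.substrate_sequence)
        if not 1 <= self.planted_bond <= L - 1:
            raise ConfigurationError(
                f"planted_bond {self.planted_bond} outside 1..{L - 1}")
        for name in ("bound_fraction", "mode_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.flap_coupling is not None:
            if not all(0.0 <= p <= 1.0 for p in self.flap_coupling):
                raise ConfigurationError("flap_coupling probabilities in [0, 1]")
        bad = sorted(set(self.substrate_sequence) - STANDARD_AA)
        if bad:
            raise FormatError(f"invalid residue letters {bad}")


_FLAP_CLOSED_RANGE = (7.0, 11.0)   # Å, sampled flap separation when closed
_FLAP_OPEN_RANGE = (13.0, 18.0)    # strict thresholds never sit on a sample
_DEFAULT_FLAP_SEPARATION = 8.0


def make_cleavage_ensemble(
    params: PlantParams,
    receptor_template: Sequence[PeptideChain] | None = None,
) -> tuple[Ensemble, pd.DataFrame]:
    """Pose ensemble with a planted scissile bond and full truth bookkeeping.

    Bound poses keep the ligand extended through the cleft along ±x (with a
    small random in-plane tilt); the carbonyl oxygen of the centred bond —
    the planted bond, or a ±1 register-slipped neighbour — lands at the
    active-site centre plus a Gaussian jitter whose norm is capped so the
    *planted* bond always stays within (cutoff − margin) Å. Decoys are
    rigid random rotations placed on a shell: their nearest atom is at
    least ``decoy_radius`` from the centre, so they are always classified
    unbound. The truth table records, per model: bound flag, binding mode,
    centred bond, flap state and flap distance.
    """
    rng = np.random.default_rng(params.seed)
    receptor = list(receptor_template) if receptor_template is not None \
        else build_model_protease(_DEFAULT_FLAP_SEPARATION)
    extent = max(float(np.linalg.norm(c.calpha, axis=1).max()) for c in receptor)
    if params.decoy_radius <= extent + params.cutoff:
        raise ConfigurationError(
            f"decoy_radius {params.decoy_radius} Å must exceed the receptor "
            f"extent ({extent:.1f} Å) plus the contact cutoff"
        )
    base = ideal_extended_chain(params.substrate_sequence,
                                params.ligand_chain_id, with_backbone=True)
    base_atoms = {"CA": base.calpha, **base.backbone}
    planted_o = base.backbone["O"][params.planted_bond - 1]
    half_reach = max(float(np.linalg.norm(v - base.calpha.mean(0), axis=1).max())
                     for v in base_atoms.values())
    L = len(params.substrate_sequence)
    flap_a_idx = None
    if receptor_template is None:
        flap_a_idx = 21  # 0-based index of the flap tip in the model protease

    slip_choices = np.array([-1, 0, 1])
    slip_probs = np.array([params.register_slip_p / 2, 1 - params.register_slip_p,
                           params.register_slip_p / 2])

    models, rows = [], []
    for i in range(1, params.n_models + 1):
        bound = bool(rng.random() < params.bound_fraction)
        mode = None
        slip = 0
        if bound:
            mode = "forward" if rng.random() < params.mode_mix else "reverse"
            slip = int(rng.choice(slip_choices, p=slip_probs))
            if not 1 <= params.planted_bond + slip <= L - 1:
                slip = 0
            # jitter capped so the planted bond stays within (cutoff - margin)
            cap = max(params.cutoff - params.margin - DEFAULT_CA_SPACING * abs(slip),
                      0.3)
            g = rng.normal(0.0, params.bound_noise_sigma, 3)
            gn = float(np.linalg.norm(g))
            if gn > cap:
                g *= cap / gn
            tilt = Rotation.from_euler(
                "zy", rng.uniform(-20.0, 20.0, 2), degrees=True).as_matrix()
            R = tilt if mode == "forward" else \
                tilt @ Rotation.from_euler("z", 180, degrees=True).as_matrix()
            centred_o = base.backbone["O"][params.planted_bond + slip - 1]
            t = g - R @ centred_o  # centred bond O -> centre + jitter
        else:
            q = rng.normal(size=4)
            R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            centroid = (params.decoy_radius + half_reach
                        + abs(rng.normal(0.0, 2.0))) * u
            t = centroid - R @ base.calpha.mean(0)

        ligand = base.transformed(R, t)

        # receptor copy; per-model flap geometry if coupled
        flap_closed: bool | None = None
        flap_distance: float | None = None
        rec = receptor
        if params.flap_coupling is not None and flap_a_idx is not None:
            p_cb, p_cu = params.flap_coupling
            flap_closed = bool(rng.random() < (p_cb if bound else p_cu))
            lo, hi = _FLAP_CLOSED_RANGE if flap_closed else _FLAP_OPEN_RANGE
            flap_distance = float(rng.uniform(lo, hi))
            rec = []
            for chain in receptor:
                ca = chain.calpha.copy()
                sign = 1.0 if chain.chain_id == "A" else -1.0
                ca[flap_a_idx] = (0.0, sign * flap_distance / 2.0, 4.0)
                rec.append(PeptideChain(chain.chain_id, chain.sequence, ca))

        lig_d = cdist(ligand.calpha, np.concatenate([c.calpha for c in rec]))
        energy = -float((lig_d <= 8.0).sum())
        models.append(ComplexModel(i, rec, ligand, energy=energy))
        rows.append((i, bound, mode, params.planted_bond + slip if bound else None,
                     flap_closed, flap_distance))

    truth = pd.DataFrame(rows, columns=[
        "model_index", "bound", "mode", "centred_bond", "flap_closed",
        "flap_distance"])
    truth.attrs["planted_bond"] = params.planted_bond
    return (Ensemble(models, source_tag=f"synthetic-poses(seed={params.seed})"),
            truth)
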