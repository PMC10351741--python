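"""Cleavage-site protocol: active-site geometry, contact histograms,
binding-mode partitioning, pose clustering and flap-state analysis.

An aspartate protease has two catalytic Asp residues; their Cα midpoint
serves as the active-site centre. For every enzyme–substrate pose the
distance d_n from the carbonyl oxygen of each substrate peptide bond to
that centre is measured; bonds with d_n ≤ 7 Å are counted as contacts, and
the bond with the most contacts over a pose ensemble is called as the
scissile (cleaved) bond. Symmetric homodimeric proteases (HIV-1 protease)
bind the substrate in two equivalent directions, so contacts can be
partitioned by binding mode; asymmetric enzymes (pepsin, renin) define a
single productive orientation against which poses are filtered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, DomainCheckError, NoContactsError
from .structio import (
    AtomMode,
    ComplexModel,
    Ensemble,
    bond_reference_points,
    kabsch_superpose,
)

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 7.0   # Å, d_n ≤ cutoff counts as an active-site contact
DEFAULT_BOUND_THRESHOLD = 9.0  # Å, scissile-bond distance (strict <) for "bound"
DEFAULT_CLOSED_THRESHOLD = 12.0  # Å, flap Cα–Cα distance (strict <) for "closed"


# ---------------------------------------------------------------------------
# active-site geometry
# ---------------------------------------------------------------------------

ResidueAddress = tuple[str, int]  # (chain_id, 1-based sequence position)


@dataclass(frozen=True)
class ActiveSiteSpec:
    """The two catalytic residue addresses; the centre is recomputed per model."""

    catalytic_a: ResidueAddress
    catalytic_b: ResidueAddress


def active_site_center(model: ComplexModel, spec: ActiveSiteSpec) -> np.ndarray:
    """Midpoint of the two catalytic Cα atoms (Å)."""
    a = model.find_residue_ca(*spec.catalytic_a)
    b = model.find_residue_ca(*spec.catalytic_b)
    return 0.5 * (a + b)


def bond_distances(model: ComplexModel, spec: ActiveSiteSpec,
                   atom_mode: AtomMode = "carbonyl_O") -> np.ndarray:
    """d_n for every ligand peptide bond: reference point to active-site centre."""
    center = active_site_center(model, spec)
    refs = bond_reference_points(model.ligand, atom_mode)
    return np.linalg.norm(refs - center, axis=1)


BindingMode = Literal["forward", "reverse", "unbound"]


def classify_binding_mode(model: ComplexModel, spec: ActiveSiteSpec,
                          reference_axis: np.ndarray,
                          cutoff: float = DEFAULT_CONTACT_CUTOFF,
                          atom_mode: AtomMode = "carbonyl_O") -> BindingMode:
    """Direction of the substrate chain through the active site.

    Unbound if no bond reference point lies within ``cutoff`` of the centre;
    otherwise the sign of the dot product between the local N→C direction at
    the closest bond and ``reference_axis`` decides forward (≥ 0) vs reverse.
    The reference axis is configuration (e.g. the substrate direction of an
    inhibitor crystal pose), not inference.
    """
    axis = np.asarray(reference_axis, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ConfigurationError("reference_axis must be non-zero")
    d = bond_distances(model, spec, atom_mode)
    if d.min() > cutoff:
        return "unbound"
    n_star = int(np.argmin(d))  # 0-based bond index
    direction = model.ligand.calpha[n_star + 1] - model.ligand.calpha[n_star]
    return "forward" if float(direction @ axis) >= 0.0 else "reverse"


# ---------------------------------------------------------------------------
# contact histograms and the cleavage call
# ---------------------------------------------------------------------------

ModeFilter = Literal["all", "forward", "reverse", "per_mode"]


@dataclass
class ContactHistogram:
    """Per-bond active-site contact counts, partitioned by binding mode."""

    n_bonds: int
    counts_per_mode: dict[str, np.ndarray]
    cutoff: float
    atom_mode: AtomMode
    models_per_mode: dict[str, int] = field(default_factory=dict)

    @property
    def bonds(self) -> np.ndarray:
        """1-based bond indices."""
        return np.arange(1, self.n_bonds + 1)

    def combined(self) -> np.ndarray:
        return np.sum(list(self.counts_per_mode.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        data = {"bond": self.bonds}
        for mode, counts in self.counts_per_mode.items():
            data[f"count_{mode}"] = counts
        if len(self.counts_per_mode) > 1:
            data["count_combined"] = self.combined()
        return pd.DataFrame(data)


def contact_histogram(ensemble: Ensemble, spec: ActiveSiteSpec,
                      cutoff: float = DEFAULT_CONTACT_CUTOFF,
                      atom_mode: AtomMode = "carbonyl_O",
                      mode_filter: ModeFilter = "all",
                      reference_axis: np.ndarray | None = None) -> ContactHistogram:
    """Count, per peptide bond, the poses whose bond oxygen contacts the site.

    Every bond with d_n ≤ ``cutoff`` increments its own count, so one pose
    may increment several bonds. ``mode_filter`` restricts counting to one
    binding mode ('forward'/'reverse'; used for asymmetric enzymes where
    only the crystallographic substrate orientation is productive) or splits
    counts per mode ('per_mode'; used for the symmetric HIV-1 protease).
    """
    if len(ensemble) == 0:
        raise DomainCheckError("contact_histogram needs a non-empty ensemble")
    if mode_filter != "all" and reference_axis is None:
        raise ConfigurationError(f"mode_filter={mode_filter!r} needs a reference_axis")
    n_bonds = len(ensemble[0].ligand) - 1
    modes = {"all": ("all",), "forward": ("forward",),
             "reverse": ("reverse",), "per_mode": ("forward", "reverse")}[mode_filter]
    counts = {m: np.zeros(n_bonds, dtype=int) for m in modes}
    n_models = {m: 0 for m in modes}
    for model in ensemble:
        d = bond_distances(model, spec, atom_mode)
        if mode_filter == "all":
            mode = "all"
        else:
            mode = classify_binding_mode(model, spec, reference_axis, cutoff, atom_mode)
            if mode not in counts:
                continue
        n_models[mode] += 1
        counts[mode] += (d <= cutoff).astype(int)
    return ContactHistogram(n_bonds, counts, cutoff, atom_mode, n_models)


ModePolicy = Literal["combined", "max_over_modes"]


@dataclass
class CleavageCall:
    """Argmax cleavage-site call with runner-up evidence."""

    bond: int
    count: int
    runner_up_bond: int | None
    runner_up_count: int | None
    tie: bool
    mode_policy: ModePolicy
    per_mode: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bond": self.bond, "count": self.count,
            "runner_up_bond": self.runner_up_bond,
            "runner_up_count": self.runner_up_count,
            "tie": self.tie, "mode_policy": self.mode_policy,
            "per_mode": dict(self.per_mode),
        }


def call_cleavage_site(hist: ContactHistogram,
                       mode_policy: ModePolicy = "combined") -> CleavageCall:
    """Call the bond with the highest contact count as the cleavage site.

    ``combined`` sums counts across modes before the argmax (the default:
    for a symmetric enzyme both binding directions are productive);
    ``max_over_modes`` takes the elementwise maximum instead. Ties break
    toward the lower bond index and are flagged (and logged). An all-zero
    histogram raises :class:`NoContactsError` — a no-call is distinct from a
    tie.
    """
    if mode_policy == "combined":
        reduced = hist.combined()
    elif mode_policy == "max_over_modes":
        reduced = np.max(list(hist.counts_per_mode.values()), axis=0)
    else:
        raise ConfigurationError(f"unknown mode_policy {mode_policy!r}")
    if reduced.max() <= 0:
        raise NoContactsError(
            "no peptide bond recorded any active-site contact; cannot call a site"
        )
    top = int(reduced.max())
    bond0 = int(np.flatnonzero(reduced == top)[0])  # low-bond tie-break
    tie = int((reduced == top).sum()) > 1
    if tie:
        logger.warning("cleavage call tie at count %d between bonds %s; "
                       "calling the lowest bond", top,
                       (np.flatnonzero(reduced == top) + 1).tolist())
    runner_bond = runner_count = None
    if len(reduced) > 1:
        rest = reduced.copy()
        rest[bond0] = -1
        rb = int(np.flatnonzero(rest == rest.max())[0])
        runner_bond, runner_count = rb + 1, int(reduced[rb])
    per_mode = {}
    for mode, counts in hist.counts_per_mode.items():
        if counts.max() > 0:
            per_mode[mode] = int(np.flatnonzero(counts == counts.max())[0]) + 1
    return CleavageCall(bond0 + 1, top, runner_bond, runner_count, tie,
                        mode_policy, per_mode)


# ---------------------------------------------------------------------------
# pose clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    n_models: int
    labels: np.ndarray            # per-model cluster id, in ensemble order
    cluster_sizes: dict[int, int]
    representatives: list[int]    # model_index of the medoids, largest cluster first

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "cluster_sizes": {int(k): int(v) for k, v in self.cluster_sizes.items()},
            "representatives": [int(r) for r in self.representatives],
        }


def pose_distance_matrix(models: Sequence[ComplexModel]) -> np.ndarray:
    """Pairwise ligand Cα RMSD after superposing receptors (receptor Cα only)."""
    n = len(models)
    rec = [m.receptor_calpha() for m in models]
    lig = [m.ligand.calpha for m in models]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sup = kabsch_superpose(rec[j], rec[i])
            moved = sup.apply(lig[j])
            d = float(np.sqrt(np.mean(np.sum((lig[i] - moved) ** 2, axis=1))))
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_representatives(ensemble: Ensemble, k_keep: int = 10,
                            linkage_method: str = "average",
                            distance_matrix: np.ndarray | None = None) -> ClusterReport:
    """Medoids of the ``k_keep`` largest pose clusters.

    Poses are clustered agglomeratively (average linkage by default) on the
    ligand-RMSD-after-receptor-fit matrix and the tree is cut into
    ``k_keep`` clusters; each representative is its cluster's medoid — the
    member minimising the summed intra-cluster distance. Representatives
    are ordered by descending cluster size. With fewer models than
    ``k_keep`` every model is returned as a singleton (with a warning).
    """
    models = list(ensemble)
    n = len(models)
    if n == 0:
        raise DomainCheckError("cannot cluster an empty ensemble")
    if n < k_keep:
        warnings.warn(f"only {n} models for k_keep={k_keep}: "
                      "returning all models as singleton representatives")
        labels = np.arange(n)
        sizes = {i: 1 for i in range(n)}
        return ClusterReport(n, labels, sizes, [m.model_index for m in models])
    dist = distance_matrix if distance_matrix is not None \
        else pose_distance_matrix(models)
    if n == k_keep:
        labels = np.arange(n)
    else:
        z = linkage(squareform(dist, checks=False), method=linkage_method)
        labels = cut_tree(z, n_clusters=k_keep).ravel()
    sizes = {int(c): int((labels == c).sum()) for c in np.unique(labels)}

    def cluster_order_key(c: int):
        members = np.flatnonzero(labels == c)
        return (-sizes[c], min(models[i].model_index for i in members))

    reps = []
    for c in sorted(sizes, key=cluster_order_key)[:k_keep]:
        members = np.flatnonzero(labels == c)
        sums = dist[np.ix_(members, members)].sum(axis=1)
        best = min(zip(sums, (models[i].model_index for i in members),
                       members))  # ties: lower model_index
        reps.append(models[best[2]].model_index)
    return ClusterReport(n, labels, sizes, reps)


# ---------------------------------------------------------------------------
# flap-state analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlapSpec:
    """Flap residue pair, scissile bond, and the bound/closed thresholds.

    Defaults reflect the HIV-1 protease convention: flaps closed when the
    Gly52(A)–Gly52(B) Cα distance is below 12 Å, substrate bound when the
    scissile-bond oxygen sits within 9 Å of the active-site centre. Both
    thresholds are strict (<): a frame exactly at a threshold counts open /
    unbound.
    """

    flap_a: ResidueAddress
    flap_b: ResidueAddress
    scissile_bond: int
    closed_threshold: float = DEFAULT_CLOSED_THRESHOLD
    bound_threshold: float = DEFAULT_BOUND_THRESHOLD

    def __post_init__(self) -> None:
        if self.closed_threshold <= 0 or self.bound_threshold <= 0:
            raise ConfigurationError("flap thresholds must be positive")


@dataclass
class FlapReport:
    p_closed_given_bound: float   # NaN when no bound frames
    p_closed_given_unbound: float
    n_bound: int
    n_unbound: int
    frames: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "p_closed_given_bound": self.p_closed_given_bound,
            "p_closed_given_unbound": self.p_closed_given_unbound,
            "n_bound": self.n_bound, "n_unbound": self.n_unbound,
        }


def flap_state_analysis(trajectory: Ensemble, flap: FlapSpec,
                        spec: ActiveSiteSpec,
                        atom_mode: AtomMode = "carbonyl_O") -> FlapReport:
    """Conditional closed-flap frequencies given substrate binding.

    Per frame: bound := scissile-bond distance to the active-site centre
    < bound_threshold; closed := flap Cα–Cα distance < closed_threshold.
    Returns P(closed | bound), P(closed | unbound) and the full frame table
    (for scatter plots of flap distance against scissile-bond distance).
    """
    rows = []
    for model in trajectory:
        d_sciss = float(bond_distances(model, spec, atom_mode)[flap.scissile_bond - 1])
        fa = model.find_residue_ca(*flap.flap_a)
        fb = model.find_residue_ca(*flap.flap_b)
        d_flap = float(np.linalg.norm(fa - fb))
        rows.append((model.model_index, d_sciss, d_flap,
                     d_sciss < flap.bound_threshold,
                     d_flap < flap.closed_threshold))
    frames = pd.DataFrame(
        rows, columns=["model_index", "scissile_distance", "flap_distance",
                       "bound", "closed"])
    bound = frames[frames["bound"]]
    unbound = frames[~frames["bound"]]
    p_cb = float(bound["closed"].mean()) if len(bound) else float("nan")
    p_cu = float(unbound["closed"].mean()) if len(unbound) else float("nan")
    return FlapReport(p_cb, p_cu, len(bound), len(unbound), frames)
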