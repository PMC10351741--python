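"""Restraint generation, pcaRMSD, contact energy, selection, reference RMSD."""

import numpy as np
import pytest

from dockens.errors import DomainCheckError, FormatError
from dockens.protofil import (
    ContactPotential,
    ScoreRecord,
    generate_inregister_restraints,
    interaction_energy,
    pca_rmsd,
    read_restraints,
    reference_rmsd,
    sidechain_centers,
    two_stage_select,
    write_restraints,
)
from dockens.structio import Ensemble, OligomerModel, PeptideChain
from dockens.synthgen import StackParams, build_ideal_stack

from conftest import random_rotation


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

def test_inregister_restraints_count_and_defaults():
    seq = "SNFLNCYVSGFHPSDIEVDLLK"  # 22-residue amyloidogenic peptide
    restraints = generate_inregister_restraints(seq, n_chains=5)
    assert len(restraints) == 4 * 22  # (M-1) x L
    assert all(r.target_distance == 5.0 for r in restraints)
    assert all(r.residue_a == r.residue_b for r in restraints)  # in register
    # deterministic order: chain pair major, residue minor
    assert [(r.chain_a, r.chain_b) for r in restraints[:22]] == [("A", "B")] * 22
    assert [r.residue_a for r in restraints[:22]] == list(range(1, 23))


def test_restraint_edge_cases():
    assert generate_inregister_restraints("KPAEF", 1) == []
    gg = generate_inregister_restraints("GG", 2)
    assert len(gg) == 2 and all(r.atom_role == "calpha" for r in gg)
    mixed = generate_inregister_restraints("AGA", 2)
    assert [r.atom_role for r in mixed] == \
        ["sidechain_center", "calpha", "sidechain_center"]
    with pytest.raises(FormatError):
        generate_inregister_restraints("AZ1", 2)


def test_restraint_file_round_trip(tmp_path):
    restraints = generate_inregister_restraints("AGAEF", 3, target_distance=5.0,
                                                weight=0.5)
    path = tmp_path / "restraints.txt"
    write_restraints(restraints, path)
    back = read_restraints(path, sequence="AGAEF")
    assert back == restraints


# ---------------------------------------------------------------------------
# pcaRMSD
# ---------------------------------------------------------------------------

def _random_model(rng, m=3, n=4):
    chains = [PeptideChain(chr(65 + i), "A" * n, rng.normal(scale=3, size=(n, 3)))
              for i in range(m)]
    return OligomerModel(1, chains)


def _pca_rmsd_oracle(model):
    """Naive ordered-pair enumeration on an independent superposition route."""
    from Bio.SVDSuperimposer import SVDSuperimposer

    m = model.n_chains
    total = 0.0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            sup = SVDSuperimposer()
            sup.set(model.chains[j].calpha, model.chains[i].calpha)
            sup.run()
            total += float(sup.get_rms())
    return total / (m * m - m)


def test_pca_rmsd_congruent_chains_is_zero(stack_factory):
    assert pca_rmsd(stack_factory(sigma=0.0)) == pytest.approx(0.0, abs=1e-9)


def test_pca_rmsd_two_chains_equals_pair_rmsd(rng):
    from dockens.structio import calpha_rmsd

    model = _random_model(rng, m=2, n=6)
    assert pca_rmsd(model) == pytest.approx(
        calpha_rmsd(model.chains[0], model.chains[1], fit=True), abs=1e-9)


def test_pca_rmsd_matches_ordered_pair_oracle(rng):
    for m, n in [(3, 4), (4, 7), (5, 5)]:
        model = _random_model(rng, m=m, n=n)
        assert pca_rmsd(model) == pytest.approx(_pca_rmsd_oracle(model), abs=1e-9)


def test_pca_rmsd_invariances(rng, stack_factory):
    model = stack_factory(sigma=0.8, seed=4)
    base = pca_rmsd(model)
    # whole-model rigid motion
    moved = model.transformed(random_rotation(rng), rng.normal(scale=20, size=3))
    assert pca_rmsd(moved) == pytest.approx(base, abs=1e-9)
    # independent rigid motion of one chain
    model.chains[2] = model.chains[2].transformed(random_rotation(rng),
                                                  rng.normal(scale=30, size=3))
    assert pca_rmsd(model) == pytest.approx(base, abs=1e-9)
    # chain-order permutation
    perm = model.chains[::-1]
    assert pca_rmsd(OligomerModel(1, perm)) == pytest.approx(base, abs=1e-9)


def test_pca_rmsd_domain_errors(rng):
    with pytest.raises(DomainCheckError):
        pca_rmsd(_random_model(rng, m=1))


# ---------------------------------------------------------------------------
# contact energy
# ---------------------------------------------------------------------------

def _energy_oracle(model, potential, cutoff):
    """Pure double loop over all inter-chain residue pairs."""
    total = 0.0
    centers = [sidechain_centers(c) for c in model.chains]
    codes = [potential.encode(c.sequence) for c in model.chains]
    m = model.n_chains
    for i in range(m):
        for j in range(m):
            if j <= i:
                continue
            for a in range(len(centers[i])):
                for b in range(len(centers[j])):
                    if np.linalg.norm(centers[i][a] - centers[j][b]) <= cutoff:
                        total += potential.matrix[codes[i][a], codes[j][b]]
    return total


def test_energy_zero_at_separation(stack_factory):
    model = stack_factory(sigma=0.0)
    model.chains[1] = model.chains[1].transformed(np.eye(3), [0.0, 0.0, 100.0])
    model.chains[2] = model.chains[2].transformed(np.eye(3), [0.0, 0.0, 200.0])
    model.chains[3] = model.chains[3].transformed(np.eye(3), [0.0, 0.0, 300.0])
    model.chains[4] = model.chains[4].transformed(np.eye(3), [0.0, 0.0, 400.0])
    assert interaction_energy(model) == 0.0


def test_uniform_potential_counts_contacts(stack_factory):
    model = stack_factory(sigma=0.3, seed=9)
    e = interaction_energy(model, ContactPotential.uniform(-1.0))
    assert e == pytest.approx(round(e))  # integer count
    assert e < 0
    assert e == pytest.approx(
        _energy_oracle(model, ContactPotential.uniform(-1.0), 6.5), abs=1e-9)


def test_energy_matches_brute_force_for_random_model(rng):
    chains = [PeptideChain(c, "KPAEFIRL", rng.normal(scale=4, size=(8, 3)))
              for c in "AB"]
    model = OligomerModel(1, chains)
    pot = ContactPotential.hydrophobic()
    assert interaction_energy(model, pot) == pytest.approx(
        _energy_oracle(model, pot, 6.5), abs=1e-9)


def test_energy_rigid_invariance(rng, stack_factory):
    model = stack_factory(sigma=0.5, seed=2)
    base = interaction_energy(model)
    moved = model.transformed(random_rotation(rng), rng.normal(scale=15, size=3))
    assert interaction_energy(moved) == pytest.approx(base, abs=1e-9)


def test_energy_monotone_on_approach():
    """Two rigid chains approaching from non-contact to packed never gain
    energy, and end strictly lower than at separation."""
    base = build_ideal_stack(StackParams("KPAEFIRL", n_chains=1))
    chain = base.chains[0]
    energies = []
    for d in [12.0, 8.0, 6.5, 6.0, 5.5, 4.8]:
        other = chain.transformed(np.eye(3), [0.0, 0.0, d])
        other = PeptideChain("B", other.sequence, other.calpha, other.backbone)
        energies.append(interaction_energy(OligomerModel(1, [chain, other])))
    assert all(e1 <= e0 + 1e-12 for e0, e1 in zip(energies, energies[1:]))
    assert energies[-1] < energies[0]


def test_unknown_residue_scores_neutral():
    pot = ContactPotential.hydrophobic()
    with pytest.warns(UserWarning, match="unknown residue"):
        codes = pot.encode("AXA")
    assert codes[1] == 20 and pot.matrix[20].sum() == 0.0


# ---------------------------------------------------------------------------
# two-stage selection
# ---------------------------------------------------------------------------

def _records(pairs):
    return [ScoreRecord(i, e, p) for i, (e, p) in enumerate(pairs, start=1)]


def _dummy_ensemble(n):
    chain = PeptideChain("A", "AA", [[0, 0, 0], [3.8, 0, 0]])
    chain2 = PeptideChain("B", "AA", [[0, 0, 4.8], [3.8, 0, 4.8]])
    return Ensemble([OligomerModel(i, [chain, chain2]) for i in range(1, n + 1)])


def test_two_stage_select_matches_hand_enumeration():
    # (energy, pcaRMSD) per model, model_index 1..10
    pairs = [(5.0, 1.0), (1.0, 9.0), (2.0, 8.0), (3.0, 0.5), (9.0, 0.1),
             (4.0, 7.0), (8.0, 0.2), (7.0, 6.0), (6.0, 5.0), (0.5, 9.5)]
    recs = _records(pairs)
    ens = _dummy_ensemble(10)

    # E-first, pool 3: lowest energies are models 10, 2, 3; best pcaRMSD there: 3
    rep = two_stage_select(ens, "E_then_pcaRMSD", pool_size=3, records=recs)
    assert sorted(rep.pool) == [2, 3, 10]
    assert rep.best_model == 3
    assert rep.top10 == [3, 2, 10]

    # pcaRMSD-first, pool 3: lowest pcaRMSD are models 5, 7, 4; best energy: 4
    rep2 = two_stage_select(ens, "pcaRMSD_then_E", pool_size=3, records=recs)
    assert sorted(rep2.pool) == [4, 5, 7]
    assert rep2.best_model == 4


def test_two_stage_select_tie_breaks_to_lowest_index():
    recs = _records([(1.0, 1.0)] * 6)
    rep = two_stage_select(_dummy_ensemble(6), "E_then_pcaRMSD", pool_size=3,
                           records=recs)
    assert rep.pool == [1, 2, 3]
    assert rep.best_model == 1


def test_two_stage_select_degenerate_pool():
    pairs = [(float(i), float(10 - i)) for i in range(10)]
    recs = _records(pairs)
    ens = _dummy_ensemble(10)
    rep = two_stage_select(ens, "E_then_pcaRMSD", pool_size=1000, records=recs)
    assert sorted(rep.pool) == list(range(1, 11))  # degenerates to everything
    # whole ensemble ranked: best is the global pcaRMSD minimum (model 10)
    assert rep.best_model == min(recs, key=lambda r: r.pca_rmsd).model_index
    assert rep.best_model == rep.top10[0]


def test_two_stage_select_deterministic_and_pool_membership(rng):
    pairs = [(float(e), float(p)) for e, p in rng.normal(size=(40, 2))]
    recs = _records(pairs)
    ens = _dummy_ensemble(40)
    rep1 = two_stage_select(ens, "pcaRMSD_then_E", pool_size=15, records=recs)
    rep2 = two_stage_select(ens, "pcaRMSD_then_E", pool_size=15, records=recs)
    assert rep1.to_dict() == rep2.to_dict()
    assert rep1.best_model in rep1.pool
    assert set(rep1.top10) <= set(rep1.pool)
    with pytest.raises(DomainCheckError):
        two_stage_select(Ensemble([]), "E_then_pcaRMSD")


# ---------------------------------------------------------------------------
# reference evaluation
# ---------------------------------------------------------------------------

def test_reference_rmsd_identity_and_reversal(stack_factory):
    # noise breaks the mirror symmetry of the ideal planar stack, so the
    # identity mapping of a chain-order-reversed copy cannot superpose
    model = stack_factory(sigma=0.5, seed=21)
    assert reference_rmsd(model, model) == pytest.approx(0.0, abs=1e-9)
    reversed_model = OligomerModel(2, model.chains[::-1])
    assert reference_rmsd(reversed_model, model, "identity") > 0.5
    assert reference_rmsd(reversed_model, model,
                          "best_cyclic_or_reversed") == pytest.approx(0.0, abs=1e-6)


def test_reference_rmsd_matches_mapping_enumeration(rng, stack_factory):
    """best_cyclic_or_reversed equals brute force over all 2M orderings."""
    from dockens.structio import kabsch_superpose

    ref = stack_factory(sigma=0.0)
    model = stack_factory(sigma=0.5, seed=11)
    got = reference_rmsd(model, ref, "best_cyclic_or_reversed")
    m = model.n_chains
    candidates = []
    for shift in range(m):
        fwd = [(shift + i) % m for i in range(m)]
        candidates.append(fwd)
        candidates.append([(shift - i) % m for i in range(m)])
    best = min(kabsch_superpose(model.all_calpha(order), ref.all_calpha()).rmsd
               for order in candidates)
    assert got == pytest.approx(best, abs=1e-9)
    assert got <= reference_rmsd(model, ref, "identity") + 1e-12
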