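# dockens

Ensemble analysis of coarse-grained protein–peptide docking poses, for two
structural-biology problems that share the same workflow shape — a docking
engine (e.g. CABS-dock) produces thousands of candidate models, and the
science lives in how those models are scored, filtered and read out:

1. **Amyloid protofilament model selection.** Protofilaments are rod-like
   precursors of amyloid fibrils, commonly built from M identical peptide
   chains stacked in an in-register parallel β-architecture. Given an
   ensemble of candidate M-chain models, `dockens` scores each model by an
   inter-chain interaction energy E and by its translational symmetry,
   measured as the peptide-chain-average RMSD

   $$\mathrm{pcaRMSD} \;=\; \frac{1}{M^2 - M}\sum_{i=1}^{M}\sum_{j=1}^{M}
   \sqrt{\tfrac{1}{N}\sum_{k=1}^{N}\lVert X_k^{i}-Y_k^{j}\rVert^2},$$

   where each chain pair (i, j) is independently superposed (Kabsch, proper
   rotations only) before its Cα RMSD is taken and the i = j terms vanish.
   A true in-register parallel stack has pcaRMSD ≈ 0. Selection is
   two-stage: keep the 1 000 best models on one score, rank them on the
   other (both orders supported). The package also generates the 5 Å
   in-register side-chain distance restraints used to set such dockings up,
   and evaluates models against a reference structure (all-Cα RMSD, with
   optional search over cyclic/reversed chain correspondences).

2. **Protease cleavage-site identification.** For an aspartate protease
   (pepsin, renin, HIV-1 protease), the active-site centre is the midpoint
   of the two catalytic Asp Cα atoms. For every docked substrate pose the
   distance $d_n$ from the carbonyl oxygen of each peptide bond *n* to that
   centre is measured; bonds with $d_n \le 7$ Å count as contacts, and the
   bond with the most contacts over the ensemble is called as the scissile
   bond. Poses can be partitioned by binding direction (the substrate can
   run either way along the cleft of a symmetric homodimer), clustered
   (average-linkage on ligand-RMSD-after-receptor-fit, medoids of the ten
   largest clusters), and analysed for flap state: closed flaps =
   Gly52–Gly52 Cα distance < 12 Å, bound substrate = scissile-bond oxygen
   within 9 Å of the centre.

A `synthgen` module builds seed-deterministic synthetic fixtures — noisy
in-register stacks and pose ensembles with a planted scissile bond around a
compact model protease — with ground-truth tables, so the whole pipeline is
testable without any external data.

Residue addresses everywhere are sequential 1-based positions within a
chain; bond *k* joins residues *k* and *k+1*. Annotated substrate strings
mark the cleavage site with an em-dash (`KPAEF—IRL` → bond 5); `–` and `--`
are accepted equivalents.

## Worked example

Generate a 500-pose synthetic ensemble for the pepsin substrate KPAEF—IRL
(12 % bound poses, planted scissile bond 5), then call the cleavage site:

```sh
dockens synth cleave-ensemble --substrate "KPAEF--IRL" --n 500 \
    --bound-frac 0.12 --seed 7 --out poses.pdb --truth truth.tsv
dockens cleave scan --ensemble poses.pdb --asp A:3 --asp2 B:3 \
    --mode-filter per-mode --axis 1,0,0 --out-dir scan
```

prints

```json
{
  "call": {
    "no_call": false,
    "bond": 5,
    "count": 53,
    "runner_up_bond": 6,
    "runner_up_count": 50,
    "tie": false,
    "mode_policy": "combined",
    "per_mode": {"forward": 5, "reverse": 5},
    "cutoff": 7.0,
    "atom_mode": "carbonyl_O"
  }
}
```

Bond 5 — the planted site — records contacts in 53 of the 500 poses, more
than any other bond; its neighbours score high too (50 and 45) because an
extended substrate threading the cleft keeps adjacent carbonyls within the
7 Å cutoff, which is exactly the histogram shape seen with real docking
ensembles. Both binding directions independently point at bond 5
(`per_mode`). The per-bond histogram is in `scan/histogram.tsv`:

```
bond  count_forward  count_reverse  count_combined
4     18             27             45
5     23             30             53
6     22             28             50
```

For the protofilament side, restraints and two-stage selection on a
synthetic stack ensemble of the 22-residue β2-microglobulin amyloid
peptide:

```sh
dockens protofil restraints --seq SNFLNCYVSGFHPSDIEVDLLK --chains 5 --out restraints.txt
# -> wrote 88 restraints (4 chain pairs x 22 residues) to restraints.txt
dockens synth stack --seq SNFLNCYVSGFHPSDIEVDLLK --chains 5 --sigma 1.0 \
    --n 50 --seed 7 --out stacks.pdb --energies energies.tsv
dockens protofil score --ensemble stacks.pdb --energies energies.tsv \
    --variant e-then-pca --out-dir sel
# -> {"variant": "E_then_pcaRMSD", ..., "best_model": 30, "pool_actual": 50}
```

`sel/scores.tsv` holds the per-model energy and pcaRMSD table,
`sel/selection.json` the ranking, and `sel/manifest.json` a config echo
sufficient to reproduce the run.

The same pipelines are available as library functions
(`dockens.two_stage_select`, `dockens.call_cleavage_site`,
`dockens.flap_state_analysis`, …) operating on ensembles read with
`dockens.read_pdb_ensemble`; per-model energies from an external engine
attach via a `model_index\tenergy` TSV sidecar.

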