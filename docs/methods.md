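# Methods

This note documents the models, conventions and numerical choices behind
`dockens`, and what the synthetic generators do and do not emulate.

## Scope and data model

The package analyses *ensembles* of coarse-grained docking poses; it does
not run docking simulations. A pose is either an `OligomerModel` (M chains,
identical sequences in protofilament mode) or a `ComplexModel` (receptor
chains + one peptide ligand), each carried as Cα traces with optional
backbone N/C/O atoms. Multi-model PDB files (one `MODEL` block per pose)
are read through Bio.PDB; a file without `MODEL` wrapping is a one-model
ensemble. Chains keep file order; altLoc conflicts keep the first location;
insertion codes are rejected rather than silently renumbered. Residues are
addressed by sequential 1-based position within their chain — author
numbering of deposited structures is *not* preserved, so catalytic/flap
residue addresses for real enzymes must be given as sequence positions.
All coordinates and distances are in Å throughout.

Per-model energies normally come from the docking engine; they attach via a
TSV sidecar (`model_index`, `energy`, lower = better).

## Superposition

All fits use least-squares rigid superposition with proper rotations only
(determinant +1; reflections are never allowed), computed via
`scipy.spatial.transform.Rotation.align_vectors`, with index-wise
(sequence-order) correspondence. Degenerate inputs — fewer than three
points, or collinear point sets, where the optimum rotation is not unique —
are flagged but still fitted best-effort. The test suite cross-checks the
kernel against Bio.PDB's independent SVD superimposer and a random-rotation
optimality probe.

## pcaRMSD

The translational-symmetry score of an M-chain model is the full double sum
over ordered chain pairs of the independently fitted pairwise Cα RMSD,
divided by M² − M. The diagonal contributes zero, so this equals the mean
over the M² − M ordered pairs i ≠ j; since the fitted RMSD is symmetric the
implementation computes each unordered pair once and doubles it, which is
exact, not an approximation. pcaRMSD is invariant under rigid motion of the
whole model, independent rigid motion of any single chain, and chain
permutation; it is zero iff all chains are mutually congruent.

## Interaction energy

The statistical potentials used by coarse-grained docking engines are
engine-internal; the shipped contact energy is this package's own simple
stand-in, not a reproduction of any engine's force field. It sums a
pairwise table over all inter-chain residue pairs whose side-chain
reference points lie within 6.5 Å. The default table is a hydrophobicity
product, e(a,b) = −h_a·h_b with h the Kyte–Doolittle hydropathy rescaled to
[0, 1] (so every contact is non-positive and hydrophobic–hydrophobic
contacts dominate — the driving force of amyloid packing). Any 20×20 table
can be supplied; unknown residue types score a neutral 0 with a warning.

Side-chain reference points are derived from the Cα trace: Cα displaced
1.5 Å along the local curvature vector (Cα_i minus the midpoint of its
neighbours, orthogonalised against the chain tangent). This differs from a
fixed-axis Cβ placement deliberately: a curvature-based construction is
exactly equivariant under rigid motion, which the energy's invariance
contract requires, whereas any arbitrary fallback axis for locally straight
backbones would break it. Glycine, terminal residues and locally straight
geometry fall back to the Cα itself. Real side-chain centroids are not
reproduced; only rough contact topology is.

## Two-stage selection

Variant `E_then_pcaRMSD` keeps the `pool_size` (default 1 000) lowest-energy
models and ranks them by ascending pcaRMSD; `pcaRMSD_then_E` mirrors it.
Ties break toward the lower `model_index` at every stage, making selection
fully deterministic; a pool larger than the ensemble degenerates to the
whole ensemble (logged). The top-10 list is the head of the stage-2
ranking, and `best_model == top10[0]` by construction.

Reference evaluation superposes the whole model once (all Cα atoms) under a
chosen chain correspondence. Default is identity — in restraint-guided
setups the restraints fix chain order — with `best_cyclic_or_reversed`
minimising over the 2M cyclic shifts and reversals for references whose
deposition order may differ.

## In-register restraints

One restraint per residue per adjacent chain pair, (M−1)·L records, between
side-chain centres of the *same* residue position (Cα for glycine), target
distance 5 Å, the typical inter-strand side-chain separation of in-register
parallel protofilament structures. The text format is one record per line
(`chain_a resid_a chain_b resid_b distance weight`, `#` comments). The
format supports arbitrary residue pairings; only the in-register generator
is provided.

## Cleavage-site protocol

* Active-site centre: midpoint of the two catalytic Asp Cα atoms,
  recomputed per model.
* d_n: Euclidean distance from the bond-n reference point to the centre.
  The default reference is the carbonyl oxygen of residue n (the atom
  attacked during hydrolysis); `calpha_midpoint` (midpoint of Cα_n and
  Cα_{n+1}) is the documented fallback for pure Cα traces.
* Contact criterion: d_n ≤ 7 Å (inclusive). Flap and bound criteria are
  strict: flap closed at < 12 Å, substrate bound at < 9 Å. A frame exactly
  at a threshold counts open / unbound. These boundary conventions are
  fixed and tested.
* Histogram: every bond within the cutoff increments its own count, so one
  pose may increment several bonds — per-bond tallies, not a
  one-bond-per-pose assignment. The call is the argmax (ties toward the
  lower bond, flagged and logged); the runner-up is always reported as
  confidence evidence; an all-zero histogram is a distinct no-call error.
* Binding mode: the substrate of a symmetric homodimeric protease can run
  either way along the cleft. A pose is `unbound` if no bond is within the
  cutoff; otherwise the sign of the dot product between the local N→C
  direction at the closest bond and a user-supplied reference axis decides
  forward/reverse. The axis is configuration (e.g. taken from an inhibitor
  crystal pose), not inference; a zero dot product counts forward. For
  asymmetric enzymes (pepsin, renin) the histogram is restricted to the
  productive direction (`mode_filter=forward`); for symmetric enzymes both
  per-mode histograms are kept and the call defaults to their sum
  (`combined`), with `max_over_modes` available.

## Pose clustering

Pairwise pose distance is the ligand Cα RMSD after superposing the
receptors (receptor Cα atoms only; the ligand is *not* refit, so the
distance measures binding-pose difference, not ligand conformation alone).
Agglomerative clustering uses average linkage by default (the linkage is a
parameter; no single linkage is canonical for pose clustering) and the tree
is cut into exactly `k_keep` clusters. Representatives are the medoids —
the member minimising summed intra-cluster distance, ties toward lower
`model_index` — of the `k_keep` largest clusters, ordered by descending
size (ties by smallest member index). Fewer models than `k_keep` returns
every model as a singleton with a warning. The O(n²) distance matrix is the
cost driver; it is exact (no sketching), which is comfortable up to a few
thousand poses.

## Flap-state analysis

Per frame: bound := scissile-bond d < 9 Å; closed := flap-residue Cα–Cα
distance < 12 Å. The report gives P(closed | bound) and
P(closed | unbound) plus the full frame table for scatter plots. With no
bound frames the conditional is NaN with an explicit zero count rather than
an exception.

## Synthetic generators

`build_ideal_stack` lays extended chains (Cα spacing 3.8 Å) along x and
stacks M of them along z at a 4.8 Å rise — the canonical cross-β
inter-strand spacing; at that rise the in-register side-chain pair
distances sit near the 5 Å restraint target. Backbone N/C/O atoms are
placed with idealised trans-peptide offsets (carbonyl O ≈ 2 Å from the
bond's Cα midpoint). Noise is i.i.d. Gaussian per coordinate of every
atom — there are no correlated backbone modes, no β-twist, no rotamers, so
passing noise-response tests says nothing about those features of real
ensembles. Ensemble generation records per-model σ and a contact-count
energy proxy (−number of inter-chain contacts) in a truth table.

`make_cleavage_ensemble` plants poses around a compact synthetic two-chain
model protease (22 residues per chain, mirror-symmetric lobes flanking a
cleft; catalytic residues at position 3 put the active-site centre at the
origin; flap tips at position 22 hover above it). Bound poses (fraction
`bound_fraction`, default 0.12) keep the ligand extended through the cleft
along ±x with a small random tilt (≤ 20°); the carbonyl oxygen of the
*centred* bond lands at the centre plus a Gaussian jitter (sd
`bound_noise_sigma`, default 1.0 Å). The centred bond is the planted bond
or, with probability 0.2, a ±1 register-slipped neighbour: register slip is
what produces the secondary histogram peaks seen in real docking ensembles,
and without it the ±1 neighbours of an extended ligand (adjacent carbonyls
~3.8 Å apart) would exactly tie the planted bond at the 7 Å cutoff. The
jitter norm is capped at (7 − margin − 3.8·|slip|) Å, margin 1 Å, so the
planted bond always stays within 6 Å — every bound pose contributes to the
planted bond's count by construction. Decoys are random rigid placements
whose nearest atom is at least `decoy_radius` (default 25 Å, validated
against the receptor extent) from the centre, guaranteeing the unbound
classification and clean truth bookkeeping — uniform-in-a-box decoys would
need per-decoy geometric checks instead. Optional flap coupling draws the
closed state per model from P(closed | bound) / P(closed | unbound) and
sets the flap separation uniformly in (7, 11) Å when closed and (13, 18) Å
when open, keeping samples off the strict thresholds.

All generators are driven by one `numpy.random.default_rng(seed)` stream,
so identical parameters give byte-identical PDB output.

## Test and fixture sizes

The seeded sweeps in the acceptance-style tests use 100 seeds × 500 poses
for planted cleavage recovery (12 % bound, σ = 1.0 Å), a 2 000-frame
trajectory for flap conditional recovery (± 0.03 at that sample size is a
~3 standard-error band), 50 seeds for pcaRMSD noise ordering across
σ ∈ {0.2, 0.5, 1.0, 2.0} Å, and 100 seeds × 30 poses for cluster recovery;
together with the unit tests the suite completes in well under a minute.
These sizes were chosen as the smallest at which the binomial/ordering
margins are decisive, and are stated here as the package's own defaults.

## Known limitations

* The contact potential is a coarse hydrophobicity stand-in; absolute
  energies are meaningless and only rankings within one ensemble are used.
* Published headline accuracies of restraint-guided protofilament
  prediction and docking-based cleavage-site assignment depend on the
  upstream docking engine's sampling and force field; this package
  reproduces the *analysis* layer, and its tests certify that layer on
  synthetic ensembles with known truth, not end-to-end prediction accuracy
  on real systems.
* No mmCIF, no hydrogens, no residue repair; PDB numbering is rewritten
  sequentially on output.
* The binding-direction rule (dot-product sign at the closest bond) is one
  operationalisation of "same orientation as the inhibitor pose"; strongly
  bent ligands near the site could be direction-ambiguous.
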