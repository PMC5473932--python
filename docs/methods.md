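# Methods

This note documents the models, conventions and numerical choices behind
`mdrin`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate conventions and features

Residue numbering is 1-based (as in PDB files); internal atom indices are
0-based and never serialized. Only chain A is read unless another chain is
requested. Alternate locations beyond the first are ignored.

Domain centers are the **unweighted mean of the domain's Cα coordinates**,
not an all-atom center of mass. Superposition and PCA are likewise
Cα-based, so a single convention runs through the geometric layer; a
different center definition would shift R/Θ/Φ values slightly but not the
analysis structure. "Backbone" RMSD uses N, Cα, C, O where present and
falls back to Cα-only on coarse (Cα-pseudo-atom) fixtures.

The torsion Φ_abb′a′ of the ordered domain centers follows the IUPAC
right-handed sign convention with range (−180°, 180°] (cis = 0, trans =
180°); the sign matches biotite's `dihedral`, which the tests use as an
independent reference. Angles at coincident centers are undefined and
propagate as NaN for that frame rather than raising.

Residue-pair distances d_ij are Cα–Cα Euclidean distances. The full
per-frame matrix is materialised only for explicit residue subsets;
configured pairs (e.g. catalytic Cys pairs 53–56 and 397–400 of hPDI)
stream through the same code path via `residue_pair_distances` — there is
no separate implementation to diverge.

## Superposition, DCCM, PCA, FEL

Each frame is fitted to the reference by the least-squares rigid-body
(Kabsch) transform over the fit selection's Cα atoms (SciPy's
`Rotation.align_vectors`), typically the b+b′ base so that hinge motions
of the terminal domains remain visible. Fitting can only decrease the
fit-selection RMSD; the tests assert this frame by frame.

The cross-correlation matrix uses the standard normalised displacement
form C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with Δr taken from the
per-atom trajectory mean. Zero-variance atoms have undefined correlation
and are reported as NaN rows/columns rather than zeros.

PCA diagonalises the covariance of the (frames × 3N) Cα coordinate matrix
(scikit-learn, full SVD, which handles both the 3N ≤ frames and
frames < 3N shapes). All min(frames, 3N) components are kept so the
eigenvalue sum equals the total coordinate variance (asserted to 1e-6
relative); a motionless trajectory yields all-zero eigenvalues instead of
an error. Sampling convergence is checked by the absolute inner products
of eigenvectors fitted on data halves.

Free-energy landscapes are Gaussian KDEs on a pair of principal-component
projections, reported as F = −ln(p/p_max) in k_BT so the global minimum is
exactly 0 (the temperature never enters). The default bandwidth is
Scott's rule for d = 2 with an isotropic kernel, h = n^(−1/6)·σ_pooled,
user-overridable; the grid pads the data range by three bandwidths, and
local minima are interior grid cells strictly below all eight neighbours.
Densities from several trajectories of one state are pooled. No basin
clustering or barrier analysis is attempted.

## State classification

The linear discriminator scans candidate thresholds at the midpoints of
consecutive sorted unique training values plus one candidate below the
minimum and one above the maximum, in both inequality directions, and
keeps the training-accuracy maximiser. Ties are broken by the larger
margin (distance from the threshold to the nearest training value; the
two outside candidates sit at distance 1 by construction), then by the
direction that labels the high side with the lexicographically first
class ("ox" before "red"), then by the smaller threshold — fully
deterministic. A property test checks exact agreement with a brute-force
scan over all 2·(u+1) candidates. Because the rule is rank-based,
accuracy is invariant to strictly monotone feature transforms.

The SVM comparison uses an RBF kernel with the common library defaults
(C = 1, γ = 1/(p·Var)), recorded in the output. Train/test is a single
random split with P(train) = 1/2 per snapshot — not cross-validation —
and both classifiers report test-split accuracy for comparability; when
no split is given, accuracy is reported on all data (both conventions are
available, since reported single-threshold accuracies in the literature
are sometimes computed on all data). The mechanism the benchmark encodes:
on unimodal class distributions a single threshold is already
Bayes-adequate and the SVM matches it within sampling noise, while a
bimodal class (two modes flanking the other class) defeats any single
threshold but not the RBF kernel — hence the ≥ 15-point gap asserted on
the half-N(−4,1) + half-N(4,1) vs N(0,1) benchmark. The residue-pair
discrimination matrix applies the threshold classifier to every d_ij,
with the diagonal fixed at 0.5 and entries floored at 0.5 (a pair that
cannot beat a coin flip is uninformative).

## Residue interaction networks

Per-frame contact detection uses declared geometric criteria (an
interpretable, versioned stand-in for black-box contact tools):

| type | rule | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance; D–H···A angle gate when an H is bonded (< 1.3 Å) to the donor, heavy-atom-only fallback otherwise | ≤ 3.5 Å, ≥ 120° |
| salt bridge | charged-group centroid distance, {Arg, Lys, His} vs {Asp, Glu} | ≤ 4.0 Å |
| van der Waals | heavy-atom distance ≤ r_i + r_j + slack | slack 0.5 Å |
| π-π | aromatic ring-centroid distance | ≤ 6.5 Å |
| cation-π | cation center to ring centroid | ≤ 6.0 Å |

Sequence neighbours (|i−j| < 2) are excluded: covalent neighbours are not
non-covalent contacts. All cutoffs ship as a YAML-serialisable config and
are user-overridable; exact numerical agreement with any specific external
contact program is not a goal, since such tools' internal parameters vary.
A pair may carry several typed edges at once. Detection is deterministic
and rigid-motion invariant (all rules are internal distances/angles); a
conservative centroid-distance gate prunes far-apart residue pairs without
affecting results. Synthetic fixtures attach labelled pseudo-atoms (DON/HD,
ACC, POSC, NEGC, RNGC) that stand directly for donor, acceptor,
charge-center and ring-centroid groups, so detection is testable at desk
scale without side-chain chemistry.

## DRIN and the differential network

`max_lifetime` returns the longest run of consecutive 1s in A_ij(t) — the
largest window length τ for which some start τ₀ gives an all-ones window.
A pair that never interacts has an empty window set and Γ = 0 by
convention, and zero-lifetime edges are dropped from the graphs. Γ is
monotone under switching any frame on. When a state has several
independent trajectories, Γ is computed per trajectory and combined by
maximum (`combine_drins`): a "consecutive" run spanning a boundary
between independent simulations would be physically meaningless. Γ is
stored in frames, with any frame→time conversion carried as metadata,
because frame spacing is an input-data property.

Δ_ij = log2((Γ_ox + ε)/(Γ_red + ε)) is evaluated as a **difference of
logarithms**, which makes the antisymmetry Δ(ox,red) = −Δ(red,ox) exact
in floating point (the log-of-ratio form is off by an ulp). The
pseudocount default ε = 1 frame makes Δ a well-behaved shrunken log fold
change; it is config-exposed and recorded in outputs. The default cutoff
|Δ| ≥ 1 keeps pairs whose persistence changed at least two-fold — an
interpretable default that reports should always state explicitly.

The merged graph keeps parallel typed edges, sets node size to the
maximum |Δ| over incident edges, and maps |Δ| to an edge display weight
2/(1+e^(−|Δ|)) − 1 ∈ [0, 1). Exports are GraphML (round-trips all weights
to < 1e-9) or SIF plus node/edge attribute TSVs; in the TSVs, Δ and the
display weight are written with `repr` so the round trip is exact.

## Synthetic data: what it emulates, and what it does not

The generator builds domains as compact Gaussian blobs of Cα pseudo-atoms
(sd 3 Å) spaced 18 Å apart on a line, joined by 3-residue linkers, with
four domains tagged a, b, b′, a′, the first linker L1 and the terminal
linker the x-linker. The terminal domain rotates rigidly about a unit
axis through the terminal-linker centroid by amplitude·sin(2πt/T), with
independent per-atom Gaussian jitter — a minimal model of a hinge motion
over a static bb′ base. The planted mode vector (u × (x − c) on the
terminal domain, zero elsewhere) is exposed for PCA-recovery checks. A
variant translates the two terminal domains in exact anti-phase to plant
block anti-correlation. Default conditions used by the benchmarks:
20° hinge amplitude, 0.05–0.1 Å jitter (small thermal noise against a
multi-Å collective motion), 1,000–2,000 frames — chosen once as a
desk-scale regime where the planted signal dominates sampling noise the
way a stable collective mode dominates a converged trajectory.

Scripted interaction schedules place each residue pair at its own site
60 Å from the others; the mobile group atom sits at the interaction
type's on-distance in on-frames and 20 Å away otherwise, so geometric
detection recovers the scripted binary series exactly. Schedules realise
an exact longest run (plus optional extra on-frames in runs no longer
than the target, separated by at least one zero). One caveat: a scripted
hydrogen-bond pair also registers as a van der Waals contact (N···O at
2.9 Å is within the radii sum), exactly as in real structures; tests
therefore verify the scripted (pair, type) channel.

All randomness flows from a single integer seed expanded into fixed
per-operation substreams, making every generated artifact bit-identical
across runs and the full pipeline byte-identical in its exports.

These fixtures validate the *machinery* — recovery of planted modes,
lifetimes and separations — not the *science* of any real system: there is
no force field, no solvent, no realistic energy landscape, and feature
distributions are specified rather than emergent. Passing tests show the
statistics are computed correctly, not that a particular protein behaves
any particular way.

## Known limitations

- Contact chemistry is geometric only: no energy weighting, no
  solvent-mediated or disulfide contacts, His is always treated as
  protonatable (counted among cations and H-bond donors/acceptors).
- The DCD/XTC path requires MDAnalysis and takes the file's chain
  assignment at face value.
- The linear-threshold scan is O(n log n) per feature, but the full
  residue-pair discrimination matrix is O(R² n log n) and intended for
  residue subsets, not all ~500² pairs at full trajectory length in one
  call (stream pairs of interest instead).
- FEL minima detection uses strict 8-neighbour comparison on the grid;
  plateaus at machine precision would report no minimum.
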