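# Methods

## Model

A structural unit — a chain, a domain, or a domain composed of fragments of
several chains — is represented by one effective atom per residue, the
unweighted arithmetic mean of the residue's atom positions (hydrogens
included when present in the deposited coordinates).  The unit is assessed by
comparing four normalized per-residue distributions of length N:

- **T**: a separable 3D Gaussian evaluated at the effective atoms.  The
  envelope is fitted to the unit itself: centre at the mean effective
  position; axes along the principal axes of the effective-position
  covariance, so the result does not depend on the deposited coordinate
  frame; per-axis sigma from the *3-sigma bounding rule*,
  `σ_axis = max |coordinate along axis| / 3` after centering and rotation.
  The multiplier is configurable (`sigma_multiplier`); a floor of 1 Å guards
  degenerate (collinear/coincident) geometry and is reported with a warning.
- **O**: `O_i ∝ Σ_{j≠i, r_ij ≤ c} (H_i^r + H_j^r) · w(r_ij/c)` with the
  quartic-in-x² contact polynomial `w(x) = 1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸)`,
  which decays smoothly from 1 at contact to 0 at the cutoff.  Distances are
  between effective atoms, consistent with the single-point representation.
  The self term `j = i` is excluded by default (the quantity is an
  *inter*-residue interaction); `include_self=True` restores it for
  sensitivity checks.  A unit in which every pairwise weight is zero has no
  observed distribution and is reported as a degenerate-profile error.
- **R**: the uniform distribution `1/N`.
- **M(K)**: `M_i ∝ T_i + K (T_MAX − T_i)`, normalized, with `T_MAX` the
  maximum of the unit's normalized T values (not the analytic Gaussian
  peak).  `K = 0` gives T; `K = 1` gives the uniform distribution; `K > 1`
  tips toward the inverted, membrane-like pattern.

Divergences are Kullback–Leibler with base-2 logarithms (bits).  `O_i = 0`
terms contribute zero; T is strictly positive by construction so `D(O|T)` is
always defined.  `RD = D(O|T) / (D(O|T) + D(O|R))`; the degenerate case of
both divergences vanishing returns RD = 0 with a warning.  RD is compared
with 0.5 unrounded; tables print 3 decimals.

`K` is fitted by grid search minimizing `D_KL(O | M(K))` over `[0, 10]`:
coarse step 0.1, then 0.01 refinement in the bracket around the coarse
minimum, ties toward smaller K.  Minimizing the divergence to M is the
natural objective in this machinery (it reduces to the RD numerator at
K = 0); observed K values for real proteins rarely exceed ~2.5, so the
bound 10 is conservative.  K resolution is 0.01; table outputs round to one
decimal.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| scale | bundled Black & Mould (1991), min–max rescaled to [0, 1] | intrinsic residue hydrophobicity `H^r`; swappable via two-column TSV |
| cutoff `c` | 9.0 Å | interaction range of the contact polynomial |
| `sigma_multiplier` | 3.0 | extent-to-sigma divisor of the envelope fit |
| `sigma_floor` | 1.0 Å | minimum sigma for degenerate geometry |
| `k_max`, `k_step` | 10, 0.1 | K grid bounds (refined at 0.01) |
| `model_index` | 0 | model used from multi-model (NMR) files |
| `tau` | 0 | threshold on `O_i − T_i` for excess/deficiency calls |

Structure handling: author (PDB) numbering with inclusive ranges; insertion-
coded residues are kept in file order within a range; for altloc atoms the
highest-occupancy conformer wins (ties by altloc letter); common
non-standard residues (MSE, SEC, ...) map to their standard parent for scale
lookup and unmapped ones are excluded with a warning; waters and
non-amino-acid heterogens are dropped; missing side chains are tolerated —
the effective atom averages whatever atoms are present.

Multi-chain selections (`A:198-221+C:224-298`) are treated as one body: one
envelope over all selected residues.  The "without guest" status re-fits the
envelope on the host residues alone as a fresh unit.  Mutant-profile
averaging aligns structures by the intersection of `(chain, seq_id)` keys —
no sequence alignment — and reports arithmetic means with *population*
standard deviations (divide by n).

## Synthetic generators

The generators emulate the hydrophobicity statistics the pipeline measures,
not protein geometry (no bonds, no secondary structure):

- `make_micelle`: n points from an isotropic 3D Gaussian (σ = 8 Å); each
  point's `H^r` is its own T value min–max rescaled to [0, 1], the simplest
  rule that makes O track T through the distance weighting.  Frozen
  regression: RD < 0.15 and K ≤ 0.1 at n = 100.
- `make_uniform`: a cubic lattice whose diagonal is 25 % of the cutoff, so
  every pair interacts at near-unit weight and O is flat to within 0.1/N,
  while T stays strongly peaked: RD > 0.85.  Such a compact cloud
  deliberately trips the envelope's degenerate-geometry floor; the warning
  is expected.  A 1 % seeded jitter distinguishes seeds.
- `make_modified(k_true)`: Gaussian cloud (σ = 5 Å — dense enough that the
  inverted target is representable with non-negative H); `H^r` is the
  non-negative least-squares solution of the linear map
  `(W + diag(rowsum W)) H = M(T, k_true)`, where W is the pairwise weight
  matrix, making O ≈ M(T, k_true) by construction.  Fitted K recovers
  `k_true ∈ {0.5, 1, 2}` within ±0.2 across seeds at n = 200.
- `make_swapped_pair`: one micelle cloud split at the median of the first
  coordinate into a host chain A and guest chain B.  With `complete=True`
  the guest keeps the joint-core hydrophobicities and the combined unit
  scores a lower RD than the host alone; with `complete=False` the guest's
  H values are inverted (`h → h_max − h`) and the combined unit scores no
  better.

Because O is steered directly, passing tests demonstrate the statistical
machinery (profiles, divergences, RD, K fit, envelope invariances) — they do
not validate the hydrophobicity scale or the contact polynomial against
experimental structures, and real proteins carry sequence and packing
correlations the generators do not emulate.

## Numerical choices

- T is computed in log space with max subtraction before exponentiation.
- Envelope axes come from `eigh` of the covariance (descending variance);
  an improper frame is fixed by flipping the third axis.  Axis sign is
  irrelevant to T (the Gaussian is even).
- The K grid always contains K = 0, so `D(O|M(K*)) ≤ D(O|T)` holds exactly.
- Fixture files carry 6-decimal coordinates and hydrophobicities; round
  trips are lossless at that precision.
- Exclusion-based re-assessment (`rd_excluding`) always rebuilds the unit
  from scratch; eliminating nothing reproduces the original status exactly.

## Design notes and limitations

- The paperless constants of the wider FOD literature (exact intrinsic
  scale, cutoff, sigma convention) vary between publications; this package
  fixes one documented convention each (Black & Mould scale, 9 Å cutoff,
  3-sigma principal-axis rule) and exposes all three as configuration, so
  published table values from other implementations should be expected to
  agree qualitatively (which units fall below/above RD = 0.5) rather than
  to the third decimal.
- Removing a unit's single most O-excess residue does *not* always lower
  RD: the envelope is re-fitted to the reduced unit, and for already
  core-like units the geometric shift can outweigh the removed mismatch.
  Elimination analysis is therefore user-driven (explicit fragments, as in
  loose-loop elimination), not an automated search.
- Problem sizes in the test and acceptance runs (n = 100–200 residues,
  5 seeds per condition) are the package's frozen study conditions; each
  assessment is O(N²) in memory and time and completes in milliseconds at
  these sizes.
- No biological-assembly expansion, structure repair or superposition;
  units are defined on deposited chains.  Interface/catalytic annotations
  are user-supplied, never computed.
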