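# Methods

This note documents the models and numerical choices behind `polyforge`,
what the bundled synthetic systems do and do not emulate, and where the
design was genuinely open.

## Residue-level graph matching

Links are matched on the residue graph, not at the target resolution, which
keeps the subgraph-isomorphism problem small (patterns of 2–4 residues on
graphs of arbitrary size). Matching is *induced*: a pattern edge must map
to a graph edge and a pattern non-edge to a non-edge. Consequence worth
knowing: a 3-node angle pattern has no match inside a triangle of residues,
while it matches every site of larger cycles. Matches that cover the same
residue set (the two orientations of a symmetric bond link, say) are one
physical site and are reported once, with the orientation of the lowest
mapped node id. Links apply in library file order; when two links produce
an interaction on the same atom tuple and directive, the later one wins.
Both conventions are contracts of this package — nothing in GROMACS forces
either — and the matcher is continuously cross-checked in the test suite
against an exhaustive injective-map enumerator on hundreds of random
graph/pattern pairs.

## Residue templates and the super-CG model

Template coordinates come from a two-step embedding: a 3-D Kamada-Kawai
layout of the residue's bonded graph (edge lengths set to equilibrium bond
lengths, initial positions drawn from a seeded generator, default seed 42,
so templates are bit-reproducible) followed by L-BFGS minimization of the
bonded energy. The energy uses harmonic bonds (constraints as stiff bonds,
k = 5·10⁴ kJ mol⁻¹ nm⁻²), harmonic angles, cosine proper dihedrals,
harmonic signed impropers, and a short-range quadratic repulsion that keeps
nonbonded atoms at least ~0.1 nm apart. Convergence: gradient tolerance
1e-6, at most 2000 iterations; a bond further than 10% from its equilibrium
length after minimization is an error, not a warning. Chirality is kept by
signed improper dihedrals: a minimized improper with the wrong sign
triggers a reflection of its first atom through the plane of the other
three and a re-minimization (up to five passes).

The super-CG bead radius is `rho = sqrt(5/3)·R_g + r_a`: the first term
converts the unit-weight radius of gyration of the template into the
radius of a uniform sphere with the same R_g, the second accounts for the
finite size of the atoms themselves (`r_a`, default 0.21 nm, configurable
per library). Pair diameters combine additively, `sigma_ij = rho_i +
rho_j`, and the LJ well depth is fixed at 1 kJ/mol — the model only steers
packing during the walk and is never meant for dynamics. The exact mapping
from R_g to a hard radius is a documented choice of this package; the
scaling experiments below are insensitive to its prefactor because all
lengths scale together.

## The constrained random walk

Growth follows a breadth-first traversal of the molecule's residue graph,
so graph-adjacent residues are spatially adjacent and branched molecules
pose no special case. Defaults, all configurable through the build file:

| parameter | default | meaning |
|---|---|---|
| `f_max` | 5·10⁴ kJ mol⁻¹ nm⁻¹ | per-pair LJ force above which a trial placement is rejected |
| step length | 0.8·sigma_ij | distance between bonded beads |
| `max_attempts` | 100 | trials per bead before backtracking |
| `backtrack` | 10 | beads removed and regrown after a failure |
| `max_restarts` | 50 | backtracks before the build errors out |
| grid spacing | max sigma | start-point lattice for molecule placement |

The rejection criterion is the *maximum per-pair* force, not the vector
sum: pair forces are what the self-exclusion guarantee is stated in (no
nonbonded pair closer than the distance where the LJ force equals
`f_max`), and summed forces could cancel between opposing neighbors and
admit overlaps. Bonded neighbors are exempt. Neighbor queries use scipy's
periodic cKDTree over finished molecules plus a brute-force scan over the
growing chain; all distances are minimum-image under the rectangular box.

Distance restraints `(u, v, d*, tol)` bound every step: while `g` bonds
remain between the current bead and the restrained partner, the distance
to the anchor must stay inside `[d* − g·s − tol, d* + g·s + tol]` (`s` the
step length) — the bound is exactly the reachability condition and
tightens to the bare tolerance at the restrained bead. Infeasible
restraints (target beyond the stretched contour) are rejected before any
walking. Steps under an active bound sample their direction uniformly on
the feasible spherical cap rather than by naive rejection; because the
direction cosine towards any axis is uniform for isotropic directions, the
two procedures draw from the identical conditional distribution, but the
cap draw cannot stall when the feasible cone narrows near the end of a
restrained span.

### Persistence lengths

A persistence specification `(l_p, span)` does two things, mutually
consistent by construction:

1. the end-to-end distance of the span is restrained to a draw from the
   worm-like-chain distribution. The sampler realizes a discrete freely
   rotating chain of the span's actual bonds whose direction correlation
   `g` is calibrated (by root finding on the closed summation form
   `⟨R²⟩ = b²[n + 2·Σ_k (n−k) g^k]`) so that its analytic mean square
   end-to-end equals the WLC value `2 l_p L − 2 l_p²(1 − e^{−L/l_p})`
   exactly; samples are bounded by the contour length by construction.
2. the walk itself takes its steps at that same fixed bond-correlation
   angle (uniform azimuth) along the span, so the generated chain *is*
   locally a worm-like chain with the requested persistence length rather
   than a flexible chain that happens to end in the right place.

The second point is a deliberate design decision. Restraining only the
endpoints leaves the chain interior with random-walk statistics (a bridge),
which systematically underestimates the radius of gyration of stiff
chains: closed-form analysis of the bridge ensemble shows its R_G scaling
exponent over N = 8–100 cannot exceed ~0.65 at l_p = 3.2 nm, whereas the
locally stiff chain reaches the expected ~0.71. The flip side, visible in
the acceptance results, is that a constant-l_p worm-like chain is *more
expanded than real high-salt ssDNA*: at l_p = 1.4 nm the WLC closed form
itself gives an R_G exponent near 0.66 over this length window, and the
built chains measure ~0.61 — real chains at high salt scale closer to
0.55–0.57, which no single constant-l_p chain model reproduces across this
window. The monotonicity v(3.2 nm) > v(1.4 nm) holds in every batch.

## Backmapping

Template placement is exact by construction: the template is centered on
its bead (per-residue center of geometry equals the bead position to
machine precision), rotated by the closed-form orthogonal-Procrustes
solution aligning connector atoms with their bonded neighbors (already
backmapped neighbors contribute their target-resolution positions,
not-yet-built neighbors their beads), and scaled about the bead by the
fudge factor (default 0.45), so intra-residue distances are exactly
fudge × template distances. Rank-deficient connector sets (zero or one
connector) resolve to the identity and to the minimal-angle rotation
respectively, making the output deterministic. The final relaxation is
left to the user's MD engine; `gen-coords` reports the worst residual
inter-residue contact so obviously broken placements are visible before
minimization.

## Synthetic systems: what they emulate, what they do not

The bundled libraries are deliberately minimal: `bead_spring` (one bead,
harmonic bond + angle links), `vinyl3` (three atoms with a cross-residue
improper for chirality handling), and `nucleotide1`, a one-bead thymine
surrogate with 0.63 nm per base and a bead radius of 0.43 nm derived from
the molecular volume of a nucleotide (~322 g/mol at ~1.6 g/cm³). They
exercise every pipeline stage — parsing, matching, templates, walking,
backmapping, writing — without any external parameter files.

The ssDNA experiment builds 100 replicas per length in {8, 16, 50, 65,
100} bases in dilute boxes (edge 1.2× the contour length), at persistence
lengths 3.2 nm and 1.4 nm, and fits `R_G = A·N^v` on the per-length mean
radii (unweighted least squares on log-log data). The surrogate captures
chain-level statistics — stiffness, self-exclusion, contour geometry —
but none of the chemistry: no charges or ionic screening, no base
stacking, one bead where an all-atom nucleotide has ~30 atoms. Passing
results therefore validate the walk engine's chain statistics, not ssDNA
thermodynamics. The melt fixtures likewise size their cubic boxes from a
bead volume fraction (default 0.4, capped below random close packing) and
validate packing and self-exclusion, not any specific polymer's density.
The ideal-chain control (stiffness and exclusion disabled, N up to 512)
ties the engine to the exact random-walk exponent v = 1/2.

Problem sizes throughout (replica counts, chain lengths, melt sizes) are
chosen so the full suite runs in minutes on one core while keeping fit
standard errors well below the tolerances asserted.

## Known limitations

- Rectangular periodic boxes only; no triangulated boundary surfaces.
- Only GROMACS-dialect files are written; no preprocessor conditionals
  (`#define`/`#ifdef`) are honored on reading.
- Molecules with rigidly defined geometry (double-stranded DNA) are out of
  reach of the one-bead walk.
- Link semantics support interaction addition and same-tuple replacement,
  not removal or charge rebalancing at junctions.
- The walk ensemble is a growth ensemble, not a Boltzmann ensemble: it is
  meant to produce relaxable starting structures, and melt-scale agreement
  with ideal-chain statistics is its calibration point.
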