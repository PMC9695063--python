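# Methods

## Model

A protein is reduced to a chain of N hard spherical beads centred on the
C-alpha atoms, joined by rigid sticks whose lengths are the native
C-alpha–C-alpha distances (2.9 Å for cis peptide bonds, 3.8–3.9 Å for
trans).  Beads have a uniform radius of 1.7 Å (the C-alpha van der Waals
radius); no non-bonded pair (sequence separation ≥ 2) may come closer than
two radii.

The potential is structure-based (Gō-type): only native contacts interact.
Two residues form a native contact when the smallest distance between any
two of their heavy atoms is ≤ 4.5 Å in the native structure and their
sequence separation is at least 2.  The energy of a conformation {r_i} is

    E = ε Σ_{(i,j) native}  φ(d_ij) · c_ij ,
    φ(d) = [ ((d − d_ij^nat)/w)² + 1 ]⁻¹ ,
    c_ij = χ_ij χ_ij^nat + χ_ji χ_ji^nat + ½ ,

with ε = −1 (reduced units, k_B = 1) and w the half-width of the
inverse-quadratic contact well.  The chirality χ_ij = Θ((r_i − r_j) ·
[(r_{j+1} − r_j) × (r_{j−1} − r_j)]) − ½ takes the values ±½ (Θ(0) = 0 by
convention, so an exactly coplanar geometry counts as −½).  The factor
c_ij is 1 when both orders match the native chirality, ½ when one matches,
and 0 for the full mirror geometry, so the native state is the global
minimum at E = −Nc while its mirror image gains nothing from the contact
wells.  When i or j is a chain terminus the corresponding χ is undefined;
that product is replaced by its native-matching value +¼, which keeps
terminal contacts attractive without ever penalising them and reduces to
the defined formula everywhere else.

A native contact counts as *formed* when |d_ij − d_ij^nat| < w (strict
inequality); Q is the formed fraction and serves as the folding reaction
coordinate.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| ε | −1 | reduced energy | energy per native contact |
| w | 1.0 | Å | well half-width; larger w → higher Tm, broader (less cooperative) transition.  For quantitative work w is tuned until the CV peak's FWHM/Tm falls in 4–5 %, the experimentally calibrated two-state range |
| bead radius | 1.7 | Å | hard-sphere exclusion; also guarantees topology preservation (below) |
| contact cutoff | 4.5 | Å | heavy-atom contact definition |

## Move set and linear topology preservation

One Monte Carlo step (mcs) is one elementary move per replica: a crankshaft
(rotation of an interior window about the axis through its two flanking
beads) or a pivot (rotation of a terminal segment about a uniformly random
axis through the bead bounding it), chosen with probability ½ each.  The
moving-set size is uniform on {1, …, m_max} with m_max the largest integer
strictly below 3N/4; infeasible (kind, size) draws are redrawn.

In the linear-topology-preserving (LTyP) variant the rotation angle is
drawn uniformly on the *free rotation interval*: for every (moving bead,
fixed bead) pair that can reach contact distance, the clockwise and
counter-clockwise contact angles are solved in closed form on the rotation
circle (law of cosines), and the per-pair free arcs are intersected into
the maximal connected clash-free arc containing zero.  Pairs whose closest
possible approach exceeds the contact distance are pruned by an exact
bound (axial offset and radial gap); the pruned computation is
oracle-tested against an unpruned dense angular scan.  Two numerical
choices matter:

- Interval bounds are genuine contact angles on the circle and may extend
  beyond ±π.  Clipping them to ±π would shorten the arc by a
  state-dependent amount, making the proposal density asymmetric between a
  move and its reverse and biasing the sampler (this was observed
  directly: a zero-energy chain sampled with clipped intervals fails a
  Kolmogorov–Smirnov comparison against a rejection-sampling oracle; with
  the unclipped arc it passes).  The arc width is invariant under the
  move, so the LTyP proposal is exactly symmetric.
- An arccos argument within 1e−12 of ±1 is clamped; grazing contact
  (distance exactly two radii) counts as allowed.

Because every moving–fixed pair is screened along the whole rotation path,
and because the bead radius 1.7 Å exceeds (3.9 Å/2)(√2/2) ≈ 1.38 Å — the
radius below which two bonded sticks could intersect with all four beads
disjoint, the worst case being a perpendicular mid–mid crossing — LTyP
moves can never take the chain across itself.  The package recomputes the
1.38 Å bound numerically by maximising the minimal bead–bead distance over
intersecting stick-pair geometries rather than hard-coding it.  Non-LTyP
moves rotate by an unrestricted angle uniform on (−π, π] and only screen
the endpoint conformation; the move may legally pass the chain through
itself, which is exactly the property under study.

## Replica-exchange Monte Carlo

Replicas sit on a strictly increasing temperature ladder.  The default
ladder is geometric (uniform in log T) with the density tripled inside
±10 % of a melting estimate obtained from a short pilot run, implementing
"denser near Tm" without inventing fixed values; production ladders use 64
temperatures, desk-scale checks 8.  Every 10³ mcs (default), adjacent
pairs — alternating even/odd pairing between sweeps — swap conformations
with probability min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]).  Tokens travel
with conformations; completed bottom→top→bottom ladder traversals per
token diagnose exchange mixing.

Determinism: one counter-based RNG stream per replica plus one for
exchange decisions, all derived from the master seed.  A run is a pure
function of (seed, config); checkpoint/resume is bit-identical, which the
test suite verifies.

Relaxation rule: runs shorter than two relaxation units discard their
initial half; runs of n units (n ≥ 2) discard n − 1 units.  The unit is
10⁹ mcs for production scale and configurable so that desk-scale runs
exercise the same rule.  Samples (E, Q, optional knot state, token) are
recorded every sample period (a multiple of the exchange period) after
relaxation.

## Knot analysis

Knot state is computed by: (1) closing the open chain through a sphere of
radius 10× the maximal centroid distance — each terminus extended along a
closure direction, the two sphere points joined by a great-circle arc too
distant to cross the chain; (2) cyclic KMT reduction of the *closed*
polygon — a vertex is deleted whenever its elimination triangle is pierced
by no other segment, with conservative scale-normalised orientation
predicates (ambiguous geometry blocks deletion, which can only delay
simplification, never change the type); (3) Alexander typing on a generic
planar projection of the reduced loop, with exact integer (Bareiss)
determinants at t = −1 and t = −2.  The classification key is
(|Δ(−1)|, odd part of |Δ(−2)|): the Alexander polynomial is defined up to
±t^k, which at t = −2 contributes only a power of two, removed by taking
the odd part.  The key separates all prime knots to six crossings: unknot
(1,1), 3₁ (3,7), 4₁ (5,11), 5₁ (5,31), 5₂ (7,1), 6₁ (9,5); everything
else reports "other".

Two design points deserve emphasis:

- *Reduction happens after closure.*  Open-chain KMT is an isotopy rel
  endpoints only; a loosely knotted arc can legitimately simplify to a
  straight segment by sliding the knot out through the unclosed end gap
  (the package's open reducer demonstrably does this on a smooth trefoil
  arc).  Reducing the closed polygon is exactly type-preserving.
- *The default knot-state call votes over 13 deterministic closure
  directions* (a Fibonacci-sphere lattice; ties break lexicographically).
  A single radial closure is unreliable when a terminus is buried inside
  the hull — the outward ray can thread a knot lobe and untie (or tie) the
  chain, which is observable on the parametric trefoil benchmark.  Voting
  over well-spread directions is the uniform-closure estimator of the
  knot-detection literature, derandomised for reproducibility.  The plain
  radial closure and a seeded random-direction majority remain available.

The knotted core is found by trimming beads from the N-terminus while the
remainder stays knotted, then from the C-terminus, and is reported in the
source residue numbering.  Tails shorter than 15 residues on both sides
classify the knot as shallow, otherwise deep.

## WHAM

Per-temperature histograms over (E, Q, knot state) are combined by
iterating the standard self-consistency equations in log space until the
per-temperature log-normalisers change by less than 1e−8 (cap 1e5
iterations).  Energy bins default to width max(0.05, range/400) reduced
units; Q bins are one per formed-contact count when the contact number is
known.  Adjacent-temperature histogram overlap below 1 % warns; zero
overlap is an error naming the gap.  Canonical curves U(T) and
CV(T) = (⟨E²⟩ − ⟨E⟩²)/T² follow by reweighting; Tm is the CV grid argmax
(error if at a boundary), FWHM interpolates the half-maximum crossings
linearly.  Knotting profiles: pk(T) is the canonical knot-indicator
average; pk(Q) is the knotted fraction per Q bin of the density reweighted
to a reference temperature (default Tm); empty bins are NaN, not zero.

Equilibration is verified by the four-run cross-check: runs started from
the native and from a denatured conformation, each with the LTyP and the
non-LTyP move set, must agree in direct per-temperature U and CV within 3
combined standard errors (block bootstrap: 50 contiguous blocks, 200
resamples, fixed sub-seed) at every ladder temperature.  Agreement across
starting regions and move sets is evidence all four reached equilibrium.
With 2 statistics × 6 run pairs × 8 temperatures the check makes ~100
3-sigma comparisons, so a marginal exceedance on a fully equilibrated
system is possible by chance alone; the report carries the worst deviation
so such cases are inspectable.

## Synthetic model systems

All tests and the acceptance script run on package-generated fixtures; no
structure downloads are required.

- **Hairpin / helix / compact globule** (unknotted): 3.8 Å bonds, contact
  proxy = native C-alpha distance ≤ 6.5 Å at separation ≥ 2 (synthetic
  chains have no side chains; the rule in force is recorded in the
  topology metadata and is deliberately wider than the heavy-atom 4.5 Å
  rule it stands in for).  The hairpin carries a 0.3 Å alternating
  out-of-plane pucker: an exactly planar chain sits on the chirality
  term's Θ(0) discontinuity, where numerical noise after rigid motions
  could flip signs.
- **Open trefoil** (knotted): the parametric curve
  (sin t + 2 sin 2t, cos t − 2 cos 2t, −sin 3t) resampled to equal 3.8 Å
  chords, cut at a lobe tip (t₀ = π, the curve's outermost point) so the
  termini exit the hull as protein termini do — cutting near t = 0 buries
  both ends at the knot's centre and makes every closure marginal.  Its
  contact proxy is 8.5 Å (76 contacts at n = 35): with sparser maps an
  unknotted conformation can satisfy essentially every native well and
  the low-temperature ensemble is not knotted; at 8.5 Å the unknotted
  anneal floor lies ≈ 11|ε| above the knotted thermal band, so the knot
  is genuinely thermodynamically enforced.
- **Denatured starts**: a hot (≈ 2 Tm) non-LTyP run from the extended
  chain, re-seeded until the result is unknotted with Q < 0.2.

What these fixtures do *not* emulate: side-chain packing (contacts are
C-alpha proxies), sequence heterogeneity (ε is uniform), cis bonds, chain
breaks, and the 10⁸–10¹⁰-mcs, 64-replica production scale of real
knotted-protein studies.  Passing desk-scale checks demonstrates that the
machinery — potential, move sets, exchange, knot detection, WHAM — is
correct and that the move-set-independence claim holds on small systems;
it does not reproduce protein-specific melting curves.

## Problem sizes used by the default test run and the acceptance script

Four-run equilibrium equivalence: 15-bead hairpin, 8 temperatures,
2×10⁶ mcs per run.  Knotting profiles: 35-bead trefoil, 8 temperatures,
10⁶ mcs (6×10⁵ in the test suite) with knot state evaluated every 10³
sampled mcs.  Free-interval oracle: 100 random 9-bead geometries against a
10⁻³ rad dense scan.  Energy bound: 10⁴ thermal conformations.  Two-level
WHAM: 2×10⁴ samples at each of 4 temperatures.

## Known limitations

- The Alexander pair (|Δ(−1)|, odd |Δ(−2)|) cannot separate knots sharing
  both values (e.g. composites may collide with "other" prime types); all
  knots named by the typing table are separated, finer invariants are out
  of scope.
- Closure voting with 13 directions can still misclassify conformations
  whose knot state is genuinely closure-ambiguous (open-chain knottedness
  is defined only relative to a closure operator); such states are rare in
  compact sampled ensembles.
- Replica advancement is serial; the per-replica RNG streams make a
  parallel implementation bit-compatible by construction, but none is
  provided.
- The four-run check is a necessary, not sufficient, equilibration test;
  deeply knotted systems can agree transiently before the slow knotting
  coordinate has relaxed.
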