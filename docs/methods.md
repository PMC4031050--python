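# Methods

`tmrebuild` models the structure of an α-helical membrane protein (the
*target*) starting from a single, possibly distant, homolog of known
structure (the *template*). The template's transmembrane helices (TMHs) are
often individually accurate but their kinks, tilts, and connecting loops can
differ from the target's. The package implements a rebuild-and-refine
protocol: decide from the sequence alignment which TMHs cannot be trusted,
re-sample those helices as constrained rigid bodies, rebuild bends and loops
de novo, refine, and select final models by energy and clustering.

## Kinked-helix representation

A kinked TMH is decomposed into three contiguous regions: a moveable helical
fragment **m**, a 4–6 residue distorted **bend**, and a fixed helical
fragment **f** whose bend-adjacent residue (typically the kink-inducing
proline) is the *reference residue*. Helical axes are fit in two stages:
the direction comes from averaged cross products of consecutive local CA
bisectors (each interior CA's bisector points at the axis), the axis origin
from an algebraic circle fit of the CAs projected onto the orthogonal plane.
This is exact on ideal helices and stable down to 4-residue fragments, where
principal-component fits are biased by helical wobble.

Kink descriptors: the *kink angle* between the fitted m and f axes (both
oriented N→C); the *translation* between the two bend-side terminal CAs;
and the *swing*, the azimuth of the m far terminus projected onto the plane
orthogonal to f through the reference residue, measured right-handed about
f from the direction toward the reference residue's CB. Ideal helices are
generated from canonical torsions (φ, ψ = −57.8°, −47.0°; ~1.5 Å rise,
~100° twist per residue).

## Alignment gating

A target TMH is rebuilt when any of three conditions holds against its
aligned template TMH: (1) an alignment gap intersects the helix span;
(2) bend-inducing positions mismatch — a position counts as bend-inducing
when the target has a proline there or at least 10% of homologs do (via the
per-column proline profile), and mismatch means such a position is unaligned
or not matched by a template proline (checked symmetrically); (3) the
annotated helix lengths differ by more than 4 residues (about one helical
turn). Non-proline bend motifs are not gated on; sequence-based predictors
for them are not reliable enough to automate.

## Constraints

Comparative-modeling restraints tie pairs of residues that are identical or
similar (classes ILVMF / KR / DE / ST / NQ / FYW) in both sequences and
close in the template (Cα–Cα ≤ 8 Å by default; the "vicinity" cutoff is
configurable) to their template distance d₀ with a flat-bottom harmonic:
zero inside a width band, ((|d−d₀|−width)/σ)² outside, σ = 1 Å. Widths
follow the distance: 0.2 Å for contacts ≤ 5 Å, 0.5 Å near 8 Å, linear in
between. To avoid over-constraining distant templates the number of
retained pairs is budgeted by sequence identity: ~5% of modeled residues
below 20% identity, rising linearly to 10% at 25%, and unbudgeted above
25%. Selection is deterministic (ascending d₀, ties by descending sequence
separation). Pairs inside regions rebuilt de novo are excluded.

## Rigid-body TMH sampling

The m fragment (with its bend riding along as a flagged chain break) is
re-posed by Metropolis Monte Carlo with four move kinds chosen uniformly:

- **kink jump** — the m bend-side terminus is translated to a random point
  on a hemisphere centered at the f bend-side terminus (direction uniform
  over the +z half in the kink frame, radius Gaussian 7.2 ± 0.6 Å), then
  the m axis is re-oriented toward a direction restricted to the +z/+x
  quadrants of the frame, so the fragment tips away from the proline ring
  — the region native kinks occupy;
- **kink perturbation** — a small Gaussian shift (0.3 Å) and tilt (3°) of
  m about its bend-side terminus, letting the chain descend locally after a
  jump;
- **axial spins** of m or f about their own helical axes (±30°);
- **whole-unit moves** — small rigid motion of m+bend+f together.

The surrogate coarse-grained score is a weighted sum of (a) a soft-sphere
CA/CB clash term (contact radii 4.0 Å CA–CA, 3.5 Å otherwise, pairs ≥ 3
residues apart), (b) the constraint energy, (c) a Gaussian start restraint
on each fragment's rigid CA-displacement RMS with scale 1–1.5 Å (default
1.25 Å), and (d) a membrane term penalizing TMH CAs outside a ±15 Å
hydrophobic slab (membrane normal = z). It stands in for a full
low-resolution membrane potential: it has no attractive packing or
environment terms, so it validates the search and selection logistics, not
packing physics. Default weights are 1.0 (clash, constraint, restraint) and
0.5 (membrane); kT = 1 constant by default, with optional piecewise
schedules (the recovery experiments use 2.0 → 1.0 → 0.5). Production runs
use 1000–5000 steps per TMH; ensemble generation at desk scale uses
500-step runs.

## Loop and bend rebuilding

Loops and bend windows are rebuilt by fragment insertion with cyclic
coordinate descent (CCD) closure. Torsion fragments of sizes 9 and 3 come
from an enumerated ideal set (helical, 3₁₀, π, extended, polyproline-II,
turn and junction combinations), optionally augmented with
Ramachandran-basin samples, or from a user-supplied fragment table.
Each rebuilding step inserts a random fragment at a random window position
(35% of steps re-seed every window position at once, a fully decorrelated
restart), re-derives the window from ideal internal coordinates, and closes
the break by CCD; candidates are accepted by Metropolis on a local
clash+constraint score plus a chain-break penalty whose weight doubles each
step from 1.0. If after 12 steps the residual break exceeds 0.2 Å, the
window grows by one residue on both sides (default cap: 5 expansions).

CCD operates on the window's φ/ψ torsions plus the torsions placing an
ideal continuation (overlap) triplet N′/CA′/C′ of the first fixed residue;
each update applies the analytic angle minimizing the summed squared
deviation of the overlap atoms — a quantity that cannot increase, which is
the invariant tested. The reported chain-break deviation is the distance
between the ideal continuation N′ and the actual downstream N (equivalently
the C–N bond-length deviation). Iteration stops at a 0.05 Å tolerance, a
cycle cap, or when the gap improves by <0.5% over ten cycles (CCD's linear
tail is then better spent on a fragment-insertion restart). The cycle loop
is numba-compiled with an equivalent numpy fallback.

Bends are rebuilt as 4-residue windows by default; a 5–8 residue window
re-models distorted cases. Because windows are re-derived from ideal
internal coordinates, covalent geometry inside rebuilt regions is ideal by
construction.

## Refinement and selection

Refinement requires a closed chain and proposes small φ/ψ perturbations
(default 3° sd) inside short windows that are immediately CCD-closed back
onto the unmoved downstream chain, so moves stay local; CB is re-derived
after every accepted move (a stand-in for discrete side-chain optimization
— no rotamers are modeled). The clash weight ramps up across the schedule
(default 0.1 → 0.5 → 1.0, ending at 1.0), with Metropolis acceptance and a
step-halving retry when a proposal fails to re-close. The returned model is
the best seen at full repulsive weight, so refinement never worsens the
reported energy.

Model selection follows the protocol exactly: keep the min(1000, ⌈10%⌉)
lowest-energy models; leader-cluster their TM region by Cα RMSD (models in
ascending energy; each joins the first cluster whose leader is within the
radius, else founds one); return the lowest-energy member of each of the
five largest families (ties by the family's best energy). Ranking uses
clash + constraints + membrane at full weights — the start restraint is a
sampling device and would bias ranking toward the template. The cluster
radius defaults to 2.0 Å; it should be chosen at roughly half the
conformational spread of the ensemble, since leader clustering with a
radius at or above the spread collapses everything into one family and
makes the five-families rule inert. The desk-scale recovery experiment
(below) uses 1.0 Å for this reason.

## Synthetic fixtures

The generator builds idealized TMH bundles: helices on a circle with ~10 Å
inter-axis spacing, antiparallel alternation, membrane normal along z,
loops (default 8 residues) closed de novo. Kinks are created by rotating
the two helix fragments by ±angle/2 about an axis chosen from the
proline-CB frame so the moveable fragment tips away from the proline ring
— the native-like geometry the sampler searches — and the bend is then
rebuilt de novo. Splitting the rotation keeps both helix termini near
their straight positions so flanking loops remain closable. Templates
derive from targets by (i) straightening chosen kinks by swinging only the
m fragment onto the f axis (f keeps the target pose, as for a homolog with
a different kink pattern), with the proline optionally mutated away;
(ii) chain-smoothed Gaussian coordinate noise (±2-residue moving average,
normalized to the requested per-atom RMS) that preserves covalent geometry,
emulating low-frequency structural divergence rather than thermal jitter;
(iii) loop deletions (alignment gaps), capped so the shortened loop can
still span its anchors, with the shortened loop re-closed; (iv) sequence
mutations to a requested identity, applied to loop positions first so
constraint-eligible conserved pairs survive when possible. Construction
uses a Ramachandran-augmented fragment library seeded from the bundle seed.

What the fixtures do **not** emulate: real side chains and packing
heterogeneity, irregular helix distortions beyond single proline kinks,
lipid/solvent effects, and realistic sequence covariation. Tests passing on
these fixtures therefore demonstrate that the algorithmic machinery (gating,
move geometry, closure, selection arithmetic, metrics) behaves as specified
— not that the surrogate energy would rank real decoys like a full
physical potential.

## Recovery experiment (desk scale)

The standard benchmark pair is a 3-helix bundle (18-residue helices,
8-residue loops, 70 residues) whose second TMH carries a 30° proline kink,
paired with a template in which that kink is straightened, the proline
mutated, loops shortened by two residues, the sequence mutated to ~35%
identity, and coordinates perturbed by 0.2 Å smoothed noise. Constraints
for the recovery experiment come from the target's own contacts (a
self-alignment with the target as distance source, vicinity cutoff 10 Å —
at the fixture's 10 Å helix spacing the 8 Å cutoff leaves too few
informative inter-helix pairs to define the experiment), excluding the bend
and loops, which are rebuilt de novo. Kink-angle recovery is measured over
20 seeded 1000-step Monte Carlo runs; the end-to-end experiment runs the
full pipeline 10 times at 200 models per run (the production protocol
generates 10,000–40,000; 200 keeps a full run in tens of seconds while
still exercising truncation, clustering, and family selection).

## Numerical choices and limitations

- Residue numbering is 1-based with closed intervals throughout; altLoc
  conflicts resolve to highest occupancy; missing CB atoms are rebuilt at
  fixed ideal internal coordinates (bond 1.527 Å, angle 110.1°, improper
  −122.6°), glycine included (virtual, flagged, not written for Gly).
- A C(i)–N(i+1) distance outside (1.0, 2.0) Å flags a chain break.
- GDT/GDT-HA maximize per-threshold residue fractions over superpositions
  seeded from all 4/8/16-residue sequence windows plus the global fit; this
  approximates the full LGA search from below. TM-score uses
  d₀(L) = 1.24·(L−15)^⅓ − 1.8 with an iterative subset-extension search
  (exhaustive window seeds for chains ≤ 40 residues).
- Every stochastic component takes an explicit numpy Generator; equal seeds
  give bit-identical outputs end to end.
- The quadrant restriction biases but does not force the m projection into
  the semicircle away from the proline (the hemisphere translation is
  unrestricted in x); sampled poses land there ~90% of the time.
- Only backbone + CB are modeled; no side-chain packing, no ligands, no
  waters, single chains only.
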