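# Methods

This note documents the models, conventions and numerical choices behind
`arbordyn`, in the spirit of a methods appendix: what each quantity means,
which decisions were genuinely open and how they were fixed, and what the
synthetic generator does and does not emulate.

## Arbor model and segment decomposition

An arbor is a single rooted tree of 3D nodes (μm) with radii, read from and
written to the standard 7-column SWC dialect (1-based ids, parent −1 root;
unknown structure-type codes pass through; files are re-emitted in
parent-first order with original ids, so round trips are exact up to the
6-decimal float format, ≤ 1e-4 μm).

A *segment* is a maximal unbranched path bordered by two branch points or
by a branch point and a terminal point. Node ownership is fixed so that
lengths are exactly conserved: a branch point belongs to the segment it
terminates (its parent side), while each child segment starts at the branch
point as a border marker only — but its length includes the step from the
branch point. Hence Σ segment lengths = total cable length to 1e-6 μm,
which the tests assert on every fixture. Nodes with three or more children
are allowed and simply border one segment per child.

**Strahler ordering** runs on the segment tree: terminal segments have
order 1; a parent takes the maximum child order, +1 when two or more
children tie at the maximum. *Terminal segments* are the order-1 segments;
*skeleton length* sums segments of order > 1 (zero for an unbranched
arbor). The implementation is iterative; tests compare it against an
independent recursive node-based formulation on 200 random trees.

**Terminal-segment length bins** default to [1.5, 5), [5, 10), [10, 15),
[15, ∞) μm and report percent of the per-arbor total. The 1.5 μm floor
matches the persistence threshold below which branches are not analysed;
lengths under the floor are excluded from the denominator so percentages
always sum to 100. Edges are configurable.

## Rigid alignment

Landmark pairs (≥ 3, non-collinear) are fitted by closed-form orthogonal
Procrustes (Kabsch) with a determinant correction forbidding reflections;
no scaling. Collinearity is detected via the second singular value of the
centred source cloud (relative tolerance 1e-9). Time series are aligned by
*consecutive-pair chaining to the first time point*: the pairwise fits
(k−1, k) are composed cumulatively. Chaining was chosen over a global
reference because landmarks are placed between neighbouring frames in
practice; its cost is a slow random walk of the alignment error
(≈ σ·√T scaled by the landmark lever arm — with σ = 0.1 μm noise on six
landmarks over ~25 frames, accumulated drift stays within a few μm, small
against typical event pair distances of tens of μm, and it cancels exactly
in the pair-distance ratios, which compare statistics within a common
frame).

## Branch dynamics

Branch identity across time points is *consumed*, not computed: the tracing
workflow (or the generator) maintains a stable `branch_id`, and real-data
re-identification is out of scope. Conventions:

- interval *i* spans (t[i−1], t[i]]; a missing acquisition yields one
  longer (20 min) interval that contributes a single count observation;
- a branch first seen at acquisition *k* was added in interval *k*; its
  addition event sits at the branch point at that first frame;
- a branch last seen at *k* was eliminated in interval *k+1*; its
  elimination event sits at the terminal point at frame *k*;
- an interval belongs to the epoch containing its end time; trailing
  acquisitions outside every epoch are dropped from rate windows;
- only branches that ever attained 1.5 μm are analysed.

Normalized rates divide per-interval counts by the kind's mean darkness
count, so the darkness mean is 1 by construction; an all-zero darkness
baseline flags the axon instead of dividing by zero. Window averages take
additions over the first 60 min of each stimulation epoch and losses over
the last 60 min — or the last 40 min when the epoch is shorter than 2 h
(the 1.5 h protocol variant) — plus the async/sync ratio per kind.

## Spatial statistic and Monte-Carlo null

The observed statistic per epoch and kind is the mean over all n(n−1)/2
Euclidean 3D distances between event coordinates pooled across the epoch
(straight-line distances; path-along-cable metrics are a non-goal). Cells
with fewer than two events are undefined and reported as exclusions, never
zeroed.

The null preserves per-interval counts and per-time-point geometry: for
each of 100 replicates, each interval's additions are redistributed
uniformly over the nodes of the 0.15 μm-resampled arbor at that interval's
later frame, and its eliminations over the terminal points of the arbor at
the earlier frame (the arbor from which the branches vanished) — without
replacement when enough terminals exist, with replacement otherwise.
Replicate draws are pooled per epoch before the mean pair distance is
taken, mirroring the pooling of the observed statistic (pooling per
interval first was the alternative; per-epoch pooling was chosen because
the observed quantity is an epoch-level mean). One generator seed drives
an axon's whole analysis; identical seeds give bit-identical replicates.

The reported quantity is the observed/randomized ratio normalized to the
axon's darkness ratio. Normalization removes arbor-size trends *and* any
systematic placement bias shared across epochs, so under uniform placement
its expectation is 1. Being a ratio of noisy ratios it carries a finite-
sample (Jensen) bias of order CV² of the darkness ratio; with ~15+
darkness events the bias is below 1–2%, which is why the calibration
experiment (below) uses event-rich conditions.

## Arbor span volume

The 0.15 μm-resampled node cloud is triangulated (Delaunay; joggled on
degenerate input) and filtered by tetrahedron circumradius. The *tight*
boundary is the alpha complex at the smallest radius whose kept tetrahedra
cover every node and form a single face-connected region — found by an
ascending union-find sweep, deterministic by construction. Shrink 0 is the
convex hull (the full Delaunay complex). *Convexity* = tight volume / hull
volume ∈ (0, 1]. The span volume feeds the shrink factor 1 − convexity
back into the boundary family, so a nearly convex arbor is spanned by its
hull and a sprawling one by its tight fit. Because raw circumradii span
orders of magnitude (hull slivers are huge while cable-scale tetrahedra
are ~0.1 μm), intermediate shrink values select the radius on the
cumulative tetrahedron-volume scale; this keeps the family evenly graded
and monotone non-increasing in shrink with the exact limits at 0 and 1.
The exact boundary parameterization used by the original MATLAB toolchain
is not published; this mapping is this package's own declared choice and
is deliberately configurable. The expansion index
(V_last − V_first)/(V_first + V_last) is bounded in (−1, 1) and
antisymmetric.

Degenerate inputs (fewer than 4 points, coplanar clouds) raise a
`DegenerateGeometryError`; the pipeline logs and skips such time points.

## Synthetic generator

The generator emulates the *statistical* structure of a DAS imaging
session, not biophysics:

- fixed structural skeleton: a ~60 μm trunk plus four persistent major
  branches (one sized to hold a configurable fraction — default 25% — of
  the skeleton, serving as the clustered-elimination subtree);
- per 10-min interval, additions ~ Poisson(λ_add) attach at uniformly
  chosen skeleton nodes and grow as jittered random-walk polylines toward
  a target length (exponential tail, min 1.5 μm); a configurable fraction
  (default 25%) is capped below 1.5 μm to exercise the culling rule;
- eliminations ~ Poisson(λ_elim) remove whole dynamic branches — uniformly,
  or with probability p_cluster from the designated subtree during the
  configured epochs; a clustered draw with an empty subtree pool is
  dropped rather than silently redirected, so confinement is exact;
- per-frame rigid motion (≤ 4°, ≤ 2 μm) with landmark pairs observed under
  0.1 μm Gaussian noise; interior acquisitions dropped with probability
  0.02, creating the occasional 20-min interval;
- default epoch rates follow the Stentian/Hebbian preset: dark (2.0 add /
  1.5 elim per interval), async (3.5 / 2.5), sync (1.2 / 1.5 with
  clustering at p = 0.8), so the out-of-the-box demo reproduces the
  qualitative pattern of elevated asynchronous exploration and locally
  clustered synchronous elimination.

The ground-truth log is derived from the emitted snapshots, so detection
closure (precision = recall = 1) is a meaningful test of the bookkeeping
conventions, not a tautology of shared code. What the generator does *not*
emulate — tracing errors, branch re-identification ambiguity, optical
sectioning anisotropy, biologically structured geometry — bounds what
passing tests say about real data: they validate the statistics and
bookkeeping, not robustness to reconstruction noise.

## Verification experiments and problem sizes

The acceptance experiments (tests and `scripts/acceptance.py`) use:

- **Closure**: 20 sessions, uniform rates 2.0/1.5, full imperfections on.
- **Calibration**: 50 sessions, uniform rates 3.0/2.4, clustering off,
  100 replicates; per-axon mean normalized ratio, pass within 3 SE of 1.
  Event-rich rates are used so the finite-sample bias of the ratio of
  ratios (see above) is well below the resolution of the check.
- **Power**: 50 sessions, rates 2.5/2.0, eliminations fully confined
  (p_cluster = 1) to the 25% subtree during sync; mean sync elimination
  ratio < 0.95 plus a one-sided sign test at p < 0.01.
- **Rate recovery**: 50 sessions with the persistence filter made
  non-binding (no capped branches, initial length 1.6 μm, 20-branch
  starting pool so elimination draws never truncate), no missing frames;
  recovered per-interval rates within 2 empirical SE of the configured λ.
- **Oracles**: 200 random trees (Strahler), 100 random event sets (pair
  distance, 1e-9 relative), 100 random p-vectors (FDR vs statsmodels).

These sizes keep the full suite under a minute of compute while leaving
each statistical check with comfortable resolution.

## Known limitations

- Branch correspondence must be supplied; there is no matcher.
- Event distances are extracellular straight lines, not path distances.
- The span-volume boundary parameterization is a declared substitute for
  an unpublished one; absolute span values are comparable within this
  package only (ratios and indices are robust to the choice).
- Alignment drift from consecutive-pair chaining grows as √T; sessions
  much longer than a few hours would warrant a global registration.
- The pipeline exports tidy per-axon tables for group-level inference
  (mixed models, rank tests) in external statistics software; only the
  two-stage FDR helper is built in.
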