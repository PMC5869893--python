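# Methods

`lexiplan` implements an automated, wishlist-driven planning pipeline for
two-phase whole-pelvis prostate radiotherapy (WPRT) and the evaluation
machinery used to judge the resulting plans. This note documents the
models, the defaults and why they were chosen, and what the synthetic
test bed does and does not establish.

## The planning problem

WPRT treats two nested targets: the pelvic lymph-node volume (CTV-LN,
which contains the prostate CTV-P) and the prostate itself. The packaged
prescription is the two-phase protocol: phase 1 delivers 60 Gy to PTV-P
and 50 Gy to PTV-LN in 25 fractions as a simultaneous integrated boost;
phase 2 adds a sequential 13 Gy boost to PTV-P in 5 fractions. PTVs are
the CTVs expanded by a 5 mm setup margin. The two phases are planned
independently, each with its isocentre at the centre of the phase
target, and judged together on the summed dose.

The planning protocol itself is data: a *wishlist* of hard constraints
(inviolable dose limits) and prioritized objectives (cost functions with
goals, worked through in strict priority order). The two packaged
wishlists (`lexiplan/data/wprt_phase[12].yaml`) encode the published
whole-pelvis protocol verbatim: phase 1 carries 7 hard constraints and
priorities 1–12 (14 objective rows), phase 2 carries 5 constraints and
priorities 1–8 (10 rows). Limits and goals are stored as percentages of
the named prescription references `D_high` = 60 Gy, `D_low` = 50 Gy,
`D_p` = 13 Gy and resolved to absolute Gy at run time, so the same
wishlist re-scales with the prescription context.

## Cost functions

All four wishlist cost types are convex in dose, which is what makes the
prioritized sweep globally valid:

* **LTCP** (logarithmic tumor control probability), the target-coverage
  surrogate: `LTCP = (1/m) Σ_j exp(−α (d_j − D_p))`. It equals 1 for a
  uniform dose at prescription, explodes for underdose, and decays to 0
  as voxels rise above `D_p`; `α` (1/Gy) is the cell-sensitivity
  parameter (0.7–0.95 in the packaged wishlists). Internally LTCP is
  handled in log form (a log-sum-exp of affine functions, hence convex)
  because `α·D_p ≈ 42` makes the plain exponential span ~18 decades
  between zero dose and prescription.
* **EUD** (equivalent uniform dose), the generalized power mean
  `((1/m) Σ d_j^k)^(1/k)` with volume-effect exponent `k ≥ 1`: `k = 1`
  is the mean dose, large `k` approaches the maximum. Evaluation is
  max-scaled so `k = 64` at 60 Gy does not overflow. Note the exact
  power-mean bound `EUD(k) ≥ max · m^(−1/k)`: at `m = 1000`, `k = 64`
  the gap to the maximum can be ~10%, so "EUD(64) ≈ max" statements
  only hold for tightly grouped (target-like) dose vectors.
* **max dose** and **mean dose**, exact over the structure voxels.

## Phantom

The synthetic pelvis phantom replaces patient CT + contours. It is built
from analytic solids on a regular grid (voxel-centre semantics, mm
units, axes x = left-right, y = anterior-posterior, z = inferior-
superior): an elliptic body contour (230 × 190 × 180 mm — sized so the
default 4 mm grid is about 63 × 53 × 51 voxels, a desk-scale problem), a
prostate sphere abutting a rectum tube posteriorly, an anterior-superior
bladder ellipsoid, lateral femoral-head spheres, and a nodal target
swept as a tube along an elliptic arc whose anterior opening leaves room
for bladder and bowel — the concave horseshoe that makes WPRT planning
hard. The bowel bag fills the concavity and is delineated up to exactly
20 mm cranial of the nodal target, mirroring clinical contouring
practice. A 2 mm clearance is kept between the nodal CTV and each OAR
so CTV voxels are never simultaneously organ voxels (PTV margins may
still overlap OARs, as in reality).

A seeded jitter (uniform ±3 mm on organ centres, ±1.5 mm on radii)
produces reproducible anatomy variants for cohort runs; spec + seed
fully determine the structure set.

What the phantom does **not** emulate: CT densities and heterogeneity
(the body is water-equivalent), realistic nodal-chain topology (the
target is a smooth horseshoe), intra-organ texture, or inter-patient
volume distributions. Passing tests on the phantom therefore establish
the *mechanics* of the method — constraint satisfaction, prioritized
trade-offs, metric bookkeeping — not clinical dose-volume statistics.

## Dose model

Dose is linear in the beamlet fluence weights: `d = D x` with a sparse
influence matrix `D` (Gy per unit weight). Rotational delivery is
approximated by 20 static equi-angular coplanar beams, the way the
clinical pre-optimizer approaches an arc, each decomposed into 10 mm
beamlets sized to cover the phase target's projection plus an 8 mm
margin (beamlets whose rays never pass within 5 mm + half a beamlet of
the target are dropped). Each beamlet deposits dose along its divergent
ray from the source (SAD 1000 mm): entry at the body surface located by
ray marching, depth dose `∝ exp(−μ · depth)` with μ = 0.04/cm, lateral
Gaussian spread σ = 5 mm, no buildup region, no scatter kernels, no
inverse square by default (flag available). Entries below 10⁻³ of a
beamlet's peak are dropped for sparsity; the matrix is stored in float32
(dose values have ~3 significant digits of physical meaning here). The
matrix is calibrated so unit weight on every kept beamlet gives 2 Gy at
the isocentre.

This surrogate is qualitatively realistic — crossfire, exponential
attenuation, finite penumbra — but it is not a clinical dose engine;
its role is to give the optimizer genuine geometric trade-offs.

## Prioritized (lexicographic ε-constraint) optimization

`solve_prioritized` visits objective rows in priority order (rows
sharing a priority are processed sequentially in listed order by
default; a joint min–max mode over goal-scaled rows is available behind
`joint_same_priority`). Each stage minimizes one objective subject to
the hard constraints and all previously imposed bounds; then the stage
is frozen:

* goal reached → bound at the **goal** (leaving headroom for lower
  priorities, which is what the wishlist's goal column means),
* goal missed → bound at the attained value × δ, δ = 1.03 by default
  (a 3% relaxation so lower priorities retain a little room).

After the sweep, a **tighten pass** revisits every objective, re-
minimizes it under all other bounds and replaces its bound by the value
actually attained, removing most of the δ slack — this is what makes
the final plan Pareto-consistent with the priority order. A final stage
minimizes the fluence ℓ₂ norm under all bounds to pick a deterministic
representative among near-degenerate optima.

Every stage is a convex program (linear dose map; convex costs). Stages
are solved with a safeguarded augmented-Lagrangian method:

* per-voxel max-dose constraints over large structures (unspecified
  tissue can be ~10⁵ voxels) enter through a **working set** of hot
  voxels; the full voxel list is re-checked against the incumbent at
  every outer iteration and violators are added, so the reduction is
  exact at convergence. Structures at or below the working-set cap
  (1500 voxels) are carried in full.
* max-dose *objectives* use the epigraph form (auxiliary variable `t`,
  couplings `d_i/s ≤ t`) with the same working-set machinery.
* inner minimizations use L-BFGS-B (bound constraints x ≥ 0) on the
  augmented Lagrangian, with automatic restarts when the line search
  stalls at a penalty wall; a projected Newton-CG inner (exact
  Hessian-vector products) is available via `inner_method`.
* dual updates follow the classical safeguard: multipliers move only
  when the constraint violation improved sufficiently, otherwise the
  penalty is stiffened; duals are never updated against an incomplete
  working set.
* the variable space is diagonally preconditioned by column
  equilibration of the influence matrix (unit-norm columns), which
  equalizes central and grazing beamlets.
* a stage is accepted only when all constraints hold within tolerance
  *and* the objective has stopped improving between feasible outer
  iterations (≤ 5 × 10⁻⁴ relative), so a stage cannot stop at its first
  feasible iterate with immature duals.

Tolerances: a hard limit L is enforced to `max(0.05 Gy, 10⁻³ · L)`;
LTCP bounds to `α ×` the Gy tolerance of their prescription, expressed
in log units, so both constraint families carry the same effective dose
tolerance (with mismatched tolerances, stages where an LTCP bound and a
mean cap are simultaneously active become numerically unsolvable).
A stage that still ends beyond tolerance is restored without ever
weakening an earlier bound — weakening would invert the priority
order: first by exact uniform fluence down-scaling when only linear
upper hard limits are marginally violated (scaling is an exact
projection in that direction), otherwise by a backtracking line search
toward the stage's incumbent, which satisfies every imposed bound by
induction. Both events are logged; in the worst case the stage simply
makes no progress and its bound freezes the incumbent's value.

Infeasibility: the packaged wishlists contain only upper bounds, so
zero fluence is always feasible and the pre-flight check is trivial;
when user-supplied MIN constraints make the problem genuinely
infeasible, a least-violation fluence is sought and the violated
constraints are reported by name.

### Attainability at desk scale

On the default phantom the phase-1 LTCP goals are *not* reachable: the
ring target (PTV-LN minus the boost transition region) is capped by its
own hard Max 105% / Mean 101% limits while 4 mm sampling of a σ = 5 mm
penumbra leaves a thin cold boundary layer, and LTCP — an exponential
of the cold tail — lands near 8 rather than 0.5. This mirrors clinical
reality (target D98% sits a few percent below prescription; homogeneity
indices are ~0.1) and is why plan acceptability is judged by coverage:
the solved plans reach V95% ≥ 96% for both targets in the summed dose,
with headroom. The trace records the missed goal and the imposed bound
honestly.

## Evaluation

`D_q%` uses linear interpolation between order statistics (the
`numpy.percentile` convention), making reported quantiles reproducible
bit for bit. `V_xGy` is the fraction of structure voxels at or above
the threshold; volumes in ml are voxel count × voxel volume. The
homogeneity index is `(D2% − D98%)/D50%`; conformity indices
`CI = V95%/V_PTV` and `CI50% = V50%/V_PTV` measure the isodose volumes
over the whole body, not the PTV. For PTV-LN statistics the boost
volume expanded by 20 mm is subtracted so the SIB region does not
contaminate them. Summed-plan coverage is judged per target against its
summed prescription (PTV-P: 73 Gy, PTV-LN: 50 Gy) — the protocol's
V95% ≥ 96% criterion. The packaged clinical organ-at-risk table (16
constraints over rectum, bowel bag, bladder and femoral heads) is
evaluated on the summed dose with `D_max` as the true voxel maximum
(a near-maximum variant is available). Rectal V70/V55 are reported
after converting the summed dose voxelwise to EQD2 with α/β = 3 over
the 30 total fractions; converting the thresholds instead is available
behind a flag (the two agree exactly at 2 Gy per fraction).

## Gamma QA

The gamma index uses local dose normalization (per-voxel reference
dose) with the clinical 3%/3 mm criterion, a 10% low-dose cutoff
(standard QA practice; the source protocol does not state one), and a
search capped at 3 × the distance criterion — any gamma beyond that cap
is > 3 and irrelevant to pass/fail. Sub-voxel agreement is resolved by
trilinear interpolation of the evaluated dose on a half-voxel search
lattice. On lattice-only searches the implementation agrees with an
exhaustive per-voxel-pair oracle to rounding.

## Problem sizes and determinism

The default end-to-end configuration — 4 mm grid (≈ 97 000 body
voxels), 20 beams × 10 mm beamlets (≈ 3 700 after pruning), both
phases with tighten pass — completes in roughly twenty minutes on a
single core (the whole-pelvis phase dominates; the boost phase takes
about a minute). Stage iteration budgets (8 outer × 350 inner for the
main sweep, 4 × 250 for the tighten pass) are part of the method's
defaults; coarser grids (6–8 mm) are used in unit tests and examples
where only mechanics are exercised. All
randomness (phantom jitter, cohort seeds) flows from explicit integer
seeds; the solver itself is deterministic, so fixed inputs reproduce
the objective trace exactly.

## Known limitations

* The dose surrogate has no buildup, scatter, or density corrections;
  absolute OAR dose levels are not clinically meaningful, only the
  trade-off structure is.
* Arc delivery is approximated by the 20-beam static formulation; no
  aperture sequencing or monitor-unit model, so deliverability is out
  of scope (the gamma module compares dose grids, not measurements).
* Stage optimality at desk scale is budgeted (iteration caps); the
  audit trail records attained values, and hard constraints are always
  enforced to tolerance, but low-priority objectives may sit slightly
  above their true optima.
* Cohort statistics produced from jittered phantoms share one anatomy
  template and understate real inter-patient variability.
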