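# Methods

This note documents the models, numerical choices and known limitations of
the `subtendon` package: a desk-scale re-analysis pipeline for the mechanics
of the three Achilles sub-tendons (lateral gastrocnemius LG, medial
gastrocnemius MG, soleus SOL) and the associated in vitro and in vivo
statistics.

Units are mm–N–MPa throughout (1 N/mm² = 1 MPa). The longitudinal axis is
z, +z proximal with the distal (calcaneal) face at z = 0; x is lateral and
y posterior.

## Parametric geometry

The free tendon is an extruded stack of elliptical cross-sections
partitioned by two straight chords into the three sub-tendons: a transverse
chord separates the anterior soleus region, a sagittal chord splits the
posterior remainder into the medial (MG) and lateral (LG) gastrocnemius
regions. Chord positions are solved analytically (ellipse segment areas +
Brent root-finds) so the partition areas match prescribed fractions; the
default fractions are the in vitro mean cross-sectional areas
LG : MG : SOL = 9.3 : 13.4 : 32.8 mm². The canonical arrangement is defined
at the proximal end; sections rotate laterally toward the distal end by a
total twist angle, linear in z.

Three archetypes emulate the three dissected source tendons:

| archetype | length (mm) | total CSA (mm²) | default twist (deg) |
|-----------|-------------|-----------------|---------------------|
| 1         | 70          | 89.1            | 90                  |
| 2         | 40          | 90.4            | 40                  |
| 3         | 40          | 42.3            | 40                  |

Only the section spacing (10 mm), total CSAs, lengths, arrangement and the
qualitative twist of the real tendons are reproduced; the outlines are
procedural (the real cross-section photographs are not available). The
twist magnitudes are stated modelling assumptions: the most twisted tendon's
LG reaches the anterior surface distally, implying roughly a quarter turn;
the shorter tendons twist less. All parameters (CSA, length, twist,
fractions, ellipse aspect ratio, default 2:1 mediolateral : anteroposterior)
are overridable, and `gen_geometry_params` produces seeded jittered
parameter sets for population-variability experiments.

## Meshing

Each convex 2-D partition is triangulated (shared chord discretisation, a
hexagonal interior lattice at 0.85 h with 0.35 h boundary clearance, and a
Delaunay triangulation per partition — valid because each partition is
convex). Arc points are pushed radially, in circle-mapped coordinates, by a
per-arc factor solved so the polygonised segment area equals the analytic
one; section areas are then exact to O(h⁴) and a zero-twist loft reproduces
the analytic prism volume to machine precision. The triangulation is
extruded layer by layer (layer spacing 0.7 h) following the twist; wedges
split into tetrahedra with a minimum-global-index diagonal rule, which makes
neighbouring wedges — including wedges of different sub-tendons across an
interface — choose identical diagonals, so the mesh is conforming.
Elements are straight-edged 10-node quadratic tetrahedra (TET10); no
element edge exceeds 1.5 h.

Each sub-tendon owns private copies of its interface nodes; coincident
copies (tolerance 1e-6 mm) become interface node pairs with a local
orthonormal frame and a lumped tributary area. The frame's normal n is the
area-weighted average of the adjacent interface face normals; the
longitudinal tangent t1 is the local helical fascicle direction
ez + τ(−y, x, 0) projected onto the surface (τ = twist rate), which lies
exactly in the lofted interface; t2 = n × t1. Collapsing all pairs
(union-find) yields the conforming merged mesh used as the bonded oracle.
A structured box-bar mesher provides exact-geometry meshes for the
verification problems.

`converge_mesh` refines h by a constant factor until the mean proximal
soleus-face displacement changes by less than a criterion (default 1%)
between successive refinements, returning the coarser member of the
converged pair.

## Material model

Compressible neo-Hookean strain energy W = C10 (Ī₁ − 3) + (1/D1)(J − 1)²,
parameterised from an initial (small-strain) Young's modulus E and Poisson
ratio ν via C10 = E / (4(1+ν)) and D1 = 6(1 − 2ν)/E. Tendon is nearly
incompressible; ν defaults to 0.49 (the printed moduli behave identically
at any ν by construction). The default moduli are the values fitted from
the in vitro axial tests — LG 226.7, MG 143.2, SOL 103.1 MPa — which differ
from the per-specimen tabulated Young's moduli; the simulation uses the
fitted set because it is the set that parameterises the solver. First
Piola–Kirchhoff stress and the full first elasticity tensor are analytic
and finite-difference verified.

The uniaxial nominal-stress oracle solves the zero-lateral-stress condition
by a safeguarded vectorised Newton iteration (tolerance 1e-10 on the
lateral stress). `fit_initial_modulus` least-squares fits this model to
measured stress–strain data between 20% and 80% of the failure force, with
a strain-offset nuisance parameter that absorbs the toe region; it recovers
a noiseless generated modulus to machine precision and a 2%-noise modulus
within 5% per curve with < 1% bias.

## FE solver

Static total-Lagrangian formulation, 4-point quadrature on TET10 (affine
geometry, so the isoparametric map has a constant Jacobian), Newton
iteration with a backtracking line search (which also guards against
element inversion under the large rotation increments that one-sided
loading induces), sparse direct solves (SuperLU in symmetric mode,
MMD_AT_PLUS_A ordering, relaxed diagonal pivoting). Loads ramp linearly
(default 10 steps in the data type; the sweep driver uses 3, see below);
convergence requires a relative residual ≤ 1e-6 (≤ 1e-9 N absolute for
zero-load cases). Each loaded sub-tendon receives its 100 N as a uniform
+z traction over its proximal face via consistent nodal loads (for a
straight-edged quadratic triangle: one third of the face force on each
midside node); distal faces are fully fixed (a "roller" variant — z fixed
plus minimal lateral anchors — exists for the homogeneous uniaxial
verification problems). Verification: a bar matches FL/(EA) within 1%, a
homogeneous block at 30% stretch matches the analytic uniaxial response to
~1e-10, global equilibrium residuals are ~1e-11.

### Interface model

Matched node-pair penalties (no contact search; the interfaces are
conforming by construction). The normal and in-plane transverse relative
displacements are penalised bilaterally — the discrete analogue of a
translational joint that resists separation and interpenetration alike —
with per-area stiffnesses k_n = k_t = 1e3 MPa/mm by default. The
longitudinal direction depends on the mode: frictionless (free), bonded
(tied with k_t), or Coulomb friction with the tangential force capped at
μ|N|, where |N| is the pair's bilateral normal penalty force.

The solver iterates a regularised Coulomb law: the cap uses the smooth gap
magnitude sqrt(dn² + ε²) (ε = 1e-6 mm) and the clip is replaced by a tanh.
This keeps the residual differentiable — the sharp law makes Newton chatter
indefinitely on marginal pairs — while a pair is flagged "slip" once its
force reaches 99% of the cap, so flagged pairs satisfy |f_t| = μ|N| within
1% (plus an absolute slack of order μ k ε for near-zero-pressure pairs).
Friction history uses an elastic-predictor / return-mapping stick reference
committed at each converged ramp step; loading is monotone and
proportional, so a single reference per step suffices. Within a sweep,
each interface model warm-starts from the previous one's solution and
applies the full load in one step, which is consistent with this monotone
treatment and several times faster than re-ramping.

### Penalty sensitivity (measured)

Doubling k_n/k_t at the defaults moves the monitored soleus-face
displacement by < 0.05% for bonded, ~1.5–3% for frictionless and ~5–6% for
frictional interfaces (archetype 3, soleus loaded). The bonded mode is
constraint-driven and converges in k (it also matches a merged-node mesh
within 0.1%). The sliding modes inherit two genuine limitations of
fixed-reference-frame, small-sliding node-pair penalties: (i) a relative
slide s under the bending rotation β that one-sided loading induces leaks a
spurious s·β component into the penalised transverse directions, and
(ii) the Coulomb cap scales with the penalty's resolution of the contact
pressure concentration along the three-sub-tendon junction line. Both
effects shift absolute displacements slowly with k but leave the reported
μ-sweep *trends* (computed at fixed k) intact; the analysis is accordingly
trend-level, and the figure-style ordinates are not treated as numeric
targets.

## Outcome measures

* mean face displacement: area-weighted nodal average of u_z over the
  proximal soleus face (weights from a corner/midside sub-triangle lumping
  of the 6-node faces);
* normalisation: within each (model, load) group, displacement and mean von
  Mises stress divide by the frictionless row (identically 1 there);
* stress: von Mises from the element-centroid Cauchy tensor; the mean is
  volume-weighted over the whole mesh (a plain element average is
  available); the peak excludes one element ring around the fully fixed
  distal face, where the clamp creates a discretisation artefact
  (configurable to zero rings);
* peak location: owning sub-tendon plus a surface-region label from the
  nearest boundary face (dominant outward-normal axis: ±y
  posterior/anterior, ±x lateral/medial; interface-adjacent peaks and ties
  are "internal");
* face rotation: closed-form least-squares rigid rotation of the face's
  nodes about z, atan2(Σ p×q, Σ p·q).

## Sweep at desk scale

The experiment grid is 7 interface conditions (frictionless; μ = 0.2, 0.4,
0.6, 0.8, 1.0; bonded) × 3 isolated 100 N loads × 3 archetypes. The
default desk-scale meshes use edge lengths 3.4 / 3.0 / 2.8 mm (roughly
2,200 / 1,900 / 1,300 TET10 per model) and 3 ramp steps for the cold solve
of each load-case column; the full 63-solve grid completes in about ten
minutes on one CPU. At this resolution all of the qualitative results
hold: soleus-loaded soleus-face displacement decreases monotonically with
μ in every archetype; gastrocnemius-loaded soleus displacement increases
with μ (archetypes 1 and 2, and in practice 3); the long, strongly twisted
archetype 1 shows the largest gastrocnemius-to-soleus transfer (measured
against each model's soleus-loaded frictionless displacement, because the
gastrocnemius-loaded frictionless reference is itself near zero and
sign-unstable under bending); and the bonded mean von Mises stress is below
the frictionless one in all nine model × load cells.

## In vitro analysis

Per-curve metrics: failure force = force maximum (a ≥ 20% terminal drop is
required), ultimate stress = failure force / CSA, ultimate strain =
displacement at peak / 60 mm gauge length. The "linear region" slope is
operationalised as the maximal slope of sliding-window straight-line fits
(window = one third of the region, minimum five samples) between 20% and
80% of the failure force, on force–displacement for stiffness and
stress–strain for Young's modulus. This is deterministic and excludes toe
and yield regions; note that because a hyperelastic curve's tangent
stiffness decays with stretch, the windowed slope under-reads the *initial*
tangent by a few percent — the modulus used by the FE model therefore comes
from `fit_initial_modulus`, not from this table metric.

The packaged fixture stores the published five-donor table at 1-decimal
precision and regenerates every printed mean/SD cell and the male/female
whole-tendon subgroup means exactly at that rounding. A loader validation
checks ultimate stress against failure force / CSA with an interval test
that accounts for 1-decimal rounding of both operands; exactly one
published cell (donor 69 M, soleus ultimate stress, 45.3 vs 43.4 MPa) fails
it and is exempted as a presumed typographical error — it is never used as
an oracle.

Statistics: Kruskal–Wallis on mid-ranks with tie correction (chi-square
approximation, df = 2) per metric; exact two-sided Mann–Whitney post hoc
tests of each gastrocnemius against the soleus, starred at p < 0.017
(Bonferroni 0.05/3) and gated on a significant omnibus test at 0.05. The
exact test enumerates all rank arrangements for combined samples ≤ 20
(two-sided p = doubled smaller tail, capped at 1 — the convention of the
standard packages); larger samples fall back to the tie-corrected normal
approximation.

## In vivo analysis

Trials deliver 4 s on / 4 s off stimulation cycles (first onset at 4 s,
≥ 3 complete cycles). Per cycle, the peak displacement is measured relative
to the median of the 0.5 s pre-onset baseline; the trial value is the
median across cycles (the aggregation is not specified by the protocol;
the median is robust to a single poor contraction). The outcome is peak
soleus musculotendinous-junction displacement normalised by the contracted
muscle's own peak displacement, which cancels stimulation-intensity
scaling; group comparison (young n = 9 vs old n = 7) uses the shared exact
Mann–Whitney test. The a priori sample size uses the noncentral t
distribution: d = 1.9, α = 0.05, power 0.90 interpreted as in G*Power, and
a one-tailed test — which yields the design total of 12 (two-tailed gives
14); both the interpretation and the tails are explicit parameters.

## Synthetic data

Generators are pure functions of (spec, seed):

* tensile curves: strain is re-mapped through a quadratic toe (default
  extent 2%, C1-joined so the post-toe curve is the neo-Hookean response
  shifted by half the toe extent), evaluated at the generating modulus,
  scaled by CSA, offset by the preload, sampled at the 0.75 mm/s pull rate
  and truncated by a terminal force drop at the failure strain (default
  14%, inside the observed 8–19% range); optional multiplicative Gaussian
  force noise;
* cohorts: per participant × muscle, smooth trapezoidal pulse trains whose
  amplitude ratio is drawn from Normal(group mean, SD), with the old-group
  soleus mean shifted by −d·SD. Defaults: base means 0.5 (soleus trials)
  and 0.35 (gastrocnemius trials), SD 0.12 — chosen so the design effect
  d = 1.9 is attainable with strictly positive displacements — d = 0 for
  the gastrocnemii, reference amplitude ~2 mm, 0.02 mm trace noise;
* geometry jitter: unbiased multiplicative Gaussian jitter on CSA, twist
  and (renormalised) fractions, clipped away from non-physical values.

What the generators deliberately omit: preconditioning mechanics (the 20
cycles to 5% strain are protocol metadata), viscoelasticity, ultrasound
imaging and tracking noise structure (trace-level analysis replaces
image tracking), movement artefacts, and muscle physiology. Passing tests
therefore demonstrate that the analysis pipeline recovers the statistical
and mechanical structure it assumes — not that it is robust to every
artefact of real recordings.

## Verified behaviour

At the defaults, the test suite verifies: the exact reproduction of the
published summary table, significance pattern (exact p = 2/252 for every
starred comparison), Kruskal–Wallis H = 10.82 on the CSA groups and the
total-of-12 power computation; the FE verification oracles; the sweep
trends above; modulus recovery (0.5% noiseless / 5% per curve and < 1%
bias at 2% noise over 100 seeds); ≥ 90% Mann–Whitney power over 200 seeded
cohorts at the design effect size; and a type-I error within 0.05 ± 0.02
over 1000 null cohorts.
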