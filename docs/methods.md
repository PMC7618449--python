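# Methods

## Scope and data flow

plexflow models steady-state blood flow and oxygen transport on skeletonized
capillary networks of the retinal deep vascular plexus. A network enters as
a geometric graph (3-D node positions in μm, per-segment diameter and arc
length), either ingested from NEURON-style `.hoc` Imaris exports / the
tabular CSV format, or generated synthetically. The pipeline is

    ingest or generate → assign boundaries → resample → solve flow
    → solve oxygen → metrics → group summary.

Image segmentation itself is out of scope: the package starts where a
skeleton exists.

## Hemodynamic model

Each segment is a rigid Poiseuille conduit; the network reduces to a linear
resistor graph. Assumptions: steady, non-pulsatile flow; rigid walls; no
flow regulation; Newtonian plasma corrected by an empirical effective
viscosity.

* **Viscosity closure.** The in-vitro diameter/hematocrit law of Pries,
  Neuhaus & Gaehtgens (1992), constants verbatim, chosen because it is the
  standard closure for pore-network models of microvascular beds. At
  H_D = 0.45 the curve has its minimum (~1.25) near d = 7 μm and rises
  steeply below ~6 μm (η(4 μm) ≈ 2.31), so capillary-range narrowing is
  penalized twice: by the d⁴ conductance and by rising viscosity. A
  `constant` mode (μ_eff = μ_p) exists for analytic tests.
* **Hematocrit.** One uniform discharge hematocrit network-wide
  (default 0.45). No phase separation at bifurcations — this keeps the
  model linear; it overestimates red-cell flux into low-flow branches and
  is a known limitation.
* **Boundary conditions.** Degree-1 nodes on the low-x face of the bounding
  box are inlets, the high-x face outlets (per-node overrides available).
  Defaults P_in = 45, P_out = 15 mmHg — representative pre/post-capillary
  values. Real arteriole/venule connection points and pressures of the deep
  plexus are rarely known from images, so this is an explicit modelling
  choice, logged at the start of every run and echoed into every report.
* **Solve.** Dirichlet elimination on the weighted graph Laplacian, sparse
  direct solve; components without boundary nodes are reported and assigned
  zero flow; interior mass-conservation residuals above 1e−9·max|Q| raise.
  Segments with |Q| < 1e−12·max|Q| are flagged unperfused and excluded from
  transit-time statistics (avoids τ = volume/|Q| blow-ups).

## Oxygen model

Intravascular: content C(P) = C_Hb·H_D·S(P) + α_pl·P with Hill saturation;
convective balance Q·dC/dx = −q per vessel element; inlet blood enters at
the inlet PO₂. Radial intravascular gradients are not modelled (element
mean = wall value, i.e. no wall transport resistance).

Tissue: Michaelis–Menten consumption M(P) = M0·P/(P + P_m) sampled on a
regular lattice over the inflated bounding box (lumen-interior points
excluded). Vessels act as point sources, tissue cells as sinks of the
free-space kernel G(r) = 1/(4πDαr), superposed with a free far-field
constant P∞:

    P(x) = P∞ + Σ_v q_v G − Σ_t s_t G.

Unknown effluxes q and P∞ solve the vessel-surface matching system
(tissue PO₂ at each element wall = intravascular PO₂) bordered with the
balance constraint Σq = Σs.

### Numerical scheme

* Vessel–vessel kernel matrix: midpoint distances clamped below the source
  radius; diagonal from the finite-line surface potential
  2·asinh(l/2a)/(4πDα l).
* Tissue sink self-interaction: exact pairwise lattice sum via FFT
  convolution; the zero-offset term uses the center potential of the
  equal-volume sphere.
* The convective feedback (wall PO₂ falls when efflux rises, locally by
  q/(2Q C′(P)) and downstream through flow-fraction mixing) is linearized
  *into* the matching matrix. The sensitivity matrix is a property of the
  flow field and is built once per solve by the same downstream march that
  propagates contents. Leaving this feedback lagged makes the fixed point
  violently unstable, because the kernel collocation matrix is
  ill-conditioned.
* Supply limits: the march clamps contents to [0, C(max inlet PO₂)] —
  blood can neither deliver more oxygen than it carries nor absorb beyond
  the inlet ceiling. Elements whose requested efflux is undeliverable are
  pinned at the deliverable value (active set) and the balance constraint
  is redistributed over the free elements, so Σq tracks Σs even with
  clamps engaged.
* Outer fixed point: consumption evaluated at the previous tissue iterate
  (negative excursions clamped to zero inside M only, counted), tissue
  field damped by 0.5; termination when the max PO₂ update falls below
  tol·P_inlet (tol = 1e−6) or max_iter = 200 with an explicit
  non-convergence flag — never silent. Identical inputs give bit-identical
  fields.
* Final fields must be non-negative; sub-resolution negative excursions
  (> −1e−6·P_inlet) are clamped, anything larger flags the solve.

### Validation

* Zero consumption reproduces PO₂ = inlet PO₂ everywhere and E = 0 to
  machine precision.
* Krogh cylinder (single vessel, coaxial consuming cylinder, P_m → 0):
  radial tissue profile within 2% of the closed form over the mid-annulus,
  axial intravascular decline within the convective-budget closed form.
* Independent finite-difference oracle (below): ≤ ~3% max deviation at
  matched tissue points on tube, bifurcation and mini-plexus fixtures.

Validation fixtures run at elevated demand (M0 = 1e−3 cm³O₂·cm⁻³·s⁻¹) so
that diffusion drops are O(10 mmHg) and percentage comparisons are
meaningful, with consumption confined to a sleeve around the vessels so
that the free-space treatment and the oracle's no-flux box agree away from
the sleeve edge.

## Finite-difference reference solver

A deliberately independent route: 7-point second-order finite differences
for Dα∇²P = M(P) on a box grid with no-flux faces, vessels rasterized
geometrically as Dirichlet cells at the wall PO₂ of the nearest element,
coupled to the same convective march through the net grid efflux of each
element's cells, damped Picard inside (reaction lagged, factorized operator
reused) and a damped outer fixed point. The grid must resolve the lumen
(h ≲ r_lumen/2): a sub-grid line of Dirichlet cells has an effective radius
of ≈ 0.2 h, which would inflate the logarithmic part of the perivascular
drop. Fixtures therefore use 8 μm vessels on a 2 μm grid. Grid-refinement
against the Krogh closed form shows error ratios of ~2.8 (4→2 μm) and ~1.7
(2→1 μm) per halving — between first and second order, limited by the
rasterized lumen interface, not by the interior stencil (which reproduces
the 1-D slab parabola to machine precision).

## Parameters

| symbol | meaning | default | unit | note |
|---|---|---|---|---|
| μ_p | plasma viscosity | 1.2 | mPa·s | |
| H_D | discharge hematocrit | 0.45 | — | uniform, no phase separation |
| P_in / P_out | boundary pressures | 45 / 15 | mmHg | modelling choice, echoed |
| D | tissue O₂ diffusivity | 1.5e−5 | cm²/s | literature-typical rodent |
| α, α_pl | O₂ solubility (tissue, plasma) | 3.1e−5 | cm³O₂·cm⁻³·mmHg⁻¹ | |
| M0 | max consumption | 1e−4 | cm³O₂·cm⁻³·s⁻¹ | literature-typical rodent |
| P_m | Michaelis constant | 1 | mmHg | |
| C_Hb | RBC O₂ capacity | 0.5 | cm³O₂/cm³ RBC | |
| P50 / n_h | Hill curve | 38 / 2.7 | mmHg / — | rodent blood |
| P_inlet | inlet blood PO₂ | 60 | mmHg | |
| element_len | vessel discretization | 10 | μm | 15 in batch runs |
| tissue_spacing | tissue lattice pitch | 4 | μm | 8 in batch runs |
| P_h | hypoxia threshold | 15 | mmHg | HS curve over thresholds available |

All parameters are pydantic-validated and echoed in full into every
metrics report and run record, because the boundary pressures, viscosity
law, consumption constants and hypoxia threshold are modelling choices
rather than measured properties of any one dataset.

Batch-scale group comparisons (including `scripts/acceptance.py`) use
element_len = 15 μm and tissue_spacing = 8 μm; at the deep plexus'
~55 μm inter-capillary spacing this resolves the inter-vessel PO₂ field
while keeping a 12-network comparison under a minute. Solver-validation
fixtures run at or near the finer defaults.

## Synthetic deep-plexus generator

The generator emulates exactly the two statistical features the analysis
consumes — the diameter distribution and the spatial density of the mesh —
as a jittered planar lattice in a 10 μm slab over a 581 × 581 μm field
(55 μm pitch, in-plane Gaussian jitter sd 8 μm clipped to keep nodes off
the boundary faces, z-jitter confined to the slab). Per-edge diameters are
log-normal with arithmetic mean 5.5 μm and CV 0.15 (moment-matched
parameters), drawn for the *full* edge list before pruning from a dedicated
RNG stream so that presets differing only in `diameter_scale` produce
exactly proportional diameters. Pruning removes a fraction of grid edges
(healthy 0.10, diabetic 0.25) in seeded random order, skipping any removal
that would disconnect all inlet–outlet paths. Short stubs on the two x
faces (3 inlets, 3 outlets by default; counts configurable, since real
arteriole/venule connection counts are not known) provide the boundary
nodes for the geometric policy. RNG: numpy PCG64 with three named streams
(jitter / diameters / pruning) derived from the spec seed; output is
bit-stable across platforms.

The diabetic preset (diameters ×0.9, 25% pruning) encodes subtle capillary
vasoconstriction plus sparsification. What the generator does *not*
emulate: tortuous centerlines, spatially correlated diameters, flow-coupled
topology (real plexi are remodelled by perfusion), microaneurysms and
acellular capillaries. Passing tests on synthetic networks therefore
demonstrates correctness of the solvers and the direction of
geometry-driven effects, not quantitative agreement with any particular
retina.

Group designs derive per-network seeds as base_seed + i consecutively
across groups; `GroupDesign(paired=True)` instead reuses the same seed
sequence in every group for common-random-number comparisons.

## Degenerate inputs and tie-breaks

* Networks without both an inlet and an outlet in one component: error.
* Isolated components: zero flow, pressures reported as NaN, listed.
* Line-scan counting uses the half-open straddle rule, so a vessel chain
  passing exactly through a node on the line counts once; a segment lying
  exactly on the line counts once.
* Weighted medians take the first value whose cumulative weight reaches ½.
* Cohen's d with zero pooled variance is reported as NaN.
* Groups with fewer than two networks are excluded from summaries with a
  warning.

## Known limitations

* Uniform discharge hematocrit; no plasma skimming. Low-flow branches are
  modestly oxygen-optimistic.
* Free-space Green's kernel: no no-flux images at the domain boundary. For
  a quasi-planar plexus analyzed as an interior slab the induced error is
  small away from the outer rim (quantified against the FD oracle on
  fixtures); metrics that average over the whole lattice inherit a small
  rim bias.
* The oxygen fixed point is contractive while tissue PO₂ stays well above
  the Michaelis constant. In deeply supply-limited regimes (demand several
  times the deliverable O₂), the lagged consumption field can oscillate;
  such solves terminate flagged as non-converged rather than silently. The
  study conditions modelled here (healthy/diabetic presets at default
  demand) are far from this regime.
* At default demand the synthetic deep plexus is consumption-limited
  everywhere: tissue PO₂ stays in the high 50s mmHg and the hypoxia
  susceptibility at the 15 mmHg threshold is 0 for both presets. The
  diabetic effect is then carried by flow, transit time, extraction and
  the downward shift of the whole tissue-PO₂ distribution; HS becomes
  discriminating only at higher demand or lower perfusion pressures (the
  threshold-sweep mode exposes the full distribution).
* Vessels are sequences of straight elements; centerline curvature within
  an element is ignored by the oxygen kernel (midpoint sources).
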