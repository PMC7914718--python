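# Methods

`cardiomech` is a discrete-cell (agent-based) simulator of early cardiac
tissue formation in an engineered hydrogel. Cells — mesenchymal stem
cells (MSCs) and the cardiomyocytes (CMs) they differentiate into — are
quasi-spherical agents of radius `r_cell` living in an 800×400×400 µm
linear-elastic block of 20 kPa hydrogel with a stiffer (25 kPa), hollow,
optionally piezoelectric fiber of 40 µm outer diameter along the central
longitudinal axis. One time step represents 1 h of culture.

## Cell mechanics

**Contraction law.** Each cell samples its membrane with 24 quasi-uniform
unit directions (rhombicuboctahedron vertices; they partition into 8
octant faces of 3 nodes, which carries the 8-contact-face limit). The
internal stress at a node follows a three-branch piecewise law: a passive
line `K_pas·ε` outside the active strain range `[ε_min, ε_max]`, and two
active branches meeting at the strain of maximum force
`ε̃ = σ_max/K_act`. With the default constants (`K_pas = 2.8 kPa`,
`K_act = 7 kPa`, `σ_max = 0.25 kPa`, `ε_min/ε_max = ∓0.09`) the rising
branch is the line `σ = a + b·ε` with `a = 0.17898 kPa`,
`b = 4.78864 kPa`.

**Node equilibrium.** The matrix resists a contracting node with an
effective substrate stiffness `K_sub`, so the node settles where
`σ(ε) = −K_sub·ε`. For any `K_sub > 0` the intersection lies on the
rising branch, giving the closed form `ε = −a/(b + K_sub)`; a bisection
fallback covers non-default parameter sets. Stiffer surroundings mean
less contraction and more exerted stress.

**Motor forces** (consistent units µm/h/kPa make forces nanonewtons):

- traction: `F_i = σ_i·(S/24)·ζ·n̂_i` per active node, `S = 4πr²`;
  the resultant points toward the stiffer side (durotaxis);
- protrusion: `F_prot = κ·F_scale·ê_rnd`, `κ ~ U[0,1]`, `F_scale` the
  mean active nodal traction magnitude — random motility of the same
  order as traction;
- electrotaxis: `|F_EF| = c_ef·min(E, E_sat)·Ω·S` along the (radially
  inward) field, saturating at `E_sat = 1200 V/m`;
- cell–cell repulsion: screened Coulomb form
  `c_rep·(k_e/ε_r)(ΩS)²/r²` pushing overlapping neighbours apart;
- drag: `F = f_sh·η·v` with `f_sh = 6πr` for a single cell; velocities
  follow the overdamped balance, e.g. 1 nN moves a 10 µm cell at
  19.1 µm/h in the 1000 Pa·s gel.

Faces in cell–cell contact lose their matrix interaction: the blocked
octant's nodes are excluded from traction and from the stimulus average.

## Substrate sensing (compliance probes)

The full model this package re-implements couples every cell into one
finite-element problem. Here the coupling is one-way: the matrix is
solved once per load state and cells *read* it through compliance
probes. A probe applies a self-equilibrated force dipole (±1 nN at
`x ± r_cell·d̂`, each spread over an adhesion patch of fixed physical
size) and reads the relative approach `u` of the two patches:

```
K_sub(x, d) = c_sub · E_ecm · probe(fibered matrix) / probe(homogeneous matrix)
```

Three choices make this reading behave like the local material stiffness
rather than a mesh- or boundary-artifact:

1. *Self-equilibrated dipoles*: a cell pulls against its own footprint,
   not against infinity, so the far boundary contributes only at cubic
   order in distance.
2. *Symmetry (roller) boundary conditions* on the probe operator: each
   face acts as a mirror plane, emulating a gel that continues beyond
   the box. They also remove all rigid-body modes.
3. *Normalization by the identical probe on the fiber-free matrix*:
   whatever discretization artifact remains divides out exactly. A
   homogeneous gel is sensed as exactly `E_ecm` everywhere — the premise
   that a uniform hydrogel delivers a uniform stimulus — while the fiber
   ring reads a few percent stiffer (the blended-modulus contrast at the
   40 µm desk-scale resolution) and is the durotaxis target.

Under an applied strain the X-component of the field is augmented by the
local prestress ratio `σ_xx/E` (geometric stiffening of the loaded
direction). The engine precomputes the field at element centers once per
load state and interpolates; the point-probe operation is the reference
it is checked against.

**Calibrations** (all recorded in every run manifest):

- `c_sub` maps the dimensionless probe reading onto the stimulus scale
  of the fate model. It is identified once per matrix composition by
  bisection against the observable it controls: the median
  first-differentiation time in the stem-cell scenario equals 18 h
  (three fixed internal seeds; deterministic). A static anchor was
  rejected because migrating cells average the stimulus along their
  paths.
- `c_rep` scales the (otherwise astronomically large) printed Coulomb
  constants so repulsion equals the typical traction resultant at a
  separation of 2.5 r. The median resultant over admissible positions is
  used; the mean is skewed by the fiber region.
- `c_ef` scales the electric force so the saturated field force equals
  the cell's maximal nodal motor force (`a·S/24·ζ ≈ 9.4 nN`); the bare
  printed constants would drive cells at 240 µm/h and tear every
  junction. At 200 V/m cells move toward the fiber at ≈30 µm/h.
- `ζ = 1` (the printed adhesivity product normalized by itself) keeps
  nodal tractions of order nanonewtons.

## Fate

The stimulus is `γ_c` = mean equilibrium strain over active nodes
(negative under contraction; softer reading ⇒ more negative). The cycle
time is `t_mat = t_min + t_p·γ̄` with `t_min = 6 d`, `t_p = 200 d` and
`γ̄` the running average over the current cycle, clamped below at one
step; the maturation index is the ratio `MI = t_cycle/t_mat`, capped at
1, so a single anomalous step cannot complete a cycle. At `MI = 1`:

- an MSC whose instantaneous `γ_c` lies in the differentiation window
  `(−0.04, −0.01]` becomes an early CM (cycle resets);
- a free MSC/early CM with fewer than `CJ_max = 4` junctions divides;
  the second daughter is placed `2r` away along a random direction
  (re-sampled ≤50 times; crowding defers the division);
- any cell with `γ_c > 0.6` apoptoses (with the default calibration the
  achievable range `(−a/b, 0)` never reaches it, so the rule is latent);
- an early CM inside a stable group (junction component ≥ 2) matures to
  a late CM and never divides again.

With the homogenized sensed field, differentiation is nearly synchronous
(first event at the calibrated ≈18 h, all cells within a few hours
after). The reference model reports a wider 18–58 h spread driven by
spatial stiffness differences that the homogenized reading deliberately
suppresses; both satisfy "all cells differentiate within 75 h". A
related caveat: under the signed-`γ` cycle law, a *stiffer* reading
(near the fiber) gives a *less* negative stimulus and hence a slower
cycle — the opposite ordering to the narrative of the reference study,
which is internally inconsistent on this point (its Table constants
cannot give both an 18 h first cycle and faster-near-fiber maturation).
The consequence is visible in population sizes: proliferation here is
fastest in the bulk, so the strained/stimulated scenarios end with
slightly *fewer* cells than the plain fibered one rather than more.

## Junctions and collective migration

Cells at center distance `2r` (within a 2 % latch band that covers the
slack of the overlap resolver) are in contact. A contact becomes a
stable cell junction when its direction is aligned with the global
polarization: `l_ij = |ê_ij·G_pol| ≥ l_adh = 0.5` (boundary inclusive;
the projection is sign-free because a tissue axis has no sign). `G_pol`
is the normalized resultant of the per-cell polarizations, which combine
the traction and field force directions; degenerate resultants keep the
previous direction. Junctions form only between differentiated cells,
and persist: they act as distance constraints in the position resolver
(attached pairs are pulled back to contact), dissolving only when a
partner dies or a relocation rewires them.

Junction-connected components move as rigid groups dragged by the sum of
their members' motor forces with the ellipsoid-corrected shape factor
`f_sh = 6π·r_grp·((l_max·l_med)/l_min²)^0.096`, `r_grp = r·n^{1/3}`,
extents from the member-position covariance eigenframe plus one cell
diameter (the spherical limit recovers `6πr`; the printed formula omits
the 6, which the limit fixes). A group slower than `0.1·r_cell` per step
enters the relocation phase: non-articulation members may move to the
best free site at distance `2r` from another member along their own
desired direction, preserving connectivity.

Positions update by explicit Euler with movement substepping (at most
one cell diameter of advection between overlap resolutions, at most 5
substeps) followed by position-based relaxation: half-gap pushes for
overlapping pairs and half-gap pulls for stretched junctions, shared
over each cell's constraint count, iterated until the packing is clean
(≤ 10⁻⁷·r residual overlap); the box clamp and the radial fiber
exclusion are applied every sweep.

## ECM finite elements

Structured trilinear hexahedra (2×2×2 Gauss) with per-element modulus;
the fiber wall is thinner than a 40 µm element, so ring elements carry a
cross-section-area-weighted blend of `E_fib` and `E_ecm` (thickness
enters the mechanics through this blend). The displacement solve uses a
completed 3-2-1 point-constraint set plus imposed end-plane `u_x` (0 and
`ε·L`); it passes the uniaxial patch test to machine precision
(`ε_xx = 0.25`, `ε_yy = ε_zz = −0.10` everywhere for the homogeneous
block). Sparse direct factorization (`MMD_AT_PLUS_A`) is reused across
right-hand sides; the probe field costs one batched diagonal sweep per
geometry and is cached across replicates and scenarios.

## Electric field

The strained piezoelectric fiber generates a radial field, homogeneous
in the radial direction, pointed toward the axis (its outer surface
charges positively). The default `lookup` mode maps wall thickness to
the field magnitude (2→50, 5→75, 10→100, 18→200 V/m, linear in
between), zero without deformation. A reduced `constitutive` mode exists
for users with piezoelectric material data (effective strain coefficient
`d`, radial permittivity `D_r`): wall stress `E_fib·ε` drives an
electric displacement `d·σ`, a wall field `q/D_r`, a surface potential
`V = field·thickness` and a hydrogel field `V`/gap. It reproduces the
qualitative contracts (zero coupling ⇒ zero potential, linearity in
strain, growth with thickness); absolute potentials are not targeted
because the reference material constants are unpublished.

## Scenarios and desk-scale sizes

All four standard experiments seed 60 cells uniformly at random (no
overlap, clear of walls and fiber):

| scenario     | cells     | duration | strain | field  |
|--------------|-----------|----------|--------|--------|
| DIFF         | MSC       | 75 h     | 0      | off    |
| F-ECM        | early CM  | 250 h    | 0      | off    |
| MSF-ECM      | early CM  | 250 h    | 0.25   | off    |
| MSF-PZE-ECM  | early CM  | 250 h    | 0.25   | lookup |

Replicates draw disjoint seeds from a base seed. Desk-scale choices:
40 µm elements (2000 for the full box, FEM solve ≈ 3 s, probe field
≈ 20 s, cached), 250 one-hour steps with populations growing to
roughly 10³ cells (≈ 1 min per replicate on one CPU). The test suite
runs the cross-scenario comparisons at 1–2 replicate seeds per
condition; the acceptance script uses 3 (group sizes) and 5
(differentiation milestones).

## What the synthetic conditions do and do not show

The simulated conditions are the study conditions themselves (the
scenarios above); there is no external data. Passing tests demonstrate
that the implemented mechanisms reproduce the reference phenomenology at
desk scale — timed differentiation, junction-mediated aggregation into
one dominant group, faster fiber-ward migration under stronger coupled
stimuli — under the recorded calibrations. They do not validate the
model against wet-lab measurements, and three known gaps temper
quantitative readings: (1) the homogenized sensing compresses the
differentiation-time spread; (2) the stiffness–maturation ordering near
the fiber is inverted relative to the reference narrative (see Fate);
(3) group elongation responds only weakly to fiber thickness in the
purely mechanical scenarios, because a 2–18 µm wall modulates the
blended modulus of 40 µm elements by only a few percent.

## Numerical choices and degenerate inputs

Ties and guards: contact directions of coincident centers are
randomized; zero polarization resultants keep the previous direction;
collinear groups floor their transverse extents at one cell diameter;
cells on the fiber axis receive a zero field with a warning; divisions
that cannot place a daughter are deferred, never forced. Determinism is
exact for a fixed (configuration, seed) pair; replicate seeds come from
a seed sequence and stay below 2³¹.
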