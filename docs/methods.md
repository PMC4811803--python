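# Methods

## The decomposition

A tracked monolayer movie is a stack of integer label images (one
persistent label per cell, background 0) plus a lineage table (cell id,
mother, first/last frame, fate).  The analysis frame is the *Lagrangian
patch*: the group of cells whose centroids fall in one grid box on the
first frame (128 px ≈ 40 µm boxes with 50 % overlap by default), followed
thereafter, daughters inheriting their mother's patches.

All measurements are built on *half-links*: the directed vector from a
cell's area centroid to a neighbour's centroid, with c→k and k→c listed
independently.  Neighbourhood is shared boundary under 4-connectivity, so
corner-touching cells are not neighbours and four-fold vertex
configurations are recorded explicitly (and pooled with their category by
default).  Cells touching the image border have no reliable centroid and
are excluded, as are their links.

Between consecutive frames every half-link of either frame receives
exactly one category.  The base cell's event decides first, then the
neighbour's, so c→k and k→c can differ:

- **conserved** — same ordered pair present and valid in both frames;
- **division** — the base cell divides (its links at t) or is a newborn
  daughter (its links at t+δt; the daughter–daughter link is additionally
  flagged as a *sister link*, the raw material of the division-orientation
  tensor Do);
- **delamination / fusion / flux** — the base cell (or the neighbour)
  leaves the monolayer this way; links of a cell that *absorbs* a fusing
  partner are fusion-category on both frames, because its centroid jumps
  discontinuously at the merge and the geometric fit must not read that
  jump as deformation — the mirror of the mother/daughter rule;
- **integration** — a cell newly joins the sheet (its first-frame links);
- appearing links between two *persisting* cells are attributed to a
  removed shared neighbour (the contact closing over a delaminated, fused
  or exited cell) and disappearing ones to a removed or newly *inserted*
  shared neighbour, when one exists; ties follow the precedence
  division > delamination > fusion > integration > flux;
- **rearrangement** — everything that remains: T1 neighbour exchanges.

Classification completeness (every link, one category) is what makes the
balance equation exact bookkeeping rather than an approximation.

## Estimators

Let M = (1/N) Σ ℓ⊗ℓ be the per-link texture of a patch (µm²); its trace
is a mean-squared cell size, its deviator the cell-shape anisotropy.
With frame interval δt (5 min default; rates are reported per hour):

**Tissue deformation G and rotation Ω.** Least-squares fit of the link
displacement gradient over conserved links, using the *midpoint*
regressor: minimize Σ‖Δℓ − L m δt‖² with m = (ℓ+ℓ′)/2.  G = sym(L),
Ω = antisym(L).  Two properties motivated the midpoint form.  (i) It is
unbiased under stationary centroid tracking noise: regressing Δℓ on ℓ(t)
correlates the regressor with the noise in Δℓ and produces a spurious
contraction (≈ −0.01 h⁻¹ on a fluctuating but undeformed Potts tissue at
our scales); the midpoint decorrelates them.  (ii) It is a Cayley
discretization — for an affine map F it returns exactly
(2/δt)(F−1)(F+1)⁻¹, which equals the generator of F = exp(Lδt) to
O((Lδt)³/12) and is exactly antisymmetric for a pure rotation, so a
rotating pattern yields Ω without spurious strain.

**Shape change S.** The rate carried by the change of the total texture:
the unique symmetric positive F with F M(t) F = M(t+δt) (a 2×2 Riccati
solve via the matrix geometric mean), reported in the same Cayley form
S = (2/δt)(F−1)(F+1)⁻¹.  Two non-obvious choices:

- *Total* texture, not a topology-corrected one.  Because M is a per-link
  average, link creation/destruction enters S through the 1/N
  renormalization (divisions halve the mean cell size through it), and
  this is exactly what makes S + ΣP telescope back to the conserved-link
  deformation G.  Subtracting the topological terms from the texture
  change before computing S double-counts them and breaks the balance.
- The Riccati/Cayley solve is exact for rotation-free affine maps even
  when the map does not commute with M, so G = S holds to machine
  precision on affine fixtures at the link level, and to rasterization
  noise (~10⁻⁴ relative) on rendered fixtures.

**Topological process rates.** For each process P with appearing links
(geometry at t+δt) and disappearing links (at t),

    T_P = [ Σ_app ℓ′⊗ℓ′ − Σ_dis ℓ⊗ℓ − Δn_P · M ] / (N̄ δt)
    P   = −¼ (M⁻¹ T_P + T_P M⁻¹),

with N̄ the mean of the two frames' link counts, M the midframe texture
and Δn_P the process's net link-count change.  The −Δn_P·M term is the
renormalization of the per-link mean that the process causes; without it
the sign contracts fail (divisions add many short links and would appear
contractile).  With it: divisions carry Tr D > 0 of order the cell-number
growth rate, delaminations Tr A < 0, integrations Tr N > 0,
count-preserving T1s carry the pure orientation exchange — a T1 elongates
the patch along the axis of the *disappearing* centroid link, which is
where the R bar points.

**Balance.** The residual G − (S+D+R+A+N+C+J) is computed per patch and
interframe and summarized as ‖residual‖ / max(‖G‖, Σ‖P‖).  With the
estimators above the identity holds up to the commutator error between
the least-squares fit and the texture symmetrization plus O(change²)
linearization error; on the synthetic single-process scenarios at test
scale (61 frames, ~80 cells) the window-averaged residual is 0.3–2.4 %,
against a 5 % acceptance tolerance.  Keeping per-interframe topological
changes small (a few events per interframe) matters: the identity is
first-order in the per-interframe change, which is why the generator
staggers delaminations and removes flux cells a few at a time.

**Weights.** Boxes near the tissue boundary get weight
w_a = (a_norm · Rc_norm)², where a_norm is the relative cell count (area)
normalized by its bulk minimum and capped at 1, and Rc_norm the likewise
normalized reciprocal 2-norm condition number of M (1 for isotropic link
sets, 0 for degenerate ones).  Bulk = patches at least three patches from
the boundary; when a movie is too small to contain bulk patches the
driver (bulk_mode="auto") falls back to the best available patch as
reference — the strict variant raises instead.  Stress maps use (a_norm)²
only, since no texture inversion is involved.  Time averages are sliding
w_a-weighted means (2 h windows evaluated every frame), carrying
W_a = mean w_a.

## Cohort statistics

Landmarks (bristle positions) registered per animal: archetype = per-landmark
across-animal barycentre; per-axis scale α = Σx·x̄ / Σx², the least-squares
dispersion minimizer; left hemi-tissues mirrored first (n → −n, Q_xy → −Q_xy,
Ω → −Ω).  Time registration aligns the first crossing of ¾ of the rotation-rate
peak on the rising flank (linear interpolation between frames; the ascent is
steep where the peak is flat).  Cohorts acquired at a faster developmental
rate divide time intervals by a configured factor (default 0.9).  Ensemble
means are W_a-weighted; variability is the unbiased weighted standard
deviation with prefactor ΣW/((ΣW)²−ΣW²), reducing to 1/(N−1) at unit
weights; a box is significant when the mean deviator amplitude
√((Q̄xx−Q̄yy)² + 4Q̄xy²) is at least the corresponding variability amplitude.
Genotype comparison: ΔP = P_mutant − P_wt per box, with ΔP∥ its projection
on the wild-type CE direction.

## Force inference

Vertex force balance at every interior vertex (incident to no boundary
cell): Σ_j γ_j t̂_j + Σ_j (p_left − p_right)(L_j/2) n̂_j = 0, with straight
junction chords.  The homogeneous sparse system is solved by maximizing
marginal likelihood with a prior γ ~ N(1, σ²/h); h is scanned
logarithmically over 10⁻³…10³ and selected by minimizing
ABIC(h) = dof·log S(h) − K log h + log det A(h), evaluated through sparse
LU factorizations; a weak zero-mean pressure prior pins the
pressure-offset gauge.  Outputs are normalized to mean γ = 1, mean p = 0
(the two quantities image analysis cannot determine).  Patch stress uses
the Batchelor formula; only tensions enter its deviator.

The recovery benchmark is a synthetic foam built by the reciprocal-diagram
(Maxwell–Cremona) construction: a Voronoi tessellation of jittered
hexagonal seeds is in exact equilibrium, with zero pressures, under
tensions equal to the dual Delaunay edge lengths — each Voronoi edge is
the 90°-rotated Delaunay edge, so the tension vectors around a vertex
close into a triangle.  Seed jitter 0.22 gives a near-log-normal tension
spread (σ of log ≈ 0.17–0.19); inference recovers the true tensions with
correlation ≥ 0.93 at ~120 cells.  A direct tension-only relaxation was
tried first and abandoned: constant-tension energy minimization is
degenerate (edges collapse), leaving the "ground truth" far from
equilibrium.

## Synthetic data (morphosim)

Cellular Potts model on a square lattice: energy = uniform interfacial
energy per unlike 8-neighbour pair (J_cell = 1, J_medium = 1.6), quadratic
area constraint λ(A−A₀)² (λ = 0.4), and, in forced scenarios, a potential
−f·((x−cₓ)/W)² rewarding cell pixels far from the patch centre along x.
One Monte-Carlo step visits every pixel once in random order and proposes
copying a random 8-neighbour's label; decreases are accepted, increases
with a constant fluctuation allowance (0.05).  A local ring-arc test keeps
cells simply connected (a post-sweep repair reassigns rare stray
fragments); the lattice boundary behaves as medium — the patch never
reaches it.  All randomness is pre-drawn from one seeded generator, so a
fixed seed reproduces output bit-exactly; labels are never recycled.

Scenario specifics: divisions — target areas grow with 0–40 % initial
cycle asynchrony; at doubling, the cell splits through its centroid
perpendicular to the long axis of its pixel-inertia tensor, daughters
keep the initial target (no regrowth).  Delamination — half the cells,
chosen at random, shrink their target to zero, each over a few interframes
with staggered starts (in vivo apical closure takes minutes, and gradual
events keep per-interframe texture jumps small); a fully shrunk cell
lingering below 5 px is closed outright.  Integration — the delamination
movie reversed, with the lineage remapped.  Fusion — junction removal by
direct label merging at spread-out interframes, then relaxation.  Flux —
medium-adjacent cells removed a few per interframe.  Affine fixtures —
Voronoi polygons transformed exactly at the vertex level by constant-rate
maps exp(Lδt) and re-rasterized, with no relaxation: dilation then pure
convergence–extension, a 90° rotation, and a CE round-trip (forth along
x, back along y) whose |S| path integral must not vanish although start
and end patterns coincide.

What the generator does *not* emulate: segmentation and tracking errors
(labels are perfect), curved tissue geometry, junction curvature,
out-of-plane motion, and realistic spatial gradients of the processes.
Passing tests therefore demonstrate the correctness of the measurement
machinery on clean tracked data, not robustness to imaging artefacts.

## Problem sizes and numerical choices

Validation suites run the scenarios at 61 frames of 220–260 px lattices
with ~80 cells (affine fixtures: 21 frames, 420–600 px, ~100 cells) —
large enough that window-averaged residuals sit well below the 5 %
tolerance, small enough to iterate quickly.  Degenerate inputs yield
*missing* values rather than zeros: a singular texture (all links
parallel) drops the box through its Rc weight; a zero-norm G makes P∥
undefined (NaN); a deviator below 10⁻¹² has no bar angle.  The affine
validation target (measured vs imposed rates within 0.3 %) is met at
≈ 0.08–0.12 % with per-interframe rates of 10⁻²; the residual error is
rasterization noise in the polygon centroids, which averages down with
cell count and interframe count.
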