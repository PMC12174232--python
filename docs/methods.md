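# Methods

## Model classes

The toolkit discretizes six classes of problems on a compact domain
Ω ⊂ R^d (d = 2, 3) with boundary surface Γ = ∂Ω (closed, so surface
problems need no boundary conditions):

1. elliptic bulk: −d_Ω Δu + αu = f, with homogeneous Dirichlet or Neumann
   data (α > 0 required under pure Neumann data);
2. semilinear parabolic bulk systems ∂u_i/∂t − d_i Δu_i = f_i(u, x, t);
3. elliptic surface: −d_Γ Δ_Γ v + βv = g (β > 0);
4. semilinear parabolic surface systems;
5. coupled elliptic bulk–surface with flux condition ∂u/∂n = γu + δv, the
   flux entering both the bulk boundary term and the surface equation's
   conormal term.  γ, δ may take either sign (the worked benchmark uses
   γ = −1, δ = 2);
6. coupled parabolic bulk–surface reaction–diffusion systems, where the
   supplied flux functions equal d_i ∂u_i/∂n on Γ.

## Spatial discretization

Lowest-order (k = 1) virtual elements: one degree of freedom per mesh
vertex, local spaces containing harmonic non-polynomial functions that are
handled only through the elliptic projector Π onto linears.  Π is computed
from boundary data alone: edge-wise trapezoid rule in 2D (exact, since
traces are linear on edges), and in 3D face integrals
∫_F v = |F| (Π_F v)(area centroid of F) using each face's own 2D projector.
The constant part of Π is fixed by matching the vertex average.  Scaled
monomials are centered at the vertex average and scaled by the element
diameter; the monomial Gram matrix H is integrated exactly (degree-2
simplex quadrature on the star decomposition from the element's star point
P0).  Stabilization is the "dofi–dofi" form (I − Π)ᵀ(I − Π), scaled by 1
(2D stiffness), the element diameter (3D stiffness), and the element
measure (mass, both dimensions).  These scalings are the unique choice
consistent with the closed-form square/cube matrices that the quadrature
path must reproduce (and does, to ≤ 1e-14; the square stiffness exactly).

On simplicial elements the stabilization annihilates the local space and
the matrices coincide with classical P1 finite elements (verified against
an independent FEM oracle to 1e-12).  Surface operators are P1 finite
elements on segments (2D) and flat triangles (3D).  For flat triangles the
k = 1 projection is the identity, so the surface consistency matrix CS
equals the surface mass MS; CS is still produced as a separate output so
the 3D interface stays uniform with constructions where the two differ.

## Mesh generation

The bulk–surface marching-squares/cubes variant: interior cells are kept as
square/cube elements, cut cells become polygons/polyhedra whose boundary
includes the piecewise-linear isosurface, so Γ_h = ∂Ω_h holds by
construction (asserted in tests by facet matching).  Details that matter:

- **Crossing nodes** are located by bisection of f restricted to each
  sign-change grid edge (52 iterations, i.e. to machine precision), not by
  linear interpolation of the corner values.  Node counts are identical
  either way, but boundary nodes then lie on Γ itself, which improves the
  boundary consistency of the discretization by a visible constant (the
  disc benchmark error changes from 1.59e-2 to 2.37e-2-level agreement with
  the reference values; the ball Dirichlet benchmark by an order of
  magnitude).
- **Saddle (ambiguous) cells and faces** are resolved by the sign of f at
  the cell/face center; disconnected pieces become separate elements
  (edge-connected-component splitting of the face set).
- **Patch triangulation.**  The isosurface patch inside a cut cell is a
  closed loop (or loops) of crossing nodes assembled from the per-face
  chords.  Loops with more than three vertices are triangulated by a small
  dynamic program choosing the diagonals that minimize
  Σ area(T)·|f(centroid(T))| — the triangulation that hugs the zero level
  set, in the spirit of the asymptotic decider, and fully deterministic.
  The patch triangles are both faces of the cut polyhedron and the surface
  elements.
- **Node merging.**  `tol` is the minimum distance between distinct nodes:
  crossings within tol of a grid node snap to it, clusters of crossings
  within tol collapse to their mean.  The default is 1e-6·dx, which
  de-duplicates only coincident nodes (e.g. where f vanishes exactly at a
  grid corner, since the inside test is f ≤ 0).  The benchmark node counts
  (disc 1336; ball 16600/3888; torus 8144/3008) are reproduced exactly
  under this default; larger tol trades those counts for the removal of
  sliver elements (see Limitations).
- **Non-square boxes** are covered by ceil(side/dx) congruent cells with
  the box enlarged symmetrically, so all cells are congruent
  squares/cubes; this convention makes the torus mesh size √3·dz.
- Bulk polygon rings are stored counterclockwise; polyhedron faces are
  re-oriented outward at construction; surface facets are oriented so the
  implied normal points toward f > 0.
- Star points P0: cell centers for full cells, vertex averages for cut
  cells (checked; star-shapedness of marching-cell cuts holds for the
  geometries used here, and a failed check raises rather than silently
  degrading quadrature).

## Time discretization

IMEX Euler with timestep τ: diffusion implicit, kinetics (and coupling
fluxes) explicit, evaluated nodally at t_{k−1} and weighted by the mass
matrix.  N_T = ceil(T/τ) steps at t_k = kτ (the final step may overshoot T
by less than τ).  Each implicit matrix (M + τ d K, MS + τ d KS per
component) is LU-factorized once.  The discrete mean ∫ u is conserved
exactly for source-free Neumann heat flow (K1 = 0 and symmetry).
Indicators for the first component are recorded at every step:
‖u₁^k − u₁^{k−1}‖_{L²}/τ with ‖w‖² = wᵀMw (MS for surface-only problems),
and ⟨u₁^k⟩ = 1ᵀMu₁ᵏ / 1ᵀM1.

Spatially uniform steady states of the reaction kinetics are exact discrete
fixed points: constants are in the kernel of K and KS, so the IMEX step
reproduces them whenever the kinetics and fluxes vanish there (the
activator-depleted state (a+b, b/(a+b)²) and its bulk–surface counterpart
are verified to 1e-9 over many steps).

## Error evaluation

VEM basis functions are not known in closed form, so errors are measured on
the piecewise polynomial projection of the solution: the bulk consistency
matrix C is the Gram matrix of the projected basis, giving
err = sqrt(eᵀCe / u_exᵀCu_ex) with e the nodal error; surface errors use
MS, and coupled errors combine both quadratic forms under one square root.
The measure is relative (homogeneous of degree zero) and vanishes iff the
nodal vectors coincide.

## Synthetic data and what the tests show

All inputs are analytic: level sets with bounding boxes, polynomial /
separable exact solutions, and named kinetics presets (activator-depleted
a = 0.1, b = 0.9, d₂ = 10, γ = 300; the coupled preset adds the exchange
coefficients α₁ = β₁ = 5/12, α₂ = 5, κ₂ = 5, β₂ = κ₁ = 0).  Initial data
for pattern-formation runs are uniform steady states plus seeded uniform
perturbations of amplitude 1e-3.  The synthetic ellipsoid triangulation
(subdivided icosahedron mapped to semi-axes (2, 1, 1.5)) stands in for a
third-party surface mesh generator to exercise the import path; it matches
that format, not any particular generator's node placement, so node-count
statistics of external meshes are not reproduced, only the solver behaviour
on them.

The full Turing runs (τ = 1e-5 with T = 10 on the ellipsoid, T = 5 on the
torus) are long; the test suite runs reduced-scale versions (ellipsoid:
refine-3 surface, τ = 1e-3, T = 2; torus: Nx = 6, τ = 1e-5, T = 1) and
asserts the qualitative outcome — a spatially inhomogeneous field far above
the perturbation amplitude with a decaying time-derivative norm — rather
than pointwise fields, since the discrete RNG and pattern phase are not
universal.  For the coupled system the timestep stays at 1e-5 even at
reduced scale: the explicitly treated membrane flux (γ_Γ κ₂ = 1500,
amplified by the surface-to-bulk mass ratio on sliver cut cells, up to
~100 on the coarse torus) makes larger steps unstable.  This is a genuine
property of the IMEX splitting on unmerged marching-cube meshes, not an
artifact of the reduced scale.

## Numerical choices and degenerate inputs

- Sparse LU (SuperLU via scipy, with its default fill-reducing ordering)
  for all linear systems; the coupled elliptic block system is assembled
  unsymmetric and solved as one monolithic system.
- Homogeneous Dirichlet data are imposed by row/column elimination; the
  restricted operators remain symmetric positive definite.  The load keeps
  the full mass-matrix rows, so source values at boundary nodes contribute
  to adjacent interior equations.
- Degenerate geometry (zero-area rings, zero-length edges, non-watertight
  face lists, empty level-set domains) raises typed exceptions naming the
  offending entity; nothing is silently dropped except sub-tol duplicates
  and cut fragments with fewer than 3 distinct vertices (2D) / 4 vertices
  (3D), which have measure zero at the merge tolerance.
- Mesh generation is fully deterministic (bit-identical repeated runs).

## Limitations

- k = 1 only; no anisotropic diffusion, curved elements, nonzero Dirichlet
  data, or evolving domains.
- Marching squares/cubes does not guarantee shape regularity: cut cells can
  be slivers.  This affects constants (not rates) in the error bounds and
  sets the explicit-flux stability bound above.  Merging with a larger tol
  removes slivers but perturbs the boundary and can, at aggressive
  tolerances, degenerate faces; the generator then raises.
- The surface of a 2D domain must be a closed curve lying strictly inside
  the bounding box for Γ_h = ∂Ω_h to describe the whole boundary (an
  all-inside box yields an empty surface mesh by design).
- Interactive plotting is out of scope; solutions are exported to VTK
  (including the x ≤ xcut cut-surface view of 3D interiors) for external
  viewers.
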