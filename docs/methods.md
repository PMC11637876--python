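# Methods

## Model

`osteoadapt` simulates load-adaptive bone remodeling on a macroscopic
continuum: a cube of trabecular bone, discretized into identical cubic
(voxel) finite elements, whose per-element apparent density
ρ (g/cm³) evolves in response to a mechanical stimulus derived from
strain energy density (SED).

Each remodeling iteration couples three stages:

1. **Elasticity.** Every element is linear, elastic and isotropic with
   Young's modulus given by a power law of density, E(ρ) = a·ρᵇ MPa,
   and a fixed Poisson ratio ν = 0.3. The cube is loaded by a
   compressive surface pressure on its top face, decreasing linearly
   from p_max = 10 N/mm² at x = 0 to zero at x = L, uniform in z;
   the bottom face is fixed vertically. A sparse direct solve yields
   nodal displacements and the apparent SED U_a of every element,
   evaluated from the trilinear interpolation at the element centroid.

2. **Stimulus with spatial influence.** The local stimulus at element x
   is a distance-weighted sum over elements j of the specific SED
   excess, with the exponential influence function
   w(x, j) = exp(−dist(x, j)/D) over element centroids. D is the
   distance at which the influence decays to e⁻¹ ≈ 36.8% of its
   zero-distance value; it plays the role of the osteocyte sensing
   range and damps element-scale checkerboard instabilities. The sum
   includes the self term (weight 1) and is **not** normalized by the
   weight sum.

3. **Density update.** The density rate is

       dρ(x)/dt = τ · Σ_j w(x, j) · (U_a,j / ρ_j − k)

   integrated in time by one explicit Euler step per iteration
   (Δt = 1 time unit; τ carries the rate scale) and clamped to
   [ρ_min, ρ_max]. ρ_j in the stimulus denominator is the current,
   already-clamped density.

The loop repeats until the iteration budget is exhausted, or stops
early if the elasticity stage fails ("unsolvable" structure; see
below). Convergence bookkeeping records the mean absolute density
increment per iteration; a run is CONVERGED if that metric is below
`tol` at the final iteration, and the first iteration at which it
dropped below `tol` is recorded separately. The pipeline has no random
component: identical configurations give bit-identical traces.

## Units

Lengths in mm, forces in N, moduli and stresses in MPa, densities in
g/cm³. In this system SED is in MPa ≡ J/cm³, so the specific stimulus
U_a/ρ is in J/g with **no conversion factor**, matching the units of
the reference stimulus k. τ is in (g/cm³)²/(MPa·time unit), which is
dimensionally consistent with one Euler step per iteration.

## Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| cube edge L | 5.0 | mm | domain size |
| element edge h | 0.25 | mm | 20³ = 8,000 elements |
| material law | E1: 1904·ρ^1.64 | MPa | alternatives E2: 2038·ρ^2.5, E3: 3227·ρ^3.0 |
| ν | 0.3 | – | Poisson ratio |
| p_max | 10 | N/mm² | graded top-face pressure |
| ρ₀ | 0.87 | g/cm³ | homogeneous initial density |
| ρ_min, ρ_max | 0.0174, 1.74 | g/cm³ | density clamps |
| D | 0.20 | mm | spatial influence parameter |
| k | 0.025 | J/g | homeostatic reference stimulus |
| τ | 1.0 | (g/cm³)²/(MPa·tu) | rate constant |
| max_iter | 200 | – | iteration budget |
| tol | 0.01 | g/cm³ | mean-increment threshold |
| cutoff_multiple | 5 | ×D | kernel truncation radius |

The 13 sensitivity scenarios (`Baseline`, `S1`–`S12`) vary the material
law, D ∈ {0.10…0.30} mm, k ∈ {0.005…0.045} J/g and τ ∈ {0.5, 1, 2}
one factor at a time.

## Numerical choices

**Discretization.** 8-node trilinear bricks, 2×2×2 Gauss quadrature for
stiffness. All elements are identical cubes, so a single unit-modulus
24×24 element matrix is computed once and scaled per element, and
assembly reduces to one vectorized scatter. SED uses the single
centroid evaluation point.

**Boundary conditions.** Fixing only the vertical displacement of the
bottom face leaves two lateral translations and one rotation about y
unconstrained. Three auxiliary pins remove them: x and z at the bottom
corner (0,0,0) and z at the adjacent bottom corner (L,0,0).
Homogeneous strain states are compatible with these pins, so
uniform-pressure patch tests reproduce the closed-form solution
(vertical stress −p everywhere, SED = p²/2E) to solver precision, and
any alternative rigid-body handling changes displacements only by a
rigid motion, to which SED is invariant.

**Surface load.** The pressure profile is integrated against the
bilinear face shape functions of each top facet with 2×2 Gauss points,
exact for a linear-in-x pressure; the resultant is p_max·L²/2 for the
graded profile.

**Solver and the UNSOLVABLE status.** Sparse LU factorization
(SuperLU) after eliminating constrained DOFs. A solve counts as
unsolvable when factorization fails, the solution contains non-finite
values, or the relative equilibrium residual exceeds 1e-4. This is
deliberately a *recorded status*, not an exception: density fields
driven by the higher-power laws E2/E3 can stiffen self-reinforcingly
into extreme-contrast structures that a solver rejects, and the run
must terminate gracefully with the failing iteration on record. The
direct solver tolerates the low-density conditioning (E3 at the lower
clamp is ≈ 0.017 MPa) far longer than iterative methods would.

**Kernel truncation.** Pairs beyond `cutoff_multiple·D` (default 5D,
per-pair relative weight below e⁻⁵ ≈ 0.7%) are dropped and the weights
stored sparsely via a k-d tree radius query; `cutoff_multiple=None`
switches to the exhaustive all-pairs sum. Note that the *collective*
truncation error is the dropped per-pair weight times the number of
dropped pairs: on coarse meshes whose element spacing is comparable to
the cutoff radius, trajectories can differ from the exhaustive sum by
~1e-3 g/cm³ over tens of iterations (still well below the 0.01 g/cm³
convergence tolerance). On the fine 0.25 mm production mesh the
dropped pairs are farther into the exponential tail relative to the
retained mass, and the truncation is correspondingly more accurate.

**Convergence protocol.** Runs always continue to `max_iter` (unless
unsolvable). Early stopping on `tol` alone is not used, because
seemingly converged early density evolutions can still drift into
unsolvable structures; running the full budget and recording the first
tol-satisfying iteration keeps both pieces of information.

**Tie-breaks and degenerate inputs.** The density clamp is applied
after every Euler step; elements at ρ_min keep their small positive
modulus (no element removal — the model is a continuous solid volume).
Zero applied load short-circuits to the exact zero solution, and the
rate law then resorbs every element monotonically to the lower clamp.

## Desk-scale (scaled) mode

Full-scale runs (8,000 elements × 200 iterations) take tens of minutes
on one CPU. `scaled=True` substitutes a 10³-element mesh (h = 0.5 mm)
and a 50-iteration budget. The scaled mode exercises every code path
and preserves the qualitative resorption/formation balance, but it is
**not** a physical surrogate for the production mesh in one important
respect: the checkerboard-mitigation effect of D requires D to be at
least comparable to the element size. On the scaled mesh all studied
D values (0.10–0.30 mm) are *below* h = 0.5 mm, so the kernel cannot
smooth element-scale alternation there; instead, larger D accelerates
structure formation and *raises* neighbor-contrast metrics. The
decreasing checkerboard-vs-D trend is therefore a property of the
fine mesh only, and the scaled checkerboard assertion in the
acceptance suite documents this limitation by failing honestly (see
the repository's test suite) rather than being weakened.

## Morphometrics

* `checkerboard_index`: mean over elements of |ρ_e − mean of
  face-adjacent neighbor densities|, normalized by the clamp range.
  0 for locally constant fields, 1 for a perfect parity alternation
  between the clamps. Note it responds to *any* neighbor-scale
  contrast, including genuine trabecular structure, not only to the
  numerical checkerboard artifact.
* `bone_volume_fraction`: fraction of elements with ρ ≥ threshold
  (≥ convention at the boundary).
* `symmetry_error`: mean |ρ_e − ρ_mirror(e)| about the mid-z plane.
  The benchmark load is uniform in z, so this should remain at
  round-off level throughout a run (observed: ~1e-15).

## Known limitations

* The influence sum is not normalized by the weight sum, so the
  effective remodeling gain per iteration scales with the number of
  retained neighbors, roughly (D/h)³ for D ≳ h. On fine meshes with
  large D the explicit Euler update can therefore enter clamp-to-clamp
  oscillations instead of settling; lowering τ, or normalizing the
  kernel (a deliberate departure from the rate law as implemented),
  restores stability at the cost of slower evolution.
* Single load case and cubic domain; no tetrahedral/adaptive meshes.
* Linear kinematics and isotropic elasticity only; no lazy zone,
  rate limiting, or overload resorption in the rate law.
* Trabecular thickness is not measured; bone volume fraction and the
  checkerboard index are the quantitative stand-ins.
* The checkerboard index conflates artifact and structure (above);
  a spectral or parity-correlation detector would separate them.
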