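# Methods

## The model

`neurocable3d` solves the three-dimensional generalization of the cable
equation.  The intra- and extracellular spaces Ω_in and Ω_out are treated as
purely resistive volume conductors (no free charge), so both potentials obey
Laplace equations, coupled only through the membrane Γ where the electric
flux is continuous and equals the total transmembrane current density
j_all(V_m):

    -ΔΦ_out = 0                 in Ω_out
    -σ_out ∇Φ_out · n = j_all   on Γ          (n = intra→extra normal)
    -ΔΦ_in  = 0                 in Ω_in
    -σ_in  ∇Φ_in  · n = j_all   on Γ
     V_m = Φ_in − Φ_out         on Γ

Because V_m lives only on the two-dimensional membrane, it cannot be
discretized alongside the volume unknowns directly.  The solver therefore
introduces the harmonic *extension field* Φ_out^IN: the continuation of the
extracellular potential into the cell interior (zero interior source,
Dirichlet-coupled to Φ_out on Γ).  Subtracting it from the intracellular
problem turns V_m = Φ_in − Φ_out^IN into a volumetric unknown on Ω_in:

    -ΔΦ_out^IN = 0 in Ω_in,   Φ_out^IN = Φ_out on Γ
    -ΔV_m      = 0 in Ω_in,
    -σ_in ∇V_m · n = j_all(V_m) + j_eph  on Γ,
     j_eph := σ_in ∇Φ_out^IN · n.

j_eph is the **ephaptic current**: the route by which the extracellular
field feeds back onto every membrane.  It can be toggled off, which
decouples the membrane problem from the field while leaving the forward
map (membrane currents → extracellular potential) intact; the paired
ephaptic experiment is exactly this toggle under identical stimulation.

The membrane current is composed per surface patch:

    j_all = c_m dV_m/dt + δ_active j_HH(n,m,h,V_m) + δ_stim j_stm(t)
            + δ_syn j_syn(V_m|pre, t)

with Hodgkin–Huxley channel kinetics on active membrane (soma, nodes of
Ranvier), capacitive-only current on myelin (reduced sheath capacitance),
capacitive+leak on passive dendrites, and latched threshold synapses: once
the area-weighted mean presynaptic V_m exceeds the threshold, a predefined
postsynaptic current pulse runs for its full duration regardless of the
presynaptic potential afterwards.

### A consequence: no current monopole

Integrating −ΔΦ_in = 0 over the cell gives ∮_Γ j_all dS = 0 at every
instant: the membrane's influx and outflux always balance.  The multipole
analyzer makes this quantitative on a spherical cell: expanding
Φ_out = Σ b_lm r^−(l+1) Y_lm and matching −σ_out ∂Φ/∂r = j_all at r = R
gives

    b_lm = R^(l+2) / ((l+1) σ_out) ∮ j_all Y_lm dΩ,

so b_00 ∝ ∮ j_all dS = 0: the extracellular potential has no monopole and
decays at least as r^−2.  (This sign/σ convention is the self-consistent
one obtained from the radial-derivative matching; it is what the
`fit_coefficients` implementation uses.)

## Discretization

**Grids.** Tetrahedral meshes with labeled subdomains, membrane triangles
(oriented intra→extra) and per-triangle patch labels.  All geometries are
generated programmatically and deterministically: a polygonal-cross-section
prism cylinder, an icosphere-based ball-in-shell, and Kuhn-tetrahedral
voxel grids for multi-cell arrangements.  The unbounded extracellular space
is truncated at a configurable margin; the far boundary condition is
`grounded` (Φ_out = 0, the default — consistent with the multipole decay)
or `insulated` (zero-flux plus a one-point gauge pin, since the pure
Neumann problem has the constant in its kernel).

**Finite volumes.** Vertex-centered box method on the barycentric dual
grid: each tet is split by edge midpoints, face barycenters and its own
barycenter; the sub-volume around each vertex is exactly V/4, and the dual
face of each tet edge is a (generally non-planar) quadrilateral whose
*integrated* normal is stored exactly (it depends only on the contour).
Since P1 shape-function gradients are constant per tet, the stiffness
entries a_kj = ∮_∂Bk σ ∇b_j · n dS are exact; interior rows sum to zero,
which is what makes the discrete flux-balance identity hold to roundoff.

Membrane flux terms enter the three field equations through per-vertex
patch areas (each membrane triangle contributes A/3 per vertex).  The
discrete ephaptic current is recovered as the consistent boundary flux
−(S_in Φ_out^IN)_k at membrane rows, which is exact for linear fields.

**Time stepping and Newton.** Backward Euler (first order; dt default
10 µs, the gating time scale).  The per-step nonlinear system is solved by
Newton iteration.  Gating is handled in one of two modes:

* `monolithic` (default): the unconditionally stable implicit gating update
  x⁺ = (x + dt α)/(1 + dt(α+β)) is *eliminated* per vertex, so Newton sees
  the composed map V_m → gating → j_HH; the membrane diagonal of the
  Jacobian is formed by finite differences of this composed map.
* `staggered`: gating frozen at the previous step's V_m, making the step
  linear (Newton converges in one iteration); cheaper, and used by the
  threshold-calibration experiment where both arms share the identical
  discretization.

The Newton convergence norm is the residual **ℓ1 norm** (default
tolerance 1e-6 nA).  This choice is deliberate: |Σ_k j_all,k A_k| per cell
is a sub-sum of residual entries, so a converged step *provably* satisfies
the discrete flux balance (and hence the vanishing monopole) to the same
tolerance.  The floating-point floor of the telescoping sums is ~1e-8 nA on
the test meshes, comfortably below the tolerance.

**Linear solver.**  ILU-preconditioned BiCGstab by default, with the
incomplete factorization cached across Newton iterations and time steps —
only the membrane diagonal of the Jacobian changes in time, and its
dominant c_m/dt part not at all, so the preconditioner stays effective
(~20 iterations/solve in practice).  It is refreshed on failure, falling
back to a sparse direct factorization (also selectable outright with
`linear_solver="direct"`).

## The 1D cable reference

The verification partner is an in-repo compartment solver of the standard
cable equation c_m ∂V/∂t = (d σ_in/4) ∂²V/∂x² − j_ion + j_stim with sealed
ends, the same membrane model, units and backward-Euler/Newton scheme, and
axial resistivity R_i = 1/σ_in so the comparison is parameter-consistent.
Verified against the analytic passive cosh profile (λ = √(dσ_in/4g_L)), the
√d conduction-velocity scaling law (measured ratio 1.412 vs √2) and spatial
refinement convergence.

Comparison metrics: the relative L2-in-time error
‖V_3D − V_1D‖/‖V_1D‖ over the probes (trapezoidal quadrature on a common
grid, squared norms summed over probes), and the conduction velocity from
first upward half-amplitude crossings with linear interpolation in time.

## Experiment presets and problem sizes

All presets run at desk scale on one CPU; the sizes below are the
package's defaults and are also what the test suite and the acceptance
script use.

* **Cylinder verification** — diameter 200 µm and σ_in = 2 mS/cm,
  σ_out = 20 mS/cm like the full-length experiment, shortened to 1.6 mm and
  2.5 ms so that three uniform refinement levels (≈1.4k → 92k tets) fit in
  minutes.  The 1D reference uses the same diameter.  The plateau of the
  error table (~0.1) is dominated by the deliberate octagonal cross-section
  (area deficit ≈10% → ≈5% slower wave), the finite cylinder and the
  extracellular loading — the same deficit classes that separate any
  polyhedral 3D cylinder from the ideal 1D cable.  Expected behavior:
  errors decrease with refinement and the last two levels agree to within
  one percentage point.
* **Sphere multipole** — radius 10 µm soma-scale sphere, icosphere
  subdivision 2, ~0.6–1 ms of activity following a 25° stimulus cap;
  expansion to l_max 6–8.  The monopole ratio sits at the flux-balance
  floor (~1e-8 and below, depending on the step), far below the 1e-6
  requirement.  The per-triangle
  barycenter quadrature is used deliberately: its vertex weights coincide
  with the finite-volume membrane areas, so the fitted b_00 inherits the
  solver's conservation identity exactly.  A Gauss–Legendre product-grid
  variant provides an exactly orthonormal basis for arbitrary flux fields
  (the Parseval/re-fit identity holds to 1e-12 there).
* **Ephaptic experiment** — a reduced two-cell paradigm: a 120 µm driver
  (d = 10 µm) fires a propagating action potential next to a 30 µm target
  (d = 6 µm) across a 4 µm gap in a thin extracellular sleeve.
  σ_out = 3 mS/cm, the physiological non-membrane conductivity (the larger
  20 mS/cm is kept for the other presets).  The target's ephaptic
  depolarization is a few µV here, so the experiment calibrates the spike
  threshold of a 20 µs pulse by bisection twice — with and without the
  ephaptic current — to ~3e-5 relative, and places the pulse amplitude
  between the two thresholds.  The solver is exactly deterministic, which
  is what makes this knife-edge comparison meaningful.  Note the scale:
  in µm-sized cells a nearly space-clamped membrane generates almost no
  external field (the flux-balance theorem again), so the driver must be
  long enough to sustain a spatially nonuniform wave; the few-µV effect at
  these sizes is the reduced-scale analogue of the "very small but
  decisive" full-scale effect.

## What the generated data does and does not emulate

The geometries are idealized primitives (polygonal cylinders, icospheres,
voxel-staircase cells) with sharp patch boundaries, uniform conductivities
and the classical squid-axon HH parameter set at 6.3 °C (no Q10 scaling,
no ion accumulation, no stochastic channels).  Passing tests therefore
demonstrate correctness of the discretization and the conservation
structure, and qualitative electrophysiology (thresholds, propagation,
field signs and decay laws) — not quantitative predictions for any real
neuron; absolute conduction speeds, for example, depend strongly on the
membrane parameter set, which real neurons do not share with squid axon.

## Numerical choices and degenerate inputs

* Units: µm, ms, mV, nA internally; σ in mS/cm converted once
  (1 mS/cm = 0.1 µS/µm); membrane densities in the physiological
  µA/cm², µF/cm², mS/cm² and converted at the flux assembly.
* The classical leak reversal E_L = 10.6 mV leaves a ~3 nA/cm² rest
  imbalance; `e_l_for_rest` rebalances E_L so the rest state is exactly
  stationary, and the presets use it.
* Gating rates use a series expansion within 1e-7 of the removable
  singularities (α_n at 10 mV, α_m at 25 mV); gating is clamped to [0, 1]
  (the implicit update preserves the interval anyway).
* Degenerate (zero-volume) tets are rejected with their index; builder
  meshes are validated for the membrane-separation and orientation
  invariants; voxel builders additionally reject cells that share mesh
  vertices, which would couple their membrane potentials spuriously.
* Synapse latches are evaluated from the previous step's presynaptic
  potential (a one-step delay), keeping the latch out of the Jacobian; the
  latch instant is the only non-smooth point of j_all.
* Probes given as explicit vertex ids are honored exactly on the subdomain
  where the field lives; probes given as points snap to the nearest
  intracellular/extracellular vertex (cell-bound markers for multi-cell
  meshes, so a probe can never silently read the neighboring cell).

## Known limitations

* Backward Euler is first order; halving dt halves the error but the
  scheme damps fast transients (verified by the Richardson test).
* The uniform-refinement path keeps the polyhedral geometry fixed (by
  design, for the verification ladder); curved convergence requires
  rebuilding at higher subdivision, which the Laplace oracle test does.
* Mesh I/O supports the ASCII variants of Gmsh MSH 4.1 and VTK .vtu only.
* No branched 1D morphologies, ion dynamics, adaptive time stepping, or
  distributed parallelism.
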