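# Methods

## Model and assumptions

`wavydrift` implements the reduced description of solute dispersion in a
slender, vertical, wavy-walled channel driven by a harmonic end-to-end
pressure difference.  The derivation rests on four assumptions:

1. **Slenderness** — the wall wavelength is much larger than the gap, so
   longitudinal diffusion of momentum and solute is negligible and the
   transverse momentum balance reduces to ∂p/∂y = 0 (lubrication limit).
2. **Small stroke length** — the ratio ε of stroke length to wavelength is
   small; the velocity is harmonic at leading order and convective
   acceleration enters only through O(ε) corrections, of which the steady
   part (steady streaming) matters for transport.
3. **Two time scales** — the solute evolves on the slow time τ = ε²t.  The
   averaged transport equation advances only the cycle-averaged
   concentration c(x, y, τ); concentration fluctuations on the fast time
   are never represented.
4. **Comparable buoyancy** — the Richardson number is O(1), so the
   buoyancy-induced mean flow is of the same order as the steady streaming
   and both enter the mean Lagrangian velocity
   u_L = u_SD + u_SS + u_B(c), making the averaged equation a nonlinear
   integro-differential one.

The coordinate x points *downward* (distance from the upper end), so a
light solute (Ri > 0) drives a negative chimney flow rate Q_B and rises
toward x = 0.  A heavy solute is the exact mirror image (Ri → −Ri,
gravity reversed).

## Sign conventions and the Womersley parameter branch

Two sign-sensitive choices are fixed by re-derivation and enforced by
runtime checks and tests:

- **Branch of Λ.**  With the phase convention u₀ = Re(i e^{it}U), the
  profile U = (dP/dx)·G with G = 1 − cosh(Λ(2y/H−1))/cosh Λ satisfies the
  momentum balance −U = −dP/dx + (i/α²)∂²U/∂y² only for
  Λ² = +iα²H²/4; the implementation uses the Re Λ > 0 root
  Λ = αH(1+i)/(2√2).  The test suite asserts the residual at round-off.
  The branch is observable: conjugating U and V flips the sign of the
  Stokes drift, and only this branch reproduces the combined-field peak
  table (below).
- **Flux relations.**  Double integration of the averaged momentum
  equation gives Q = −α²[(dp/dx)H³/12 + ½∫F y(H−y)dy] for forcing F, and
  hence Q_B = −α²Ri·[∫₀ⁿ H⁻³m dx]/(2n∫₀¹H⁻³dx),
  m = ∫₀^H c y(H−y)dy.  The minus sign makes the draft upward for a light
  solute, consistent with the physics; the steady-streaming pressure
  closure dp_SS/dx = −6H⁻³∫F y(H−y)dy follows from the zero-flux theorem
  Q_SS = 0.  The code cross-checks Q_B two ways (direct quadrature of u_B
  against the closed form) at every evaluation and raises on
  disagreement beyond quadrature scale.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| α | Womersley number | 4 | 3–6 typical of cardiac-driven CSF flow; 16 probes the high-frequency regime |
| β | wall-waviness amplitude | 0.2 | 0.4 for the strongly wavy mean-flow diagnostics; β < 1 always |
| Ri | Richardson number | 1 | O(1) for ITDD density offsets of 10⁻³–10⁻² relative |
| σ | reduced Schmidt number ε²ν/κ | 1 | O(1) in the distinguished limit κ/ν ~ ε²; σ ≪ 1 has a dedicated solver |
| n | number of cells | 3 | bolus deposited in the central cell |
| ε | stroke-length ratio | 0.02 | metadata only: converts τ to t = τ/ε² and to cycle counts |
| x₀, δ | bolus centre, width | 1.75, 0.2 | truncated Gaussian c = min(1, 1.5 e^{−16((x−x₀)/δ)²}) |

All quantities are dimensionless (lengths on the wavelength/gap scales,
velocities on the oscillatory scale and ε·that scale for the drift).

## Numerical scheme

**Mapped grid.**  All fields live on the uniform tensor grid
(x, η = y/H(x)) ∈ [0, n] × [0, 1] with endpoints included; cell-periodic
fields (base flow, steady streaming, Stokes drift) are computed on one
cell and tiled.  Defaults: 200 points per cell in x, 101 in η for
transport; ×2 refinement ladders for converged diagnostics.

**Drift fields.**  The transverse integrals of the Womersley profile use
the closed form; x-derivatives use 4th-order central stencils (periodic on
the cell, one-sided at the channel ends), η-derivatives 4th-order
stencils, and all transverse integrals the trapezoidal rule.  The
transverse velocities v_SS and v_B are recovered from continuity via the
streamfunction (identical analytically to the printed transverse
solutions, with fewer transcription hazards); v_SD uses its own closed
formula and is cross-checked against continuity in the tests.

**Transport.**  The averaged equation is advanced in the mapped form
∂c/∂τ + u ∂c/∂x|_η + w ∂c/∂η = (1/α²σH²) ∂²c/∂η², w = (v − uηH′)/H.
The advective transport is discretised in conservative flux form: face
volume fluxes are differences of the total streamfunction
ψ = ψ_drift + ψ_B between cell corners — a construction that is exactly
divergence-free discretely (a uniform concentration is a fixed point to
round-off) and telescopes (total solute conserved to machine precision) —
with face concentrations from the second-order upwind-biased
reconstruction, falling back to first order at the node nearest each
boundary and to the zero-gradient ghost value at inflow ends.  Both
streamfunctions are gauged so their wavy-wall row is exactly their
analytic wall value (0 for the drift, Q_B for buoyancy), which zeroes the
spurious quadrature-level wall flux.  The pointwise sign-selected upwind
stencils are retained as `advect_upwind` (the advective-form scheme is
selectable and used for operator-order verification).

Transverse diffusion uses the 4th-order compact scheme
(1/12)(f″₋ + 10f″ + f″₊) = δ²c/Δη² with explicit one-sided wall closures
exact for quintic polynomials with zero wall slope (homogeneous Neumann
built in).  Inside the transport solver the operator is defect-corrected:
the trapezoidal η-mean of the result — the O(Δη⁴) residual of the
discrete integration by parts — is subtracted, so the diffusion term
deposits exactly zero net solute between the impermeable walls without
affecting the order of the scheme.

Time marching is the three-stage third-order TVD (SSP) Runge–Kutta
scheme; the buoyancy velocity is re-evaluated from the stage
concentration at *every* stage.  The step size is
dt = 0.4·min(Δx/max|u|, Δη/max|w|, ½α²σ(H_min Δη)²), re-evaluated every
step.  Over/undershoots of the upwind reconstruction are monitored (warn
outside [−0.05, 1.05]) but never clipped — clipping would silently break
conservation.  No randomness enters anywhere; reruns are bit-identical.

**σ ≪ 1 limit.**  Rapid transverse diffusion makes c independent of η;
the solver advances Hc in finite-volume form with flux Q_B(τ)·c and
second-order upwind faces, conserving ∫Hc dx up to end fluxes, with
Q_B = −α²Ri ∫₀ⁿc dx/(12n∫₀¹H⁻³dx) recomputed per stage.

**x-end conditions.**  The reduced model needs no boundary condition at
the open ends when the solute stays away from them (all scenarios here);
the solver applies zero-gradient ghosts and warns whenever the end solute
flux exceeds 10⁻⁶ of the total per unit τ.

## Converged diagnostics and verification targets

Peak |ψ| and |Ω| of the drift fields are extracted on a ×2 refinement
ladder (start 64×129 per cell) until both peaks change by <0.1%; the peak
search spans one cell, which is sufficient because the fields are
cell-periodic.  At β = 0.4 the converged values reproduce the reference
peak table (steady streaming 0.0115/1.4474 at α = 4, 0.1699/40.787 at
α = 16; combined field 0.0235/1.9906 and 0.1491) to better than 0.5%.

The exact zero-flux theorems (Q_SS = Q_SD = 0) and the two-way Q_B
agreement are verified to 10⁻⁸ by Richardson extrapolation over an η
refinement pair, which removes the second-order trapezoid bias; raw
single-grid values carry that bias (~10⁻⁶ at 513 points) and are guarded
at runtime only against order-one sign errors.

## Scenario presets and what they do (and do not) emulate

The presets encode the study conditions: a three-cell canal, ε = 0.02,
the truncated-Gaussian bolus at x₀ = 1.75, δ = 0.2, and the base case
β = 0.2, α = 4, σ = Ri = 1, with one-at-a-time sweeps in β, σ, Ri, α.
These capture the mechanism — closed Lagrangian vortices trapping a
neutrally buoyant solute, and the buoyant draft connecting cells — but
not the real spinal canal: the geometry is two-dimensional and strictly
periodic, the canal is not annular or eccentric, there are no anatomical
fine structures (trabeculae), no respiratory forcing, no absorption, and
the wall is rigid.  Passing tests therefore validate the reduced model in
its canonical geometry, not quantitative in-vivo predictions.

## Problem sizes used in the automated checks

The scenario-level checks integrate to τ = 8 on a 100×51 desk-scale grid
(the production default is 200×101; results at the two resolutions agree
to plotting accuracy, and total-solute conservation is at machine
precision at any resolution by construction).  The σ ≪ 1 consistency
check uses σ = 0.05 and 0.02 to τ = 1 on 100×26, where the full solver
and the limiting solver agree to ~4% and ~2% in L1 respectively.

## Known limitations

- The second-order upwind reconstruction is not TVD: sharp fronts can
  produce small over/undershoots (monitored, not suppressed).  At the
  desk-scale resolution the trapped-bolus scenario shows |undershoot|
  below 0.005.
- The explicit diffusion step makes the cost scale like α²σ(H_minΔη)⁻²
  steps per unit τ; very fine η grids at large σ are expensive.  An
  implicit transverse solve would lift this but is not implemented.
- At α ≳ 70 the cosh evaluations in the Womersley profile overflow;
  the solver raises rather than rescaling (the regime of interest is
  α ≤ 16).
- The plotted sign convention of external Q_B(τ) figures cannot be
  verified from the available source; the package reports Q_B signed with
  x pointing downward, so an upward draft is negative.
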