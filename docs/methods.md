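# Methods

This note records the model, the numerical choices and their rationale,
and the known limitations of the package, in the order a user meets them.

## Model and assumptions

The package implements a spatiotemporal SIRS system with reinfection and
saturated incidence on a 2-D domain with no-flux (Neumann) boundaries:

    ∂S/∂t = b − dS − β₀SI²/(1+αI²) + μR + D₁∇²S
    ∂I/∂t = β₀SI²/(1+αI²) − (γ+d)I + D₂∇²I + ξ
    ∂R/∂t = γI − (μ+d)R + D₃∇²R

Assumptions baked into the analysis:

* densities are non-dimensional and non-negative; total population relaxes
  to b/d (adding the three equations gives ∂(S+I+R)/∂t = b − d(S+I+R) plus
  diffusion);
* the incidence force is sigmoidal in I (β(I) = β₀I²/(1+αI²)); α ≥ 0
  measures behavioural saturation of spread, α = 0 recovers the
  unsaturated β₀SI² coupling;
* reinfection is a linear drain μR of the recovered pool, μ ∈ [0, 1];
* noise is additive, Gaussian, white in space and time, and acts only on
  the infected density.  On a lattice with spacing Δx = Δy its per-cell
  correlation is ⟨ξ_ij(t₁)ξ_kl(t₂)⟩ = 2C_I δ_ik δ_jl δ(t₂−t₁), with C_I
  the continuum intensity divided by the cell area.

## Homogeneous equilibria

Setting reactions to zero: the infected-balance equation gives
S₀ = (γ+d)(1+αI₀²)/(β₀I₀), the recovered balance gives R₀ = γI₀/(μ+d),
and substituting both into the population identity S₀+I₀+R₀ = b/d yields
an exact quadratic in I₀:

    [α(γ+d) + β₀(μ+d+γ)/(μ+d)]·I₀² − (β₀b/d)·I₀ + (γ+d) = 0.

Solving this quadratic (rather than running a generic 3-D root finder)
enumerates the endemic roots completely and exactly; the disease-free
state (b/d, 0, 0) always exists but is out of scope for the pattern
analysis.  Each root carries a stability tag from the eigenvalues of the
kinetics Jacobian at k = 0, C_I = 0.  At the base parameter set only the
upper branch (larger I₀) is stable; should both roots ever be stable the
upper branch is selected and a warning emitted — a package convention,
recorded in run metadata, since the model itself does not prefer one.

## Second-order moment system

Perturbations (δS, δI, δR) around the stable endemic state are expanded
to second order, projected on a mode cos(kₓx)cos(k_y y) with
k² = kₓ²+k_y², and averaged.  Closing at second moments yields a linear
9-dimensional system Ẋ = AX in

    X = (⟨δS⟩, ⟨δI⟩, ⟨δR⟩, ⟨δS²⟩, ⟨δI²⟩, ⟨δR²⟩, ⟨δSδI⟩, ⟨δSδR⟩, ⟨δIδR⟩).

Only two curvature terms survive because F and G are linear in S and H is
fully linear: a₅ = ½F_II and a₇ = F_SI, with the infection equation
carrying the opposite signs (b₅ = −a₅, b₇ = −a₇).  The noise intensity
C_I enters A at exactly three positions, coupling first moments into the
equations of ⟨δI²⟩, ⟨δSδI⟩ and ⟨δIδR⟩.  At C_I = 0 the system is block
triangular: the first-moment block is exactly the classical linearised
operator J − k²D and the 6×6 second-moment block decouples, so the 9×9
spectrum is the union of the two block spectra — the package's tests use
this as an internal cross-check, and it explains why noise-free results
coincide with first-order Turing analysis.

The matrix is implemented exactly as assembled above; re-deriving the
⟨δR²⟩ equation (multiply the δR equation by 2δR and average) gives a
2γ⟨δIδR⟩ coupling, which is what row six of A contains.

## Dispersion, thresholds, stability regions

* **Leading eigenvalue.** At each k² the eigenvalue with maximal real
  part is reported; ties on the real part (conjugate pairs) are broken by
  smaller |Im λ|, then by smaller Im λ, making curves deterministic.
* **Threshold.** k is scanned over (0, 2] in steps of 10⁻³ and the first
  sign change of Re λ_max is bisected to 10⁻⁶.  The threshold is accepted
  only if Im λ_max vanishes there (a stationary, Turing-type crossing);
  an oscillatory crossing raises a distinct error.  The scan range covers
  the physically relevant band — all computed bands at the base
  parameters lie well inside k < 1.5 — and diffusive damping guarantees
  stability at larger k.  At the base parameters (μ = 0, C_I = 0,
  D₁ = 10) the bisected thresholds are k = 0.5744, 0.5864 and 0.6262 for
  α = 0, 0.5 and 2.0; at a 0.01 scan resolution these read 0.57, 0.58,
  0.62, and the threshold grows with saturation while the band narrows.
* **Stability diagrams.** In the (k², D₁) plane the growth rate is
  evaluated directly per grid point; in the (α, μ) plane the endemic
  equilibrium is re-solved per point and the growth rate maximised over
  an internal 400-point k-scan of (0, 2].  Points with no stable endemic
  equilibrium are a third state (NaN + mask), distinct from stable and
  unstable.  Default diagram resolution is 100×100.

A finding worth recording: noise (C_I = 8×10⁻²) expands the unstable
region of the (k², D₁) plane pointwise (every deterministically unstable
grid point stays unstable, and the set grows), but in the (α, μ) plane
the expansion holds in bulk, not pointwise — at one near-boundary grid
point in 2500 (α ≈ 0.26, μ ≈ 0.29, |Re λ| < 10⁻³ on both sides) noise
nudges the leading eigenvalue slightly negative.  Stability classifications
within ~10⁻³ of the boundary should not be over-read.

## Stochastic integrator

* **Grid.** Cell-centred, square cells.  The 5-point Laplacian uses
  mirror ghost nodes equal to the adjacent interior cell (reflection
  about the cell face).  This is the discrete no-flux condition: boundary
  fluxes vanish identically, the stencil conserves mass exactly
  (telescoping sum), and cell-centred cosines cos(mπx/L) are exact
  eigenfunctions with eigenvalue −(4/h²)sin²(kh/2) per axis.
* **Time stepping.** Forward Euler for S and R, Euler–Maruyama for I:
  per cell and step an independent N(0, 2C_I·dt) increment.  With purely
  additive noise the Itô/Stratonovich distinction does not affect the
  increment.  The explicit-stability bound dt ≤ h²/(4·max Dᵢ) is enforced
  with an error; the reference setup (h = 1, dt = 0.01, D₁ = 10) sits at
  40 % of the bound.
* **Initial condition.** The stable endemic equilibrium plus independent
  uniform perturbations in [−a, +a] per cell and field, a = 10⁻² by
  default, seeded.  The underlying study never states its initial
  condition; this choice is exposed in the configuration and echoed in
  run metadata.
* **Positivity.** Noise can push densities below zero; negative values
  are clipped to zero and every clip is counted and reported.
* **Termination.** A run ends at t_end or earlier when the relative L₂
  change of I per unit time falls below 10⁻⁶ (stationarity).  With the
  base unstable parameters the leading growth rate is ≈ 0.8, so patterns
  saturate well before t = 150 even on a 100×100 grid; the package's
  consistency tests therefore use 100×100, dt = 0.01, t_end = 150 rather
  than the full 200×200 reference setup, which behaves identically but
  more slowly.
* **Determinism.** One seeded generator drives the initial perturbation
  and the noise stream; equal seeds give bit-identical runs.

## Convergence diagnostics

* **Error norm.** L₂ with the cell-area weight,
  ‖e‖ = sqrt(Σ e²·h²), so errors are domain integrals comparable across
  resolutions; the fitted order is the least-squares slope of log error
  vs log h.
* **Reference and restriction.** Self-convergence against the finest
  grid, restricted to coarse grids by cell-centre sampling (odd
  refinement ratio) or the mean of the 2×2 cells around the coarse
  centre (even ratio).
* **Initial data for refinement studies.** A per-cell white perturbation
  has no grid-independent limit, so refinement studies replace it with a
  seeded band-limited cosine perturbation (modes up to 4π/L per axis,
  same amplitude), identical as a physical field at every resolution.
  Pattern runs keep the white per-cell perturbation.
* **Stochastic studies.** Common random numbers: one Gaussian field per
  step is generated on the finest grid and block-averaged to coarser
  grids.  Because lattice noise intensity scales with inverse cell area,
  block averaging reproduces the correct coarse-cell variance with no
  rescaling, and the error limit is path-wise well defined.  One
  realisation is used by default.
* **Scales.** The full-scale study (200×200 domain, h ∈ {4, 2, 1, 0.5},
  integration to stationarity) reproduces orders near 2 (deterministic)
  and below 2 (stochastic) but takes hours; the shipped tests run a
  64×64-domain deterministic study (order ≈ 2.0, asserted within
  [1.7, 2.3] — h = 4 is outside the asymptotic range on this small
  domain and is excluded) and a manufactured diffusion-only problem with
  a closed-form cosine solution (order asserted within [1.8, 2.2]).
* **Pattern spectrum.** The dominant wavenumber is the peak of the
  radially averaged power spectrum of I − mean(I), computed with the
  type-II DCT (the natural transform for cell-centred Neumann data);
  wavenumbers are angular, matching cos(kx), so a pattern of wavelength
  ℓ reports k = 2π/ℓ.  Spectrally flat fields (e.g. white noise) are
  flagged unreliable rather than raising; fields with no variance raise
  "no dominant mode".

## Degenerate inputs and tie-breaks

* b, d, β₀, γ may be zero in the parameter container so reduced systems
  (pure diffusion) can reuse the integrator; equilibrium solvers demand
  them strictly positive and say so.
* Equilibrium residual tolerance 10⁻¹⁰; derivative cross-checks 10⁻⁶
  (first order) and 10⁻⁵ (second order); threshold bisection 10⁻⁶.
* Eigenvalue ties: see dispersion above.
* Both-roots-stable: upper branch + warning, see equilibria above.

## Limitations

* The moment system follows one lattice mode at a time; mode-mode
  coupling beyond second order and amplitude equations are out of scope,
  so the analysis predicts onset and band, not pattern amplitude.
* The 2-D SPDE with space-time white noise is not function-valued in the
  continuum limit; simulated noisy fields are lattice objects whose
  statistics depend on the cell area through C_I = D_I/(ΔxΔy).  The CRN
  convergence study measures the smooth-component limit, not strong SPDE
  convergence.
* Stability-region classification is exact up to the internal k-scan
  resolution; growth rates within ~10⁻³ of zero are boundary-limited
  (see the noise-expansion finding above).
* Synthetic inputs only: the package emulates the model's own dynamics;
  nothing here validates the SIRS-with-reinfection model against
  epidemiological data.
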