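# Methods

This note records the modelling conventions, numerical choices and known
limitations of `sentipol`, in the spirit of a solver's methods appendix.

## 1. Model family and conventions

### 1.1 Diffusivity convention

The agent SDE carries multiplicative noise σ s(W) dB and its mean-field
Fokker–Planck limit the diffusion term (σ²/2) ∂²[s(w)² f]. Throughout the
package the *squared* amplitude — the diffusivity a(w) = s(w)² — is the
primitive object:

* `product`: a(w) = w(1−w). The SDE noise is σ√(w(1−w)) (Wright–Fisher
  type), vanishing at both extremes. This is the only choice in the family
  a(w) = [w(1−w)]^p for which the stationary marginals are Beta densities;
  squaring the self-thinking function once more (p = 2) produces essential
  singularities exp(−c/w) in the stationary state and destroys the Beta
  equilibria, so the marginal dynamics analysed and discretized here is

      ∂_t g = λ ∂_w[(w − m) g] + (σ²/2) ∂²_w[w(1−w) g].

* `distance`: a(w) = (w − m)², with m the instantaneous population mean.
  The variance then obeys dV/dt = (σ² − 2λ)V and the population collapses
  onto its mean whenever 2λ > σ² (consensus), with no nontrivial stationary
  profile.

For the product diffusivity the stationary marginal is Beta(a, b) with
a = m/ν, b = (1−m)/ν and **shape ratio ν = σ²/(2λ)**: the balance of noise
against compromise. Conserved mean, one shape degree of freedom.

### 1.2 Reporting convention for calibrated rates

Equilibrium fits identify only the shape ratio, never λ and σ separately.
Published calibrations conventionally report per-component (m, λ, σ) triples
that encode the fitted ratio as **μ = λ/σ²**; `BetaSpec.from_rates`
implements exactly that reading, and it is the convention under which the
shipped corpus calibration reproduces its published structure (interior
polarization peak at w⁻ = 0.597, component shapes (0.250, 2.904) and
(2.728, 2.166)). When a calibrated component is used to parameterize the
*dynamics*, `OpinionParams.from_shape_ratios` keeps the reported λ as the
relaxation rate and sets the dynamical noise to σ_dyn = √(2λμ), so that the
solver's long-time marginal is precisely the calibrated Beta. The two
conventions agree on every observable equilibrium quantity; they differ only
in which σ is attached to a given μ, which no stationary observable can
distinguish.

### 1.3 Boundary handling

The kinetic equations carry no-flux conditions on all four edges of [0,1]²,
so total mass is exact. The agent simulator projects (clamps) opinions onto
[0,1]² after every Euler–Maruyama step — the simplest contract consistent
with densities compactly supported on the square, and inert for the product
diffusivity whose noise vanishes at the walls.

## 2. The structure-preserving 1-D scheme

Writing the 1-D operator in flux form ∂_t f = ∂_w F, F = (B + D')f + D f'
with B = λ(w − m) and D = (σ²/2) w(1−w), cell averages evolve by

    df_i/dt = (F_{i+1/2} − F_{i−1/2}) / Δw,
    F_{i+1/2} = C̃_{i+1/2} f̃_{i+1/2} + D_{i+1/2} (f_{i+1} − f_i)/Δw,
    f̃ = (1−δ) f_{i+1} + δ f_i,   δ(ℓ) = 1/ℓ + 1/(1 − e^ℓ),
    ℓ_{i+1/2} = Δw C̃_{i+1/2} / D_{i+1/2} = ∫_{w_i}^{w_{i+1}} (B + D')/D dw.

The gap integral is evaluated **exactly** for the product diffusivity — the
integrand is (1−a)/w + (b−1)/(1−w), so the antiderivative is logarithmic —
and by 4-point Gauss–Legendre quadrature otherwise. Exactness is the point:
ℓ equals ln(g^∞(w_i)/g^∞(w_{i+1})) for the Beta steady state, a short
computation then shows every interior flux vanishes identically at the
steady profile evaluated on the mesh. The discrete stationary state *is* the
analytic one (verified to 5e−17 in flux, 5e−15 in L∞ after 1000 steps),
rather than an O(Δw) approximation of it.

δ(ℓ) is computed from its series for |ℓ| < 1e−6 (δ → 1/2, the central
scheme) and with a clipped `expm1` otherwise (δ → 0 or 1, full upwinding);
δ ∈ (0,1) for all finite ℓ, which makes the off-diagonal rate-matrix entries
nonnegative. Consequences:

* **mass**: the rate matrix has exactly zero column sums (fluxes telescope,
  boundary faces carry no flux) — mass is conserved to round-off by both the
  explicit and the semi-implicit step;
* **positivity**: I − Δt·A is an M-matrix, so the semi-implicit solve is
  unconditionally positivity-preserving; the explicit step is nonnegative
  under the usual parabolic restriction Δt ≤ Δw²/(2 max D).

Time stepping is semi-implicit — flux linear in f with (C̃, δ, D) frozen at
the previous mean — and the tridiagonal system is solved exactly by Thomas
elimination, vectorized across the mesh lines of the other dimension. The
2-D (and coupled) solves use first-order Lie splitting: all w⁺ lines, mean
recomputation, all w⁻ lines (then the compartment exchange). Default mesh
20 cells per axis with Δt = Δw, the coarse-mesh configuration used for the
reproduction runs; refinement studies in the test suite halve Δw and Δt.

The compartment exchange step is explicit Euler on the cellwise reaction
terms (−K, +K − ζf_E, +ζf_E − γf_I, +γf_I); the terms telescope, so total
mass is again exact, and the step raises a diagnostic error if Δt is large
enough to produce negative cells.

## 3. Oracles and cross-checks

* The SEIR final-size relation is implemented as
  ln(ρ_S^∞/ρ_S(0)) = −(β/γ)(ρ_R^∞ − ρ_R(0)): the sign-corrected,
  initial-removed-aware form, which is the only one that reproduces the
  shipped contact rate β = 1.21 from ρ_S(0) = 0.9, ρ_R(0) = 0.025,
  ρ_S^∞ = 0.5188. The uncorrected textbook-style misprint
  ln(ρ_S/ρ_S(0)) = (β/γ)(1 − ρ_S^∞) equates quantities of opposite sign and
  has no admissible root; it is kept behind `verbatim=True` and its failure
  is asserted in the tests.
* For constant contact functions the masses and per-compartment means of the
  kinetic system obey a closed 12-dimensional ODE system
  (`moment_ode_oracle`), integrated independently with an adaptive
  Runge–Kutta method. The exposed compartment's first-moment sink is
  −ζ ρ_E m_E± (dimensional consistency; the variant that drops the m_E
  factor is available behind a flag). The kinetic solve matches the oracle
  to ~1e−3 in masses (O(Δt), dominated by the explicit exchange step, and
  halving under step refinement) and to ~1e−15 in means for resolved
  profiles.
* The agent simulator and the mean-field solver are cross-validated at
  N = 10⁴: moments agree within 3 Monte-Carlo standard errors at five
  checkpoints.

## 4. The synthetic-data generator

The generator emulates the corpus the calibration came from: timestamped
(w⁺, w⁻) pairs, 4077 posts across six group-chat labels over a 191-day
window, with times i.i.d. uniform (or user-scheduled) and scores drawn
per-axis from specified Beta mixtures — by default the shipped calibrated
equilibria, i.e. the same "the last snapshot is an equilibrium" ansatz the
calibration itself makes. Alternatives: linear-in-time interpolation of
mixture parameters between an initial and a final spec (an evolving opinion
climate with explicit ground truth), or sampling from any solver snapshot
(cells by mass, uniform within a cell). What it does **not** emulate:
within-chat correlation (posts are i.i.d. given the time law), per-author
effects, axis coupling beyond the product of marginals, NLP scoring noise,
or bursty posting times. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data artifacts.

Binning follows the data pipeline: half-open cells [a, b) with the last cell
closed (a score of exactly 1.0 is kept), counts normalized per time window
to a probability density, zero-record windows yielding a zero-mass field
rather than NaN.

## 5. Calibration details

The mixture misfit is the Δw-weighted discrete squared L2 norm on the binned
grid. The default parameterization is the identifiable `shape` vector
(weight, m_S, μ_S, m_R, μ_R); `rates` mirrors the conventional
(weight, m, λ, σ) reporting and carries the μ = λ/σ² degeneracy (two rate
pairs with equal ratio give bitwise-equal residuals — asserted in the
tests). The objective is non-convex: label switching is resolved by
reporting components in ascending mean order, and the optimizer (bounded
trust-region least squares) is restarted from a seeded Latin-hypercube of
initial points (default 32; the positive-axis calibration, whose components
overlap strongly, needs the larger multi-start budgets). Weights pinned
within 1e−3 of 0 or 1 raise a degenerate-component flag.

Sampling variability: at corpus scale (n = 4077) the mixture weight is
identified by this estimator with a standard deviation of about 0.065 across
seeds (unbiased to ~0.01); single-corpus weight estimates should be read
with that uncertainty in mind.

## 6. Known limitations

* **Under-resolved singular profiles.** Boundary-unbounded equilibria
  (a < 1) on the default 20-cell mesh are represented faithfully in mass but
  not in midpoint-quadrature moments: the self-consistent mean can drift
  (e.g. from 0.09 to 0.19 over 200 days for the calibrated positive
  marginal) even though the continuum mean is conserved. For resolved
  profiles the discrete mean is conserved to machine precision. Moment-based
  diagnostics should use resolved initial data or finer meshes.
* **Distance diffusivity near the walls and near the degeneracy point.** The
  exponential variance law V(t) = V(0)e^{(σ²−2λ)t} holds only while the
  population stays clear of the boundaries; rare multiplicative excursions
  that reach the walls are truncated by the no-flux condition (and by the
  clamp in the agent model), making the true bounded-domain variance decay
  faster. Additionally, a uniform mesh cannot resolve the logarithmic scale
  structure at the interior point w = m where the diffusivity vanishes, so
  long-horizon distance-kind solves develop a mesh-scale spike there. The
  law is reproduced to 0.2% in resolved, boundary-safe settings (tested);
  outside that window deviations are a property of the bounded model and
  its discretization, not of the implementation being wrong per se — but
  treat quantitative distance-kind output with care.
* **Transient nature of bimodality in the coupled solve.** Because every
  compartment's drift targets the *global* mean, compartment means converge
  to a common value and the long-time marginal is a two-Beta mixture with
  shared mean (this is asserted in the tests, L1 < 5e−2 at 20 cells). A
  bimodal structure with well-separated component means — as fitted from
  data — is therefore a long-lived transient, not a stationary state: in the
  calibrated run it survives the active spreading phase (a few days, with
  the interior peak near w⁻ ≈ 0.45–0.6) and is smoothed afterwards on the
  susceptible-side relaxation timescale (2λ_S + σ_S²)⁻¹ ≈ 8 days. Fitted
  mixtures with distinct component means should be read as empirical
  snapshots, not model equilibria.
* **Constant epidemiological rates.** ζ(w), γ(w) are implemented as
  constants (signature-ready for opinion dependence); the contact function
  κ may be constant or separable.
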