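# Methods

## Physical model

The package treats a CH₃ group in a crystalline powder as n_I = 3 protons (I)
dipolar-coupled to one ¹³C (S), with the C–H vectors undergoing free rotational
diffusion on a cone of half-angle Θ_IS about the local C₃ axis.  Free diffusion
is preferred over a three-site jump model because it carries the fewest
parameters and both give closely similar spectral densities for methyl
rotation.  The motion enters through two correlation times, τ₁ for the first
rotational harmonic and τ₂ = τ₁/4 for the second (the factor 4 is exact for
axial diffusion), in Lorentzian spectral densities g(τ, ω) = τ/(1 + ω²τ²).

For a static orientation θ of the C₃ axis from B₀ the six dipolar transition
probabilities (W₀, W₁S, W₁I, W₂ for the I–S pair; W₁, W₂ for the I–I pairs)
are assembled from the cone-geometry factors A₁ = sin²2Θ, A₂ = sin⁴Θ and five
polynomials B₁, B₂, B₄, B₅, B₆ in cos θ, with overall prefactor 9ω_D²/64.
Under MAS, cos θ(t) = √(2/3) sin β cos(ω_r t + φ) + √(1/3) cos β with β the
inclination of the C₃ axis from the rotor axis.  Because the B polynomials are
linear in cos²θ and cos⁴θ, rotor-period averaging amounts to substituting the
moments  cos²θ̄ = 1/3 (for every β — the magic-angle condition) and
cos⁴θ̄(β) = (1/9)cos⁴β + (2/3)sin²βcos²β + (1/6)sin⁴β.  A further average over
the powder (sphere moments 1/3 and 1/5) gives the constants
B̄₁ = B̄₂ = 8/15, B̄₄ = B̄₅ = 4/5, B̄₆ = 16/5 and hence closed-form MAS rates
with prefactors 3/40, 9/80, 18/40.

Replacing the time-dependent rate matrix by its rotor-period average is an
average-Hamiltonian-style approximation; it is excellent because relaxation
per rotor period is of order 10⁻⁴.  The package carries an explicit
piecewise-constant rotor propagator (`rotor_propagation_oracle`) as an
internal check: at 19.2 kHz MAS and rates ≤ 10 s⁻¹ the averaged solution and
the propagated one agree to better than 10⁻³ relative (observed ~10⁻¹¹),
and exactly at β = 0 where the time dependence vanishes.

The coupled recovery of the populations (I, S, B) — B being an effective bath
of n_B isotopically enriched carbons cross-relaxing with the methyl ¹³C at
rate σ — follows dm/dt = −R m with the bath block carrying only the exchange
terms (the intrinsic bath relaxation is negligible: natural-abundance
backbone carbons relax two orders of magnitude more slowly).  The observed
signal is M(t) = M₀(1 − Σ α_k e^{−λ'_k t}) with Σα_k = 1.

## Parameters, units, defaults

| parameter | meaning | unit | default | origin of default |
|---|---|---|---|---|
| Θ_IS | cone half-angle, C₃ axis to C–H | deg | 69.1 | liquid-crystal NMR methyl geometry |
| r_IS | C–H distance | Å | 1.106 | same |
| Θ_II, r_II | H–H vector geometry | deg, Å | 90, √3·r_IS·sinΘ_IS ≈ 1.79 | cone geometry (three protons on a circle of radius r_IS sinΘ_IS) |
| S² | librational order parameter | – | 0.93 | best-fit value; applied **once** to every squared coupling |
| ω_I/2π | ¹H Larmor frequency | MHz | 800 | experimental field |
| ω_r/2π | MAS rate | kHz | 19.2 | experimental spinning speed |
| n_B | effective bath carbon count | – | 1.6 | average of per-temperature fits (may be fractional) |
| σ | spin-diffusion cross rate | s⁻¹ | 0.9 | same |
| E_a | activation energy of methyl rotation | kcal/mol | 3.5 | Arrhenius regression of the bath model |
| τ₀ | Arrhenius prefactor | s | 2.5e-13 | same |
| R | gas constant | kcal mol⁻¹ K⁻¹ | 1.9872e-3 | fixed, matches kcal energies |

Physical constants are pinned to CODATA-2018 in `constants.py`; the dipolar
coupling is computed in SI including the μ₀/4π factor, giving
ω_D/2π ≈ 22.3 kHz for the 1.106 Å C–H bond.  Angles are degrees at every
interface, radians internally; temperatures kelvin; times seconds.

## Design choices at genuinely open points

* **Order parameter power.**  S² multiplies each squared dipolar coupling
  once (model-free convention), not S⁴.
* **W₁I.**  Only the carbon single-quantum rate has a printed closed form;
  the proton one is taken as the same expression with ω_I in place of ω_S
  (standard dipolar transition-probability symmetry).
* **Initial conditions.**  The echo-detected saturation-recovery experiment
  saturates *all* carbons while a long recycle delay (5 T₁ᴴ) leaves the
  protons at equilibrium: m_I(0) = 0, m_S(0) = −M_S(∞), m_B(0) = −n_B M_S(∞)
  (bath equilibrium magnetization scales with its population).
* **Two-component summary.**  The triple-exponential solution is reported as
  a bi-exponential by dropping the negligible-|α| eigenterm and renormalizing
  the remaining amplitudes to 1, mirroring how bi-exponential fits summarize
  measured curves.  Both the full 3×3 and the reduced (S, B) 2×2 model are
  implemented; across the fitted parameter range they agree on (λ_fast,
  λ_slow, α) within 5%.
* **Anisotropy spread.**  The residual MAS anisotropy is quantified as the
  peak-to-peak spread of R₁(β) over β ∈ [0°, 90°] divided by the β-averaged
  (powder) rate, evaluated at the correlation time that maximizes the powder
  rate; ≈ 13.8% at an 800 MHz ¹H field, i.e. the rate stays within roughly
  ±7% of its average, small enough that powder averaging of the B̄ factors is
  justified for analyzing powder data.
* **Eigenvalue ordering and degeneracy.**  Rates are reported sorted
  descending (α₁ = fastest).  Relative eigenvalue separations below 1e-9
  raise a degenerate-system error rather than returning near-singular
  amplitudes.

## Fitting machinery

* **Multi-exponential fits** use `lmfit` on the saturating form with
  amplitudes constrained to sum to 1 and non-negative rates; α is attached to
  the faster rate.  Near-equal rates or a vanishing amplitude set a
  `degenerate` flag (a 2-component fit of 1-component data is not
  identifiable).
* **Objective.**  Unweighted SSR on intensities.  The overall scale M₀ is
  profiled out analytically (linear least squares given the curve shape), so
  the physical parameters are (n_B, σ, S², τ₁).
* **Grid search.**  A coarse 4-D sweep (n_B ∈ [0.1, 10], σ ∈ [0, 10] s⁻¹,
  S² ∈ [0.7, 1], τ₁ ∈ [1e-12, 1e-6] s log-spaced) followed by binary
  refinement.  Two pathologies shape the implementation: R₁(τ₁) is
  double-valued (fast/slow branches of the T₁ minimum), creating alias basins,
  and S² and τ₁ trade off along a nearly flat diagonal valley.  Refinement
  therefore (a) restarts from the best mutually separated sweep points,
  (b) uses a pattern-search rule — the spacing is halved only when the
  incumbent stays at the centre of its local grid, so the search can walk
  along valleys — and (c) finishes with a derivative-free Nelder–Mead polish
  of the incumbent, which follows the valley below grid resolution.  On
  noiseless synthetic curves this recovers generating parameters essentially
  exactly; without the polish the search stalls on the valley floor with
  residuals ~10⁻⁷.  An optimum on (or beyond) the initial grid boundary
  triggers a warning to widen the grid.
* **τ₁ with fixed bath.**  One-dimensional SSR scan on a log-spaced τ₁
  bracket, golden-section refinement of every local minimum, and an explicit
  fast/slow side flag relative to the rate-maximizing τ₁.  Across a
  temperature series the branch ambiguity is resolved by dynamic programming
  under the constraint that τ₁ must not decrease on cooling, then iterated to
  self-consistency against an Arrhenius regression of the series (each
  temperature re-assigned to the candidate nearest the fitted line in ln τ₁).
  The self-consistency pass matters near the T₁ minimum, where both branches
  fit a noisy curve almost equally well.
* **Arrhenius regression.**  OLS of ln τ₁ on 1/T; E_a = slope·R,
  τ₀ = exp(intercept), standard errors propagated linearly (delta method for
  τ₀).  At least three distinct temperatures are required.

## Synthetic data

The generator samples the analytic recovery solution of the forward model on
16 log-spaced delays spanning [0.01/λ_fast, 5/λ_slow] (both the fast process
and the spin-diffusion tail are covered) and adds homoscedastic Gaussian
noise specified relative to M₀; the default temperature series is
268/233/198/178/149 K.  Generating parameters and the seed are recorded in
each dataset, so every curve is bit-for-bit reproducible.  What it does *not*
emulate: intensity-dependent (heteroscedastic) spectrometer noise, baseline
or phasing errors, rotor-synchronous echo artifacts, temperature calibration
error, and any temperature dependence of σ or S².  Passing round-trip tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to systematic experimental error.

The Monte-Carlo checks use 100–500 replicates at 1% noise; the rotor
propagator is validated over 20 000 rotor periods at 19.2 kHz; quadrature
oracles use Gauss–Legendre nodes (exact for the low-order polynomials
involved).  These sizes keep the full suite around a minute on one CPU while
leaving Monte-Carlo standard errors well below the tolerances tested.

## Known limitations

* The bath is a single effective population with one temperature-independent
  σ and n_B; the per-temperature fits suggest σ actually varies with
  temperature, which propagates into the activation parameters.
* ¹H–¹H spin diffusion to a proton bath and dipole–dipole cross-correlation
  are not modelled (the latter largely averages out when a J-unresolved
  multiplet is integrated).
* Chemical-shift-anisotropy and quadrupolar mechanisms are out of scope, as
  is explicit ²H relaxation in deuterated isotopomers (only the γ²I(I+1)
  scaling factor ≈ 15.9 is provided).
* The Solomon treatment supports a single S spin per group (n_S = 1).
* β-resolved fitting of oriented-sample data is not implemented; the powder
  averages are built in.
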