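# Methods

## Models

**Core rheostat (3 species).** Ceramide (x₁), sphingosine (x₂) and S1P (x₃)
interconvert by mass action; ceramide synthesis enters as a boundary
exchange with zero-order forward rate k₀ and first-order reverse rate k₁ᵣ,
so that v₁ (synthesis exchange), v₂ (ceramide⇌sphingosine) and v₃
(sphingosine⇌S1P, forward rate k₃ = SphK) are all reversible while S1P
degradation v₄ = k₄·x₃ is irreversible:

    dx₁/dt = k₀ − k₁ᵣx₁ − k₂f x₁ + k₂ᵣx₂
    dx₂/dt = k₂f x₁ − k₂ᵣx₂ − k₃x₂ + k₃ᵣx₃
    dx₃/dt = k₃x₂ − k₃ᵣx₃ − k₄x₃

This assignment (boundary exchange as the reversible v₁) is the only one
consistent with three reversible reactions among three species plus a
separate irreversible degradation step. At steady state the net fluxes
satisfy v₁ = v₂ = v₃ = v₄ (an effective downstream flux from x₁ to x₃).

**Extended rheostat (4 species).** Sphinganine (the de novo precursor) is
prepended: k₀₀ (zero-order de novo input) → sphinganine → (k₀₁) → ceramide ⇌
sphingosine ⇌ S1P → degradation. The two genotype conditions differ only
through a Boolean switch S_on — 1 in wild type, 0 in the hai1a-amorphic
mutant — entering two apparent rates:

    k₃,app  = k₃  · (1 − S_on·α_hai1a),  α_hai1a ∈ [0.5, 1)
    k₀₀,app = k₀₀ · (1 + S_on·α_cer),    α_cer ∈ [−1, 0]

α_hai1a ≥ 0.5 encodes that mutant SphK is at least twice the wild-type rate;
α_cer < 0 encodes the negative-feedback hypothesis: in wild type, ceramide
is above the feedback threshold and de novo synthesis is repressed (fully so
at α_cer = −1); in the mutant the 2-dpf ceramide drop has de-repressed it.
The switch is static per condition; an explicit ceramide-threshold switching
function is deliberately not modelled (the threshold narrative concerns how
the switch came to its state before the modelled window). α_cer's domain is
closed at −1 so the fully engaged feedback is an admissible parameter value,
not just a limit. No ceramide boundary efflux (e.g. to sphingomyelin) is
included in the extended chain: sphingomyelin levels mirror ceramide in the
underlying data and sphingomyelinase inhibition had no phenotypic effect, so
a separate efflux would add an unidentifiable parameter.

Both systems are affine-linear, dx/dt = A·x + b with A a compartmental
(Metzler, diagonally dominant) matrix. Consequences used throughout:
steady states are the linear solve A·x* = −b and are nonnegative whenever
the outflow chain is open (k₄ > 0); trajectories have the closed form
x(t) = x* + e^{At}(x₀ − x*); nonnegativity of trajectories is automatic.

Time is measured in days with t = 0 at 2 dpf; all first-order constants are
day⁻¹, zero-order inputs a.u.·day⁻¹, concentrations in arbitrary model
units mapped to measured units by the scaling factors below.

## Metabolic control analysis

Control coefficients are taken with respect to proportional scaling of whole
reactions — a factor p_j multiplies forward and reverse constants of
reaction j together (k₀ with k₁ᵣ; k₂f with k₂ᵣ; k₃ with k₃ᵣ; k₄) — the
standard convention under which the summation theorems hold exactly:
Σ_j C^J_j = 1 and Σ_j C^{x_i}_j = 0. Implicit differentiation of
A(p)x + b(p) = 0 gives dx/dp_j = −A⁻¹(∂A/∂p_j·x* + ∂b/∂p_j); scaled
(logarithmic) coefficients are the primary output, raw sensitivities behind
a flag. A central-difference implementation over log-perturbations
(default relative step 1e−4) serves as an independent check; both are tested
to agree to 1e−4 relative over random parameter draws.

A zero net reaction rate at the reference state makes scaled elasticities
and coefficients undefined; this is treated as an error naming the reaction,
not as a limit.

The biological conclusion is a sign statement: C^{ceramide}_{v₃} ≤ 0 always,
strictly negative whenever any reverse/efflux rate (k₁ᵣ, k₃ᵣ) is positive.
`k3_perturbation_report` restates this non-logarithmically: scaling k₃ alone
(SphK catalyses only the forward step) by any fold > 1 gives a steady-state
ceramide ratio ≤ 1.

## Likelihood and calibration

Measurements m (pmol per mg protein) are modelled as s_i·x_i(t, θ) + ε with
ε ~ N(0, σ_i²): one scaling s_i and one σ_i per species, the σ shared across
time points and conditions. The objective is the negative log-likelihood

    NLL(θ) = Σ [ ½ln(2π) + ln σ_i + (s_i·x_i(t,θ) − m)² / (2σ_i²) ].

Conventions:

* **2-dpf initial condition.** For each observed species and condition,
  x_i(0) = (2-dpf replicate mean)/s_i, so predictions at 2 dpf equal the
  sample means exactly; 2-dpf residuals are the replicate deviations and are
  θ-independent. The latent S1P initial value is a free parameter.
* **Shared latent initial.** By default one S1P initial value is shared
  across conditions. With only two time points, a per-condition latent
  initial is structurally non-identifiable and acts as an unobserved
  condition-specific reservoir: the no-feedback variant can then route an
  arbitrarily large initial S1P pool back through sphingosine into mutant
  ceramide and mimic the feedback signature, making the variants
  non-discriminable by design rather than by data. Sharing the latent
  initial removes that artifact; a `per_condition` mode exists for richer
  time designs.
* **σ profiling.** The conditional maximiser σ̂_i = RMS of species-i
  residuals is exact for this likelihood, so σ is profiled out of the
  optimisation by default (floor 1e−8 against the noise-free degeneracy);
  joint numerical estimation is available and is tested to agree with the
  analytic profile.
* **Transforms and bounds.** Positive parameters (rates 1e−3–1e3 day⁻¹,
  scalings 1e−2–1e4, latent initial 1e−4–1e3) are optimised in log₁₀ space;
  α's in native space with box bounds. Multi-start local optimisation
  (L-BFGS-B, finite-difference gradients, ftol 1e−12) from log-uniform
  start samples; 100 starts by default, a
  conservative budget for this landscape. Within the likelihood the exact matrix-exponential propagator
  of the affine system is used (the model is linear, so this is exact and
  about two orders of magnitude faster than adaptive integration); the
  numeric stiff-capable integrator (LSODA, rtol 1e−8 / atol 1e−10,
  configurable) remains the default for `simulate` and the two routes are
  cross-checked in the tests.
* An optimiser endpoint is re-evaluated before comparison across starts
  (scipy can report a stale objective value after an abnormal line-search
  exit).

Identifiability: with two time points, individual rate constants are not
identifiable (the fit is over-parameterised by design); all conclusions are framed on fit quality, CI coverage and the
sign/boundary behaviour of α_cer, never on pointwise rate recovery.

## Model comparison

`compare_variants` fits the no-feedback variant (α_cer fixed at 0) and the
feedback variant (α_cer free in [−1, 0], or fixed at −1), with the feedback
start list augmented by the no-feedback optimum — α_cer = 0 is feasible for
the feedback variant, so this warm start makes the nesting property
(NLL_feedback ≤ NLL_no-feedback + tolerance) hold by construction up to
optimiser tolerance. The verdict is CI-coverage-based (no information
criteria are used): which variant places all 4-dpf sphinganine and ceramide
predictions inside the 95% confidence intervals of the measurements. CIs are Student-t by default
(mean ± t₀.₉₇₅,ₙ₋₁·sd/√n — deterministic and exactly testable); a
bootstrap-percentile alternative is available behind a flag since plotting
libraries commonly bootstrap. 2-dpf cells are trivially inside by the
initial-condition convention and are flagged `pinned`.

## Synthetic data

The generator emulates the study design: wild-type sibling (S_on = 1) and
hai1a-amorphic mutant (S_on = 0), 2 and 4 dpf, four biological replicates,
observed species sphinganine, C16 ceramide, sphingosine; S1P latent. Values
are s_i·x_i(t) + Gaussian noise truncated at 0 (truncations logged; at the
preset σ the probability is negligible). Only biological replication is
simulated — no technical-replicate hierarchy, no LC-MS peak-level artefacts,
no internal-standard or protein normalisation (abundances are emitted
already normalised). Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed noise model, not robustness to
real-data features such as heteroscedasticity, batch effects or replicate
correlation.

The `study_like_feedback` preset (rates k₀₀ = 0.9, k₀₁ = 0.5, k₂f = 0.45,
k₂ᵣ = 0.3, k₃ = 1.1, k₃ᵣ = 0.15, k₄ = 1.0 day⁻¹; α_hai1a = 0.6,
α_cer = −1) was chosen once so that the noise-free trajectories show the
qualitative experimental signature — mutant ceramide below wild type at
2 dpf and above it at 4 dpf, mutant sphinganine elevated at 4 dpf — which is
asserted at construction. 2-dpf states encode the biologically motivated
starting point (mutant ceramide depleted, S1P elevated, sphingosine equal).
Scaling factors (10, 200, 8 measured units per model unit for sphinganine,
ceramide, sphingosine) place values on typical LC-MS scales: ceramide in the
low hundreds of pmol/mg protein, sphingoid bases in the units-to-tens range.
Preset σ (0.5, 6.0, 0.35 — coefficients of variation of roughly 4–7%) are
set so that the CI-based variant discrimination succeeds at n = 4
replicates, the regime the study worked in; larger σ widens the t-intervals
until the structurally misplaced no-feedback prediction is no longer
excluded, which degrades the discrimination rate rather than the fits.

## Problem sizes and determinism

Tests and the acceptance script run scaled-down versions of the experiments:
100 random draws for the control-analysis checks, 50 for the linear-algebra
oracles, 20 synthetic datasets with 6 optimisation starts per variant
(warm-started) for structure recovery; the library default for a single fit
remains 100 starts. All stochastic stages are keyed by explicit seeds
(numpy `SeedSequence` spawning, children reduced below 2³¹), and
synth → fit → compare with a fixed seed is byte-reproducible; every CLI run
writes a provenance record (version, seed, config hash).

## Known limitations

* No spatial or compartment structure (plasma-membrane vs
  mitochondria-associated-membrane pools are discussed in the source
  literature but not modelled); sphingomyelin and very-long-chain ceramide
  species are outside the model boundary.
* The feedback is a static per-condition switch, not a dynamic
  ceramide-threshold mechanism; the model cannot describe re-engagement of
  the feedback within the simulated window.
* S1P is latent; its absolute level is set by the shared initial-value
  parameter and the rates, not by data.
* Mass-action linearity is an idealisation: saturation of SphK or of the
  de novo pathway would make control coefficients state-dependent in ways
  the linear model cannot express.
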