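# Methods

## The model

`angiosched` simulates vascular tumour growth as a pair of coupled
ODEs for tumour volume `V` (mm³) and its carrying capacity `K` (mm³),
the effective vascular support of the tumour:

    dV/dt = −λ₁ (V−V*) ln((V−V*)/(K−V*)) − K_F I₂(t) f(V−V*, K−V*)
    dK/dt = −λ₂ (K−V*)
            + c β (V−V*)^p (V−V*) / (α (β + (V−V*)^p) + I₁(t))
            − d (K−V*) (V−V*)^{2/3}

This is the Hahnfeldt tumour–angiogenesis family: Gompertzian growth
toward a capacity that itself grows with the tumour (recruitment term
in `c`), decays spontaneously (`λ₂`), and is inhibited endogenously
(`d`, with the `V^{2/3}` surface scaling from the diffusion argument).
`V*` is the prevascular volume — the volume sustainable without
angiogenesis, and the asymptote under unbounded anti-angiogenic drug.
`I₁(t)` is the plasma concentration of bevacizumab (bvz), which
suppresses recruitment through the denominator; `I₂(t)` is the plasma
concentration of a lumped FOLFOX species, which removes tumour volume
through the response law `f`.

With zero drug, `V* = 0`, `p = 0`, `β = 1` the system reduces to the
classical form with untreated steady state
`V∞^{2/3} = (c/(2α) − λ₂)/d`; both reductions are asserted numerically
in the test suite.

Two rival laws for chemotherapy delivery are implemented:

* **continuous**: `f = (V−V*)^{α₁} (K−V*)^{β₁}` — a bimolecular-type
  power-law product; exponents make the dependence on tumour and
  vasculature flexible (priors allow negative exponents);
* **threshold**: `f = (V−V*) · (K−V*)^h / (α₂^h + (K−V*)^h)` — kill
  linear in tumour volume, Hill-saturating in vasculature; at large
  Hill exponent `h` the vasculature dependence becomes a switch: no
  delivery below `α₂`, full delivery above. (`h` is printed both p₁
  and p₂ in the source literature; it is one parameter here.)

All equations are implemented in raw numeric units (day, mm³, mg, ml)
with no unit conversion; the printed parameter values and priors are
only mutually consistent that way. The mouse weight `w = 0.025 kg` is
carried as metadata and never enters the right-hand side.

### Pharmacokinetics

Each drug follows a two-compartment model with zero-order infusion of
duration `T = 1/48 day` and first-order elimination from the central
compartment (volume `V_c = 7.975 ml`). The central concentration has
the standard biexponential closed form with hybrid constants

    b = ½(Σk − √(Σk² − 4 k₂₁ k_e)),  a = k₂₁ k_e / b,
    A = (a−k₂₁)/((a−b) V_c),  B = (b−k₂₁)/((b−a) V_c),  Σk = k₁₂+k₂₁+k_e,

evaluated per administration and **superposed** over repeated doses
(valid for linear PK; the single-administration closed form is what
the model family publishes, and superposition reproduces weekly
regimens without re-deriving multi-dose algebra). Properties asserted
against independent oracles: `a`, `b` are the eigenvalues of the
transfer matrix; single-dose AUC `= D/(V_c k_e)`; pointwise agreement
(rel. 10⁻⁶) with direct integration of the compartment ODEs, single
and repeated dosing. Degenerate repeated roots (`a ≈ b`) raise an
error; under continuous priors this set has measure zero, and during
inference such proposals are simply rejected.

FOLFOX (folinic acid + 5-FU + oxaliplatin) is modelled as one PK
species with one 56 mg dose, as in the source model; bvz doses are
10 mg. The printed dose table is in mg although the in-vivo dosing was
per kg; the model uses the printed numbers verbatim.

### Schedules

`TS1` = bvz, then FOLFOX 24 h later, weekly cycles; `TS2` = FOLFOX
first, bvz 24 h later. Defaults are 4 weekly cycles (the TS2 animal
experiment managed only 3 before euthanasia; cycle count is a
parameter). Treatment breaks defer every administration from the break
start by the break length.

## Numerics

Infusion starts and ends are kink times of the forcing (continuous,
not smooth), so every integration is split piecewise at them rather
than relying on event detection inside a step controller.

Two integration paths share one interface and are cross-validated in
the tests (0.1% sup-norm on the published example parameter sets):

* reference: scipy `solve_ivp` (LSODA default, BDF available),
  rel/abs tolerances 10⁻⁶/10⁻⁸ mm³;
* fast: a numba-compiled embedded Dormand–Prince 5(4) integrator with
  proportional step control (rel 10⁻⁶/abs 10⁻⁸ for trajectory work;
  rel 10⁻⁴/abs 10⁻² mm³ inside inference, where the ~0.1 mm³
  integration error sits two orders below the per-point residuals at
  the distance floor), used by the ABC engine, where ~10⁶ forward
  simulations per fit make scipy's per-call overhead prohibitive.

Inside the chemotherapy response only, `(V−V*)` and `(K−V*)` are
floored at 10⁻⁶ mm³: the continuous law's negative exponents diverge
as `V → V*`, and the floor keeps likelihood-free exploration of the
printed prior finite without touching well-behaved states. States
reaching `V ≤ V*` or `K ≤ V*`, and non-finite right-hand sides, abort
the simulation with a reportable error; the inference engine counts
such proposals as rejections.

## Synthetic xenograft studies

No raw animal data are published (volumes appear only in figures), so
every fit runs on synthetic studies with known ground truth. The
generator emulates a subcutaneous caliper-measured xenograft
experiment: cohorts of 12 animals per arm; inter-animal lognormal
variation of λ₁ (σ = 0.10) — the growth rate is where real replicate
experiments differed most; enrolment when the cohort mean crosses
200 mm³ (the pre-treatment growth phase runs from a 25 mm³ implant
with `K₀ = 5 V₀`); weekly dosing; twice-weekly measurements to day 45;
10% proportional Gaussian caliper noise, truncated at zero and
flagged; arm mean and SEM reported.

What it does **not** emulate: animal dropout, measurement-day jitter,
correlated within-animal errors, or any vascular/histology readout —
so passing recovery tests demonstrate the inference machinery is
correct and the design informative, not that real xenograft data would
constrain the model equally well.

Ground truths (all inside the prior support):

* **recovery study** (threshold law): λ₁ = 0.15, λ₂ = 0.002, c = 1.5,
  α = 0.05, d = 0.12, K_F = 0.08, α₂ = 300, h = 15, with moderate PK
  rates. Chosen so the untreated plateau (~1400 mm³) is reached within
  the horizon, both monotherapies are clearly active, and neither
  eradicates the tumour.
* **selection studies**: the two laws overlap heavily on monotone
  vasculature effects, so ground truths were designed (before the
  acceptance tests were frozen) to exercise each law's distinctive
  signature: the threshold truth (K_F = 0.3, α₂ = 450, h = 15) drives
  `K` below the Hill threshold mid-arm, shutting delivery off and
  producing sawtooth regrowth no power law with |exponent| ≤ 3 can
  follow; the continuous truth (α₁ = 0, β₁ = 1, K_F = 0.03) kills at a
  rate independent of tumour volume, which the strictly
  volume-proportional threshold law cannot imitate. Stronger
  volume-independent kills (K_F ≥ 0.05) exterminate the simulated
  tumour, which bounds that design.

## Inference

ABC-SMC with simultaneous Bayesian model selection. The parameter
vector is θ = (λ₁, λ₂, c, α, d, Bk₁₂, Bk₂₁, Bk_e, Fk₁₂, Fk₂₁, Fk_e,
K_F, x₁, x₂) with (x₁,x₂) = (α₁,β₁) or (α₂,p₁) by model; a discrete
model indicator `m` is sampled and perturbed alongside θ (switch
probability 0.05 per proposal between surviving models). Priors are
independent uniforms on the printed ranges (a log-uniform option
exists behind a flag, e.g. for `d` whose range spans five decades; the
defaults are linear because the printed table says uniform).

The distance is the squared Euclidean misfit of the tumour-volume
series, pooled over the vehicle and two monotherapy arms
simultaneously; each arm is simulated from its own first non-zero
mean volume with `K₀ = 5 V₀`. Generation 0 is a straight prior sample
(ε = ∞, uniform weights); thereafter ε is the 0.1-quantile (0.07 for
the recovery experiment) of the previous generation's accepted
distances. Weights follow the standard sequential importance ratio
prior/(model-kernel mixture × θ-kernel mixture), computed in log
space. A model whose particle count reaches zero is extinct for the
rest of the run (reported, not fatal).

**Perturbation kernel.** A component-wise uniform kernel with
half-width 0.5× the previous population's per-parameter *range* was
implemented first and abandoned on evidence: ranges are
outlier-dominated and never shrink for weakly constrained parameters,
so acceptance collapsed below 0.5% while ε stalled ~100× above the
noise floor. The shipped kernel is the optimal-local-covariance
multivariate normal: each parent perturbs with 2× the weighted scatter,
about that parent, of the previous particles that already satisfy the
*next* tolerance (all of the model's particles when fewer than dim+1
qualify), ridged with a tiny diagonal jitter so the Cholesky factor
always exists. This follows the curved, strongly correlated posterior
ridges (the c–α–d surface; the Bk_e–α trade-off) that a global
covariance cannot track, and keeps per-generation acceptance in the
1–15% range to the noise floor.

Throughput choices that matter: the three arms and the distance are
fused into one compiled pass that aborts as soon as the accumulated
squared error exceeds ε; out-of-support proposals are rejected before
any simulation and do not count against the proposal budget; proposal
generation is vectorised in batches. Randomness comes from one seeded
generator in the serial proposal loop; distance evaluation is a pure
function of (θ, m), so the optional threaded evaluation (`n_jobs`)
cannot change results — fixed-seed runs are asserted bit-identical
across worker counts.

Reference budgets: recovery N = 2000 particles, prior + 6 tolerance
updates at the 0.07 quantile (~1.5 M simulations, ~5 min single-core);
selection N = 1500, prior + 13 updates at the 0.15 quantile
(~0.4–0.9 M simulations per direction) — the gentler schedule lets the
weaker model family survive the middle generations where the two laws
still mimic each other. These sizes were chosen so a full pipeline
re-run completes on one CPU in well under an hour; posterior medians
for λ₁ land within a few percent of truth and K_F within ~10–25%, with
95% credible intervals covering both. An optional total-simulation
budget (`max_total_sims`) stops a run gracefully after its last
completed generation instead of grinding on a pathological
acceptance collapse; the reproduction script uses it to bound its
wall time deterministically.

## Posterior diagnostics

* **Best fit**: the minimum-distance particle (first occurrence on
  ties) — used for forward predictions, as the source study did.
* **NRMSE**: per-arm RMSE divided by that arm's mean observed volume,
  summed over the three fitted arms. The caption quantity it mirrors
  never defines its normaliser, so values are comparable within this
  package, not bit-comparable to the published 0.38/0.24.
* **Sensitivities**: diagonal of the inverse weighted posterior
  covariance (conditional precisions), scaled to a dimensionless
  "relative" score. The default scaling is the squared weighted
  posterior mean (an inverse squared conditional coefficient of
  variation); squared-prior-width scaling is available but inflates
  any parameter whose true value is tiny relative to a wide prior
  (α's [0,10] range being the canonical offender). Under the default,
  the growth constant λ₁ ranks first on the recovery posterior.
  Singular covariances fall back to a flagged pseudo-inverse.
* **Posterior shift**: weighted two-sample Kolmogorov–Smirnov
  statistic between one parameter's marginals in two populations
  (0 = identical, 1 = disjoint), e.g. prior generation vs final
  posterior, or two experiments' posteriors.

## Open choices, resolved

* `V*` is never given a number in the source; it defaults to 0
  (recovering the classical equations exactly) and is validated to be
  below every initial volume when set.
* Whether the original fits superposed repeated doses or reset
  concentrations per administration is unstated; superposition is the
  physically consistent choice for linear PK and is what the
  dose-carrying ODE oracle confirms.
* The α₂ units are printed inconsistently (mg/nl vs mg/ml); all
  values are used raw, making the priors and caption values mutually
  consistent.
* "6 generations" for the recovery budget is read as six tolerance
  updates after the prior generation.
* The per-arm dosing start in synthetic studies is the arm's own
  enrolment-crossing day, mirroring how real arms start at different
  days; the fitted schedules are taken from the ground-truth record,
  as the real study took them from the experimental log.

## Known limitations

* The ABC engine is single-machine; `n_jobs` uses threads and buys
  little while numba holds the GIL — it exists for the determinism
  contract more than for speed.
* Posterior effective sample sizes in late generations can drop to a
  few tens (importance-weight variance inherent to the prior/mixture
  ratio); medians and intervals quoted on the reference budgets are
  stable, but tail quantiles should be treated cautiously.
* Selection outcomes depend on the data actually exercising the laws'
  distinctive regimes; on data where both laws fit equally (e.g. no
  chemotherapy signal) the model probabilities correctly hover near
  1/2, which the suite asserts.
* K_F recovers with an upward bias until ε approaches the noise floor
  because K_F trades off against the Hill saturation level; the
  reference budget is deep enough to bring the median within ~10–25%.
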