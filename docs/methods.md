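# Methods

## Model

A two-drug (or n-drug) combination is modelled at the level of the single
drugs' pharmacodynamic parameters. Each drug has a sigmoidal Emax
exposure–response, `E(C) = Emax·C^H/(EC50^H + C^H)`, evaluated on the
logistic scale (`Emax·expit(H·(ln C − ln EC50))`), which is exact for C = 0
and immune to overflow at any C/EC50 ratio. Linear-slope (`E = SLOPE·C`) and
power (`E = SLOPE·C^H`) forms cover screens whose top concentration stays
well below the EC50; for those, an interaction factor placed in the
denominator reads as a fractional EC50 change and in the numerator as a
fractional Emax change (with opposite sign convention, approximate for the
power form where the slope aggregates Emax/EC50^H).

An interaction is a directed, saturable shift of a victim parameter θ by a
perpetrator at concentration C:

    θ → θ · (1 + INT·C^H_INT/(EC50_INT^H_INT + C^H_INT)).

INT ≥ −1 so the factor stays positive; the estimation transform log(1+INT)
enforces this without a constrained solver. Shifts on EC50 produce
competitive-type behaviour and are the only kind admitted under Loewe
Additivity (which presumes a mutual maximum effect); shifts on Emax produce
allosteric-type behaviour with opposite effect-level polarity. Multiple
perpetrators on the same victim parameter multiply, and the factor scales
EC50 *before* exponentiation by the victim's Hill factor: `(EC50·f)^H`.
Modulation terms apply the same functional form to another term's INT
(`INT_AB·(1 + INT_AB|C·sat(C_C))`), nested arbitrarily deep; terms are
identified by the chain of drug ids `(perpetrator, victim[, modulators…])`
and resolved iteratively, so effective INT values are well defined for any
number of drugs.

Perturbed single-drug effects are combined under one of four criteria:
Bliss Independence `1 − ∏(1 − E_i)`, effect addition (clipped at a
configurable ceiling, default 1), highest single agent, or Loewe Additivity.
The Loewe combined effect is the root of the dose-fraction sum
`Σ C_i/(EC50_i·f_i·(E/(Emax_i − E))^(1/H_i)) = 1`, which is strictly
decreasing in E on (0, min Emax): the scalar API uses Brent's method on the
bracket `[ε, min(Emax)(1−ε)]` with ε = 1e−12 and verifies the residual below
1e−10; surface evaluation over well grids uses a fixed-iteration (90
halvings) vectorised bisection of the same function, which agrees with the
scalar path to ~1e−9 and handles zero-dose margins by short-circuiting to
the perturbed single-drug effect. When the dose-fraction sum exceeds 1 even
at the upper bracket end, the effect is capped just below min(Emax) and
flagged; unequal Emax values (> 1% apart) additionally warn, since the
dose-substitution definition presumes a mutual maximum. The n-drug sum is a
direct extension of the two-drug pattern.

Time-course screens are modelled by a lag + logistic growth system,
`dS1/dt = −k_lag·S1`, `dS2/dt = k_lag·S1 + k_growth·S2·(1 − S2/B_max)·(1 −
E_comb)`, observed as OD = S1 + S2. Concentrations are constant within a
well, so E_comb is evaluated once per well. The reference integrator is
adaptive RK45 (rtol 1e−8, atol 1e−12) with an LSODA fallback; inside
objective functions a fixed-step RK4 over all wells at once (step ≤ 0.1 h,
S1 eliminated by its closed form) reproduces the adaptive solution to
~1e−8 OD units at a fraction of the cost.

## Comparator models

The Greco response surface extends the Loewe sum by a single interaction
index α (α = 0 additive, α > 0 synergy, α < 0 antagonism); its implicit
equation shares the bracketing/bisection machinery. The unsubscripted Emax
in its interaction term is taken as min(Emax_A, Emax_B), consistent with
the model's mutual-maximum assumption. For strongly negative α the equation
can lose its root; the nearer boundary value is returned with a warning so
batch fits proceed. The empiric Bliss model `E = E_A + E_B − β·E_A·E_B`
(β = 1 additive, β > 1 antagonism, β < 1 synergy) is explicit. The isobole
curvature score `γ = logit(x) − logit(y)` is computed on user-supplied
MIC-normalised contour points (a linear-interpolation contour extractor at a
caller-chosen effect level is provided as a convenience); the logarithm base
defaults to natural and only rescales the score. γ < 0 is read as synergy
and γ > 0 as antagonism; sign readings at the classification step are
configurable because the convention pairs by sentence order in common
usage.

## Estimation

The residual model is additive Gaussian on the observation scale (effect or
OD), with SD either fixed or profiled out of the likelihood (σ̂² = RSS/n);
the reported objective is OFV = −2 log L and AIC = OFV + 2·p with p counting
estimated structural parameters plus σ when estimated. Because the Gaussian
ML estimates coincide with least squares, optimisation uses
`scipy.optimize.least_squares` (trust-region reflective, tolerances 1e−12)
on transformed parameters — log for Emax, EC50, Hill factors, rate
constants and interaction potencies; log(1+INT) for interaction fractions —
with 5 jittered restarts (SD 0.3 on the transformed scale, seeded) to guard
against local minima. Invalid parameter excursions during the search are
absorbed as large residuals. This replaces a generic simplex + quasi-Newton
pairing deliberately: for this objective it reaches machine-precision
zero-noise recovery and is an order of magnitude faster, with identical
estimates. Standard errors come from the Gauss–Newton approximation to the
observed information, `cov = s²(JᵀJ)⁻¹` in transformed coordinates,
delta-method back-transformed; when that matrix is singular (typically a
potency escaping beyond the tested range) no SEs are reported, mirroring a
failed covariance step in standard fitting tools.

The stepwise build has four steps. (1) Single-drug parameters are estimated
on monotherapy wells only (at least three non-zero concentrations per drug
are required); time-course data additionally estimate the growth parameters,
shared across all wells of a scenario, and pin Emax to 1 by default because
a turbidity read-out cannot see effects beyond full growth stasis (endpoint
effect data estimate Emax by default). (2) With those fixed, the combination
wells are fitted with a reduced one-parameter model — joint INT for both
directions, each interaction potency pinned to its perpetrator's EC50 — and
expanded greedily one parameter at a time (directional INT split, each
EC50_INT freed, optionally each H_INT), accepting an expansion only when the
objective drops by ≥ 3.84 (χ²₁ at α = 0.05; a drop of 3.83 is rejected).
Ties prefer the directional split, then fewer parameters, then lexicographic
order. H_INT estimation is off by default. (3) On data with three or more
drugs, modulation terms are tested with all lower-order parameters fixed;
the implementation provides this as a focused single-term test on trio
endpoint grids rather than a fully general n-drug driver, since the primary
pipeline is the two-drug checkerboard. (4) All retained parameters are
re-estimated jointly on all wells for the final objective and standard
errors. The history records every candidate with its ΔOFV and decision.

Different expansions can be near-equivalent: on monodirectional truth, the
greedy step sometimes frees the silent direction's EC50_INT (driving it far
above the tested range) instead of splitting INT — both parameterisations
say the same thing, and the shift-based classification is invariant to the
choice.

A known property of this conditional procedure is that the step-2
likelihood-ratio test is calibrated only given correct single-drug
parameters. Conditioning on noisy step-1 estimates makes the test
anti-conservative — on 8×8 endpoint checkerboards at σ = 0.03 the
directional split is accepted in roughly a fifth of null replicates rather
than the nominal 5%, and richer combination data sharpen the propagated
misfit rather than washing it out. This is precisely why interaction calls
are gated by the sham-calibrated additivity margin rather than by raw
statistical significance; users should read the LRT history as a
model-building device, not an error-rate guarantee.

## Classification, margins and networks

A fitted directional term is summarised as the fractional change of the
victim's EC50 at the perpetrator's EC50 (in the reduced model this equals
INT/2 exactly, since the pinned potency makes the saturation one half), and
as `(1 + shift)·100%` of baseline. Shifts whose parameters did not pass the
LRT are treated as zero. The additivity margin defaults to the fixed band
(−0.5, +0.5) and can instead be derived as the 10th–90th percentile of sham
(drug-vs-itself) shifts; boundary values count as additive (conservative
calling, configurable). The same margin is reused under Bliss, where sham
fits show a systematic negative (self-synergy) bias — expected, since a
drug's action cannot be independent of itself. Six classes partition the
shift plane: additive, bidirectional synergy/antagonism, monodirectional
synergy/antagonism, bidirectional asymmetric (opposite polarities,
concentration-dependent synergy/antagonism). Networks draw one directed
edge per outside-margin shift (synergistic when the victim's EC50
decreased); the exclusive join across Loewe- and Bliss-based analyses keeps
a direction only when it is outside the margin with the same polarity under
both, carries the Loewe shift as the primary edge value, and drops
polarity conflicts with a log entry. Per-drug profiles tally in/out degrees
by polarity and flag sole perpetrators and sole victims.

## Design identifiability

For additive Gaussian noise the expected Fisher information over a design is
`FIM = JᵀJ/σ²`, with J the central-finite-difference sensitivities (relative
step 1e−6) of the predicted endpoint effect at every well; anticipated RSEs
are `100·sqrt(diag(FIM⁻¹))/|θ|`, with singular information reported as
infinite RSEs and tallied. The bundled study draws a symmetric Bliss-based
model — both drugs share (Emax, EC50, H), one joint (INT, EC50_INT) acts in
both directions, H_INT = 1 — from Emax ~ U(0.5, 1), EC50 ~ U(0.5, 2),
H ~ U(1, 4), INT ~ U(−0.9, −0.5) ∪ U(0.5, 20) (equal weight between the
bands), EC50_INT ~ U(0.1, 1), at σ = 0.03 on the effect scale, and
summarises the RSE distribution (median, 10th/90th percentiles) per
parameter over 1000 draws. The log2 design is 0 plus seven two-fold steps
ending at 8 concentration units; the linear design spans 0–8 in equal
steps, and is evaluated with both EC50-type parameters drawn within 40–60%
of the top concentration, since a linear grid has no tiers near a sub-unit
potency — under these readings the log2 layout identifies the interaction
parameters two- to three-fold more precisely, and the anticipated RSEs agree
with Monte-Carlo refitting SDs to within a few percent.

## Synthetic data

The generator emulates antifungal checkerboard screens: an 8×8 log2
dilution grid (configurable), a known truth model, and either endpoint
effects or 24-hour growth time-courses (20 read-outs by default) with iid
additive Gaussian noise, σ = 0.03 — a typical in-vitro assay variability.
Negative observations are truncated at zero and counted on the dataset;
identical seeds reproduce datasets bit-identically. Sham combinations place
the same drug on both axes and observe the dose-addition surface
`E(C_A + C_B)`, which is what a drug physically does with itself; they feed
the margin calibration. Growth parameter defaults (k_lag 1/h, k_growth
0.5/h, B_max 1 OD, inoculum 0.01 OD starting in the lag state) are
plausible for yeast micro-cultures but arbitrary — the source screens report
no growth constants — and simulations state them explicitly. What the
generator does *not* emulate: plate-reader edge effects, evaporation, drug
degradation, carry-over, or non-Gaussian error; passing tests on these data
show correctness of the estimators and calling rules under the stated noise
model, not robustness to real-plate artefacts.

Problem sizes used by the test-suite simulation studies (error control at
100 endpoint replicates, direction recovery at 50, coverage at 200,
Monte-Carlo FIM agreement at 200) were chosen to give stable proportions
while keeping the whole suite in the minutes range on one CPU.

## Known limitations

- Loewe and Greco surfaces for more than two drugs cap at the global
  minimum Emax even when the weakest drug is absent from a well; with equal
  Emax values (the usual turbidity setting) this is immaterial.
- The empiric Bliss comparator is fitted without clipping its surface to
  [0, 1]; clipping is applied on prediction only.
- Bootstrap confidence intervals and mixed-effects (population) estimation
  are out of scope; standard errors are asymptotic.
- The time-course fitting path requires a complete common time grid across
  wells.
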