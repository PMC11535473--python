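# Methods

## The mechanistic model (MMK)

State vector (19 components, all per culture volume): volume V (mL), viable
cell density X_v (cells/mL), extracellular Glc/Gln/Glu/Lac/NH4/Gal (mM),
titer mAb (mg/L), intracellular Glc/Gln/Gal pools (mM), four nucleotide
sugar donors UDP-Glc/UDP-Gal/UDP-GlcNAc/UDP-GalNAc (mM), and three
glycoform masses M_G0F/M_G1F/M_G2F (mg/L) whose sum equals the titer by
construction.

Between feed/sampling events:

- growth: dX_v/dt = (μ − k_d)·X_v with Monod μ = μ_max·Glc/(K_glc + Glc);
  the death rate k_d is constant (byproduct toxicity deliberately not
  modeled).
- glucose: dGlc/dt = −(μ/Y_xglc + m_glc)·X_v; glutamine mirrors it with
  (Y_xgln, m_gln), a data-generation extension needed because ammonium and
  glutamate are produced from glutamine consumption.
- byproducts by yields: dLac/dt = Y_lac·|dGlc/dt|, dNH4/dt = Y_nh4·|dGln/dt|,
  dGlu/dt = Y_glu·|dGln/dt|.
- production: dmAb/dt = (α·μ + β)·X_v (Luedeking–Piret; α = 0 or β = 0
  recover the pure growth-associated or basal cases).
- galactose uptake: dGal/dt = −V_gal·Gal/(K_gal + Gal)·g(Glc)·X_v with an
  optional glucose-inhibition factor g = 1/(1 + Glc/Ki); Ki = ∞ (disabled)
  by default.
- intracellular pools: volumetric membrane transport V_t·S/(K_t + S) in,
  synthesis consumption out, and a growth-dilution term −μ·S_in.
- NSD synthesis: UDP-Glc ← Glc_in (uni-uni); UDP-Gal ← UDP-Glc (uni-uni
  epimerase) + Gal_in (uni-uni salvage — the galactose-feed route);
  UDP-GlcNAc ← (Glc_in, Gln_in) (bi-ternary,
  V·S₁S₂/((K₁+S₁)(K₂+S₂))); UDP-GalNAc ← UDP-GlcNAc (uni-uni).  Each NSD
  additionally loses a constant Golgi transport flux f_n (gated off as the
  pool empties) and a dilution term μ·N.
- maturation: antibody secreted at time t is split across glycoforms by the
  closed form of two sequential pseudo-first-order galactosylation steps
  acting over the Golgi residence time τ_G, with rates
  κ_i = k_gal,i·U/(K_gal,i + U) read from the cytosolic UDP-Gal pool U:
  φ_G0F = e^(−κ₁τ), φ_G1F = κ₁/(κ₂−κ₁)(e^(−κ₁τ) − e^(−κ₂τ)) (analytic
  limit κ₁τ·e^(−κ₁τ) when |κ₁−κ₂| < 1e-12·max), φ_G2F = 1 − φ_G0F − φ_G1F.
  dM_i/dt = φ_i·dmAb/dt, so mass conservation M_G0F+M_G1F+M_G2F = mAb is
  exact by construction.

Numerical choices: every consumption flux is multiplied by the smooth gate
S/(S + 1e-9 mM) instead of hard clipping, keeping the right-hand side
continuous; the default integrator is BDF at rtol 1e-8 / atol 1e-10 (the
gate creates a genuine boundary layer at substrate depletion that defeats
LSODA's stiffness switching); residual negative values within −1e-6 of zero
are clipped at output.  Feed events are concentration increments by default
("fed 25 mM" = +25 mM, volume unchanged); a stock-volume mode with full
dilution accounting C_new = (CV + C_f v_f)/(V + v_f) is available.  Sampling
events remove volume and leave all intensive quantities unchanged.

Default parameter values are **synthetic-fixture values**, not literature
estimates.  They were chosen once to make the fixture behave like the system
it emulates: peak VCD ≈ 1.9e7 cells/mL from a 0.3e6 inoculum, harvest titer
≈ 2–5e2 mg/L, glucose (33 mM at inoculation) running down through its
half-saturation region before depletion, and UDP-Gal rising severalfold
after each 25 mM galactose bolus, pulling the glycan split from roughly
69/29/2 toward 46/44/10 (G0F/G1F/G2F %).  K_glc = 8 mM deserves a note: a
lumped-model value this large keeps μ only partially saturated mid-culture,
which is what makes (μ_max, K_glc) jointly identifiable from batch data —
with the sub-millimolar K of single-enzyme kinetics, the Monod constant is
essentially unidentifiable from any batch trajectory because glucose then
saturates growth until the final hours.

## Estimation

Under independent Gaussian errors with channel variances 1/w_c, minimizing
Σ w_c (obs − pred)² is maximum likelihood; the default channel weights
w_c = 1/mean(|value|)² make the objective invariant to unit changes.  An
alternative `residual_scale="observation"` divides each residual by the
observation magnitude (floored at 5% of the channel mean) — the exact MLE
when measurement error has constant CV, as the synthetic generator's does;
it concentrates weight where the signal is informative (e.g. the glucose
depletion region for K_glc).

Two residual modes: free simulation from t₀, and teacher forcing, which
re-initializes every *measured* state channel to its observed value at each
observation time and emits per-segment residuals (unmeasured channels carry
the simulated value across segments).  The optimizer is multi-start
trust-region-reflective least squares; starts beyond the user's p₀ are drawn
log-uniform within the bounds from the seed.  Two settings matter and are
set internally: per-parameter `x_scale` (the parameters span six orders of
magnitude) and `diff_step = 1e-4` (finite-difference steps must sit well
above the adaptive integrator's ~1e-6 noise floor, or the Jacobian is noise
and the optimizer stalls on the flat μ_max–K_glc ridge).  Bounds keys of the
form `init.Xv` co-estimate initial-state components — anchoring a simulation
to a noisy t = 0 sample otherwise biases the growth parameters, and
biological replicates have genuinely different inocula, so fits are done per
flask.  Only a configurable subset of parameters is fitted (growth, uptake,
production, NSD V_max by default); K-constants stay fixed to keep the
problem overdetermined.  The t₀ convention for forward prediction: metabolite
and VCD initial values from the t = 0 observations, NSD initial values from
the earliest measured timepoint (~60–72 h) of the same condition.

## OPLS

Columns are autoscaled; every inner product skips missing cells (each
score/loading regression uses only entries present in both vectors).
Orthogonal components are extracted before predictive ones: a provisional
NIPALS component gives (w, t, p); the orthogonal weight is p minus its
projection onto an orthonormal basis of the column space of X'Y, so the
orthogonal scores are exactly uncorrelated with *every* response column on
complete data.  A consequence worth stating: with 7 factors and 9 responses
the cross-product X'Y is generically full rank, strictly Y-orthogonal X
variation does not exist, and the model reduces toward plain PLS — the
orthogonal loop stops early with a warning.  The pipeline default is
therefore five predictive components and no orthogonal ones (orthogonal
deflation on heavily missing X was also measured to erode R2Y badly); the
predictive/orthogonal split stays configurable and is exercised on data with
genuine Y-orthogonal structure in the test suite.  With heavy structured
missingness the masked alternating iteration can cycle rather than converge
(the masked operator is not a fixed linear map); the implementation then
falls back to a deterministic direction, the dominant left singular vector
of the mean-imputed cross-product, while scores still use skip-missing
projections.  Q² uses 7 folds (assigned round-robin after a seeded shuffle)
with PRESS accumulated over held-out rows; VIP over the predictive
components satisfies Σ VIP² = p.  Rows are observation-level (one per batch,
replicate, time), with time in hours appended as a seventh factor column so
the sensor can track culture progression; rows contribute only if they carry
at least one factor and one response value.

## The neural network

y = descale(W₂ᵀ tanh(W₁ᵀ scale(x) + b₁) + b₂) with the 6-3-8 architecture:
6·3 + 3 + 3·8 + 8 = 53 trainable parameters.  Inputs and outputs are
autoscaled; missing inputs impute to the training mean; outputs are
unconstrained reals and negative concentration predictions are preserved.
The objective is the SSE over *observed* scaled responses (rows missing a
response contribute only their observed channels) plus λ·Σ weights²
(biases unpenalized; this is also what lets a mostly-missing channel ride
along without poisoning the rest, and entirely-missing response columns are
dropped with the output layer re-sized).  Training: standard-normal random
starts drawn from the seed (default seed 1234 with 16 starts, both
configurable); first fit at λ = 0; golden-section line search on log λ;
inner BFGS with analytic gradient; per-iteration validation likelihood
monitored with a 10-iteration patience window; among line-search candidates
the model with the best training likelihood is reported.  Overfit is judged
by comparing R² and RASE (= sqrt(SSE/n) per response) between training and
validation data.

## Comparison statistics

One-way ANOVA followed by all-pairs Tukey HSD: SE_diff = √(MSW(1/n_a+1/n_b))
(Tukey–Kramer for unequal n), p from the studentized-range distribution with
k levels and the pooled df, rows oriented difference ≥ 0 and sorted by
descending |difference|.  "Whole-duration" comparisons treat the timepoints
of one trajectory as independent observations — this reproduces the
field-standard reporting convention but ignores autocorrelation, so the
p-values are optimistic; replicate construction (e.g. counting a pooled
average as a third replicate) is the caller's choice and not endorsed
statistically.  Specific rates use the trapezoid rule on the available VCD
points; the feed-window metric compares per-window increments
100·|Δpred − Δobs|/|Δobs| and is offset-invariant; the galactosylation index
uses the two-site occupancy form GI = (0.5·G1F + G2F)/ΣG.

## The synthetic generator

Four conditions (Control 144 h; 25 mM galactose at 72 h, 216 h; at 120 h,
216 h; at both, 288 h), two replicate flasks with inocula drawn uniformly in
0.3 ± 0.15 × 10⁶ cells/mL, channel-class sampling grids reproducing the
published cadences and counts (metabolites 10/13/13/18 points; NSDs every
12 h from 60 h, at the top of the stated ranges; glycans roughly daily from
72 h, validation at 72/96/144/168/192 h; galactose from the first feed on),
1.5 mL removed per sampling occasion.  Noise is multiplicative Gaussian
(default CV 5%, clip-at-zero; glycan noise hits the peak areas *before*
renormalization to 100%).  Missingness is an independent Bernoulli layer per
channel at the stated fractions — real missingness is schedule-driven and
blockwise, which the schedule grids already capture; the Bernoulli layer
adds the remainder.  What the generator does **not** emulate: batch effects,
drift, correlated assay errors, pH/DO/temperature excursions, byproduct
toxicity, amino-acid limitation.  Passing tests therefore demonstrate the
machinery is correct under the stated statistical structure, not that any
model family would win on a real campaign.

## Pipeline

One global seed fans out to per-stage seeds by fixed offsets; every random
draw flows from it, so two runs with the same seed produce byte-identical
reports.  Stages write serialized artifacts (CSV tables, JSON models) and
are resumable.  Data-driven sensors predict the held-out double-feed
condition timepoint-by-timepoint from its factor measurements; the kinetic
model predicts by forward simulation from its t₀ state.  Default pipeline
scale (2 kinetic starts, 5 fitted kinetic parameters, 4 NN starts, 4 penalty
evaluations) is chosen so a full run takes well under a minute; all counts
are configurable.

## Known limitations

- Whether the intracellular pools should be per-cell rather than per-volume
  is an open modeling question; the per-volume form with μ·N dilution is
  used.
- The OPLS batch-level unfolding of the emulated software cannot be
  reconstructed from its description; observation-level rows with time as a
  factor are used instead, and reported R²/Q² are not comparable to values
  computed under other unfoldings.
- The NN "best training likelihood" reporting rule means a nonzero penalty
  is only selected when validation stopping halts the λ = 0 fit early.
- Tukey p-values on trajectories inherit the independence approximation
  noted above.
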