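# Methods

This note documents the models implemented in `ecoeff`, the choices made
where the methodology was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Efficiency measurement (SBM and super-SBM DEA)

Each region-year is a decision-making unit (DMU) with inputs x (capital
stock, 10^8 yuan; labour, 10^4 persons; energy, 10^4 tce), a desirable
output (GDP, 10^8 yuan) and an undesirable output (carbon emissions,
10^4 t). The slack-based measure under variable returns to scale (VRS,
convexity Σλ = 1) minimizes

    ρ = (1 − (1/m) Σᵢ sᵢ⁻/xᵢ₀) / (1 + 1/(s₁+s₂) (Σᵣ sᵣ⁺/yᵣ₀ᵍ + Σᵣ sᵣᵇ/yᵣ₀ᵇ))

over nonnegative slacks and peer weights. Undesirable outputs enter with
*reduction* slacks — excess carbon is penalized symmetrically to excess
input — which is the default `as-output` mode; an `as-input` mode (carbon
folded into the input block) is available because either treatment is
common practice. The fractional program is solved exactly as an LP via the
Charnes–Cooper transformation (scale variable t bounded below by 1e-9),
with a lexicographic second stage maximizing total slack among alternative
optima so that reported slacks and peer weights are deterministic.

Super-efficiency: SBM-efficient units are re-scored against the frontier
of the *remaining* peers (the evaluated unit excluded from its own
reference set), allowing scores ≥ 1 that strictly rank efficient units.
In the super program the undesirable output behaves like an input (a
reference point may emit more carbon). With strictly positive data and
VRS this program is always feasible, by a scaling argument on t.

Frontier comparison: per-year mean scores against the contemporaneous
(same-year), sequential (all years ≤ t) and global (pooled) technologies.
Since these reference sets nest, Dg ≤ Do ≤ Dt holds per DMU before
averaging; years with fewer than two DMUs are flagged and skipped.

Correctness is checked against an independent Dinkelbach
fractional-programming oracle (parametric iteration on the *original*
variables, no Charnes–Cooper) on all instances with ≤ 6 DMUs; agreement is
at machine precision.

## Global Moran's I

I = (n/S₀) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ², z = x − x̄. The default inference is the
normal approximation under the randomization assumption (moment formula
with S₀, S₁, S₂ and sample kurtosis b₂), reporting E[I] = −1/(n−1), a z
value and a two-sided p — matching the one-z-one-p-per-year reporting
convention of applied work. A seeded permutation test (≥ 999 shuffles,
two-sided p = (#{|I*| ≥ |I|}+1)/(perms+1)) is available. Constant inputs
and n < 3 are rejected as degenerate.

## Markov and spatial Markov dynamics

Scores are discretized into k = 4 states by pooled quantiles (state 1 =
lowest); boundary values go to the lower state, and a per-year mode is
offered since pooled-vs-annual binning is an open convention. Transition
counts are taken over consecutive (t, t+1) pairs within regions; rows with
no observations are reported as *missing*, never zero-filled, so that
every observed row sums to one exactly. The spatial variant stratifies
transitions by the origin-year state of the region's spatial lag
(neighbourhood average discretized with the same bins); counts conserve
across strata by construction.

## Spatial Durbin model (SDM)

y_t = ρ W y_t + X_t β + W X_t φ + μ + ν_t + ε_t on a balanced panel with
row-standardized W. Fixed effects are removed by orthonormal
transformations rather than naive demeaning: an orthonormal basis of the
complement of 1_T sweeps region effects, and a basis Q_n of the complement
of 1_n sweeps year effects, under which W (with W1 = 1) transforms exactly
to W* = Q_n W Q_nᵀ of dimension n−1, shedding its unit eigenvalue. This
leaves a standard SAR likelihood on (n−1)(T−1) effective observations and
avoids the incidental-parameters bias in ρ̂ that direct demeaning produces
at provincial dimensions (n ≈ 30): in the package's Monte-Carlo harness
the naive estimator showed bias ≈ −0.055 and Wald size ≈ 11%, the
transformed estimator bias ≈ 0.005 and size ≈ 4.5%.

Estimation concentrates the likelihood in ρ: slope parameters have closed
forms given ρ, and ll(ρ) = T* Σ ln(1 − ρλ*ᵢ) − (N*/2) ln(e'e/N*) is
maximized by bounded scalar search (tolerance 1e-8) on the stability
interval (1/λ_min(W), 1). The parameter covariance uses the analytic
information matrix with a degrees-of-freedom-corrected σ² (divisor
N* − k − 1), which is what keeps the Wald tests near nominal size at these
panel sizes. Time-lagged regressors (`xlag_periods`) shift X back before
demeaning and drop the first periods.

Effects decomposition: for regressor k, S_k = (I − ρW)⁻¹(Iβ_k + Wφ_k);
the average direct effect is the mean diagonal, the average indirect
(spillover) effect the mean off-diagonal row sum, total = direct +
indirect identically. Standard errors come from ≥ 100 draws of (β, φ, ρ)
from the estimated parameter distribution, discarding draws with ρ outside
the stability interval.

Reduction tests are Wald tests with df = number of lagged regressors:
SAR (H₀: φ = 0) and SEM (common-factor restriction H₀: φ + ρβ = 0, delta
method).

## Stochastic frontier (time-varying translog)

ln y_it = x_itᵀβ + v_it − u_it with the translog design ordered
(t, ln x₁..₃, t², (ln x)², t·ln x, pairwise ln x crosses, intercept; 15
columns), v ~ N(0, σ_v²), and decay inefficiency u_it = e^{−η(t−T_i)} u_i,
u_i ~ N⁺(μ, σ_u²) (normal truncated at zero — the distribution the
(μ, η, σ², γ) parameterization implies). The likelihood is maximized in
(β, ln σ², logit γ, μ, η) with σ² = σ_u² + σ_v² and γ = σ_u²/σ², so γ is
the inefficiency share of the composite error variance. Technical
efficiency uses the conditional predictor
E[e^{−u_it} | ε_i] = e^{−h_it μ* + h_it²σ*²/2} Φ(μ*/σ* − h_it σ*)/Φ(μ*/σ*).

Numerical choices: the raw translog design is catastrophically
ill-conditioned (squares and cross-products of logs of 10²–10⁵ inputs), so
non-constant design columns are standardized internally for the optimizer
and coefficients mapped back exactly. Multi-start over γ ∈ {0.2, 0.6, 0.9}
(L-BFGS-B, numeric gradients, ftol 1e-8) guards against local optima; the
γ → 0 boundary is handled by comparing against the OLS limit, and fits
with γ̂ within 1e-4 of a bound are flagged. Balanced panels use a fully
vectorized likelihood.

LR tests: statistic 2Δloglik against the full fit. H1 drops all ten
second-order terms (Cobb–Douglas), H2 all five time terms, H3 pins μ = 0,
H4 pins η = 0, H5 pins μ = η = γ = 0 (OLS). Nulls that pin a variance
parameter at its boundary (H5) use the half-half mixture of χ²(df) and
χ²(df−1) rather than plain χ².

A caution on the decay anchor: u_i is the *final-period* inefficiency, so
with a large decay rate (the default η = 0.4 over T = 10 years) early
periods carry e^{3.6} ≈ 37× that inefficiency, i.e. near-zero early
technical efficiency. This is the literal implication of a decay rate of
that size in this model family; estimators handle it (it is strong signal
for η), but it should not be mistaken for a realistic efficiency path.

Under the no-inefficiency null, γ̂ from the restricted half-normal fit
(μ, η pinned — both are unidentified when σ_u² = 0) converges to zero as
the number of regions grows, but at n = 30 × T = 10 roughly one replicate
in five yields γ̂ ∈ (0.05, 0.13): the MLE attributes the one-sided part of
region-mean sampling noise to inefficiency. This finite-sample behaviour
is a property of the estimator class, not of the implementation (the
nonzero values are verified global optima under multi-start).

## Grey forecasting (GM(1,1) + BP residual correction)

GM(1,1) fits the accumulated series x¹ (running sum of the positive
series x⁰) through the grey equation x⁰(t) + a z(t) = u with background
value z(t) = (x¹(t−1) + x¹(t))/2, solved by least squares, and restores
values with the time response x̂¹(t+1) = (x⁰(1) − u/a)e^{−at} + u/a,
x̂⁰ by differencing, x̂⁰(1) = x⁰(1) (zero base-year error by convention).
Because the averaged background value is a trapezoidal discretization of
the continuous equation, the raw least-squares coefficient satisfies
a_ls = 2 tanh(a/2); `fit_gm11` inverts this, a = ln((2+a_ls)/(2−a_ls)),
u = a·(u_ls/a_ls), which removes the O(a³) discretization bias and makes
the model *exact* on geometric series (fitted ratio e^{−â} equals the
series ratio to machine precision) and exactly recoverable from its own
time-response family. The textbook plug-in estimator remains available as
`bias_correction=False`. Flat series (|a_ls| < 1e-12) fall back to a
constant model at the mean of x⁰(2..N) with a warning.

Adequacy grading uses the posterior variance ratio C = s₂/s₁ (s₁ = s.d.
of the data, s₂ = s.d. of the t ≥ 2 residuals, both population form) and
the small-error probability P = share of residual deviations within
0.6745·s₁, graded Good (C < 0.35, P > 0.95), Qualified (C < 0.5,
P > 0.8), Barely qualified (C < 0.65, P > 0.7), else Unqualified; both
bounds of a band must hold, with the strict/non-strict boundary operators
applied literally. Reported relative errors are (actual −
fitted)/actual × 100 rounded to two decimals; the mean absolute error
excludes the base year, which is zero by construction.

The BP network is a single-hidden-layer feed-forward net (sigmoid hidden,
linear output) trained by full-batch gradient descent on the MSE of
min-max-normalized data (features and targets mapped to [−1, 1]), with
seeded uniform(−0.5, 0.5) initialization. Defaults: 5 hidden units,
learning rate 0.05, 10,000 epochs, target MSE 1e-5 — unstated in the
methodology being implemented, so fixed here as package defaults. The
hybrid forecaster trains the network on sliding windows (default length
3) of past GM residuals to predict the next residual; combined value = GM
value + predicted residual, identically. When residuals are numerically
zero the BP stage is skipped and the hybrid coincides with plain GM(1,1).
Forecasts iterate the residual predictor on its own outputs.

## Economic comparisons

Yield ratios (organic as % of conventional) are rounded half-up to
integers to match display conventions; gaps are in kg/mu. Cost totals sum
itemized per-mu costs; owner-imputed items (the farmer's own labour and
land rent) can be excluded from the conventional column, following the
parenthetical convention of published cost sheets. A consistency checker
*reports* printed-vs-recomputed mismatches (e.g. a printed difference of
484 against column arithmetic of 485) without overwriting either number.

## Synthetic data: what it does and does not emulate

The generators produce exactly the structure the estimators assume:
a translog frontier with truncated-normal time-decay inefficiency
(default frontier: Cobb–Douglas special case with elasticities
0.40/0.30/0.15, intercept 3.76, time trend 0.02; defaults μ = 0.5,
η = 0.4, σ_u² = 0.12, σ_v² = 0.08, i.e. σ² = 0.2, γ = 0.6); the SDM
reduced form y_t = (I − ρW)⁻¹(X_tβ + WX_tφ + μ + ν_t + ε_t) with iid
standard-normal regressors, region/year effect variances 0.1 and defaults
ρ = 0.3, β = 1, φ = 0.2; ring / rook-lattice / random-k-regular contiguity
graphs; and GM(1,1) time-response series (default a 0.006 decline from a
base of 15,783, the scale of a national agricultural carbon-sink series)
with optional additive noise. Inputs are iid log-uniform over ranges
matching the order of magnitude of provincial statistics; carbon is
c·energyᵏ times lognormal noise (defaults c = 2, κ = 1), guaranteeing
positivity and monotonicity in energy but nothing more, since no emission
accounting scheme is implemented.

Not emulated: serial correlation in inputs, realistic cross-variable
correlations, unbalanced panels, measurement error, or actual provincial
magnitudes beyond orders of magnitude. Passing the Monte-Carlo harnesses
therefore demonstrates estimator correctness under the assumed models, not
robustness to real-data violations of them.

Harness sizes (chosen to exercise the asymptotics the estimators rely on
while staying at desk scale): SDM calibration at n = 30 regions × T = 20
years over 200 seeds; SFA calibration at n = 30 × T = 10 over 100 seeds;
DEA oracle checks on instances of ≤ 6 DMUs and ≤ 3 dimensions.

## Known limitations

* Only VRS technologies in the DEA module; CRS and Malmquist
  decompositions are out of scope.
* The SDM is static (no time-lagged outcome) and estimated by QML only.
* The frontier module offers no heteroskedastic or cost-frontier
  variants.
* The grey module's multi-indicator long-horizon forecasts depend
  entirely on the single-series GM(1,1)+BP machinery; no cross-indicator
  wiring is implemented.
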