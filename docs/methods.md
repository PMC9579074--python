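# Methods

## The problem

The likelihood-ratio model test in covariance-structure analysis compares a
confirmatory factor model against the saturated model through
T_ML = (N − 1) F̂_ML, where

    F̂_ML = ln|Σ(θ̂)| − ln|S| + tr[S Σ(θ̂)⁻¹] − p

is the normal-theory ML discrepancy between the sample covariance S and the
model-implied Σ(θ̂).  Under multivariate normality and a correct model T_ML
is asymptotically χ²(df) with df = p(p+1)/2 − q.  Under non-normality its
true limit is the weighted mixture Σⱼ wⱼ χ²(1), with weights the non-null
eigenvalues of U Γ:

    U = W⁻¹ − W⁻¹ Δ (Δ′W⁻¹Δ)⁻¹ Δ′W⁻¹

where W is the normal-theory weight matrix evaluated at Σ(θ̂)
(w₍ᵢⱼ₎,₍ₖₗ₎ = σ̂ᵢₖσ̂ⱼₗ + σ̂ᵢₗσ̂ⱼₖ), Δ = ∂σ/∂θ′ the p* × q model Jacobian, and
Γ the asymptotic covariance of √(N−1)(s − σ₀), estimated from centered
fourth moments (the ADF estimator).  All three matrices share a single vech
basis (lower triangle, column-major; `semlrt.basis`).

The package computes six statistics that respond to this mixture in
different ways: the uncorrected T_ML; the mean-scaled T_M = T_ML/c with
c = tr(ÛΓ̂)/df and its Bartlett-corrected version
T_MB = T_M · (1 − (2p + 4h + 5)/(6(N−1))); the mean-and-variance adjusted
T_MV1 = (d/tr(ÛΓ̂)) T_ML referred to χ²(d), d = tr(ÛΓ̂)²/tr[(ÛΓ̂)²]; the
scale-shifted T_MV2 = T_ML √(df/tr[(ÛΓ̂)²]) + df − √(df·tr(ÛΓ̂)²/tr[(ÛΓ̂)²]);
the third-moment adjusted T_MS = (v/tr(ÛΓ̂)) T_ML referred to χ²(v),
v = tr[(ÛΓ̂)²]³/tr[(ÛΓ̂)³]²; and T_mix, which keeps the value of T_ML but
draws its p-value directly from the estimated mixture via Imhof's
characteristic-function inversion (equal weights are special-cased to the
exact scaled chi-square; a seeded 10⁶-draw Monte Carlo backs up the
quadrature).  Note T_MV2 is never negative for T_ML ≥ 0: Cauchy–Schwarz
bounds the shift term by df.

Robust RMSEA and CFI variants rescale each statistic's excess over its own
reference df so that every variant estimates the population
RMSEA₀ = √(F₀/df) and CFI₀ = (F_nm − F₀)/F_nm.  The same correction is
applied to the independence null model (its own Δ, hence its own Û).  An
algebraic consequence worth knowing: the printed CFI formulas for the
MV1/MV2/MS/mixture variants all reduce to
1 − (T_ML − tr(ÛΓ̂))/(T_nm − tr(Û_nm Γ̂)) and therefore coincide exactly with
the mean-scaled CFI; only the uncorrected and Bartlett variants differ.
The RMSEA variants do not collapse because their denominators carry the
variant-specific reference df.  The uncorrected CFI is deliberately not
floored inside the ratio (it can exceed 1 for overfitting samples); the
corrected variants are floored as printed.  A `floor_uncorrected` switch
provides the alternative reading.

## Population model

A three-factor model with p = 15 standardized indicators, 15 primary and 6
secondary loadings, factor correlations (.3, .2, .3), and
Σ₀ = ΛΦΛ′ + Θ with Θ chosen for unit marginal variances.  The correctly
specified analysis model frees all 21 loadings (q = 39, df = 81); the
misspecified one omits the secondary loadings (q = 33, df = 87); df values
are computed, never hard-coded.  Fitting the misspecified model to Σ₀ gives
F₀ = 0.328, hence RMSEA₀ = 0.061 and, against the independence null
(closed-form minimum −ln|R|), CFI₀ = 0.884.  Expected LRT power uses a
noncentral chi-square with noncentrality F₀(N−1); the (N−1) multiplier
matches the Wishart statistic (using N instead changes the third decimal
only).

## Estimation engine

L-BFGS-B with analytic gradients on the free loadings, factor correlations
(bounded in ±0.999) and residual variances (bounded below at 1e−6; an
active bound flags a Heywood case but keeps Σ(θ̂) usable for W).  Cold
restarts polish the solution until the projected-gradient infinity norm
falls below 1e−8 (up to 4 restarts, 500 iterations each); convergence also
requires that norm.  Starting values are neutral and fixed (primary
loadings 0.5, secondary 0, correlations 0.2, residuals 0.5) so fits are
bit-reproducible.  The independence model has the closed-form solution
Σ̂ = diag(S).  Γ̂ uses the N divisor (conventional ADF); S uses N − 1
(Wishart).  Mixture weights come from the symmetric form Γ̂^{1/2}ÛΓ̂^{1/2}
with eigenvalues clipped at 1e−10 of the largest (clips are logged).

## Synthetic data: sources of non-normality

Each indicator is Xᵢ = Lᵢ + Eᵢ with Cov(X) = Σ₀; the L are mutually
correlated, the E independent of everything.  Marginal kurtosis k ∈
{3, 10, 17} (Pearson convention) is targeted through quantile mixtures
F⁻¹ = Σ βₘ Fₘ⁻¹ whose component sets per condition are: latent k=3
t(4.1) + uniform; error k=3 cubic standard normal (Z³/√15) + uniform +
normal; k=10 (both) and latent k=17 lognormal(0,1) + exponential(1); error
k=17 normal + lognormal + mirrored (negative) lognormal.  Mixture moments
are computed from closed-form pure moments plus tanh-sinh quadrature for
cross terms; two-component weights are solved by bisection, larger sets by
maximum entropy subject to the kurtosis constraint (mirror-image ties
broken toward nonnegative skewness).  Fourth-cumulant additivity converts
the indicator target into the mixture target: if the non-normal part
carries variance share s, the mixture needs kurtosis 3 + (k−3)/s².

Variance split.  In error conditions E carries the residual variance Θᵢᵢ
and L = Λf is exactly the normal common part (worst-case mixture target
3 + 14/0.36² = 111.0, inside the attainable 113.9 of the pure lognormal).
In latent conditions a communality split is impossible twice over: the
smallest communality (.16) would need mixture kurtosis ≈ 550, and — more
fundamentally — indicators loading on a single factor have *perfectly
correlated* common parts while their kurtosis targets 3 + (k−3)/sᵢ² would
demand different marginal distributions, a contradiction for comonotone
variables.  Since Cov(L) = Σ₀ − diag(1−s) pins the off-diagonals, any
heterogeneous share vector pushes same-factor pairs toward that same wall;
the shares are therefore uniform, with the independent normal part carrying
t = λ_min(Σ₀)/2 ≈ 0.197 and the correlated non-normal part 1 − t ≈ 0.803
per indicator (Cov(L) = Σ₀ − tI comfortably positive definite; worst
mixture target 24.7).  With uniform shares all 15 indicators share one
mixture, so the NORTA calibration solves one intermediate-correlation curve
(96-point Gauss–Hermite + bisection, tolerance 1e−6) per condition.

Marginal conditions use Vale–Maurelli: Fleishman third-order polynomials
with intermediate correlations solved from the cubic pair equation.  The
skewness target, which the kurtosis constraint leaves free, is taken from
the latent-route mixture at
the same k, so all three sources share their first four marginal moments
(k=10: skew ≈ 1.76; k=17: skew ≈ 2.26).  k = 3 marginal is the exact
multivariate normal control via spectral factorization of Σ₀.

What the generator does and does not emulate.  The k=3 latent/error cells
are multivariate non-normal with normal-matching marginal skewness and
kurtosis.  For the latent source this shows up in fourth-order structure
(Mardia's b₂,p ≈ 251 vs the normal 255); for the error source all fourth
cumulants vanish identically — components with kurtosis exactly 3 have zero
fourth cumulant — so the non-normality lives in sixth and higher moments
and is invisible to every fourth-moment statistic.  That is the designed
reason the error-k3 cell behaves like the normal control.  Realized sample
kurtosis deserves care when validating: the error-source mixtures at k > 3
are near-lognormal with eighth-moment-driven estimator noise far exceeding
±0.5 at any desk-scale N, and t(4.1) has infinite eighth moment, so
calibration is asserted deterministically (quadrature moments within 0.1 of
target) and realized moments only at statistically meaningful tolerances.
The exact mixture weights, variance split and marginal skewness behind the
reference results are not stated; all three are parameterized here, and the
statistic most non-linear in the eigenvalue weights (T_MS) is the most
sensitive to them.

## Monte Carlo harness

Seed schedule: master seed → (source, kurtosis, N, specification,
replication, attempt) feeds `numpy.random.default_rng`, so any replication
is reconstructible in isolation and replacements never reuse a stream.
Non-convergent fits are replaced by a redraw (never restarted from new
initial values), up to 10× the replication count; replacements are counted
and logged.  Rejection uses p ≤ α with α = .05 (configurable); rates are
flagged against Bradley's liberal interval [α/2, 3α/2] = [2.5%, 7.5%].
Point estimates of RMSEA/CFI are medians across replications.
Aggregation is order-insensitive, so replications parallelize trivially.

Problem sizes.  The full 72-condition × 1000-replication grid is an
overnight run on one core (≈ 25 ms per replication including the mixture
p-value).  The shipped tests use desk-scale versions: 500 replications for
the normal-theory baseline and the N = 200 power cells, 300 for the
type-I-inflation scan, 400 for the acceptance script's power cell, and
N = 10⁶ draws for generator calibration — large enough that binomial
3-SE bands around the reference rates are decisive, small enough to run in
minutes.

## Known limitations

- No mean structures, multiple groups, missing data, or ordinal indicators;
  no parameter standard errors (the focus is the overall test).
- Γ̂ with the N divisor and the null model's Bartlett term using h = 0 are
  conventions; both choices are isolated behind one function each.
- The generator reproduces the design's *stated* conditions; because the
  underlying mixture weights are free quantities, exact agreement with the
  reference replication-level results is not expected, particularly for T_MS.
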