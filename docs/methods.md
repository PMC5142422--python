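# Methods

## Statistical model

Two raters independently classify each of n jointly observed interactions
into one of k ordered categories (default: the five QuIS categories,
ranked `+s > +c > N > -p > -r`).  The counts form a k×k contingency table
with cell proportions p_ij, row margins p_i. (rater 1) and column margins
p_.j (rater 2).  Given a symmetric agreement-weight matrix w with unit
diagonal and entries in [0, 1],

    p_o(w) = Σ_ij w_ij p_ij        observed weighted agreement
    p_e(w) = Σ_ij w_ij p_i. p_.j   agreement expected under independence
    κ̂_w   = (p_o(w) − p_e(w)) / (1 − p_e(w)).

Identity weights recover unweighted Cohen's kappa exactly.  The standard
error is the Fleiss–Cohen–Everitt large-sample formula

    SE(κ̂_w) = sqrt( Σ_ij p_i. p_.j [w_ij − (w̄_i. + w̄_.j)]² − p_e(w)² )
              / ((1 − p_e(w)) √n),

with w̄_i. = Σ_j p_.j w_ij and w̄_.j = Σ_i p_i. w_ij, and confidence
intervals are Wald: κ̂_w ± z_{α/2}·SE.  Note this is the *chance-agreement*
(null) standard error — it uses margin products rather than observed
cells — which is the convention the QuIS reliability protocol adopts for
its intervals.  A nonparametric bootstrap reproduces it to ~1% on tables
generated under rater independence, but understates the non-null sampling
SD by roughly 10% on the strongly agreeing collapsed study table; users
needing strictly non-null intervals should bootstrap.

### Weighting schemes

Formula-based schemes work for any k: identity, linear
(w_ij = 1 − |i−j|/(k−1)) and quadratic (w_ij = 1 − ((i−j)/(k−1))²).
The twelve QuIS block schemes are parameterised by
(a, b, c) = (within-positive, neutral-adjacent, within-negative) weights
with all positive↔negative weights 0:

| scheme | a | b | c |  | scheme | a | b | c |
|---|---|---|---|---|---|---|---|---|
| A1 | 1.00 | 0.50 | 1.00 | | B1 | 0.66 | 0.33 | 0.66 |
| A2 | 0.90 | 0.50 | 0.90 | | B2 | 0.50 | 0.25 | 0.50 |
| A3 | 0.80 | 0.50 | 0.80 | | B3 | 0.50 | 0.00 | 0.50 |
| A4 | 0.75 | 0.50 | 0.75 | | C1 | 0.50 | 0.25 | 0.75 |
| A5 | 0.70 | 0.50 | 0.70 | | C2 | 0.60 | 0.40 | 0.80 |
| A6 | 0.60 | 0.50 | 0.60 | | C3 | 0.66 | 0.50 | 0.83 |

A and B schemes are invariant under reversing the scale; C schemes, which
deem within-negative confusion less severe than within-positive, are not.
A useful structural identity: A1's weights are the pullback of the
3-category matrix [[1,.5,0],[.5,1,.5],[0,.5,1]] under merging the two
positive and the two negative categories, so A1 kappa equals the weighted
kappa of the merged 3-category table with that matrix, exactly.  (It does
*not* equal the merged table's unweighted kappa: the neutral-adjacent 0.5
credit survives the merge.)  Choosing a scheme *after* inspecting which
one maximises κ̂_w is explicitly discouraged; A4 is the pre-specified
default.

### Pooling over observation periods

Period m contributes κ̂_wm with estimated variance V̂_wm = SE(κ̂_wm)².

* **collapsed** — kappa of the cellwise-summed table.  Simple but risks
  confounding by period effects; reported for comparison only.
* **fixed** — inverse-variance mean, ω_m = 1/V̂_wm;
  SE = (Σω_m)^(−1/2).  Cochran's χ² = Σ ω_m (κ̂_wm − κ̂_fixed)² on g−1 df
  tests homogeneity (conventional 0.95-percentile rejection).
* **random** — DerSimonian–Laird:
  τ̂² = max(0, (χ² − (g−1)) / (Σω − Σω²/Σω)), weights 1/(V̂_wm + τ̂²).
  With τ̂² = 0 it equals the fixed estimate; as τ² → ∞ it tends to the
  simple average.  For g = 2 the estimate provably lies between those two
  extremes; for g ≥ 3 it is not guaranteed to (the path from fixed to
  average weighting need not stay inside the interval), though it does in
  study-like configurations — the tests check exactly these statements.
* **averaged** — Σκ̂_wm / g with SE = sqrt(ΣV̂_wm / g²).  Over-weights
  sparse periods, which empirically tend to show the highest agreement,
  so it biases reliability upward; reported for comparison.

REML and Hartung–Knapp τ² variants are deliberately out of scope; DL is
the estimator the protocol specifies.

## Synthetic studies

`simulate_study` realises the random-effects model directly: per period,
δ_m ~ N(0, τ²), λ_m = clip(κ_mean + δ_m, 0, 1), and the joint rating
distribution is the mixture

    P_m = λ_m · diag(π) + (1 − λ_m) · ππᵀ,

from which n_m cell counts are drawn multinomially.  The family is our
construction (no generative form is prescribed by the protocol); it is
chosen because both margins equal π and the population weighted kappa of
P_m equals λ_m for *every* unit-diagonal scheme, giving closed-form
ground truth that favours no scheme.  Defaults mirror the motivating
study: g = 18, n_m = 20, κ_mean = 0.6, τ = 0.1, and π equal to the
study's rater-1 margins (0.167, 0.568, 0.198, 0.040, 0.028).

What the generator does **not** emulate: negative true kappa (λ is
clipped to [0, 1]), rater-specific marginal bias (both raters share π),
interactions missed by one rater, and shared raters across periods
(periods are independent).  Passing parameter-recovery tests therefore
demonstrates correctness of the estimators under multinomial sampling
with between-period variation — not robustness to those real-data
features.

Seeding: one master seed spawns per-period child streams, so enlarging g
appends periods without reshuffling existing ones, and identical
configurations reproduce studies bit-for-bit.

## Numerical and design choices

* Unused categories are retained in every period table (zero margins
  contribute zero to p_e(w)); collapsing categories per period would make
  chance correction inconsistent across periods.
* p_e(w) = 1 (e.g. a single interaction, or all mass in weight-1 cells)
  raises an explicit degenerate-agreement error instead of returning NaN.
* Periods with undefined kappa or zero estimated variance are excluded
  from inverse-variance pooling with a logged warning, but still enter
  the collapsed table; fixed/random pooling refuses with fewer than two
  usable periods.
* Wald limits are clipped to [−1, 1] for display; raw limits are kept on
  the estimate object.
* Display rounding is 2 dp, halves away from zero; machine-precision
  values accompany every display field in JSON reports, and full pipeline
  output is byte-deterministic for fixed inputs and flags.
* The SE's variance term is clamped at 0 against ~1e−17 round-off on
  exactly-degenerate tables; oracle-equivalence tests assert 1e−12
  agreement with direct summation.
* τ̂² truncation at 0 is always logged, since it silently turns a
  random-effects request into a fixed-effects answer.

## Problem sizes in the test suite

Fuzz comparisons against the brute-force oracle use 1000 random tables
(k = 5, n ≤ 50); bootstrap cross-checks use 10,000 resamples; parameter
recovery uses 500 replicate studies at the default study conditions,
where the mean random-effects pooled estimate recovers κ_mean = 0.6
within 0.02 (a small negative bias remains, as expected when estimated
variances enter the weights at n_m ≈ 20).

## Known limitations

* The chance-agreement SE (see above) understates non-null sampling
  variability; intervals inherit the protocol's convention.
* Weighted kappa remains sensitive to marginal imbalance: strongly
  skewed margins depress p_e-corrected agreement regardless of scheme.
* No modelling of correlation induced by raters appearing in multiple
  periods; the random-effects variance absorbs some, not all, of it.
* The simple-average SE treats the per-period variances as known, like
  the other inverse-variance formulas.
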