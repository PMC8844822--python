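# Methods

## Scope and units

The package analyses steady-state kinetics of multifunctional NAD(P)
glycohydrolases: enzymes following an ordered Uni-Bi mechanism in which the
pyridine base (nicotinamide-type) leaves first and the ADP-ribosyl
intermediate is then resolved by water (hydrolysis), intramolecular attack
(cyclization) or a free pyridine base (base exchange). Units are fixed
package-wide — substrate/inhibitor/effector concentrations in μM, specific
rates in mU per mg total protein (1 U = 1 μmol/min), turnover `kcat` in s⁻¹,
efficiency `kcat/Km` in M⁻¹ s⁻¹ — matching how such constants are tabulated
in practice.

## Rate laws and unbounded constants

Five closed-form laws are implemented (see README for the formulas): the
hyperbola, one- and two-site substrate inhibition, the one-site IC50 law,
and multi-site mixed inhibition with stoichiometry `n ≥ 1`. Substrate
inhibition constants may be *unbounded*: internally `math.inf`, so the term
they govern is exactly 1 in IEEE arithmetic and each law collapses exactly
to its simpler limit. Serialized records simply omit the key. Fitted
constants are censored as "> 8000 μM" when the estimate reaches 8000 μM or
when a profile-likelihood scan places the 95% lower bound above the largest
tested substrate concentration — large point values from runaway fits are
never reported as if they were measurements, because they destabilize any
downstream arithmetic.

## Curve maxima

For one finite inhibition constant the substrate optimum has the closed form
`S_opt = √(Km·K)` (with `V_opt = Vmax/(1 + 2√(Km/Kis))` in the
catalytic-site case). With both constants finite the unique interior maximum
is located numerically: a 512-point log grid over 10⁻²–10⁶ μM brackets it,
golden-section search on log S refines it; numeric and closed-form answers
agree to 10⁻⁶ relative where both exist.

## Fitting

Estimation is unweighted least squares on untransformed rates
(`scipy.optimize.least_squares`, trust-region reflective), parameterized in
log10 space to enforce positivity. Initial guesses are data-driven: Vmax₀ is
the maximal observed rate (doubled for substrate-inhibited laws, whose
observed maximum underestimates the asymptote), Km₀ the substrate at
half-maximal rate, inhibition constants start at the largest tested S, `a₀ =
n₀ = 1`, Ki₀ at the median tested inhibitor level. A deterministic multistart
varies Km and each inhibition constant over {0.3×, 1×, 3×}, plus one
far-out start (10⁸ μM) for each substrate-inhibition constant so the
optimizer can reach reduced-model solutions; best RSS wins, ties to the
first start. Standard errors come from the Jacobian at the solution by the
delta method. Model choice among the three substrate laws uses AICc with a
"simpler wins within ΔAICc < 2" rule. `n` is allowed non-integer within
[1, 8] during fitting and flagged when pinned to a bound.

### Identifiability of the dual-site law

A single substrate-inhibition curve cannot attribute the inhibition to a
site: when only one constant is finite the dual-site law is exactly
degenerate between two representations,

    Vmax·S / ((Km+S)(1+S/Kia))  ≡  Vmax'·S / (Km' + S(1+S/Kis'))

with `Kis' = Km + Kia`, `Km' = Km·Kia/(Km+Kia)`, `Vmax' = Vmax·Kia/(Km+Kia)`.
The optimizer can land in either minimum. When a fit censors the allosteric
constant but the fitted catalytic form has a real allosteric twin (which
exists iff `Kis' > 4·Km'`), the estimate is re-expressed in the allosteric
canonical form — the allosteric site is the reason the dual-site law is
fitted at all, and site attribution properly comes from orthogonal evidence
(effector titrations, truncation constructs). Genuinely catalytic-site
inhibited data (Kis below ~4 Km, as in the NADP datasets here) have no twin
and are never re-attributed. This convention is what makes the recovery
simulations well-posed.

### Inhibition classification and competition analysis

Mixed-inhibition fits classify from the multiplier: competitive when `a` is
censored at its upper bound, noncompetitive when `a ∈ [0.8, 1.25]` and
`n ∈ [0.9, 1.1]`, mixed otherwise — numeric tolerances for the verbal rule
(a = ∞ / a = 1 / else). Lineweaver–Burk slope/intercept replots versus
inhibitor are flagged nonlinear when a quadratic term significantly improves
the straight line (F-test, p < 0.05) — the signature of multi-site binding;
the double-reciprocal diagnostic additionally tests a 1/x augmentation,
which is how substrate inhibition bends these plots. The effector
(NMN-type) titration analysis fits the dual-site law per level, regresses
apparent `Kia` and the curve maxima on effector concentration, and returns
"competitive-allosteric" only for a significantly positive `Kia` slope
(two-sided OLS t-test, p < 0.05) together with monotone nondecreasing
maxima; a censored `Kia` at any level, or no trend, yields "non-allosteric".
These thresholds make the published verbal argument a deterministic rule.

## Activity accounting

Initial-rate windows are the longest prefix of a progress curve with
cumulative substrate consumption ≤ 20% of S0 (configurable) and total
products still linear in time (OLS R² ≥ 0.98 by default; the linearity
statistic is our proxy for "nearly linear"). Rates are unweighted OLS slopes
with free intercepts. Specific activity counts total products formed
(μM/min ÷ μg/mL × 1000 → mU/mg). Mass balance compares substrate consumed,
summed products and released base pointwise at a default 5% relative
tolerance (the matching is asserted qualitatively in the source protocol;
the tolerance is ours and configurable). Internal-standard normalization
divides by the recovery of spiked cAMP and by protein mass, with a 0.5
recovery floor as an arbitrary QC guard (observed recoveries are ≥ 0.96).
Temperature/pH profiles are handled only as empirical curves normalized to
their maxima. Immunoblot quantification uses a free-intercept standard line
with inverse prediction, flagging extrapolation beyond the standard range.

## Synthetic data

The generators define the study conditions. Initial-rate datasets default to
12 log-spaced substrate points over 15–4000 μM (8 points over 15–600 μM for
mixed-inhibition grids, where substrate inhibition is negligible), inhibitor
levels 10–300 μM for dose-response and 0/25/50/80/120 μM for grids, and a
single multiplicative mean-one Gaussian noise term with CV 0.05 (0.03 for
fractional-activity series), truncated at zero. The CV is not reported by
the source assays; 0.05 gives scatter comparable to published replicate
error bars and is configurable. Replicate structure (within- vs
between-preparation) is not modeled.

Progress curves integrate `dS/dt = −v(S)` (RK45, tolerances two orders
tighter than the 10⁻⁶ conservation contract), with the specific rate
converted through the assay protein concentration. Branch fractions are
configured constants independent of S, matching the observation that
substrate level does not change product proportions; free bases do not
compete with one another. Products are allocated analytically from
cumulative consumption, so conservation is exact by construction; exchange
products are capped by the supplied free base, and on exhaustion the branch
flow is renormalized over the remaining branches (entirely to hydrolysis if
none remains — water is always available as acceptor), with the event
logged.

The full-length construct's molar mass (80.4 kg/mol) is derived from the
724-residue human SARM1 sequence (~79.4 kDa) plus a C-terminal FLAG
octapeptide; with the crude Vmax of 22.4 mU/mg this gives kcat ≈ 0.030 s⁻¹.

## Problem sizes and determinism

Recovery simulations use 100 seeded datasets per experiment in the
acceptance script (40 in the routine test suite), with medians as the
recovery statistic; all randomness flows from `numpy.random.default_rng`
seeded per dataset, so every dataset, fixture and report is bit-reproducible
from its recorded seed. The fixture suite regenerates byte-identically from
its manifest.

## What passing tests do and do not show

The synthetic generator draws from the same law families that are fitted,
with independent multiplicative noise. Passing recovery tests therefore
demonstrates correctness of the estimation machinery and identifiability
under the stated designs — not robustness to the features real HPLC data
add: correlated replicate structure, peak-integration bias,
retention-time misassignment, substrate depletion during "initial" rates, or
model misspecification. Mass-balance and linearity screens will catch gross
versions of such problems but are not a substitute for assay-level QC.

## Known limitations

- Site attribution in the dual-site law is conventional when only one
  constant is identifiable (see above); only orthogonal experiments can
  decide it.
- The empirical NAD optimum of the full-length enzyme is reported near 0.25
  mM in the source, while the fitted constants place the model optimum near
  99 μM; the package follows the fitted constants and does not reconcile the
  discrepancy.
- No global multi-curve fitting across effector levels (each level is fit
  independently, as in the reference analysis) and no Bayesian inference.
- Secondary-replot nonlinearity and trend verdicts use fixed frequentist
  thresholds (p < 0.05) on few points; they are classification conventions,
  not hypothesis tests with controlled error rates.
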