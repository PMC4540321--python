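# Methods

This note documents the models, conventions and numerical choices behind
`treeholes`, and what the synthetic-data experiments do and do not show.

## Allometric biomass

Counts arrive binned into length classes (mm). The representative length of
a class is its arithmetic midpoint — unbiased if lengths are uniform within
a class; an open-ended first class ("< 0.25 mm") is encoded with lower edge
0, so its representative length is half the upper edge. Four dry-weight
models are supported, with every constant living in configuration rather
than code so published constants can be swapped:

* **Volumetric (nematodes).** Wet weight (µg) = W²·L/1.6×10⁶ with W, L in
  µm. The divisor is treated as already embodying the specific gravity of
  1.13 g cm⁻³ used in the classical volumetric nematode formula; dry weight
  multiplies by a dry/wet ratio (default 0.25). Transverse width is derived
  from length by a configurable `width_ratio`.
* **Box volume (rotifers, tardigrades).** Wet volume 0.8·L·W·H µm³
  converted at unit density (10⁻⁶ µg/µm³), times the dry/wet ratio;
  `width_ratio` and `height_ratio` derive W and H from L.
* **Power law (most insect larvae).** DW = a·Lᵇ (mg, L in mm). Constants
  for *Myathropa* are the values obtained by drying measured larvae
  (a = 0.0024, b = 3.0651); other taxa carry representative family-level
  constants that users should replace with their own fits. `fit_power_law`
  performs the standard OLS on log₁₀–log₁₀ axes and reports (a, b, R²).
* **Exponential (*Culex*).** DW = coef·e^(rate·L) with printed defaults
  coef = 4.4×10³ and rate = 0.8. The coefficient's scale is implausible for
  µg at small lengths (it makes *Culex* dominate biomass in any simulation
  that includes it); it is kept as printed, configurable, and users fitting
  real data should check the source scale (possibly 4.4×10⁻³ mg).

Biomass per cup is Σ_classes count × per-individual DW, with all outputs in
µg; areal normalization multiplies by 100/71 (the cup bottom area in cm² is
the only area the survey design defines). Biomass is additive over taxa and
zero exactly when no individuals are present.

## Secondary production

Annual production per taxon uses the Plante–Downing multiple regression,

log₁₀ P = 0.06 + 0.79 log₁₀ B − 0.16 log₁₀ M_max + c_T · T,

with P, B in g m⁻² dry weight, M_max in mg and T in °C. The temperature
coefficient defaults to c_T = 0.05 — the value of the source regression;
the alternative 0.5 sometimes quoted is a typographical corruption that
inflates production ~10⁵-fold per 10 °C and can be restored explicitly via
the argument if desired. Logs are base 10 throughout. M_max is computed
from the data as the per-individual DW at the largest size class the taxon
occupies anywhere in the dataset, not hard-coded. Carbon conversion uses a
standard 0.5 g C per g DW, configurable and always carried in the output.
B = 0 short-circuits to P = 0. Percentage shares are relative to total
community dry-weight production and sum to 100% whenever the total is
positive.

## Community metrics

Percentages of meiofauna vs macrofauna are means of per-cup percentages
over occupied cups (so they always sum to 100); dominance ratios are formed
from group means, reported in larger:1 form together with which group
dominates — group-mean vs per-cup bases can disagree wildly in such skewed
data, so the basis is fixed and documented. Occupancy is the percentage of
cups with at least one individual. Areal conversion is exact power-of-10
(and cup-area) arithmetic and therefore invertible; mass and count
dimensions are never interconverted.

The Kruskal–Wallis test uses mid-ranks and the tie-corrected H. With
pooled n ≤ 8 (default threshold) the p-value is computed by exhaustive
enumeration of all assignments of the pooled observations to the group
sizes; otherwise the χ²(k−1) approximation is used, matching the standard
implementation. The χ² approximation is coarse at enumeration-scale n: over
all two-group splits of 8 distinct values the χ² and exact p differ by up
to ≈ 0.24, which is why the exact path exists. P-values are reported
unadjusted; a Holm adjustment is deliberately not applied by default.

## Ordination

**Model gate.** Correspondence-analysis total inertia (χ²/N of the count
matrix) measures gradient length; detrending leaves total inertia
unchanged, so no detrending is implemented. Inertia < 2.6 recommends the
linear model (RDA); zero-sum rows/columns are dropped with a log notice.

**RDA.** The response is log₁₀(x+1)-transformed areal abundances. Species
columns are centered (not standardized) and the matrix is scaled globally
so total variance is 1; predictors are standardized. Fitted values from the
multivariate least-squares regression of Y on X are decomposed by SVD; the
squared singular values are the canonical eigenvalues, directly fractions
of total community variance, and their sum is the constrained R². Site
(WA) scores project the observed Y onto the axes, lc scores project the
fitted values, and the species–environment correlation per axis is the
correlation of the two (non-negative by construction). Axis signs follow a
deterministic convention: the species with the largest |loading| on each
axis scores positive. Rank-deficient predictor sets are rejected with the
offending columns named. Cups with any missing regarded predictor are
excluded listwise (and logged) before ordination; nothing is imputed.

**Forward selection.** At each step every remaining candidate's increment
in constrained variance given the selected set is evaluated via a QR
projection; the largest increment enters (ties broken by input column
order, deterministically). All variables are ranked and reported regardless
of significance; α (default 0.05) only annotates the table. Conditional λ
values telescope to the full-model constrained variance by construction
(asserted to 1e-9 in tests).

**Permutation tests.** The entering candidate is tested with a pseudo-F:
added variance over residual variance, each on its degrees of freedom.
Rows of the response residualized on the conditioning predictors are
permuted without restriction (reduced-model permutation — the conservative
standard choice when the permutation scheme is otherwise unspecified), and
p = (1 + #{F* ≥ F})/(n_perm + 1), so p has floor 1/(n_perm+1) — 0.001 at
the default 999 permutations — and ceiling 1. A single integer seed
determines every stream; forward selection derives independent per-(step,
variable) substreams from it.

## Synthetic surveys

The generator emulates the survey design: four site labels (two areas × two
forest ages), 15 trees each, 5 cups per tree, five sampling dates with one
cup harvested per tree per date (300 cups), and uniform random cup loss to
a survival rate of 264/300. Environmental variables are drawn from
date-specific normal distributions (cold/dry spring, warm/wet summers,
frozen late winter), truncated at zero where physically required. Counts
per taxon are negative-binomial with ln-mean linear in the standardized
predictors; the rotifer dispersion (k = 1/16) reproduces the SD ≈ 4× mean
overdispersion seen in such surveys, and baselines are set so realized mean
densities match field magnitudes (rotifers ≈ 1.9×10⁵ ind per 100 cm²) —
the −Σc²/2 correction on the baseline removes the mean inflation the
coefficients would otherwise cause. Individuals are allocated to size
classes multinomially with probabilities from the truncated lognormal
length distribution evaluated at the class edges — distributionally
identical to drawing each individual's length and binning it with the same
midpoint convention used downstream, but feasible at 10⁵ individuals per
cup.

What the generator does *not* emulate: within-tree correlation (cups are
exchangeable within site × date), structured cup loss, population dynamics
or species interactions, and the thin upper tail of field abundances — a
negative-binomial with SD = 4× mean necessarily produces occasional counts
one to two orders of magnitude above the field maximum. Passing
calibration and recovery tests therefore demonstrate the statistical
operating characteristics of the methods under the assumed sampling model,
not agreement with any particular field dataset.

`inject_effect` returns a config differing in exactly one taxon × variable
coefficient. The default injected effect size is 3.5 ln-units per SD of the
predictor (~30-fold response across ±1 SD, within the four orders of
magnitude spanned by field rotifer densities). It is deliberately a
*clearly detectable* effect: the recovery experiments (driver ranked first
in ≥ 95% of surveys; detection power ≥ 0.9 at n = 264) define the operating
point the default must sit at, and smaller coefficients disappear into the
prescribed rotifer overdispersion.

## Problem sizes in tests and the acceptance script

Calibration simulations use a reduced two-date, 40-cup design with five
taxa and 199 permutations per test (the nominal α = 0.05 is exactly
attainable at 199 and 999 permutations, since 10/200 = 0.05); the type-I
experiment runs 1,000 null surveys, the recovery experiment 100 full-size
(264-cup) surveys with 99 permutations per entering variable. These sizes
keep Monte Carlo error well below the asserted bands (binomial SE ≈ 0.007
at p = 0.05, n = 1000).

## Known limitations

* Power-law constants for taxa other than *Myathropa* are representative
  values, not refits of the original specimens.
* The exponential (*Culex*) coefficient is kept at its printed scale; see
  above.
* The RDA implements the linear branch only (no CCA); partial ordination
  exists only in the form forward selection needs (residualizing on
  selected predictors).
* Kruskal–Wallis p-values at 3 < n ≤ 8 are exact but the χ² path should
  not be trusted at such sizes; the default `exact_threshold = 8` guards
  this.
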