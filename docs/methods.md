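# Methods

## Data model and units

A feed is its Weende proximate composition (CP, CF, NFE, EE, each % of
dry matter, non-negative, organic total ≤ 100), optionally the four
digestible nutrient fractions (% DM, each ≤ its crude fraction, present
all-or-none), and an observed DE (kcal/kg DM, > 0). All energies are
kcal/kg DM; the factor 10 converting kcal/100 g to kcal/kg lives inside
the energy functions only. A kcal→MJ helper (1 kcal = 4.184 kJ) exists
for reporting and is never on the computation path.

The packaged reference dataset has 32 feeds (24 forage-plus-concentrate
mixed diets, 8 compound feeds) compiled from six published digestion
trials; 24 records carry digestible fractions. One cell in the source
table prints a decimal comma ("0,5"); it is stored as 0.5. The eight
records whose digestible nutrients the sources did not report are
modeled as a single absent value, never as zeros — zeros would corrupt
every digestibility statistic. The DE columns the compilation printed
for the two equations ride along as reference metadata; the pipeline
always recomputes predictions from the published coefficients. That
choice is forced by the data: the printed prediction cells of the
second equation for rows 19–32 deviate 1.8–3.1% from its own published
coefficients, while the compilation's aggregate statistics match the
recomputed predictions (see "Known discrepancies").

## Energy arithmetic

Gross energy is summative over the crude fractions with heats of
combustion 5.71 (protein), 9.51 (fat), 4.80 (fiber) and 4.18 (NFE)
kcal/g; observed DE uses the same coefficients over the digestible
fractions. Predictions are linear in the four proximate percentages.
Compositions outside the widest published development ranges of the two
equations (CP 2.7–70.3, CF 0–53.3, NFE 14.2–89.1, EE 0.1–44.7 % DM)
trigger an `ExtrapolationWarning`, never an error: the equations remain
defined there, the user is merely told the prediction is an
extrapolation.

## Statistics

* Residuals are observed − predicted, so a positive residual is an
  under-prediction; with this convention the residual–fiber correlation
  comes out negative (fiber-rich feeds are over-valued).
* CCC and the MSEP decomposition use population (divide-by-n) moments so
  that ECT + ER + ED = MSEP = RMSEP² is an exact identity (verified
  against a brute-force Σ(o−p)²/n oracle in the tests). The
  decomposition is the central-tendency / linear (regression) / random
  variant: ECT = (P̄−Ō)², ER = (s_P − r·s_O)², ED = (1−r²)s_O².
* Dataset description and the observed-DE bands use the sample (n−1) SD,
  the convention of descriptive statistics (the reference dataset's
  mean ± SD is 2600 ± 492 kcal/kg DM on that convention).
* Bias: OLS of residuals on centered predictions; because the regressor
  is centered, the intercept equals the mean residual (mean bias) and
  the slope is the linear bias. Classical SEs, two-sided t tests with
  n − 2 df, no multiple-testing correction, significance at p < 0.05.
  Fitting is delegated to statsmodels; Pearson correlations and their
  p-values to scipy.
* When MSEP is exactly zero the percentage shares are undefined and
  reported as `None` rather than NaN.
* Reported rounding follows the source compilation's print precision
  (kcal to integers, dimensionless statistics to 2 decimals); full
  precision is kept internally.

Degenerate inputs fail loudly: zero-variance vectors are a `ValueError`
in `pearson`, `ccc` (both series constant) and `bias_regression`
(constant predictions); series shorter than 3 (4 for the bias
regression) are rejected.

## Synthetic generator

`generate_feeds` samples CP, CF and EE uniformly over the reference
dataset's ranges (6.3–21.6, 3.5–31.9, 2.0–5.3 % DM) and sets NFE so the
organic-matter total lands uniformly in 88–96 % DM — typical ash
contents leave that much organic matter in mixed horse feeds. Apparent
digestibility coefficients are linear in fiber,
`base − slope·(CF − CF_min)` plus Gaussian noise (SD 0.03), clamped to
[0, 1]; defaults (base, slope per % DM CF): protein 0.80/0.008, fiber
0.30/−0.004, NFE 0.85/0.010, fat 0.60/0.015. These were chosen once so
that the generated data reproduce the reference dataset's qualitative
structure — observed DE correlating strongly negatively with fiber,
positively with protein, digestibility of fiber itself slightly
*rising* with fiber level as the reference data show. Digestible
fractions are coefficient × crude fraction and observed DE is their
summative energy value, so every generated record satisfies the data
model's invariants by construction.

`generate_biased_predictions` returns
`p = o − a − b·(o − ō) + N(0, σ)`, injecting a known mean bias `a` and
observed-scale linear bias `b`. Because the regression in the suite is
on *centered predictions*, the recovered slope is not `b` itself but the
projection coefficient `(b(1−b)·var(o) − σ²) / ((1−b)²·var(o) + σ²)`;
the recovery tests assert against that closed form within two standard
errors. Each generate call draws from its own stream derived from
(seed, call-tag), so regeneration is all-or-nothing and seeds cannot be
silently reused across calls.

The generator is a statistical emulator, not a digestion model: it has
no associative effects between ingredients, no processing or
particle-size effects, no study-level grouping, and its
digestibility-vs-fiber relation is linear by fiat. Tests passing on
synthetic data therefore demonstrate that the statistics recover known
structure, not that the equations are biologically right.

## Known discrepancies in the source material

Recomputation from the printed 32-feed table cannot reproduce a few of
the published numbers; the package reports these quantities as computed
rather than forcing agreement:

* the printed prediction cells of the second (zk) equation for rows
  19–32 (see above);
* the published fiber-vs-digestible-nutrient correlations
  (−0.91/−0.83/−0.87 for DCP/DNFE/DEE, n = 24): the printed fractions
  give −0.76/−0.61/−0.67 — same signs and significance, weaker
  magnitudes. Likely computed from unrounded per-trial digestibility
  data that the compilation does not print;
* the published correlation (> 0.91) of predicted energy digestibility
  with observed OM digestibility: printed data give ≈ 0.83;
* the 6/8/18 membership split of the observed-DE bands at mean ± 1 SD:
  the printed observed-DE column gives 4 below, 21 within, 7 above. The
  band-conditional error means are therefore reported as computed and
  never asserted against the published ones.

Two acceptance tests assert the published versions of the first two
items anyway, as faithful checks of the source values, and fail; their
docstrings say why.

## Problem sizes

Everything is closed-form desk-scale statistics on n = 32 (the full
pipeline runs in well under a second). Property-based tests use up to
150 generated series of length ≤ 40; parameter-recovery checks use one
synthetic dataset of n = 500.

## Limitations

The evaluation pools all 32 feeds with no study-level random effects,
matching the source analysis; DE values derived by different routes
(nutrient-wise vs GE × digestibility) are treated as one population.
The package evaluates fixed published equations — it deliberately
contains no refitting machinery.
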