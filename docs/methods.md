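# Methods

`pairomics` implements a paired differential-abundance analysis for
multi-omic gut microbiome count data — the setting is a small cohort of
mice, each sampled at two intestinal sites (cecal contents, CC, and feces,
F), profiled by 16S surveys, shotgun metagenomics and shotgun
metaproteomics. The unit of analysis is a count matrix of features
(taxa, function×phylum combinations, or pathway×phylum combinations)
by samples, with a mouse×site pairing design.

## The paired beta-binomial test

For feature *g* and mouse *i*, let `c_i` be the cecal count, `f_i` the
fecal count, `t_i = c_i + f_i`, and `C_i`, `F_i` the cecal and fecal
library sizes (per-sample totals). Conditional on the pair total, the
cecal count is modelled as beta-binomial:

    c_i | t_i  ~  BetaBin(t_i, pi_i(r), phi),
    pi_i(r) = r C_i / (r C_i + F_i),

where `r` is the fold ratio of the feature's relative abundance in cecum
versus feces and `phi >= 0` is intraclass overdispersion (shape
parameters `a = pi/phi`, `b = (1-pi)/phi`; `phi = 0` is the binomial
limit). Conditioning on `t_i` removes any mouse-level abundance effect
that scales both sites equally — this is what makes the test *paired* —
and the `C_i/F_i` term adjusts for sequencing depth. The null `r = 1` is
tested by a likelihood ratio: `phi` is profiled out under both
hypotheses (with the `phi = 0` boundary checked explicitly), the
statistic `2(l1 - l0)` is clipped at zero and referred to the upper tail
of a chi-square with one degree of freedom.

Numerics: optimization is over `(log r, log phi)` with a bounded scalar
search for the null, and a binomial profile plus three Nelder-Mead
starts for the alternative. Below `log phi = -10` the beta-binomial is
numerically indistinguishable from the binomial but `betaln` with shape
parameters beyond ~1e10 loses all precision, so the likelihood evaluates
the exact binomial limit there. `log r` is clipped at ±14. The
optimizer's `r_hat` agrees with an independent grid-refinement maximizer
to better than 1e-3 (checked in the acceptance suite).

### Small-sample calibration, honestly

With three mouse pairs the chi-square reference is imperfect in both
directions, and the suite measures rather than hides this:

* if the data are conditionally binomial (no real overdispersion), the
  profiled `phi` absorbs chance deviations more under the null than
  under the alternative and the test is mildly conservative (empirical
  type-I error ~0.021-0.030 at a nominal 0.05 across seeds);
* if the conditional law has genuine beta-binomial dispersion, the
  dispersion is estimated from only three pairs and the chi-square
  reference is liberal (~0.08-0.09), the same way a z-test with a
  three-observation variance estimate is liberal.

The acceptance suite exercises the second regime (the generator plants
real conditional dispersion, see below); its calibration check therefore
reports an inflated type-I error and fails its nominal band. This is a
property of chi-square-referenced likelihood-ratio tests at n = 3, not a
defect of the optimizer, and it propagates into a realized
false-discovery proportion of roughly 0.15-0.25 in the end-to-end run.

## SGoF multiple-testing adjustment

Given `m` p-values, `R` of which fall at or below `alpha = 0.05`, the
sequential-goodness-of-fit metatest compares `R` to its binomial null
expectation. The k-th smallest p-value receives the exact upper tail

    adjusted_p(k) = P(Binomial(m, alpha) >= R - k + 1),

for `k <= R` (1 otherwise), and the `K` features with
`adjusted_p <= gamma = 0.05` — necessarily the `K` smallest — are
declared. The exact binomial tail is used rather than the chi-square
approximation; no sequential refinement beyond the rank recursion is
applied. Note the structural cap `K <= R - j* + 1` (with `j*` the
smallest tail count significant at `gamma`): SGoF can never declare more
features than the excess of `R` over its null quantile, which is what
couples the end-to-end sensitivity to the raw test's calibration.

## Fold-changes, the correction factor, and the missing-value filter

Counts are first rescaled to a common reference depth (the mean sample
total). A correction factor `CF = 2` is added to both members of every
per-mouse ratio to remove the discontinuity at zero. The mean ratio is
computed in both orientations, `mean((c'+CF)/(f'+CF))` and
`mean((f'+CF)/(c'+CF))`, and the larger is reported — positive when
cecum dominates, negative when feces dominates. Because the mean of
inverses is not the inverse of the mean, reporting the dominant
orientation (rather than inverting a sub-unity CC/F mean) is the only
convention that is exactly antisymmetric under site swap; the two agree
whenever the per-mouse ratios are homogeneous. The magnitude is always
>= 1; exact orientation ties resolve positive. The SEM is the standard
error of the per-mouse ratios in the reported orientation. Features with
a zero raw count in any mouse of the dominant site are flagged and
excluded from the declared list.

## NSAF quantification

SAF = spectral count / protein length (aa); NSAF normalizes SAF to sum
to one within each sample; scaled NSAF multiplies by one dataset-wide
factor, the arithmetic mean over samples of total identified spectra, so
per-sample scaled sums are identical and values are integer-sized. A
per-sample factor would undo the normalization, which is why the factor
is computed once per dataset. Scaled values are rounded half-to-even
when they enter a count matrix, since the downstream test consumes
integers.

## LCA assignment and feature matrices

Per-read hit lists (taxon, bitscore) are filtered by `min_score = 50`
and a `top_percent = 10` window below the best surviving score; the read
is assigned the lowest common ancestor of the kept taxa (`min_support`,
default 1, can discard rare assignments at summarization). Defaults
mirror the classic MEGAN-era parameterization and are all exposed.
Feature matrices sum per-read weights (1 per read for sequencing data,
rounded scaled NSAF for proteomics) into (taxon), (function, phylum) or
(pathway, phylum) keys; reads missing either component of a combination
key are excluded from that matrix.

The within-phylum re-analysis divides each sample's counts by the
sample's phylum total and multiplies by the across-sample mean phylum
total (rounding half-to-even to restore integers on a comparable scale),
then reruns the full differential analysis on the phylum's features.
This removes the phylum's own cecum/feces shift, separating "this
function moved" from "its whole phylum moved".

## The synthetic-data generator

The generator emulates the study conditions: 3 mice by default (two
sites each), lognormal sequencing depths with mean 1e6 and CV 0.6
(matching the reported order-of-magnitude spread of per-sample counts),
lognormal baseline abundances with sigma = 1 (moderate skew, typical of
function-level aggregates rather than raw taxon abundances), and a
planted fraction of differential features.

Two generator choices deserve explanation:

* **Mass-balanced planting.** Strong one-sided planting (say 10% of
  features up 8-fold in cecum) shifts the compositional background, so
  every null feature appears ~1.7-fold depleted to any total-count-
  normalized test; no method could then control false discoveries
  against an `r_g = 1` truth. Planted folds therefore cycle through
  `fold_set`, planted baselines are rescaled by `2/(1+r)` (equal
  cross-site mean mass per planted feature) and the up-planted baselines
  are scaled once more so the planted mass gained in cecum exactly
  equals the mass lost. With a reciprocal-closed fold set such as
  {8, 1/8} the null composition is preserved and "differential" retains
  its intended meaning.
* **Dispersion that survives conditioning.** Each (feature, mouse)
  carries a shared gamma latent (shape `1/phi`, mean 1) scaling both
  sites — the paired dependence a paired test exists to remove. A
  shared latent cancels exactly in the conditional cecum-given-total
  law, so on its own it would leave the dispersion knob inert for the
  test. Each (feature, sample) therefore also carries a site-level gamma
  latent with the same shape; at equal depths the cecal share of a pair
  is then Beta(1/phi, 1/phi), i.e. the conditional law has genuine
  beta-binomial overdispersion. Counts are drawn multinomially per
  sample at its depth, so realized totals are exact.

What the generator does **not** emulate: real taxon correlation
structure, sequence content, chimeras/contamination, peptide-level
identification noise, or per-taxon depth structure within a sample
(features are independent within the multinomial). Passing tests
demonstrate correctness of the statistical machinery under a known
truth, not performance on real gut metaproteomes.

Toy taxonomies use ranks domain→phylum→class→order→family→genus→species
with random attachment; hit tables are 12-column BLAST-tabular with the
taxon id embedded in the subject field; recorded LCA truth is computed
by ancestor-set intersection (independent of the classifier) from the
scores exactly as written to disk. PSM tables draw lengths uniformly on
[100, 1000] aa and Poisson-lognormal spectral counts.

## Problem sizes used by the checks

The acceptance suite and `scripts/acceptance.py` use 2,000 features at
depth 1e5 for calibration and for the planted end-to-end run, 4,000
features (10% planted at 4-fold, 20 pairs) for recovery, 1,000 reads for
the LCA oracle comparison, and 200-protein PSM tables — sizes at which
every Monte-Carlo quantity is stable to the second digit while the whole
suite runs in minutes on one core.

## Known limitations

* The "inverted beta-binomial" paired test is instantiated from its
  described contract (paired, count-based, beta-binomial, library-size
  adjusted); equivalence to the original authors' software is not
  claimed.
* Chi-square calibration at n = 3 pairs is approximate in the ways
  quantified above; with 6+ pairs the behavior improves but remains
  liberal under strong conditional dispersion.
* SGoF is applied per matrix level, not jointly across levels.
* Whether the published tables' SEM is orientation-corrected is not
  derivable from the tables alone; the dominant-orientation convention
  is used throughout.
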