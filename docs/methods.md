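# Methods

## Scope and model

The package re-implements, as a tested pipeline over synthetic cohorts, a
tumor-expression analysis that links GSK-3 expression to an inverse
correlation between androgen-receptor (AR) and NF-kB transcriptional
programs, and asks whether the "AR-repressed NF-kB target" genes carry
prognostic information. The stages are: outlier-chip QC, reference-based
Z-score signature scoring, tumor stratification, running-sum gene-set
enrichment with a phenotype-permutation null, derivation of the repressed
target set from the negative leading edge, and Kaplan-Meier / log-rank
survival analysis of groups defined by that set.

Real accession-based cohorts are out of scope; every stage is exercised on
a generator that emulates the statistical structure the analysis assumes.

## Synthetic cohort generator

For gene g and sample s, on the normalized log2 scale:

    x_gs = mu_g + beta * (a_s * [g in AR program] + b_s * [g in NF-kB program])
           + kappa * a_s * [g in {GSK3A, GSK3B}] + eps_gs

* `a_s ~ N(0,1)` is the latent AR activity of tumor s; `b_s = -rho * a_s +
  sqrt(1-rho^2) * eta_s` is the latent NF-kB activity, so `corr(a,b) = -rho`.
  Normal-tissue references have `a = b = 0`. The bivariate-normal latent
  model is the simplest structure with one tunable anticorrelation knob.
* `mu_g ~ N(7, 1)` log2 units (typical normalized-array baselines);
  `eps ~ N(0, 0.5^2)` (a realistic residual sd for within-group log2
  expression on arrays).
* Defaults: 100 tumors, 20 normals, 2000 genes, 30 genes per program,
  `beta = 1.0` log2 per activity unit, `rho = 0.6`, `kappa = 0.5`
  (GSK3A/GSK3B rise with AR activity, so GSK-3-high tumors have low NF-kB
  activity). The source study reports no cohort effect sizes, so these are
  the package's own choice of a clearly detectable but not degenerate
  signal; they are stated in `SimulationConfig` and used unchanged
  everywhere (tests, drivers, acceptance script).
* Survival: exponential event times with hazard
  `lambda_s = (ln 2 / 60) * exp(gamma * z_s)` where `z_s` is the tumor's
  standardized NF-kB summed-Z score and 60 months the baseline median
  survival; `gamma = 0.8` by default. A `censor_rate` fraction of tumors
  (default 0.3) receives a Uniform(0, 220)-month administrative censoring
  time; everyone else is censored at the 220-month end of follow-up.
  Survival is drawn before outlier shifts are applied, and normal samples
  carry no survival fields.
* Planted outlier chips are whole-column log2 shifts added last.

What the generator does **not** emulate: probe-level/CEL structure,
batch effects, heavy-tailed or heteroscedastic noise, gene-gene
correlation beyond the two programs, and competing risks. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not performance on real tumor datasets.

The membrane generator plants normalized per-site signals on a grid with
duplicate spots, a negative-control row around the blank level (50 raw
units) and a positive-control row around the scale level (350); the qPCR
generator plants fold changes as Ct shifts of `-log2(fold)` around a gene
baseline of 24 cycles with the reference gene at 18.

## Chip QC

The per-chip metric is the median relative log expression:
`RLE_s = median_g(x_gs - median_s' x_gs')`. Chips strictly outside the
Tukey fences `[Q1 - 1.5*IQR, Q3 + 1.5*IQR]` (quartiles by linear
interpolation) are discarded. The per-chip *median* of the RLE
distribution is used because that is the standard summary for this
diagnostic; NUSE requires probe-level standard errors that do not exist
after normalization, so externally computed NUSE values can be passed
through the same fence rule instead. Values exactly on a fence are kept.

Two properties of this rule are worth stating plainly because they limit
what can be promised:

* On an approximately Gaussian metric the 1.5-IQR fence has an
  irreducible per-chip false-positive rate near 1% (fences sit at about
  +/-2.7 sigma), so with ~40 chips an extra clean chip is flagged in
  roughly a third of cohorts even though planted artifact-scale outliers
  are essentially always caught. The rate is scale-free: no noise or
  cohort setting removes it.
* The rule is not idempotent: removing the tails truncates the metric
  distribution, shrinks the IQR and tightens the re-computed fences, so a
  second pass can cascade. QC is therefore defined as a single pass; the
  tests check that nothing at artifact scale survives it.

## Signature scoring and stratification

Z-scores are computed per gene against the normal-tissue reference
(`sd` with denominator n-1); genes with zero reference sd are dropped
with a warning, and a matrix without normals falls back to cohort
mean/sd with a loud warning. A signature score is the per-tumor sum of
Z over the signature's genes (missing genes recorded, never imputed).

The "high/low AR signature" groups are the top and bottom `ceil(f*n)`
tumors by summed Z. The extreme fraction is an explicit parameter,
default 1/3, because the source analysis does not state one; every
report records it. Ties at a cut break by sample id. The GSK-3 classes
use the dual threshold rule: both isoform Z-scores strictly above 0.5 ->
high, both strictly below -0.5 -> low, otherwise unclassified (the
Methods-section thresholds; strict inequalities are the documented tie
policy). Gene symbols match exactly after upper-casing; no alias
resolution is attempted.

## Enrichment statistic and permutation null

Genes are ranked by the pooled-variance two-sample t statistic
(high minus low; zero-variance-in-both-groups genes dropped; exact ties
broken by symbol). For a gene set S in a ranked list of N genes, the
running sum gains `|t_i|^w / sum_{j in S} |t_j|^w` at members and loses
`1/(N - |S|)` elsewhere; the enrichment score (ES) is the signed maximum
deviation, and the leading edge collects the members at or before
(positive ES) / at or after (negative ES) the extremum. The weight
defaults to `w = 1`, the method-defining choice, and is exposed in
configuration. If every hit weight is zero (possible with w > 0 and all-
zero t), hit steps fall back to `1/|S|`.

Significance uses phenotype permutation: labels are reshuffled over the
pooled high+low samples preserving group sizes, the ranking and ES are
recomputed, and `p = (1 + #{same-sign null |ES*| >= |ES|}) / (1 +
#{same-sign null})` (add-one smoothing avoids p = 0); `NES = ES /
mean(|same-sign null ES|)`. A degenerate null with no same-sign scores
reports `p = 1/(P+1)` with a warning. Phenotype (not gene) permutation is
used because the contrast is a two-class tumor comparison; the choice and
the weight are recorded in output metadata.

One behavior to be aware of: once |ES| saturates near 1, |NES| is no
longer monotone in the planted effect size, because the signature genes
remain mutually correlated under label shuffles and inflate the null
magnitudes. Detection rate and |ES| are the monotone readouts.

"Collapsed probe sets" are out of scope — inputs are gene-level; the TSV
reader collapses duplicated gene symbols to the maximum-variance row as
the stand-in policy.

The "AR-repressed NF-kB targets" set is the negative leading edge of the
NF-kB set in the high-vs-low-AR contrast; requesting it from a
non-negative enrichment is an error pointing at the opposite contrast.
The 29-gene published version of this set ships as a GMT fixture and can
be substituted for the per-cohort derivation with a configuration flag
(default: derive per dataset).

## Survival

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines behind this module's interface; tests verify them against hand
product-limit and observed-minus-expected oracles. Censored subjects at
a tied time remain at risk at that time (standard convention). The
follow-up horizon parameter administratively censors records beyond the
horizon before testing; the default report runs both 100 and 220 months.
Grouping defaults to the median split of the derived-set summed-Z score
(an explicit threshold mode exists for sensitivity analyses), with at
least two tumors required per group.

## Assay quantitation

Membranes: blank = mean of negative-control spots; scale = positive-row
mean minus blank (blank-subtracting the positives keeps the normalized
signal invariant under global intensity rescaling, which is tested);
site signal = duplicate-mean of `max(raw - blank, 0) / scale` (clamping
because intensities are physical). A membrane whose positive-control
mean does not exceed the blank is rejected, as is one with > 5% of spots
at an optional saturation ceiling; exposure selection itself is out of
scope. Condition-vs-control ratios use per-membrane normalized signals
(>= 2 membranes per condition) with a two-sample t-test, flagging
p < 0.05; a site with zero control mean has an undefined ratio and is
reported missing.

qPCR: `dCt = mean Ct_gene - mean Ct_ref` per condition, `ddCt` relative
to the control condition, `fold = 2^-ddCt`; replicate sds propagate in
quadrature (`s = sqrt(s_gene^2 + s_ref^2)`, the treated condition's),
reported as the range `2^-(ddCt +/- s)`. The control condition has fold
1 identically.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integer seeds; identical config + seed reproduces every
  output bit for bit, and the orchestrated run report is byte-identical
  across repeats (no timestamps).
* The running sum is clipped into [-1, 1] at the extremum to absorb
  cumulative floating error (~1e-14); its final value is zero within
  1e-9 by construction.
* The pipeline aborts on the first failing stage with the stage name;
  partial reports carry an INCOMPLETE marker. Reports validate against a
  shipped JSON schema (minimal required-key/type validator).

## Problem sizes used in tests and the acceptance script

Calibration and power claims are Monte-Carlo estimates at the sizes the
package's own study conditions define: 200 signal-free cohorts (99
permutations each) for enrichment calibration; 50 default cohorts for
detection, derived-set precision and log-rank power (n = 200 tumors for
power); 200 cohorts for log-rank null calibration; 100 qPCR tables for
fold recovery; 200 random instances for the ES brute-force equivalence.
The full-size 1000-permutation configuration is used by the analysis
drivers and the determinism check.

## Known limitations

* The IQR fence's false-positive rate and non-idempotence (above) mean
  "exactly the planted outliers and nothing else" holds in only ~2/3 of
  small cohorts; reports therefore always list the flagged ids.
* Phenotype permutation with few classified tumors (e.g. sparse GSK-3
  classes) yields coarse p-value grids; the add-one estimator never
  reports below 1/(P+1).
* No FDR across multiple gene sets (single-signature tests only), no Cox
  models, no probe-level preprocessing, no gene-identifier mapping.
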