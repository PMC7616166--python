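# Methods notes

This note records the statistical model, the defaults and the design
decisions behind `sexmr`, in the spirit of the model documentation that
simulation and statistics packages ship alongside their APIs. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The estimation problem

Two-sample Mendelian randomization treats genetic variants as instruments:
a SNP that robustly shifts an exposure (say, non-HDL cholesterol) and can
affect a binary outcome (aSAH or IA status) only through that exposure
identifies the causal effect from the ratio of its outcome and exposure
associations. The package works entirely on GWAS summary statistics —
per-variant effect estimates with standard errors from separate exposure
and outcome studies — stratified by sex where sex-specific GWASs exist,
and with sex-combined instruments applied identically to both sexes'
outcome data where they do not (blood pressure, smoking, alcohol).

The key modelling assumptions, in the order the pipeline relies on them:

1. **Relevance** — instruments pass $p \le 5\times10^{-8}$ in the exposure
   GWAS; strength is summarised by the mean per-SNP F-statistic
   $(\hat\beta_X/\mathrm{se})^2$, flagged when $\le 10$.
2. **Independence between instruments** — greedy LD clumping at
   $r^2 \le 0.001$ on a supplied correlation panel. Clumping is purely
   $r^2$-based with no physical-distance window: the panel is the single
   source of LD truth, which keeps the procedure reproducible at desk
   scale and testable against a constructed block panel. SNPs absent from
   the panel are dropped by default (treating them as uncorrelated is
   opt-in). Ties in p-value break by ascending rsid so output is invariant
   to input row order.
3. **No (directional) pleiotropy** — not assumed but probed: the Egger
   intercept, Cochran's Q, and MR-PRESSO each target a different failure
   mode, and the multiplicative random-effects IVW absorbs balanced
   heterogeneity into wider intervals rather than ignoring it.

## Estimators and numerical choices

* **IVW**: weighted regression through the origin, weights
  $1/\mathrm{se}(\hat\beta_Y)^2$. The default is multiplicative random
  effects — the fixed-effect SE times $\max(1, \sqrt{Q/(J-1)})$ — because
  that is the default behaviour of the standard summary-data MR software
  stack; the floor at 1 means under-dispersion never narrows an interval.
  A single-SNP analysis falls back to the fixed model with a warning.
* **MR-Egger**: SNPs are first oriented so every exposure effect is
  non-negative (the convention that makes the intercept interpretable as
  directional pleiotropy), then fitted by weighted least squares with a
  free intercept; SEs carry the analogous $\max(1, \sqrt{Q/(J-2)})$
  inflation. If the oriented exposure effects have no spread the slope is
  unidentified and a typed error is raised.
* **Medians**: the weighted median uses the cumulative-midpoint
  construction (sort ratios, normalized weights $w'_j$, midpoints
  $s_j = \sum_{k\le j} w'_k - w'_j/2$, linear interpolation at 0.5); the
  simple median is the equal-weight special case. SEs come from a
  parametric bootstrap (default 10 000 resamples, mandatory explicit seed;
  the pipeline uses 2 000 to keep a full study fast). Instruments are
  canonically oriented before resampling so the bootstrap — not just the
  point estimate — is exactly invariant to per-SNP allele negation.
* **P-values** for slopes use the standard normal, the summary-data MR
  convention, with the 97.5% quantile carried at full double precision
  (1.959963985…). Two-sided p-values are floored at 1e-300 so they stay
  in (0, 1].
* **Cochran's Q** (heterogeneity): $\sum_j w_j(\hat\beta_{Yj} -
  \hat\theta\hat\beta_{Xj})^2$ on $J-1$ df around the fitted slope.

## MR-PRESSO

The global statistic is the sum over SNPs of squared leave-one-out
residuals; its null distribution is simulated by redrawing every SNP from
normals centred on the leave-one-out fits (default 5 000 replicates,
minimum 1 000). Per-SNP outlier p-values compare each observed residual
with its own simulated distribution, Bonferroni-multiplied by J, flagged
below 0.05. The distortion test removes as many random non-outlier SNPs
(sampled with replacement) as there are flagged outliers to build the null
of the percent change of the IVW estimate. All Monte-Carlo p-values use
the $(b+1)/(n_{\mathrm{sim}}+1)$ correction and are never exactly zero;
identical seeds give bit-identical results. Leave-one-out slopes use
fixed-effect weights.

## The sex-difference test

With two independent per-sex estimates the general Cochran's Q over
inverse-variance weights reduces algebraically to
$(\hat\theta_W-\hat\theta_M)^2/(\mathrm{se}_W^2+\mathrm{se}_M^2)$ on 1 df;
the implementation uses the pooled-mean form and the test suite asserts
the identity. The back-conversion from printed odds ratios uses
$\beta=\ln\mathrm{OR}$, $\mathrm{se}=(\ln U-\ln L)/(2z_{0.975})$ with the
exact quantile. Because published ORs are rounded to two decimals, a
p-value recomputed this way is arithmetic-limited: the non-HDL-C/aSAH
worked example is therefore checked within ±0.010 of its published value,
while the smoking examples are robust to the rounding and must agree to
three printed decimals. One published row (non-HDL-C vs IA) back-computes
to a p-value far from the printed one for reasons not determinable from
the printed numbers; it is excluded from the worked examples rather than
guessed at. By default the pipeline applies the test to every method's
estimates; published figures present the IVW results.

## Harmonization rules

The exposure study defines the allele orientation and its betas are never
altered. For each shared variant: identical allele pairs pass through;
swapped pairs negate the outcome beta and flip its frequency; strand
complements are relabelled then treated the same; palindromic variants
(A/T, G/C) are oriented purely by allele frequency — labels cannot
distinguish a swap from a strand flip there — and dropped as ambiguous
when the minor-allele frequency in either study exceeds
$0.5 - w$ with window $w = 0.08$ (a common community default,
configurable); irreconcilable allele sets are dropped as mismatches.
Every shared variant lands either in the harmonized table or in the
dropped report with its reason. Indels and multi-allelic records are
rejected at read time; positions are 1-based metadata only. The p-value
filter is inclusive ($\le$), the MAF filter keeps
$\min(p, 1-p) \ge 0.05$, and both are applied to the exposure and outcome
tables.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, at
the level the analysis consumes — summary effects with independent normal
noise, not genotypes:

* allele frequencies uniform on (0.10, 0.90); true per-allele exposure
  effects $b_j \sim N(0, 0.03^2)$, shared between the sexes (the same
  variants instrument both strata; only observation noise differs);
* GWAS precision $\mathrm{se} = (2p(1-p)n)^{-1/2}$ with defaults
  $n_{\mathrm{exposure}} = 300\,000$ and $n_{\mathrm{outcome}} = 50\,000$,
  sized like the large lipid-consortium exposure GWASs against a rarer
  binary outcome; these defaults put the mean instrument F-statistic near
  100, inside the 37–245 range reported for real sex-specific instruments;
* outcome effects $\hat\beta_{Yj} \sim N(\theta_{\mathrm{sex}} b_j + s_j
  \alpha_j, \mathrm{se}_Y^2)$ where $\alpha_j$ is zero, balanced
  ($N(0,\sigma^2)$) or directional ($N(\mu,\sigma^2)$) pleiotropy and
  $s_j = \mathrm{sign}(b_j)$ attaches it to the exposure-increasing
  allele — the orientation under which MR-Egger defines directional
  pleiotropy;
* binary-outcome betas are drawn directly on the log-odds scale (no
  individual-level logistic simulation): two-sample MR never sees anything
  below the summary level, so this is the level at which fidelity matters;
* optional LD blocks (compound-symmetric, block members carry $r$ times
  the index SNP's effect), decoy null SNPs, and label corruption
  (effect/other swaps, strand flips, palindromic variants) to exercise
  clumping and harmonization;
* exposure and outcome noise are independent — zero sample overlap,
  mirroring a design that excludes overlapping cohorts from the outcome
  data.

What the generator does **not** emulate: realistic allele-frequency
spectra, case-control imbalance in outcome SEs, correlated pleiotropy
violating InSIDE, winner's-curse selection in the discovery GWAS, or
population stratification. Passing tests therefore demonstrate that the
estimators and diagnostics behave as designed under their own assumptions,
not that those assumptions hold in any particular consortium dataset.

## Simulation scales used by the checks

The calibration checks run at the scales a desk machine handles
comfortably while keeping Monte-Carlo error well inside the asserted
bands: 500 repetitions for IVW coverage (J = 150 instruments), 2 000 for
the sex-difference null rate, 200 each for Egger-intercept recovery
(instruments selected at genome-wide significance from 250 candidates,
expected J = 150) and for MR-PRESSO planted-outlier detection (50 clean
SNPs + 1 outlier, 2 000 null replicates). The Egger check selects
instruments by significance because directional pleiotropy is defined on
the exposure-increasing allele: unselected near-null SNPs whose observed
exposure sign flips would dilute the intercept, and genome-wide-significant
instruments are the design's own condition anyway. The clumping check
clumps all block SNPs (p threshold 1) so the count of index SNPs is a
deterministic property of the algorithm rather than of sampling noise in
the significance filter.

## Output conventions

Result tables are tab-delimited with documented headers; forest-plot
tables render ORs and CI bounds to two decimals and p-values to three,
rounding ties away from zero, with p < 0.001 shown as "<0.001" — the
precision convention of the published figures. No multiplicity correction
is applied across exposure-outcome pairs (matching the analysis design,
which deems p ≤ 0.05 significant); the number of tests performed is
recorded in the provenance. Output tables carry a config hash and the
seed but no timestamps, so identical plan + seed reproduce byte-identical
files; timestamps live in the run log.

## Known limitations

* No proxy-SNP lookup, liftover, VCF/BGEN input, Steiger filtering,
  multivariable MR, or conditional/joint instrument selection.
* LD handling assumes the supplied panel is the truth; there is no
  distance window and no genotype-level LD computation.
* The MR-PRESSO distortion null follows the published construction
  (resampling removal sets from the non-outlier SNPs); its behaviour when
  outliers are a large fraction of the instrument set is untested.
* Sex-combined instruments applied to both sexes can bias sex-difference
  conclusions when instrument relevance itself differs by sex; the
  package reproduces that design faithfully rather than correcting it.
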