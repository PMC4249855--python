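# Methods

## The instability score

The score is a weighted sum of two per-sample counts, `Score = K·n1 + n2`
with `K = 0.5` by default. `n1` counts segmented copy-number intervals
that survive a noise filter: length strictly greater than 3 Mb (with
1-based inclusive coordinates, length = end − start + 1) and log2
tumor/normal ratio strictly greater than 0.05 or strictly less than
−0.05. All three inequalities are strict; a 3,000,000 bp segment or a
ratio of exactly ±0.05 is excluded. `n2` counts validated somatic
mutation records, pooling every variant class including silent variants;
`ScoreParams.include_silent=False` gives a non-synonymous-only
sensitivity analysis, and `mutation_set` restricts to in-frame or
frame-shift subsets, switches to all records regardless of validation
(level-2-style call sets), or empties the mutation channel entirely.
Setting `K = 0` or `mutation_set="none"` reduces the score to its
single-channel predictors (mutation-only / copy-number-only).

The sample universe for scoring is the union of ids across the segment
and mutation tables plus any roster passed in (normally the clinical
table); a sample absent from one table contributes 0 for that component
rather than being dropped, because cohort membership is a clinical fact
and an absent row legitimately means no qualifying event.

`select_k` re-derives K from a grid (default 0.1–2.0 in steps of 0.1):
for each candidate the cohort is scored, split at its median (ties to the
high group), and the groups compared by a two-sided log-rank test on
overall survival; the K with the smallest p wins, ties resolving to the
smallest K for determinism. A degenerate split (one group empty) scores
p = 1. Whether the selection median should come from the whole cohort or
from wild-type patients only is genuinely open; the whole cohort is used
here because K selection precedes any HR labelling in the analysis order.

## HR-deficiency labels

Five mutually exclusive labels are assigned with the precedence
BRCA1_MUT > BRCA2_MUT > BRCA1_SILENCED > OTHER_HR_DEFICIENT >
HR_WILDTYPE. The precedence is a package convention — the groups are
analysed as disjoint columns downstream, and overlaps (a carrier who is
also silenced) must resolve deterministically.

* **Carriers** need one or more non-synonymous BRCA1/2 records; silent
  variants never count, and germline versus somatic origin is not
  distinguished.
* **Silencing** is called by consensus k-means on the two-dimensional
  methylation/expression data. Both channels are z-scored; k-means
  (k = 2) runs on `n_resamples = 100` random 80% subsamples; a pairwise
  consensus matrix (co-clustering fraction among co-sampled pairs)
  accumulates; the final partition cuts an average-linkage tree on
  1 − consensus. The resample count, subsample fraction and threshold
  follow common consensus-clustering practice and are exposed in
  `ConsensusConfig`. The silenced cluster must have *both* the higher
  methylation centroid and the lower expression centroid; discordant
  orderings, or degenerate (identical) inputs, yield an empty silenced
  set with a warning rather than an arbitrary call. Internal
  standardization makes the call invariant to affine rescaling of either
  channel, and a fixed seed reproduces the identical set.
* **Other HR alterations** are EMSY calls of +2 (high-level
  amplification), deficiency-gene calls of −2 (homozygous deletion) — a
  single-copy gain or loss is never evidence — and validated
  non-synonymous mutations of deficiency genes. The shipped rosters
  (PTEN; FANCA–FANCM core complementation groups; RAD50/51/51B/51C/51D/
  52/54L; ATM, ATR, CHEK1, CHEK2) are editable defaults: no canonical
  list exists, so the sets are data, not code.

## Outcome statistics

All tests are two-sided.

* **Kaplan-Meier** uses the product-limit estimator with Greenwood
  variance and log-log (exponential Greenwood) 95% bands; the 5-year rate
  reads the step function at 1826.25 days (365.25 days/year). No-event
  input returns survival ≡ 1.
* **Log-rank** is the standard O−E chi-square with df = groups − 1. For
  very small two-group problems an exact permutation option enumerates
  every relabelling of subjects into groups of the observed sizes and
  reports the tail fraction of the chi-square statistic.
* **Cox regression** maximizes the partial likelihood (via statsmodels
  PHReg) with Efron tie handling by default and Breslow as an option; the
  paper-style reports never state a tie method, and Efron is the less
  biased default. Wald 95% CIs and p-values are reported per covariate.
  Non-finite estimates raise a convergence error; coefficients beyond
  |15| trigger a separation warning; fewer events than covariates warns.
  Covariate coding for adjusted models: grade G2 reference vs G3/G4;
  residual tumor 0–10 mm (categories 0 and <1 cm) reference vs >10 mm
  (1–2 and >2 cm); stage II reference vs III/IV; age continuous. Rows
  with a missing covariate are dropped (complete case).
* **Wilcoxon rank-sum** uses midranks. Combined n ≤ 12 (configurable)
  triggers exact enumeration of all group assignments; larger samples use
  the tie-corrected normal approximation with continuity correction,
  matching R's default behaviour.
* **Fisher exact** sums hypergeometric probabilities no larger than the
  observed table's; a zero margin returns p = 1; the sample odds ratio
  ad/bc is reported.
* **Response trends** divide scores into 12 equal-width intervals
  covering [min, max] (last right edge closed) and fit an unweighted
  least-squares line to rate against bin index over non-empty bins. An
  empty bin has an undefined rate and is excluded rather than imputed; a
  weighted fit is a one-line extension but the reference presentation is
  a plain regression line through the points. All-identical scores are an
  error (zero-width bins).

The whole-cohort report splits at the cohort median score (ties high);
the platinum analyses use only patients with a known platinum status and
split them at the median score *of that subset*. The disease-free-at-5-
years percentage counts event-free patients among those with an event
before 5 years or follow-up reaching 5 years; patients censored earlier
are not evaluable and are excluded from the denominator.

The cohort-characteristics report tests categorical rows across the four
status groups with Fisher's exact test when the contingency reduces to
2×2 and the chi-square test otherwise (an exact r×c network algorithm is
out of scope); age compares wild-type against pooled non-wild-type by
Wilcoxon. Missing values are excluded from every test. The wild-type
column pools truly unaltered samples with OTHER_HR_DEFICIENT, and
excludes silenced samples, so the four columns partition the cohort.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed as the study conditions:

* 325 samples; latent class fractions 0.13 BRCA1_MUT, 0.10 BRCA2_MUT,
  0.10 BRCA1_SILENCED, 0.21 OTHER_HR_DEFICIENT, remainder wild-type.
* Qualifying-CNC and validated-mutation counts are negative binomial
  (dispersion 8) rather than Poisson, mimicking the overdispersion of
  tumor mutation burden. Wild-type means are 40 and 40, so the wild-type
  score centres near 60 — the natural whole-cohort split point — and each
  deficient class is elevated 1.5-fold, putting deficient scores near 90,
  matching the direction and rough magnitude of the reported wild-type /
  HR-deficient separation.
* Counts are realised as concrete table rows. Qualifying segments draw
  lengths in (3 Mb, 20 Mb] and |log2 ratio| in [0.10, 1.00]; decoy rows
  (30% of emitted rows by default) violate exactly one filter at a time —
  too short with a passing ratio, or long with |ratio| ≤ 0.05, including
  exact boundary values — so every filter edge is exercised and scoring
  the generated tables reproduces the latent counts exactly.
* Carrier and HR-gene mutation evidence is injected by repurposing an
  existing validated record (never appending), keeping the per-sample
  count identical to the latent value; background genes come from a
  synthetic pool disjoint from all HR genes, and background copy-number
  calls never reach ±2.
* Methylation/expression is bimodal: silenced centroids shift by 4
  within-cluster SDs on both channels (+0.20 beta, −4 log-expression).
* Survival is exponential — constant hazard, chosen for analytic
  tractability of oracle checks — with per-day baseline hazard 5.2e-4
  (median OS near 3.7 years) and log hazard either linear in the
  standardized score (default slope −0.35: higher score protective) or a
  step between median-split groups (used when a planted group hazard
  ratio must be exact). Censoring is exponential with its rate tuned so
  the expected censored fraction is 45%; progression times use a 1.6×
  hazard and are capped at the death time, so PFS ≤ OS always.
* Complete response is Bernoulli with logit 0.38 + 0.6·z (59.4% baseline
  rate); platinum sensitivity derives from a CR-correlated latent
  (logit 0.26 + 0.3·z + 0.75·CR), with 40% of statuses missing.

Everything draws from a single `numpy.random.Generator`, so one seed
reproduces the bundle byte for byte.

What the generator does **not** emulate: genome positional structure
(segments are placed uniformly, may overlap, and carry no chromosome-
length constraints), real TCGA marginal distributions, correlated
missingness, non-proportional hazards, and cure fractions. Tests passing
on these cohorts therefore demonstrate the pipeline's internal
correctness and statistical calibration, not performance on real arrays.

## Verification strategy and problem sizes

Every statistical routine is checked against an independent brute-force
oracle at small n: Fisher against hypergeometric enumeration (totals ≤
40), Wilcoxon against enumeration of all group assignments (combined n ≤
12), the permutation log-rank against relabelling enumeration (n = 8),
and Cox single-covariate coefficients against direct bounded maximization
of the written-out partial likelihood (agreement to 1e-6). Calibration
and recovery use simulation: 200 null cohorts of n = 325 for p-value
uniformity (KS at α = 0.01), 200 cohorts of n = 400 for 95% CI coverage
of a planted hazard ratio of 0.5, 20 cohorts for silenced-set recovery,
and 100 cohorts for score-elevation detection. These sizes keep the whole
suite to a few minutes while leaving the Monte-Carlo margins wide
relative to the thresholds tested.

## Known limitations

* The r×c cohort-characteristics test is chi-square, not exact, when a
  table exceeds 2×2.
* The consensus-clustering final partition uses average-linkage on the
  consensus complement; with k = 2 and well-separated data this is
  stable, but for marginal separations the silenced call can vary with
  the resampling seed (the seed is part of the configuration for this
  reason).
* Exact permutation log-rank is limited to two groups and small n by
  combinatorial growth.
* The Cox implementation relies on statsmodels PHReg; penalized fallback
  for complete separation is deliberately not enabled — separation warns
  and the analyst decides.
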