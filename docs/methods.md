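# Methods

This note records the statistical model, the numerical choices and the
design decisions behind `phonotail`, in enough detail that a maintainer can
predict what the code does without reading it.

## Data model

A language is represented by its segment frequency table: a map from segment
label to a positive integer token count, derived from a wordlist in which
each lexeme contributes exactly once (lexical frequency, not discourse
frequency). The observations handed to every estimator are the *values* of
that map — one count per segment type, typically 16–37 of them. Reading
applies NFC unicode normalization and nothing else; forms must arrive
pre-segmented with a declared delimiter, and phonemic normalization or
morphology stripping are out of scope. Corpora are filtered to wordlists of
at least 250 lexemes by default, below which segment frequency estimates
degrade quickly.

## Candidate distributions

All four fitted families are discrete and truncated: the pmf is defined and
renormalized over `{x_min, x_min+1, ...}`. This uniform truncation is what
makes log-likelihoods comparable across families at a shared cutoff.

- Power law: `p(x) = x^(-α) / ζ(α, x_min)`. The Hurwitz zeta comes from
  `scipy.special.zeta`. Normalizability requires `α > 1` and the
  constructor enforces it; fitted exponents on realistic data sit well
  inside the `(1, 20]` optimization bounds.
- Lognormal: increments `F(x+1) − F(x)` of the continuous lognormal CDF on
  unit intervals, renormalized above `x_min`. Implemented with survival
  functions for tail accuracy. The pointwise-density discretization was
  rejected: its tail decays incorrectly relative to the CDF-increment form.
- Exponential/geometric: `p(x) = θ (1−θ)^(x−x_min)` with per-step decay
  `θ ∈ (0,1)`. This is the discrete analog of the exponential rate model;
  shifting `x_min` only translates the support.
- Poisson: the standard pmf renormalized over `x >= x_min` (at
  `x_min = 1`, a zero-truncated Poisson — counts of observed types are
  never zero).

Sampling is inverse-CDF throughout and fully seedable: closed form for the
geometric, quantile functions for the Poisson and lognormal, and for the
power law a table-based inversion over a 4,096-value horizon with exact
bisection on the closed-form CDF for draws beyond it (relevant for `α` near
1, where the tail is extremely heavy).

The five rank-frequency models (Zipf, Sigurd geometric, Good stick-breaking,
negative log, Yule–Simon) are exact finite probability vectors over ranks
`1..n`. They get evaluators and samplers but no maximum-likelihood
estimator: no established MLE exists for the Yule–Simon form, and the
parameter-free models need none. Good's vector is computed as
`(1/n) Σ_{i=k..n} 1/i`, which sums to one exactly.

## Estimation

MLEs use closed forms where they exist and bounded numerical optimization
elsewhere, always on the truncated likelihood over unique values with
multiplicities:

- geometric: `θ = n / Σ(x_i − x_min + 1)` (closed form);
- power law: scalar minimization of the negative log-likelihood over
  `α ∈ (1, 20]` (`scipy.optimize.minimize_scalar`, bounded, xatol 1e-9);
- Poisson: scalar minimization over `λ ∈ (0, max(4·mean, 10)]`;
- lognormal: L-BFGS-B over `(μ, σ)` with `σ >= 1e-3`, initialized at the
  mean and SD of the log-counts.

Degenerate inputs (all observations equal) push the power law to its upper
bound and the lognormal to its `σ` floor; these are returned with
`converged=False` rather than raised, so a study never aborts on one cell.
A fit needs at least two tail observations.

The KS distance is the maximum over the *observed* unique values of
|empirical CDF − model CDF|, both right-continuous on the integers.
`estimate_xmin` scans every distinct observed count as a candidate cutoff
(excluding candidates leaving fewer than `min_tail = 2` observations or
fewer than two distinct values), refits at each, and returns the smallest
KS distance; ties break toward the smaller cutoff (more data retained), and
converged candidates are preferred over non-converged ones. Candidate grids
between observed integers would be meaningless for count data. The
"without x_min" setting anchors the cutoff at the observed minimum so every
observation is in support.

## Bootstrap plausibility

Because the parameters (and possibly `x_min`) are estimated from the data,
the observed KS distance is calibrated by a semi-parametric bootstrap: each
replicate of the original size draws each point from the fitted model
(conditioned on `x >= x_min`) with probability `n_tail/n_total`, and
otherwise uniformly from the empirical sub-`x_min` observations; when
`x_min` equals the observed minimum, the scheme is fully parametric. The
exact estimation path that produced the fit — including `x_min`
re-estimation if and only if the original fit estimated one — is re-run on
each replicate. The p-value is the raw exceedance fraction
`#{D_b >= D_obs}/B`, ties counting toward plausibility; a (+1)/(+1)
smoothed estimator is available behind a flag. Replicates that fail to
refit are dropped and counted (`n_failed`), with a warning above 1%.
`p <= 0.1` rejects the family — strictly, so a p-value exactly at the
threshold rejects. Per-language generators are spawned from the master seed
(`numpy` SeedSequence), so any single cell of a study can be reproduced in
isolation.

Under the true generating model this procedure is close to nominal: across
200 simulated languages of 500 geometric observations, the 0.1 threshold
rejects about 9–12% (the acceptance suite asserts [5%, 17%]).

## Model selection

Vuong's statistic is `Σ r_i / (s_r √n)` with `r_i` the pointwise log-pmf
ratios over the shared tail and `s_r` their sample SD (ddof 1); the
two-sided p-value comes from the standard normal. No parameter-count
correction is applied by default — compared pairs at equal `x_min` differ
by at most one parameter — and zero-variance ratios yield statistic 0 and
"neither". The favored family is recorded from the raw sign whether or not
the difference is significant, mirroring how directional tallies are
usually reported separately from significance. When each family estimated
its own cutoff, the comparison runs twice (each family's `x_min` imposed on
the other, which is refitted there); each direction is tagged with the
cutoff's provenance. Bonferroni correction uses `m` = number of languages,
applied per comparison family. A practical note: on very heavy-tailed data
a few extreme observations inflate `s_r`, so a consistently positive
statistic can still fall short of formal significance — the sign is much
more stable than the p-value.

## Synthetic corpora

The generator's defaults mirror the real study sample: inventory sizes from
a discretized normal (mean 24.5, SD 3.8) clamped to [16, 37]; wordlist
sizes log-uniform over [268, 8742]; form lengths uniform on 2–10 segments.
Two generative regimes are deliberately distinct:

- A **rank model** supplies an inventory's type probabilities, and counts
  are one multinomial draw of the language's token total — reproducing the
  sampling noise a finite wordlist imposes on an underlying frequency
  vector. Draws leaving a type unobserved are retried rather than smoothed,
  keeping counts honest positive integers.
- A **tail or spliced model** specifies the distribution of count *values*,
  so counts are iid draws from it. This is the construction used wherever
  the inference target is the value distribution itself (bootstrap
  calibration, `x_min` recovery): rescaling such draws through a multinomial
  would stretch the value axis and destroy the very shape under test —
  e.g. 24 geometric draws scaled to thousands of tokens cluster at
  multiples of the scale factor, which no smooth geometric fits.

The spliced model glues a body distribution below a cutoff to a tail
distribution above it, continuous at the junction, and renormalizes; it
exists to create languages with a known regime boundary for recovery
experiments (the default experiment: geometric body `θ = 0.25`, power-law
tail `α = 2.5`, cut 8, 1,000 draws — about 18% tail mass). Synthetic
corpora serialize through the same long-format counts CSV the reader
accepts, and wordlists can be materialized by partitioning tokens into
forms so the counting path is testable end to end.

What passing synthetic tests does *not* show: real inventories are not iid
draws from any of these families (counts are weakly dependent through the
shared wordlist, and real frequency structure is shaped by history, contact
and phonotactics), so calibration and recovery results here demonstrate
correctness of the machinery, not truth of any generative claim about
language.

## Problem sizes and known limitations

The test and acceptance runs use desk-scale problem sizes chosen as the
smallest that make the statistical assertions stable: 200 simulated
languages × 500 bootstrap replicates for calibration, 20 languages × 200
replicates for the plausibility pattern, 100 replicates for cutoff
recovery, 5,000 samples for estimator bias. The reference setting of
10,000 bootstrap replicates per language per family remains the library
default for real studies.

Known limitations:

- The mean of the power-law MLE at very small samples is biased upward by
  estimator skew (about 2% above truth at n = 50, α = 2.5, even though the
  median is within about 0.7%); single-language exponent estimates from
  phoneme-sized inventories should be read with that in mind.
- KS-minimizing cutoff selection is noisy on small inventories and tends to
  sit one or two values below a sharp regime boundary, since the spliced
  pmf is continuous at the junction.
- No standard errors or confidence intervals are reported for fitted
  parameters, matching the summary-table conventions the pipeline mirrors
  (sample SD, two-decimal rounding).
- Analytic KS p-values are deliberately absent: they are invalid once
  parameters are estimated, which is the reason the bootstrap exists.
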