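# Methods

## Model and procedure

`inflaprof` treats bulk expression of an inflamed tissue as a mixture of the
baseline tissue and infiltrating cell populations. It does not estimate
mixture fractions (it is an enrichment method, not deconvolution): instead
it asks, for each candidate population, whether the transcripts that
fingerprint that population against the baseline tissue are
disproportionately *increased* in the case/control contrast.

All expression values are log2 intensities of the kind produced by
RMA-style normalisation. Fold change is always the ratio of geometric
means, `2**(mean log2 difference)` — the quantity a linear model on log2
data estimates directly.

### Differential expression

Two-group contrasts use a pooled-variance t statistic, by default with
empirical-Bayes moderation: per-probe sample variances `s2_g` (with `d_g`
residual degrees of freedom) are modelled as scaled-F around a prior
variance `s0²` with `d0` prior degrees of freedom, and the posterior
variance `(d0·s0² + d_g·s2_g)/(d0 + d_g)` replaces `s2_g`, with `d0 + d_g`
degrees of freedom for the two-sided p-value. `(d0, s0²)` are fitted by
moment-matching the mean and variance of `log s2_g` against the theoretical
moments of a log scaled-F variate (digamma/trigamma closed forms; the
trigamma inverse is found by bracketed root-finding). Numerical details
chosen to keep the estimator well-behaved at the edges, and verified against
the Bioconductor reference implementation to ~1e-13 in the test suite:

* exact-zero variances are offset to `1e-5 ×` the median variance before
  taking logs;
* when the spread of log-variances is no larger than expected under a single
  common variance, `d0 = ∞` and `s0²` is the arithmetic mean of the `s2_g`;
* total degrees of freedom are capped at the pooled residual degrees of
  freedom actually observed;
* with fewer than 10 probes the fit is skipped and the ordinary t used, with
  a logged warning;
* probes with zero variance *and* zero mean difference are vacuous: t = 0,
  p = 1, flagged.

### Signature gate

A probe is a signature transcript of a population when its BH-adjusted p
(adjusted within that population-vs-reference contrast, not pooled across
populations) is below `p_adj_max = 1e-4` and its fold change is at least
`fc_min = 16`, boundary inclusive. The gate is deliberately one-directional:
two-sided p-values are used throughout, but only population-elevated probes
can pass the fold-change condition. Gene-level reporting collapses probes to
the best probe per gene by smallest raw p.

### Profile scores and the dual test

For each population the case/control contrast splits its signatures into
`n1` increased and `n2` decreased by the strict sign of the log2 fold
change; exact zeros count as neither (ties are measure-zero on real data
and occur in simulation only at zero noise). `ratio = n1/n2` is `+inf` when
`n2 = 0 < n1` (serialised as `Inf` in TSV and as a null-with-flag in JSON)
and NA when no signature has a direction. Ranking is by descending ratio;
`+inf` rows sort among themselves by larger `n1`; finite ties break by
larger `n1`, then population id, so the ranking is total and deterministic.

The redundancy filter removes from population *j* every transcript that is
a signature of any population ranked strictly above *j*; the top-ranked
population keeps its full set (`n* = n`).

Both `n1` (of `n1+n2` draws) and `n1*` (of `n1*+n2*` draws) are tested with
the upper hypergeometric tail against the platform background — the
directional split of *all* probes in the same contrast, significant or not.
The tail is summed in log space from log-gamma binomial coefficients, so
p-values far below the smallest positive double remain usable. Each test
family is Hochberg-adjusted across the N populations separately (Hochberg
is a family-wise step-up procedure, valid under the non-negative dependence
this design induces; the upstream literature sometimes labels such values
"FDR-adjusted" — the reports here call them `p1_adj`/`p2_adj` and they are
FWER-controlling). A population is significant only when both adjusted
p-values fall below α = 0.05 (configurable).

Degenerate rows (no directional signature) get p = 1 and a flag rather than
an error, so a panel with one dead population still profiles.

### Attribution

The top-K induced transcripts (default K = 500) are selected among
increased-direction probes by smallest BH-adjusted p (ties by raw p, then
larger fold change) and displayed in descending fold-change order. Each is
assigned to the highest-ranked significant population whose signature set
contains it — a deterministic tie-break chosen because the profile rank is
the method's own measure of explanatory priority — optionally restricted to
classes of interest (e.g. dendritic cells / macrophages / monocytes).
Explained fractions are per-class assigned counts over K.

### Phenotype analyses

`phenotype_correlations` computes per-probe Pearson r against a phenotype
and compares the mean r of a probe set against the rest of the platform
(set members are excluded from the background) with a Welch unequal-variance
t-test — Welch because the set and background sizes and spreads differ by
orders of magnitude. `score_predictor_screen` correlates panel expression
with log2 profile scores; populations with infinite ratio enter at twice
the largest finite ratio so the log is defined (they belong at the top of
the score scale; the exact cap only compresses the top of an already
monotone axis), NA-ratio populations are dropped, and constant probes are
excluded with a count. Term over-representation uses the same hypergeometric
tail on an annotated universe and reports raw p-values with a 0.05 flag
(plus a supplementary BH column).

## Synthetic study conditions

The simulator emulates the data layout the algorithm consumes, at a scale
that keeps the full suite fast:

| parameter | default | rationale |
|---|---|---|
| probes | 5,000 | ~1/9 of a whole-genome array; preserves the marker fraction |
| populations | 20 | enough for ranking, redundancy and Hochberg behaviour |
| markers per population | 60 | 1.2% of probes, matching typical signature fractions |
| marker fold change | 32 | comfortably above the 16-fold gate |
| noise σ (log2) | 0.25 | replicate SD typical of RMA-normalised arrays |
| reference samples n_A | 10 | a modest multi-study liver reference |
| population replicates n_B | 3 | public reference populations average ~3 replicates |
| case/control | 3 vs 3 | the dietary-contrast design size |
| spike fractions | 0.2 | a strong but sub-dominant infiltrate |

Baseline log2 means are uniform on [4, 10]; noise is i.i.d. Gaussian on the
log2 scale (log-normal linear). Case samples are linear-scale convex
mixtures: `(1 − Σf_j)·baseline + Σ f_j·population_j`, then log2, plus
optional intrinsic differential-expression shifts, plus noise. A marker at
`fc` times baseline spiked at fraction `f` therefore shifts the case mean by
`log2(1 + f(fc − 1))` — the closed form the tests check. With
`shared_marker_frac > 0` the second population replaces that fraction of its
block with the first population's markers, creating the parent/decoy pair
that exercises the redundancy filter.

What the simulator does *not* model: probe-level normalisation artifacts,
batch effects, correlated noise across probes, population-intrinsic
transcriptional responses, or genetic variation between strains. Passing
the planted-truth tests therefore shows the algorithm recovers composition
shifts under clean mixing with realistic noise — not that it is robust to
platform artifacts or confounded designs.

The null calibration fixes one panel and its identified signatures and
redraws 200 case/control experiments with all spike fractions zero: the
randomness under the null is the contrast noise, which is exactly what the
hypergeometric test conditions on. The family-wise false-positive criterion
is that at most 5% of replicates call any population significant.

## Known limitations

* Enrichment, not deconvolution: scores order populations but do not
  estimate cell fractions.
* Signature identification assumes population and tissue references share a
  probe universe and comparable normalisation; cross-platform mapping is out
  of scope.
* The hypergeometric null treats signature directions as exchangeable draws
  from the platform; strong co-regulation within a signature set (beyond
  composition shifts) can inflate significance, which is precisely why the
  starred test and the conservative Hochberg adjustment are both required.
* The ratio score saturates at `+inf` once `n2 = 0`; downstream consumers
  should use `pct_increased` or `n1` when a bounded scale is needed.
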