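# Methods

## Model and estimand

Each tumor pair contributes, per gene, two log2 expression values from
the same patient. Intra-pair similarity is measured with the agreement
(absolute-agreement, single-rater) intraclass correlation coefficient.
For a group with n pairs, the gene's n x 2 table (patients x pair
members) is decomposed by a two-way crossed ANOVA with grand mean g, row
means r_i and column means c_j:

```
MS_patients = 2 * sum_i (r_i - g)^2 / (n - 1)
MS_members  = n * sum_j (c_j - g)^2 / (2 - 1)
MS_residual = sum_ij (x_ij - r_i - c_j + g)^2 / (n - 1)
```

with method-of-moments components sigma2_patients = (MS_patients -
MS_residual)/2, sigma2_members = (MS_members - MS_residual)/n,
sigma2_residual = MS_residual, and

```
ICC = sigma2_patients / (sigma2_patients + sigma2_members + sigma2_residual).
```

This is the *agreement* form: the member (pair-order) variance stays in
the denominator, so a systematic offset between first and second
measurements lowers the ICC. It is algebraically identical to ICC(A,1)
of McGraw & Wong, `(MS_patients - MS_residual) / (MS_patients +
MS_residual + 2*(MS_members - MS_residual)/n)`, which the test suite
uses (via pingouin) as an independent oracle.

Numerical conventions:

* components are **not** truncated at zero; negative ICCs are retained
  and enter distribution summaries as-is;
* a gene whose component total is zero within a group (e.g., constant
  values) has an undefined ICC: it is reported as NaN, excluded from
  medians/counts/tests, and counted in the run log. The undefined guard
  triggers when the component sum is below 1e-12 times the mean-square
  total, i.e., pure cancellation noise;
* the batched (all-genes) computation is the same arithmetic as the
  single-gene path; a test asserts equality to 1e-10.

Because the member effect is in the model, a fixed member-order
convention is recorded in the design: member1 = right tumor for SBC,
member1 = earlier lesion for MBC/LRC. The ICC estimate itself does not
require designating a primary lesion.

## Group comparison

Per-gene ICC values of the three groups (SBC, MBC, LRC) are compared
with a one-way ANOVA treating genes as observations, plus pairwise
two-sided Welch t-tests (a Student option exists; Welch is the default
because gene counts and variances differ across groups). Per-gene ICC
values are mutually correlated — co-expressed genes give correlated
estimates — so these p-values rank panels and groups rather than
calibrate error rates; this caveat is inherent to the design and is
documented, not corrected. Summaries per group: median ICC, number of
genes with ICC above a cutoff (default 0.5), and per-pair counts of
variant probes (|log2 difference| > log2(2), i.e., two-fold).

## Preprocessing

* **Detection filter** — a probe is kept iff its detection p-value is
  <= alpha (default 0.01) in at least one sample; probes undetected in
  *all* samples are removed. Requires a detection-p matrix; absent one,
  the stage must be skipped explicitly (deposited matrices are usually
  already filtered).
* **Normalization** — quantile normalization (each sample mapped onto
  the mean sorted profile, fractional ranks interpolated for ties).
  This deliberately stands in for platform-specific robust spline
  normalization, which belongs to the bead-array preprocessing tool;
  pre-normalized deposited values can be ingested directly instead.
* **IQR filter** — keep probes with across-sample interquartile range
  above a threshold (default 0.5 log2 units). Quartiles use linear
  interpolation between order statistics (R `quantile` type 7), fixed so
  counts are reproducible across environments.
* Filters preserve probe order and are idempotent.
* **Gene collapsing** — optional `max-iqr` mode keeps one probe per
  symbol (largest IQR). Default is per-probe analysis, since the
  original per-probe/per-gene choice in this kind of analysis is
  ambiguous; both modes are exposed.

Signature panels (intrinsic/PAM50, stromal) are mapped by
case-insensitive gene symbol on the detected matrix and are **not** IQR
filtered by default — variability filtering is part of the unselected
panel's definition, not of the biologically selected panels; a flag can
force it.

## Receptor-status calling

ER/ERBB2 status is called from the marker probe's expression across
samples by fitting a two-component univariate Gaussian mixture. The
threshold is the point between the component means where posterior
membership is 0.5 (closed-form root of the quadratic from equating
weighted component log-densities; midpoint fallback if the fitted
variances push both roots outside the inter-mean interval). A
bimodality guard — component means at least 1 log2 unit apart and both
weights >= 0.1 — must pass; otherwise every call is "indeterminate"
rather than forced. At least 6 samples are required for the fit.

## Synthetic cohorts

The generator realizes the variance-source model directly. Per gene of
class c, pair i in group gamma, member j:

```
x_gij = mu_g + h_gi + g_gi[j] + t_gi[j] + eps_gij
```

* `h ~ N(0, var_host)` — shared by both members always (same patient);
* `g ~ N(0, var_genetic)` — one draw per pair in LRC (shared clonal
  origin), independent per member in SBC/MBC;
* `t ~ N(0, var_time)` — one draw per pair in SBC (no elapsed time),
  independent per member in MBC/LRC. The unshared time term is drawn
  for *both* members rather than only the later lesion: members stay
  exchangeable and the closed form below is exact;
* `eps ~ N(0, var_noise)` iid; a hook accepts a heavier-tailed sampler
  (scaled to unit variance) for robustness checks only.

All components are normal so that the population ICC has the closed
form shared/total:

```
ICC_pop(gamma) = (var_host + var_genetic*[genetic shared in gamma]
                  + var_time*[time shared in gamma]) / total variance.
```

Defaults: var_host = 0.1, var_genetic = 0.5, var_time = 0.3, var_noise
= 0.2 (log2 units squared), 2000 genes per class, pair counts 18 SBC /
11 MBC / 10 LRC matching the bilateral/recurrence case series the model
emulates. The intrinsic-like class sets var_time = 0 (genotype-driven),
the stromal-like class var_genetic = 0 (host-driven). The relative
sizes of genetic vs. time variance are not quantified anywhere for real
tumors; the defaults are illustrative, ordered so genetic variability
dominates for unselected genes, and produce population ICCs of
0.545 / 0.364 / 0.091 (LRC/SBC/MBC) for the background class. Baseline
expression mu_g is uniform on [6, 12] log2 units — a realistic array
dynamic range that exercises the IQR filter; ICC is location-invariant,
so the choice does not affect estimates. Genes flagged `undetected` get
detection p = 0.5 in every sample (else 0): a deliberately minimal rule
that exercises the detection filter without modeling bead-level signal.

Reproducibility: gene i draws from the substream
`SeedSequence(seed, spawn_key=(i,))` with a fixed draw order (mu, then
host/genetic/time/noise per group in SBC, MBC, LRC order), so a gene's
values are independent of the total gene count and identical configs
give bitwise-identical cohorts.

### What the simulator does and does not emulate

It reproduces the sharing structure, additive normal variance sources,
realistic dynamic range, and a detection flag. It does **not** model
probe-level bead effects, mechanistic detection p-values, batch or
array effects, correlated genes (all genes are independent draws),
copy-number-driven expression, or asymmetry between primary and later
lesion. Passing tests therefore demonstrate estimator and pipeline
correctness under the stated model — not that real cohorts satisfy the
model; on real data the group comparisons carry the gene-correlation
caveat above.

## Problem sizes and tolerances in tests

Monte-Carlo checks run at 2000 genes with the default pair counts
(median recovery within 0.05 of the closed form) and at 5000 genes with
200 pairs per group (within 0.02). The SBC/MBC overlap property for
time-free genes is checked over 40 seeded replicates of 400 genes,
asserting non-significance at alpha = 0.01 in at least 95% of
replicates. Estimator equivalence uses 100 random 5–30-pair tables
against a naive direct mean-squares reference (1e-10) and pingouin's
ICC(A,1) (1e-9, its printed precision path). These sizes were chosen to
make the checks statistically decisive while keeping the suite fast.

## Known limitations

* Quantile normalization is a stand-in, not a reimplementation of
  robust spline normalization; exact probe counts on deposited data are
  only expected to match when pre-normalized values are ingested.
* One-way ANOVA / t-tests over per-gene ICCs ignore inter-gene
  correlation (see above).
* Only balanced two-member designs are supported: no confidence
  intervals, no >2 lesions per patient, no missing members.
* The bimodality guard for receptor calling is a heuristic; strongly
  skewed unimodal distributions with a long shoulder can pass it.
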