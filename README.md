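# pairdissect

Dissecting intra-pair gene-expression variability in paired breast
tumors into a **tumor genetic background** component and a
**time / microenvironment** component.

## The problem

Tumor pairs from the same patient come in three flavors that differ in
*what* they share:

| group | pair | shares genetic background? | shares time/microenvironment? |
|-------|------|---------------------------|-------------------------------|
| SBC | synchronous bilateral tumors (diagnosed within 6 months) | no (distinct primaries) | yes (same moment, same host state) |
| MBC | metachronous bilateral tumors (> 6 months apart) | no | no |
| LRC | primary + its local recurrence | yes (common clonal origin) | no |

If a gene's expression is driven by the tumor's genotype, its two
measurements should agree within LRC pairs but not within bilateral
pairs; if it is driven by the host and the elapsed time, SBC pairs
should agree and MBC/LRC pairs should not. Comparing per-gene intra-pair
agreement across the three groups therefore separates the two sources of
variability — without ever having to designate a "first" and "second"
tumor.

## The statistic

For each gene, the n pairs of a group form an n x 2 table (patients x
pair members). A two-way crossed ANOVA gives mean squares
MS_patients, MS_members, MS_residual, method-of-moments variance
estimates

```
sigma2_patients = (MS_patients - MS_residual) / 2
sigma2_members  = (MS_members  - MS_residual) / n
sigma2_residual =  MS_residual
```

and the **agreement intraclass correlation coefficient** (the
single-rater absolute-agreement ICC, ICC(A,1)):

```
ICC = sigma2_patients / (sigma2_patients + sigma2_members + sigma2_residual)
```

Components are not truncated at zero, so the ICC can be negative.
Per-gene ICC distributions of the three groups are compared with a
one-way ANOVA and pairwise Welch t-tests, on three gene panels:
biologically unselected probes passing an IQR > 0.5 variability filter,
an intrinsic / PAM50-style panel (genotype-driven genes), and a
stromal panel (host/microenvironment-driven genes).

## The simulator

Because the full analysis needs cohort-scale data, the package ships a
generative model: per gene, `x = mu + host + genetic + time + noise`,
where the host term is always shared within a pair, the genetic term is
shared only in LRC, and the time term is shared only in SBC. The
closed-form population ICC (shared variance / total variance) lets every
estimator and pipeline stage be checked against ground truth.

## Worked example

```python
import numpy as np
import pairdissect as pdx

# paired-tumor table for one gene: 3 patients x 2 tumors
vc = pdx.anova_decompose(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
print(f"MS patients={vc.ms_patients:.2f}  MS members={vc.ms_members:.2f}  "
      f"MS residual={vc.ms_residual:.2f}")
print(f"agreement ICC = {pdx.icc_agreement(vc):.4f}")

cohort = pdx.simulate_cohort(pdx.default_config(seed=1))
report = pdx.run_dissection(
    cohort.matrix, cohort.design,
    [pdx.class_signature(cohort, "intrinsic-like"),
     pdx.class_signature(cohort, "stromal-like")],
    pdx.DissectionConfig(iqr_threshold=0.5),
)
for panel, comp in report.panels.items():
    med = {g: round(v, 3) for g, v in comp.median_icc.items()}
    print(f"{panel:15s} median ICC {med}  ANOVA p={comp.anova_p:.2e}")
```

prints

```
MS patients=8.00  MS members=1.50  MS residual=0.00
agreement ICC = 0.8889
unselected_IQR  median ICC {'SBC': 0.386, 'MBC': 0.125, 'LRC': 0.529}  ANOVA p=0.00e+00
intrinsic-like  median ICC {'SBC': 0.124, 'MBC': 0.123, 'LRC': 0.751}  ANOVA p=0.00e+00
stromal-like    median ICC {'SBC': 0.667, 'MBC': 0.178, 'LRC': 0.164}  ANOVA p=0.00e+00
```

The single-gene table has strong between-patient spread and a constant
member offset, hence an ICC near (but below) 1. On the simulated cohort
the three expected patterns appear: unselected genes rank
LRC > SBC > MBC; intrinsic-like genes (no time variance) make SBC and
MBC indistinguishable while LRC rises; stromal-like genes (no genetic
variance) pull MBC and LRC down and leave SBC high.

Real data enter through `pairdissect.read_expression` (plain TSV or GEO
series-matrix text), a pair-design TSV
(`patient_id  group  member1_sample  member2_sample`) and signature
files (one symbol per line, or GMT); the packaged `PAM50` list is
resolvable by name. The same pipeline is available from the shell:

```bash
pairdissect simulate --seed 1 --out cohort/
pairdissect dissect --matrix cohort/expression.tsv --design cohort/design.tsv \
    --annotation cohort/annotation.tsv --signature PAM50 --out report/
```

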