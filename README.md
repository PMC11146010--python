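# subloc — subcytoplasmic mRNA localization analysis

`subloc` assigns mRNAs to three cytoplasmic compartments — TIS granules
(TGs, a condensate network formed by the RNA-binding protein TIS11B),
the rough endoplasmic reticulum (ER), and the soluble cytosol — from
fractionation RNA-seq, and dissects the *combinatorial code* of 3′ UTR-bound
RNA-binding proteins (RBPs) and mRNA architecture that predicts where a
transcript goes.  It is aimed at transcriptomics researchers studying mRNA
localization in non-polarized cells who have compartment-fractionated
expression tables, CLIP peak counts, and/or smFISH images.

## The model

For each gene the **localization score** in compartment *c* is

```
LS_c = mean RPKM_c / (mean RPKM_TG + mean RPKM_ER + mean RPKM_CY)
```

so the three scores are the fractions of the gene's cytoplasmic transcripts
in each compartment and sum to 1.  A non-membrane gene is called
**compartment-enriched** (TG+/ER+/CY+) when LS_c ≥ 1.25 × median(LS_c); if
two compartments pass, the higher score wins; otherwise the gene is
*unbiased*.  Membrane/secretory genes are called on the ER/TG score ratio
(> 1.25 ER, < 0.8 TG) and the cytosolic score (> 0.36 CY) instead.

The combinatorial code is a multinomial logit with *unbiased* as the base
class,

```
log P(class k | x) / P(unbiased | x) = β_k0 + β_kᵀ x
```

where `x` collects sqrt-transformed, standardized 3′ UTR CLIP peak counts of
seven RBPs (TIS11B, HuR, PUM2, HNRNPC, TIA1/L1, LARP4B, METAP2) plus mRNA
length and mean CDS exon length.  Coefficients come with Wald standard
errors and t-statistics; per-gene *propensities* are the fitted log-odds.

Additional stages quantify knockout localization shifts (two-compartment
score ER/(ER+CY), top-quantile shifts intersected with the TG+ set), smFISH
foci colocalization against compartment masks (prominence-filtered local
maxima, Mann-Whitney test against compartment-size expectations), digitonin
retention fractions, and Pro-seq/RNA-seq relative decay scores.

A fully seeded synthetic-data module generates every input with recorded
ground truth, so the complete pipeline can be exercised without downloads.

## Worked example

```python
import pandas as pd
from subloc import synth, localization, clip, code

expr, truth = synth.simulate_expression(n_genes=2000, seed=1)
ls = localization.localization_scores(expr)          # LS per gene, rows sum to 1
calls = localization.classify_nonmembrane(ls)        # TG+/ER+/CY+/unbiased
print(calls["label"].value_counts().to_dict())
# {'CY_plus': 618, 'TG_plus': 596, 'ER_plus': 555, 'unbiased': 231}

peaks = synth.simulate_clip(truth, seed=1)           # 3' UTR CLIP peak counts
sl = clip.shortlist_rbps(clip.median_targets(peaks),
                         pd.DataFrame({"label": truth.genes["true_label"]}))
print(sl.loc[["TIS11B", "TIA1/L1", "LARP4B"],
             ["ratio_TG_plus", "ratio_ER_plus", "ratio_CY_plus"]].round(2))
#          ratio_TG_plus  ratio_ER_plus  ratio_CY_plus
# TIS11B            1.81           0.79           0.79
# TIA1/L1           0.90           1.67           0.94
# LARP4B            0.77           0.83           1.67

res = code.LocalizationCode.from_tables(peaks, truth.genes, calls).fit()
print(res.params.loc[:, ["TIS11B", "TIA1/L1"]].round(2))
#          TIS11B  TIA1/L1
# TG_plus    0.83    -0.13
# ER_plus    0.03     0.32
# CY_plus   -0.06    -0.19
```

Reading the output: the observed/expected target ratios show each planted
regulator enriched in its own compartment (TIS11B among TG+ mRNAs, TIA1/L1
among ER+, LARP4B among CY+, all above the 1.5 short-listing cut), and the
fitted code recovers the same structure as signed log-odds: a gene one
standard deviation higher in sqrt TIS11B peak count has e^0.83 ≈ 2.3-fold
higher odds of being TG+ rather than unbiased.

The same stages are available from the shell: `subloc synth`, `subloc gate`,
`subloc score`, `subloc classify`, `subloc rbp-targets`, `subloc
rbp-shortlist`, `subloc fit-code`, `subloc ko-shift`, `subloc fish`.

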