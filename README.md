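# tfdosage

Analysis pipeline for **graded CRISPRi/CRISPRa Perturb-seq**: how gradual
modulation of a transcription factor's dosage propagates to the expression
of its downstream (*trans*) genes.

In this experimental design, a library of single guide RNAs — TSS-targeting,
TSS-tiling, mismatch-attenuated, enhancer-targeting, and non-targeting
controls (NTCs) — is delivered to cells carrying either a CRISPR
interference (dCas9-repressor) or activation (dCas9-activator) system. Each
guide realizes a different *cis*-gene dosage, and targeted single-cell
RNA-seq reads out the response of a panel of trans genes. The pipeline
takes the processed UMI matrices from such a screen (or from its bundled,
fully seeded synthetic-data generator) through:

1. **Preprocessing** — cell QC (≥500 UMIs, ≥50 detected genes, top-1%
   depth trim), per-guide Gaussian-mixture guide calling, single-guide
   filtering, marker-transcript modality assignment with 5% trims, and
   log1p library-size normalization.
2. **Pseudo-bulk fold changes** — NTC off-target screening by all-pairs
   differential testing, then per-(guide, modality, gene)
   `logfc = ln(mean expr in guide cells) − ln(mean expr in NTC cells)`
   with Wilcoxon rank-sum p-values and global Benjamini–Hochberg FDR.
3. **Dose-response modelling** — for each trans gene, its log2 fold change
   *y* as a function of the cis gene's log2 fold change *x* under three
   models: linear, the four-parameter logistic (4PL)

   *y* = *c* + (*d* − *c*) / (1 + exp(*b*(*x* − *a*)))

   with lower/upper asymptotes *c*, *d*, inflection location *a* and shape
   *b* (negative *b* encodes an increasing curve), and LOESS for
   non-monotonic responses. Nonlinearity is scored by
   ΔAIC = AIC(linear) − AIC(sigmoid); responsiveness by z-tests on
   10-fold-CV parameter estimates; non-monotonicity by the within-network
   top-5% of ΔRMSE = RMSE(sigmoid) − RMSE(LOESS) with an automated
   curve-reversal confirmation.
4. **Downstream analyses** — hierarchical clustering of predicted
   responses on a common dosage grid, Wilcoxon/Pearson association of
   sigmoid parameters with gene annotations (housekeeping, constraint
   scores, …), Fisher-exact enrichment of nonlinear responses in
   disease/GWAS gene sets, perturbation-profile correlation with cell-type
   expression states, and cis-determinant analyses of guide efficacy
   (distance-to-TSS trend, chromatin-peak overlap).

The synthetic generator emulates the full study design — 96 guides over
four cis genes (one a negative control), two modalities, ~80 cells per
guide, negative-binomial UMI counts — and exports its ground truth, so
every estimator is testable without any external data.

## Worked example

`examples/03_dose_response.py` simulates one trans gene from a known
increasing sigmoid (a=−0.2, b=−5, c=−0.1, d=0.8; 90 guides, noise SD 0.1)
and fits it:

```
sigmoid fit: a=-0.230 b=-5.956 c=-0.093 d=0.760
CV means:    a=-0.230, b=-5.964, c=-0.093, d=0.760, range=0.853
held-out Pearson r = 0.964 over 10 folds
dAIC (linear - sigmoid) = 85.2 (positive favours the sigmoid)
dRMSE (sigmoid - LOESS) = -0.0043 (near zero: the response is monotone)
```

The fitted parameters recover the truth to within the noise level; the
strongly positive ΔAIC says a line cannot capture the plateau-cliff-plateau
shape; the near-zero ΔRMSE says LOESS finds no reversal, so the response
is monotone. The grid predictions then interpolate the trans response at
unmeasured dosages such as one cis copy lost (x = −1) or gained
(x = +0.585).

The other examples cover dataset generation (`01`), fold-change estimation
with the NTC off-target screen (`02`), and the five-stage pipeline with
exact attrition accounting (`04`). The same pipeline is available from a
shell:

```bash
tfdosage run --out results/ --seed 7
tfdosage simulate --out data/ --seed 7     # dataset only
```

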