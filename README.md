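# panelest

Data-driven design of targeted gene panels for estimating exome-wide
mutation biomarkers — tumour mutation burden (TMB) and tumour indel
burden (TIB) — from a small, budgeted subset of the exome.

## The problem

TMB (the total number of non-synonymous somatic mutations in a tumour
exome) and TIB (the number of frameshift indels) predict response to
immune checkpoint blockade, but measuring them exactly requires
whole-exome sequencing. Targeted panels sequence only a subset of genes
at a cost roughly proportional to the panel's total coding length, so
the practical question is: *which* genes should a panel of a given
length contain, and how should their mutation counts be combined into a
biomarker estimate?

`panelest` answers both with a generative model of mutation counts. It
is written for statistical genomicists and panel designers working from
annotated somatic calls (MAF-style files) plus a gene-length table.

## The model and estimator

Counts $M_{igs}$ (sample $i$, gene $g$, variant group $s$) are
independent Poisson with log-rate

$$\log \phi_{igs} = \mu_i + \log \ell_g + \lambda_g + \nu_s + \eta_{gs},$$

where $\mu_i$ is the sample's log background mutation rate, $\ell_g$
the gene's coding length, and $\lambda_g, \eta_{gs}$ sparse gene and
gene-by-group effects fitted under an $\ell_1$ penalty
$\kappa_1(\sum_g|\lambda_g| + \sum_{g,s}|\eta_{gs}|)$ with cell-wise
10-fold cross-validation for $\kappa_1$.

A biomarker $T=\sum_{g}\sum_{s\in\bar S} M_{0gs}$ (all non-synonymous
groups for TMB, the indel group for TIB) is estimated by a weighted
count $T(w)=\sum_{g,s} w_{gs} M_{0gs}$. The weights minimise a
rescaled model-based expected squared error

$$f(w)=\sum_{g,s\in\bar S} p_{gs}(1-w_{gs})^2
     + \sum_{g,s\notin\bar S} p_{gs}w_{gs}^2
     + K\Big(1-\sum_{g,s}p_{gs}w_{gs}\Big)^2,$$

with normalised rates $p_{gs}\propto\ell_g e^{\hat\lambda_g+\hat\nu_s+\hat\eta_{gs}}$
and bias penalty $K$, plus a length-weighted group-lasso penalty
$\kappa_2\sum_g \ell_g \lVert w_g\rVert_2$ that zeroes whole genes. The
genes with non-zero weight rows form the panel; $\kappa_2$ is walked
along a path to hit a length budget $L$, and the weights are refitted
on the selected support in closed form. Panels can also be augmented
(mandatory genes escape the penalty) or have genes excluded. Heuristic
$(1-\alpha)$ prediction intervals come from Markov's inequality,
$\hat T \pm \sqrt{\widehat{\mathrm{MSE}}/\alpha}$.

## Worked example

`examples/` holds one short script per capability. From
`examples/03_predict_with_intervals.py` (150 training samples, 300
genes, 10%-of-exome budget):

```
panel: 18 genes (0.032 Mb)
R^2 on 400 fresh samples: 0.970
sample T0000: TMB-hat = 104, 90% interval [10, 198], true = 142
empirical coverage at alpha = 0.1: 98.5% (Markov bound guarantees >= 90% under the model)
```

The panel uses a tenth of the exome yet explains 97% of the variance in
TMB on unseen samples, and the conservative Markov intervals cover the
truth more often than their nominal 90%. Baselines for the same panel
(`examples/04_compare_estimators.py`): naive length-rescaled counting
reaches only $R^2 = 0.59$ — it over-estimates because selection favours
highly mutated genes — while the refitted weighted estimator corrects
that bias.

A thin CLI mirrors the pipeline stages:

```sh
panelest simulate --n-samples 200 --n-genes 500 --seed 1 --out cohort/
panelest fit --maf cohort/cohort.maf --gene-lengths cohort/gene_lengths.tsv --out fit/
panelest select-panel --maf cohort/cohort.maf --gene-lengths cohort/gene_lengths.tsv \
    --params fit/params.json --biomarker tmb --budget-mb 0.08 --out panel/
```

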