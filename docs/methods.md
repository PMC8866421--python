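# Methods

## Generative model

Mutation counts are modelled cell-wise: for sample $i$, gene $g$ and
variant group $s$,

$$M_{igs} \sim \mathrm{Poisson}(\phi_{igs}), \qquad
\log \phi_{igs} = \mu_i + \log \ell_g + \lambda_g + \nu_s + \eta_{gs},$$

with all cells independent. $\mu_i$ is the sample's background
mutation rate (BMR) on the log scale — tumours differ in mutagenic
exposure by orders of magnitude, so $\mu_i$ is per-sample and
unpenalised. The offset $\log \ell_g$ encodes the default assumption
that a gene collects mutations in proportion to its coding length;
$\lambda_g$ is the gene's departure from that (selection, chromatin
context), $\nu_s$ a global variant-group abundance, and $\eta_{gs}$ a
gene-specific group effect (e.g. a gene intolerant of frameshifts).
Most genes mutate at the background rate, so $\lambda$ and $\eta$ are
fitted under an $\ell_1$ penalty $\kappa_1$ and are sparse: a zero is
an explicit statement that the gene is background-like.

Identifiability: the model fixes $\eta_{g,s_1}=0$ for a reference
group $s_1$ (here: the non-indel group). Because neither $\mu$ nor
$\nu$ is penalised, adding a constant to every $\mu_i$ and subtracting
it from every $\nu_s$ would not change the fit, so we additionally pin
$\nu_{s_1}=0$ and let the global level live in $\mu$. Neither
convention changes any fitted rate.

By default raw variant classifications collapse to two groups —
`indel` (frameshift insertions/deletions) and `other` (the remaining
non-synonymous classes: missense, nonsense, splice site, in-frame
indels, nonstop, translation start site). Synonymous and non-coding
classes map to an excluded sentinel and never enter the model. In-frame
indels sit in `other` because TIB is defined by frameshift events; the
grouping is a plain mapping and can be reconfigured.

## Fitting

The penalised objective is the Poisson negative log-likelihood plus
$\kappa_1(\sum_g |\lambda_g| + \sum_{g,s}|\eta_{gs}|)$. Holding the
other blocks fixed, the partial objective of any single block
coordinate is $A e^x - Bx\,(+\,\kappa_1|x|)$ with $A$ the accumulated
rate mass and $B$ the count mass, whose exact minimiser is a log ratio
($x=\log(B/A)$), soft-thresholded for the penalised blocks: $x=0$
whenever $|B-A|\le\kappa_1$, else $x=\log((B\mp\kappa_1)/A)$. Since
$\mu_i$ are mutually independent given the rest (likewise $\nu_s$,
$\lambda_g$, $\eta_{gs}$), block coordinate descent over the four
blocks with these closed-form updates minimises each block exactly,
decreases the objective monotonically, and converges on the convex
problem. Updates vectorise over the whole block, so a sweep costs
$O(n|G||S|)$. Convergence: relative objective change below 1e-8, cap
500 sweeps. Samples with no observed mutations would drive
$\mu_i\to-\infty$; they are floored at $-30$ (rate effectively zero)
with a warning. Zeros from the soft threshold are exact, never merely
small.

$\kappa_1$ is chosen by cell-wise 10-fold cross-validation: the
$n|G||S|$ cells (not the samples) are partitioned uniformly at random,
each fold's complement is fitted along a decreasing log-spaced
$\kappa_1$ grid with warm starts, and held-out Poisson deviance
$2\sum[m\log(m/\hat\phi)-(m-\hat\phi)]$ (with $0\log 0=0$ and
$\hat\phi$ floored at 1e-12) is averaged per grid point; the minimiser
wins, ties to the larger (sparser) value. The default grid has 50
points spanning four decades down from the full-shrinkage threshold —
the largest count/rate gap at the null fit, above which every
penalised coordinate is zero. Desk-scale runs in the tests and
acceptance script use 25 points over three decades, which bracket the
selected value comfortably at those problem sizes.

## Estimator and panel selection

With fitted rates, the weighted count $T(w)=\sum w_{gs}M_{0gs}$ has a
model expected squared error that rescales to

$$f(w)=\textstyle\sum_{g,s\in\bar S} p_{gs}(1-w_{gs})^2
 + \sum_{g,s\notin\bar S} p_{gs}w_{gs}^2
 + K\big(1-\sum_{g,s}p_{gs}w_{gs}\big)^2,$$

where $p_{gs}$ are the fitted per-cell rates normalised so the target
groups sum to one (computed with log-sum-exp; independent of $\mu$),
and $K=K(\mu_0)=e^{\mu_0}\sum_{g,s\in\bar S}\ell_g
e^{\hat\lambda_g+\hat\nu_s+\hat\eta_{gs}}$ weights the squared-bias
term. The default anchors $\mu_0$ at the largest training pseudo-MLE
$\hat\mu_i=\log(T_i/\sum_{g,s\in\bar S}\ell_g e^{\hat\lambda+\hat\nu+\hat\eta})$,
so bias is penalised at the scale of the most heavily mutated samples;
$K=\infty$ requests exact model-unbiasedness (handled only in the
refit, where it is a hard constraint). The pseudo-MLE denominator sums
over the target groups $\bar S$, which makes the round-trip identity
exact — the model's expected biomarker at $\hat\mu_i$ equals $T_i$;
zero-burden samples are floored at 0.5 counts before the log (they
never attain the maximum that sets $K$).

The first fit minimises $f(w)+\kappa_2\sum_{g\notin P_0}\ell_g\lVert
w_g\rVert_2$ over $w_g=0$ for $g\in Q_0$, where $P_0$/$Q_0$ are
mandatory/forbidden gene sets (both empty for de-novo design). The
length weights make the penalty track sequencing cost; zeroing a whole
row removes the gene from the panel. The smooth part is a quadratic
with Hessian $2\,\mathrm{diag}(p)+2Kpp^\top$, so FISTA with the exact
group soft-threshold prox costs $O(|G||S|)$ per iteration with
Lipschitz constant $2\max p + 2K\lVert p\rVert^2$. Stopping is on the
relative first-order (KKT) residual (target 1e-8; tight runs can
request 1e-10): objective-change criteria alone leave a residual of
order $\sqrt{2L\,\Delta f}$. When the objective is numerically
exhausted but the residual is acceptable (below 1e-3 relative — the
regime of ill-conditioned tiny-rate coordinates that cannot be
polished past double precision) the solution is accepted; a genuinely
unconverged solve raises an error carrying the residual. Row norms
below 1e-10 of the largest are solver dust at the shrinkage boundary
and are snapped to exact zeros. The objective is strictly convex
($\mathrm{diag}(p)\succ 0$), so the solution is unique regardless of
start.

The refit on a selected panel is closed-form via Sherman–Morrison:
on the support, $w_{gs}=t_{gs}+K(1-c)/(1+K\sigma)$ with $t$ the
target-group indicator, $c$ the support's target-rate mass and
$\sigma$ its total rate mass; the $K=\infty$ limit $w=t+(1-c)/\sigma$
enforces $\sum p_{gs}w_{gs}=1$ exactly. Refitting can only lower $f$
on the same support.

A length budget $L$ maps to $\kappa_2$ by walking a log-spaced grid
(default 100 points over four decades, starting just above the
full-shrinkage bound $\max_g \lVert\nabla_g f(0)\rVert_2/\ell_g$) from
large to small with warm starts. Reported panel lengths take the
running maximum so a non-monotone wobble cannot flip the selection;
the chosen point has the largest reported length within $L$, ties
resolved toward the larger $\kappa_2$ (sparsest weights). Mandatory
genes count toward the panel and its length even when their fitted
weight is zero — they are sequenced regardless.

## Prediction intervals

For a new sample, $\mathrm{MSE}(w,\mu_0)=\sum_{\bar S}(1-w)^2\phi +
\sum_{S\setminus\bar S}w^2\phi + (\sum_S w\phi-\sum_{\bar S}\phi)^2$
is evaluated at plug-in parameters with $\mu_0$ replaced by the
pseudo-MLE implied by the point estimate itself. Markov's inequality
gives $P(|\hat T-T|^2\ge \mathrm{MSE}/\alpha)\le\alpha$, hence the
interval $\hat T\pm\sqrt{\mathrm{MSE}/\alpha}$, truncated below at
zero because burdens are counts. These are deliberately heuristic and
conservative: empirical coverage on model-generated cohorts runs well
above the nominal level (~98% at $\alpha=0.1$ in the acceptance run).

## Evaluation

$R^2 = 1-\sum(t_i-\hat t_i)^2/\sum(t_i-\bar t)^2$ (unbounded below).
High/low classification uses the clinical cutoffs — high TMB at
$\ge 300$ exome mutations, high TIB at $\ge 10$ indels, inclusive —
and is scored by the area under the precision-recall curve swept over
the rule "score $\ge t$": thresholds at the distinct scores, tied
scores flipping together, points with zero predicted positives dropped
(their precision is 0/0), area by right-continuous step integration in
recall. A perfect ranking scores 1; a random one averages the
prevalence up to a small positive finite-sample bias of step-integrated
average precision (about +0.02 at 47 positives of 171). ROC AUC
delegates to scikit-learn (it equals the normalised Mann–Whitney
statistic). Baselines: the count estimator
$(\ell_G/\ell_P)\sum_{g\in P,s\in\bar S}M_{0gs}$; for TIB, the same
scaling times the training-set indel fraction applied to all-group
panel counts; and OLS of the biomarker on per-gene summed panel counts
(minimum-norm with a warning when rank-deficient).

## Synthetic cohorts

The generator instantiates the generative model itself, so pipeline
closure is testable end to end: gene coding lengths are log-normal
(median ~1.3 kb, log-sd 0.6); $\mu_i$ is normal on the log scale with
spread 1.0, giving the heavy-tailed, orders-of-magnitude burden range
seen in real exome cohorts; $\lambda$ and $\eta$ are sparse (5%
non-zero at magnitude 1.0 by default, random sign); and the indel
offset $\nu$ and the centre of the $\mu$ law are solved analytically
so the cohort's expected mean TMB and TIB are 252 and 9.25 — the
training averages of the NSCLC cohort the defaults emulate. The
default scale is n = 200 samples by 500 genes, chosen so a full
cross-validated fit runs in seconds; a `wes_scale()` profile
(n = 800, 17,358 genes, the size of a full whole-exome study) exists
but takes far longer and is not used in the test suite.

What the generator does *not* emulate: mutational signatures and
trinucleotide context, copy number, overdispersion beyond Poisson,
inter-gene correlation, and study effects. Passing tests therefore
certify the estimator under its own model assumptions — correct
optimisation, recovery, coverage and closure — not robustness to the
ways real tumours violate them; on real data the model is misspecified
and performance should be validated on held-out samples as in the
examples.

## Known limitations

- The Markov intervals are not exact $(1-\alpha)$ intervals; they are
  conservative under the model and heuristic off it.
- Exact length-constrained subset selection is non-convex; the
  group-lasso relaxation plus grid walk can land strictly under the
  budget, and panel composition near the budget boundary depends on
  the grid resolution.
- The count tensor is dense; cohorts far beyond whole-exome study
  scale would need a sparse representation.
- With a single variant group the $\eta$ block is empty and TIB-style
  biomarkers are unavailable by construction.
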