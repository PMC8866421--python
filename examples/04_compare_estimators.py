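"""Compare the refitted estimator with count and linear baselines.

On the same selected panel, scores four predictors of TMB: the refitted
weighted-count estimator, the naive length-rescaled count estimator and
an OLS regression on per-gene panel counts; for TIB, the indel-fraction
count baseline.  Metrics: R^2, area under the precision-recall curve
(high class: TMB >= 300 or TIB >= 10) and ROC AUC.
"""

import panelest as pe
from panelest.pipeline import design_panel

cfg = pe.SyntheticConfig(n_samples=150, n_genes=300, seed=41)
params, lengths = pe.sample_params(cfg)
train = pe.sample_counts(params, lengths, seed=42)
catalog = pe.VariantCatalog()
spec = pe.tmb_spec(catalog)

design = design_panel(train, lengths, spec, 0.10 * lengths.total_length,
                      fit_config=pe.FitConfig(seed=43, n_grid=15,
                                              grid_decades=2.5))
panel = design.model.panel
test = pe.draw_test_cohort(params, lengths, cfg, n_test=400, seed=44)
truth = pe.biomarker_values(test, spec)
train_T = pe.biomarker_values(train, spec)

predictors = {
    "refitted T-hat": pe.predict(design.model, test),
    "count (l_G/l_P scaling)": pe.count_estimator(test, panel, lengths, spec),
    "linear (OLS on panel counts)":
        pe.linear_baseline(train, train_T, panel).predict(test),
}
print(f"panel {panel.total_length/1e6:.3f} Mb; test n = {len(truth)}")
print(f"{'model':<28}{'R^2':>8}{'AUPRC':>8}{'AUROC':>8}")
for name, est in predictors.items():
    res = pe.evaluate(truth, est, spec)
    print(f"{name:<28}{res.r2:>8.3f}{res.auprc:>8.3f}{res.auroc:>8.3f}")

tib = pe.tib_spec(catalog)
tib_truth = pe.biomarker_values(test, tib)
tib_count = pe.tib_count_estimator(test, train, panel, lengths)
print(f"\nTIB count baseline R^2: {pe.r_squared(tib_truth, tib_count):.3f} "
      "(scaled by the training indel fraction; typically poor, as the "
      "panel over-represents highly mutated genes)")
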