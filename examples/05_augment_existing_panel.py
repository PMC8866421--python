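"""Augment a predetermined gene panel to a larger length budget.

Genes already on a panel (P0) cost nothing extra to keep, so they are
excluded from the group-lasso penalty and always remain; the optimizer
spends the remaining budget on additional informative genes.  Genes that
must stay off the panel (Q0) are constrained to zero weight.
"""

import panelest as pe
from panelest.pipeline import design_panel

cfg = pe.SyntheticConfig(n_samples=120, n_genes=300, seed=51)
params, lengths = pe.sample_params(cfg)
train = pe.sample_counts(params, lengths, seed=52)
spec = pe.tmb_spec(pe.VariantCatalog())
fit_config = pe.FitConfig(seed=53, n_grid=15, grid_decades=2.5)

# a predetermined 10-gene panel, e.g. chosen for known cancer relevance
base = pe.Panel.from_genes(lengths.genes[:10], lengths)
blocked = pe.Panel.from_genes(lengths.genes[290:], lengths)
budget = base.total_length + 0.05 * lengths.total_length

design = design_panel(train, lengths, spec, budget, fit_config=fit_config,
                      include=base, exclude=blocked)
panel = design.model.panel
added = [g for g in panel.genes if g not in base]

print(f"base panel: {len(base)} genes, {base.total_length/1e6:.3f} Mb")
print(f"augmented to {len(panel)} genes, {panel.total_length/1e6:.3f} Mb "
      f"(budget {budget/1e6:.3f} Mb); {len(added)} genes added")
assert all(g in panel for g in base.genes)
assert not any(g in panel for g in blocked.genes)

test = pe.draw_test_cohort(params, lengths, cfg, n_test=300, seed=54)
truth = pe.biomarker_values(test, spec)
base_design = design_panel(train, lengths, spec, base.total_length + 1,
                           params=design.params, fit_config=fit_config,
                           include=base)
r2_base = pe.r_squared(truth, pe.predict(base_design.model, test))
r2_aug = pe.r_squared(truth, pe.predict(design.model, test))
print(f"R^2 with the base panel alone: {r2_base:.3f}; "
      f"after augmentation: {r2_aug:.3f}")
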