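import numpy as np
import pytest

import panelest as pe
from panelest.pipeline import design_panel


@pytest.fixture
def variant_catalog():
    return pe.VariantCatalog()


@pytest.fixture
def tiny_genes():
    return pe.GeneCatalog(("g1", "g2", "g3"), np.array([100.0, 200.0, 300.0]))


@pytest.fixture
def three_row_maf(tmp_path):
    """Two missense and one frameshift call in one sample."""
    path = tmp_path / "three.maf"
    path.write_text(
        "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
        "g1\tS1\tMissense_Mutation\n"
        "g1\tS1\tMissense_Mutation\n"
        "g1\tS1\tFrame_Shift_Del\n"
    )
    return path


def small_instance(n=30, G=25, seed=0, **kw):
    """A quickly fittable synthetic scenario used across test modules."""
    cfg = pe.SyntheticConfig(n_samples=n, n_genes=G, seed=seed, **kw)
    params, lengths = pe.sample_params(cfg)
    tensor = pe.sample_counts(params, lengths, seed=seed + 1)
    return cfg, params, lengths, tensor


@pytest.fixture
def small_fit():
    cfg, params, lengths, tensor = small_instance(n=50, G=40, seed=5)
    fitted = pe.fit_penalized(tensor, lengths, kappa1=2.0)
    spec = pe.tmb_spec(pe.VariantCatalog())
    return params, lengths, tensor, fitted, spec


@pytest.fixture(scope="session")
def pipeline_run():
    """One full simulate -> CV fit -> select -> predict run, shared.

    Desk-scale study conditions: n = 200 training samples, 500 genes,
    two variant groups, mean TMB ~250 (high-burden regime), 5% non-zero
    gene effects of magnitude 1.  The panel budget is 10% of the exome.
    """
    cfg = pe.SyntheticConfig(seed=11)
    params, lengths = pe.sample_params(cfg)
    tensor = pe.sample_counts(params, lengths, seed=12)
    spec = pe.tmb_spec(pe.VariantCatalog())
    fit_config = pe.FitConfig(seed=13, n_grid=25, grid_decades=3.0)
    cv = pe.cross_validate_kappa1(tensor, lengths, fit_config)
    fitted = pe.fit_penalized(tensor, lengths, cv.selected_kappa1, fit_config)
    design = design_panel(tensor, lengths, spec,
                          budget=0.10 * lengths.total_length,
                          params=fitted, fit_config=fit_config)
    test = pe.draw_test_cohort(params, lengths, cfg, n_test=1000, seed=99)
    truth = pe.biomarker_values(test, spec)
    estimates = pe.predict(design.model, test)
    return {
        "config": cfg, "true_params": params, "lengths": lengths,
        "train": tensor, "spec": spec, "cv": cv, "fitted": fitted,
        "design": design, "test": test, "truth": truth,
        "estimates": estimates,
    }
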