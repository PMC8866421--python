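"""End-to-end orchestration: fit -> select -> refit -> estimator model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative_model import (CVResult, FitConfig, GenerativeParams,
                               cross_validate_kappa1, fit_penalized)
from .mutation_data import (BiomarkerSpec, CountTensor, GeneCatalog,
                            biomarker_values)
from .panel_selection import (NormalizedRates, Panel, WeightMatrix,
                              bias_penalty_K, kappa2_for_length,
                              normalized_rates, refit)
from .prediction import EstimatorModel, recommended_mu0


@dataclass(frozen=True)
class PanelDesign:
    """Everything produced by one panel-design run."""

    params: GenerativeParams
    cv: CVResult | None
    rates: NormalizedRates
    kappa2: float
    first_fit_weights: WeightMatrix
    model: EstimatorModel


def fit_generative_model(
    train: CountTensor,
    lengths: GeneCatalog,
    config: FitConfig | None = None,
    *,
    cross_validate: bool = True,
) -> tuple[GenerativeParams, CVResult | None]:
    """Fit the penalized Poisson model, choosing kappa1 by CV by default."""
    cfg = config or FitConfig()
    cv = None
    if cross_validate:
        cv = cross_validate_kappa1(train, lengths, cfg)
        kappa1 = cv.selected_kappa1
    else:
        if cfg.kappa1_grid is None or len(cfg.kappa1_grid) != 1:
            raise ValueError("without CV, supply a single-value kappa1 grid")
        kappa1 = float(cfg.kappa1_grid[0])
    params = fit_penalized(train, lengths, kappa1, cfg)
    return params, cv


def design_panel(
    train: CountTensor,
    lengths: GeneCatalog,
    spec: BiomarkerSpec,
    budget: float,
    *,
    params: GenerativeParams | None = None,
    fit_config: FitConfig | None = None,
    include: Panel | None = None,
    exclude: Panel | None = None,
    K: float | None = None,
    kappa2_grid: np.ndarray | None = None,
) -> PanelDesign:
    """Design a panel within a coding-length budget and build its estimator.

    If ``params`` is omitted the generative model is fit (with CV for
    kappa1) first.  ``K`` defaults to the recommended K(max mu-hat_i)
    anchored at the largest training pseudo-MLE; pass ``np.inf`` for the
    exactly-unbiased refit.
    """
    cv = None
    if params is None:
        params, cv = fit_generative_model(train, lengths, fit_config)
    rates = normalized_rates(params, lengths, spec)
    if K is None:
        train_T = biomarker_values(train, spec)
        K = bias_penalty_K(params, lengths, spec,
                           recommended_mu0(train_T, params, lengths, spec))
    rates_K = rates.with_K(K if np.isfinite(K) else np.inf)
    # the first fit needs a finite K; for the unbiased variant it is only
    # the refit that enforces the constraint exactly
    first_rates = rates_K if np.isfinite(K) else rates.with_K(1.0)
    kappa2, panel, w_first = kappa2_for_length(
        first_rates, lengths, budget, grid=kappa2_grid,
        include=include, exclude=exclude)
    w_refit = refit(rates_K, panel)
    model = EstimatorModel(weights=w_refit, rates=rates_K, params=params,
                           lengths=lengths, spec=spec, panel=panel)
    return PanelDesign(params=params, cv=cv, rates=rates_K, kappa2=kappa2,
                       first_fit_weights=w_first, model=model)
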