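"""Biomarker prediction from panel counts, with heuristic intervals.

The point estimate for a new sample is the weighted count
T-hat = sum_{g,s} w_gs M_0gs, which depends only on the panel genes.
Its model-based mean squared error decomposes into the Poisson variance
of the weighted count, the variance of the unobserved biomarker, their
covariance, and a squared bias term; plugging in fitted parameters and a
pseudo-MLE for the test sample's background rate gives an estimated MSE.
Markov's inequality then yields conservative (1 - alpha) prediction
intervals: P(|T-hat - T|^2 >= MSE/alpha) <= alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .generative_model import GenerativeParams
from .mutation_data import BiomarkerSpec, CountTensor, GeneCatalog
from .panel_selection import NormalizedRates, Panel, WeightMatrix

#: Zero-burden samples are floored at this count before the pseudo-MLE log.
ZERO_BURDEN_FLOOR = 0.5


@dataclass(frozen=True)
class EstimatorModel:
    """A fitted biomarker estimator: weights, rates, model and panel."""

    weights: WeightMatrix
    rates: NormalizedRates
    params: GenerativeParams
    lengths: GeneCatalog
    spec: BiomarkerSpec
    panel: Panel

    def __post_init__(self) -> None:
        outside = self.weights.support & np.array(
            [g not in self.panel for g in self.weights.genes])
        if outside.any():
            raise ValueError("weights supported outside the panel genes")


@dataclass(frozen=True)
class PredictionInterval:
    """A heuristic Markov-bound prediction interval for one sample."""

    estimate: float
    lower: float
    upper: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("interval must contain the estimate")

    def covers(self, truth: float) -> bool:
        return self.lower <= truth <= self.upper


def predict(model: EstimatorModel, test_counts: CountTensor) -> np.ndarray:
    """Per-sample weighted-count estimates T-hat = sum w_gs M_0gs."""
    for g in model.panel.genes:
        if g not in test_counts.genes:
            raise KeyError(f"test counts missing panel gene {g!r}")
    tg = {g: i for i, g in enumerate(test_counts.genes)}
    sidx = [test_counts.group_index(s) for s in model.weights.groups]
    # only panel genes carry weight, so restrict the contraction to them
    rows = np.flatnonzero(model.weights.support)
    if rows.size == 0:
        return np.zeros(test_counts.n_samples)
    test_rows = np.array([tg[model.weights.genes[r]] for r in rows])
    sub = test_counts.counts[:, test_rows][:, :, sidx].astype(float)
    return np.einsum("igs,gs->i", sub, model.weights.w[rows])


def expected_biomarker_mass(params: GenerativeParams, lengths: GeneCatalog,
                            spec: BiomarkerSpec) -> float:
    """sum_{g, s in Sbar} l_g exp(lam_g + nu_s + eta_gs): the expected
    biomarker for a sample with mu = 0."""
    mask = np.array([g in spec.target_groups for g in params.groups])
    log_q = (np.log(lengths.lengths)[:, None] + params.lam[:, None]
             + params.nu[None, :] + params.eta)
    amax = log_q[:, mask].max()
    return float(np.exp(amax) * np.exp(log_q[:, mask] - amax).sum())


def model_mse(w: WeightMatrix, params: GenerativeParams, lengths: GeneCatalog,
              spec: BiomarkerSpec, mu0: float) -> float:
    """Model-based expected squared error of T(w) at log-BMR mu0.

    E[(T(w) - T)^2] = sum_{Sbar} (1 - w)^2 phi + sum_{S\\Sbar} w^2 phi
                    + (sum_S w phi - sum_{Sbar} phi)^2,
    with phi_0gs = exp(mu0) l_g exp(lam_g + nu_s + eta_gs).
    """
    if not np.isfinite(mu0):
        raise ValueError("mu0 must be finite")
    log_phi = (mu0 + np.log(lengths.lengths)[:, None] + params.lam[:, None]
               + params.nu[None, :] + params.eta)
    phi = np.exp(log_phi)
    tmask = np.array([g in spec.target_groups for g in params.groups])
    t = np.broadcast_to(tmask.astype(float), phi.shape)
    W = w.w
    var_term = float((phi * (t * (1 - W) ** 2 + (1 - t) * W ** 2)).sum())
    bias = float((W * phi).sum() - phi[:, tmask].sum())
    return var_term + bias ** 2


def pseudo_mle_mu(T_i: float, params: GenerativeParams, lengths: GeneCatalog,
                  spec: BiomarkerSpec) -> float:
    """Background-rate estimate matching a sample's observed biomarker.

    mu-hat = log(T_i / sum_{g, s in Sbar} l_g exp(lam + nu + eta)); under
    this mu the model's expected biomarker equals T_i exactly.  Zero
    burdens are floored at 0.5 to keep the log finite.
    """
    if T_i < 0:
        raise ValueError("biomarker value must be >= 0")
    if T_i == 0:
        warnings.warn("zero biomarker floored at 0.5 for the pseudo-MLE",
                      stacklevel=2)
        T_i = ZERO_BURDEN_FLOOR
    return float(np.log(T_i / expected_biomarker_mass(params, lengths, spec)))


def recommended_mu0(train_T: np.ndarray, params: GenerativeParams,
                    lengths: GeneCatalog, spec: BiomarkerSpec) -> float:
    """max_i of the training pseudo-MLEs — the recommended K(mu0) anchor."""
    mass = expected_biomarker_mass(params, lengths, spec)
    T = np.maximum(np.asarray(train_T, float), ZERO_BURDEN_FLOOR)
    return float(np.log(T / mass).max())


def prediction_interval(model: EstimatorModel, estimate: float,
                        alpha: float) -> PredictionInterval:
    """Markov-bound (1 - alpha) interval around a point estimate.

    The test sample's unknown log-BMR is replaced by the pseudo-MLE
    implied by the estimate itself; t_alpha = MSE / alpha and the
    interval is [T-hat - sqrt(t_alpha), T-hat + sqrt(t_alpha)], truncated
    below at zero since the biomarker is a count.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mu0 = pseudo_mle_mu(max(estimate, 0.0), model.params, model.lengths,
                        model.spec)
    mse = model_mse(model.weights, model.params, model.lengths, model.spec,
                    mu0)
    half = float(np.sqrt(mse / alpha))
    lower = min(float(estimate), max(0.0, estimate - half))
    return PredictionInterval(estimate=float(estimate), lower=lower,
                              upper=estimate + half, alpha=alpha)


def predictions_to_tsv(path: str | Path, samples, estimates,
                       intervals: list[PredictionInterval] | None = None) -> None:
    import pandas as pd
    data = {"sample": list(samples), "estimate": np.asarray(estimates, float)}
    if intervals is not None:
        data["lower"] = [iv.lower for iv in intervals]
        data["upper"] = [iv.upper for iv in intervals]
        data["alpha"] = [iv.alpha for iv in intervals]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
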