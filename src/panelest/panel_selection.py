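"""Panel selection: length-weighted group lasso on the estimator objective.

A biomarker estimator is a weighted count T(w) = sum_{g,s} w_gs M_0gs.
Under the fitted Poisson model its (rescaled) expected squared error is

    f(w) = sum_{g, s in Sbar} p_gs (1 - w_gs)^2
         + sum_{g, s not in Sbar} p_gs w_gs^2
         + K (1 - sum_{g,s} p_gs w_gs)^2,

where p_gs are the fitted per-cell rates normalized so the target-group
(Sbar) mass sums to one, and K >= 0 trades variance against squared bias
(K = infinity enforces exact model-unbiasedness).  Sparse weights are
found by penalizing f with the length-weighted group-lasso norm
kappa2 * sum_g l_g * ||w_g||_2, which zeroes whole genes: the selected
panel is the set of genes with a non-zero weight row.  A closed-form
refit on the selected support then removes the shrinkage bias.

The smooth part f is a quadratic with diagonal-plus-rank-one Hessian
2 diag(p) + 2 K p p^T, so an accelerated proximal-gradient method (FISTA)
with the exact group soft-threshold prox solves the first fit with O(GS)
work per iteration; the refit is a rank-one (Sherman-Morrison) solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .generative_model import GenerativeParams
from .mutation_data import BiomarkerSpec, GeneCatalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizedRates:
    """Per-cell rates p_gs normalized to unit mass on the target groups.

    ``K`` is the bias-penalty weight (may be ``np.inf`` for the
    exactly-unbiased refit); ``target_mask`` marks the columns in Sbar.
    """

    genes: tuple[str, ...]
    groups: tuple[str, ...]
    p: np.ndarray            # (G, S), all > 0
    target_mask: np.ndarray  # (S,) bool
    K: float = np.nan        # unset until bias_penalty_K

    def __post_init__(self) -> None:
        p = np.asarray(self.p, float)
        if np.any(p <= 0):
            raise ValueError("normalized rates must be strictly positive")
        tmass = p[:, self.target_mask].sum()
        if not np.isclose(tmass, 1.0, atol=1e-8):
            raise ValueError(f"target-group mass is {tmass}, expected 1")
        object.__setattr__(self, "p", p)

    def with_K(self, K: float) -> "NormalizedRates":
        if K < 0:
            raise ValueError("K must be >= 0")
        return NormalizedRates(self.genes, self.groups, self.p,
                               self.target_mask, float(K))

    @property
    def target_indicator(self) -> np.ndarray:
        """(G, S) indicator t with t_gs = 1 iff s in Sbar."""
        return np.broadcast_to(self.target_mask.astype(float),
                               self.p.shape).copy()


@dataclass(frozen=True)
class WeightMatrix:
    """Estimator weights w_gs; genes with a non-zero row form the panel."""

    genes: tuple[str, ...]
    groups: tuple[str, ...]
    w: np.ndarray  # (G, S)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, float)
        if w.shape != (len(self.genes), len(self.groups)):
            raise ValueError("weight matrix shape mismatch")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "w", w)

    @property
    def support(self) -> np.ndarray:
        """Boolean mask over genes with ||w_g||_2 > 0."""
        return np.linalg.norm(self.w, axis=1) > 0

    def group_l0(self, lengths: GeneCatalog) -> float:
        """Panel cost ||w||_{G,0} = sum_g l_g 1{w_g != 0}."""
        return float(lengths.lengths[self.support].sum())

    def group_l1(self, lengths: GeneCatalog) -> float:
        """Relaxed cost ||w||_{G,1} = sum_g l_g ||w_g||_2."""
        return float((lengths.lengths * np.linalg.norm(self.w, axis=1)).sum())

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        rows = [(g, s, self.w[i, j]) for i, g in enumerate(self.genes)
                for j, s in enumerate(self.groups)]
        pd.DataFrame(rows, columns=["gene", "group", "weight"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Panel:
    """A gene panel: a subset of the exome with its total coding length."""

    genes: tuple[str, ...]
    total_length: float

    @classmethod
    def from_genes(cls, genes: Sequence[str], lengths: GeneCatalog) -> "Panel":
        genes = tuple(genes)
        for g in genes:
            if g not in lengths:
                raise KeyError(f"panel gene {g!r} not in gene catalog")
        return cls(genes, lengths.length_of(genes))

    @classmethod
    def empty(cls) -> "Panel":
        return cls((), 0.0)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def write_gene_list(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{g}\n" for g in self.genes))

    @classmethod
    def read_gene_list(cls, path: str | Path, lengths: GeneCatalog) -> "Panel":
        genes = [line.strip() for line in Path(path).read_text().splitlines()
                 if line.strip()]
        return cls.from_genes(genes, lengths)

    def write_bed(self, path: str | Path,
                  coordinates: "dict[str, tuple[str, int, int]]") -> None:
        """Write the panel as 0-based half-open BED given gene coordinates."""
        with open(path, "w") as fh:
            for g in self.genes:
                chrom, start, end = coordinates[g]
                fh.write(f"{chrom}\t{start}\t{end}\t{g}\n")


def normalized_rates(params: GenerativeParams, lengths: GeneCatalog,
                     spec: BiomarkerSpec) -> NormalizedRates:
    """Fitted cell rates rescaled so the target-group mass is one.

    p_gs = l_g exp(lam_g + nu_s + eta_gs) / sum_{g', s' in Sbar} (same);
    independent of mu.  Computed via log-sum-exp for overflow safety.
    """
    target_mask = np.array([g in spec.target_groups for g in params.groups])
    if not target_mask.any():
        raise ValueError("biomarker target groups not found in params groups")
    log_q = (np.log(lengths.lengths)[:, None] + params.lam[:, None]
             + params.nu[None, :] + params.eta)
    log_norm = _logsumexp(log_q[:, target_mask])
    return NormalizedRates(params.genes, params.groups,
                           np.exp(log_q - log_norm), target_mask)


def _logsumexp(a: np.ndarray) -> float:
    amax = a.max()
    return float(amax + np.log(np.exp(a - amax).sum()))


def bias_penalty_K(params: GenerativeParams, lengths: GeneCatalog,
                   spec: BiomarkerSpec, mu0: float) -> float:
    """Bias-penalty weight K(mu0) = exp(mu0) * expected biomarker mass.

    The second factor is sum_{g, s in Sbar} l_g exp(lam_g + nu_s + eta_gs),
    so K(mu0) is the model's expected biomarker value for a sample with
    log-BMR mu0.  Pass ``np.inf`` to request the exactly-unbiased refit.
    """
    if np.isinf(mu0) and mu0 > 0:
        return np.inf
    target_mask = np.array([g in spec.target_groups for g in params.groups])
    log_q = (np.log(lengths.lengths)[:, None] + params.lam[:, None]
             + params.nu[None, :] + params.eta)
    return float(np.exp(mu0 + _logsumexp(log_q[:, target_mask])))


def objective_f(w: WeightMatrix | np.ndarray, rates: NormalizedRates) -> float:
    """Evaluate the rescaled expected-squared-error objective f(w)."""
    W = w.w if isinstance(w, WeightMatrix) else np.asarray(w, float)
    if np.isnan(rates.K):
        raise ValueError("rates.K is unset; call with_K first")
    if np.isinf(rates.K):
        raise ValueError("f is undefined for K=inf; use the constrained refit")
    p, t = rates.p, rates.target_indicator
    quad = float((p * (W - t) ** 2).sum())
    bias = float((1.0 - (p * W).sum()) ** 2)
    return quad + rates.K * bias


def _grad_f(W: np.ndarray, p: np.ndarray, t: np.ndarray, K: float) -> np.ndarray:
    return 2.0 * p * (W - t) + 2.0 * K * ((p * W).sum() - 1.0) * p


def _group_soft_threshold(W: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    """Row-wise group soft threshold: shrink each gene row toward zero."""
    norms = np.linalg.norm(W, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(0.0, 1.0 - thresh[nz] / norms[nz])
    return W * scale[:, None]


class FirstFitError(RuntimeError):
    """Raised when the proximal-gradient solve fails to converge."""


def first_fit(
    rates: NormalizedRates,
    lengths: GeneCatalog,
    kappa2: float,
    include: Panel | None = None,
    exclude: Panel | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 20_000,
    init: np.ndarray | None = None,
    kkt_stop: float = 1e-8,
    kkt_tol: float = 1e-3,
) -> WeightMatrix:
    """Solve the length-weighted group-lasso relaxation.

    Minimizes f(w) + kappa2 * sum_{g not in P0} l_g ||w_g||_2 subject to
    w_g = 0 for g in Q0 (``exclude``); genes in ``include`` (P0) escape
    the penalty and therefore stay in the panel.  FISTA with the exact
    group soft-threshold prox; first-order conditions are checked at exit.
    """
    if kappa2 < 0:
        raise ValueError("kappa2 must be >= 0")
    include = include or Panel.empty()
    exclude = exclude or Panel.empty()
    if set(include.genes) & set(exclude.genes):
        raise ValueError("include and exclude panels overlap")
    p, t, K = rates.p, rates.target_indicator, rates.K
    if np.isnan(K) or np.isinf(K):
        raise ValueError("first_fit needs a finite K; call rates.with_K")
    G, S = p.shape
    gidx = {g: i for i, g in enumerate(rates.genes)}
    pen_weight = kappa2 * lengths.lengths.copy()
    for g in include.genes:
        pen_weight[gidx[g]] = 0.0
    excluded_rows = np.zeros(G, dtype=bool)
    for g in exclude.genes:
        excluded_rows[gidx[g]] = True

    L = 2.0 * p.max() + 2.0 * K * float((p ** 2).sum())  # Lipschitz of grad f
    step = 1.0 / L
    W = np.zeros((G, S)) if init is None else init.copy()
    W[excluded_rows] = 0.0
    Y = W.copy()
    t_acc = 1.0

    def full_obj(Wm: np.ndarray) -> float:
        quad = float((p * (Wm - t) ** 2).sum())
        bias = K * float((1.0 - (p * Wm).sum()) ** 2)
        return quad + bias + float(
            (pen_weight * np.linalg.norm(Wm, axis=1)).sum())

    def rel_kkt(Wm: np.ndarray) -> float:
        residual = _kkt_residual(Wm, p, t, K, pen_weight, excluded_rows)
        gscale = max(1.0, float(np.abs(_grad_f(Wm, p, t, K)).max()),
                     float(pen_weight.max(initial=0.0)))
        return residual / gscale

    obj = full_obj(W)
    converged = False
    rel_residual = np.inf
    check_every = 50
    stalled = 0
    for it in range(max_iter):
        grad = _grad_f(Y, p, t, K)
        W_new = _group_soft_threshold(Y - step * grad, step * pen_weight)
        W_new[excluded_rows] = 0.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2))
        Y = W_new + ((t_acc - 1.0) / t_new) * (W_new - W)
        W, t_acc = W_new, t_new
        new_obj = full_obj(W)
        if new_obj > obj:  # FISTA ripple: restart momentum
            Y, t_acc = W.copy(), 1.0
        small_change = abs(obj - new_obj) <= tol * (1.0 + abs(new_obj))
        stalled = stalled + 1 if small_change else 0
        obj = new_obj
        # stationarity, not objective stagnation, decides convergence;
        # but a numerically exhausted objective with acceptable
        # stationarity is accepted (ill-conditioned tiny-rate coordinates
        # cannot be polished past double precision)
        if small_change or it % check_every == check_every - 1:
            rel_residual = rel_kkt(W)
            if rel_residual < kkt_stop or (stalled >= 10
                                           and rel_residual < kkt_tol):
                converged = True
                break
    if not converged:
        rel_residual = rel_kkt(W)
        if rel_residual > 100 * kkt_tol:
            raise FirstFitError(
                f"first_fit did not converge in {max_iter} iterations; "
                f"relative KKT residual {rel_residual:.3e}")
        if rel_residual > kkt_tol:
            logger.warning("first_fit stopped at relative KKT residual "
                           "%.3e (target %.1e)", rel_residual, kkt_stop)
    if kappa2 > 0:
        # exact group-lasso zeros: prune solver dust at the support boundary
        norms = np.linalg.norm(W, axis=1)
        dust = (norms > 0) & (norms < 1e-10 * max(1.0, norms.max())) \
            & (pen_weight > 0)
        W[dust] = 0.0
    return WeightMatrix(rates.genes, rates.groups, W)


def _kkt_residual(W: np.ndarray, p: np.ndarray, t: np.ndarray, K: float,
                  pen_weight: np.ndarray, excluded_rows: np.ndarray) -> float:
    """Max first-order violation of the group-lasso stationarity conditions."""
    grad = _grad_f(W, p, t, K)
    norms = np.linalg.norm(W, axis=1)
    active = (norms > 0) & ~excluded_rows
    inactive = (norms == 0) & ~excluded_rows
    res = 0.0
    if active.any():
        sub = grad[active] + (pen_weight[active] / norms[active])[:, None] \
            * W[active]
        res = float(np.abs(sub).max())
    if inactive.any():
        gaps = np.linalg.norm(grad[inactive], axis=1) - pen_weight[inactive]
        res = max(res, float(np.maximum(gaps, 0.0).max()))
    return res


def full_shrinkage_kappa2(rates: NormalizedRates, lengths: GeneCatalog,
                          include: Panel | None = None) -> float:
    """Smallest kappa2 at which the first fit is identically zero.

    From the gradient of f at w = 0: gene g enters whenever
    ||grad_g f(0)||_2 > kappa2 * l_g, so the threshold is the largest
    ratio over penalized genes.
    """
    p, t, K = rates.p, rates.target_indicator, rates.K
    grad0 = _grad_f(np.zeros_like(p), p, t, K)
    ratios = np.linalg.norm(grad0, axis=1) / lengths.lengths
    if include is not None and len(include):
        keep = np.array([g not in include for g in rates.genes])
        ratios = ratios[keep]
    return float(ratios.max())


def panel_of(w: WeightMatrix, lengths: GeneCatalog) -> Panel:
    """Panel selected by a weight matrix: genes with ||w_g||_2 > 0."""
    genes = tuple(g for g, keep in zip(w.genes, w.support) if keep)
    return Panel(genes, w.group_l0(lengths))


def refit(rates: NormalizedRates, panel: Panel) -> WeightMatrix:
    """Closed-form minimizer of f over weights supported on the panel.

    On the support the objective is a positive-definite quadratic with a
    diagonal-plus-rank-one Hessian, so Sherman-Morrison gives

        w_gs = t_gs + K (1 - c) / (1 + K * sigma)        (finite K)
        w_gs = t_gs + (1 - c) / sigma                    (K = infinity)

    where c = sum over support-and-Sbar of p, sigma = sum over all
    support cells of p.  The K = infinity branch is the equality-
    constrained least squares enforcing sum p_gs w_gs = 1 exactly.
    """
    K = rates.K
    if np.isnan(K):
        raise ValueError("rates.K is unset; call with_K first")
    G, S = rates.p.shape
    W = np.zeros((G, S))
    rows = np.array([g in set(panel.genes) for g in rates.genes])
    if not rows.any():
        warnings.warn("refit on an empty panel returns zero weights "
                      "(f = 1 + K)", stacklevel=2)
        return WeightMatrix(rates.genes, rates.groups, W)
    p, t = rates.p, rates.target_indicator
    sigma = float(p[rows].sum())
    c = float((p * t)[rows].sum())
    if np.isinf(K):
        shift = (1.0 - c) / sigma
    else:
        shift = K * (1.0 - c) / (1.0 + K * sigma)
    W[rows] = t[rows] + shift
    return WeightMatrix(rates.genes, rates.groups, W)


def default_kappa2_grid(rates: NormalizedRates, lengths: GeneCatalog,
                        include: Panel | None = None,
                        n_grid: int = 100, decades: float = 4.0) -> np.ndarray:
    """Decreasing log-spaced kappa2 grid from the full-shrinkage bound.

    The top of the grid sits just above the bound so the empty panel is
    attained exactly rather than resting on the shrinkage boundary.
    """
    kmax = full_shrinkage_kappa2(rates, lengths, include) * (1.0 + 1e-4)
    return np.logspace(np.log10(kmax), np.log10(kmax) - decades, n_grid)


def kappa2_for_length(
    rates: NormalizedRates,
    lengths: GeneCatalog,
    L: float,
    grid: np.ndarray | None = None,
    include: Panel | None = None,
    exclude: Panel | None = None,
    **solver_kwargs,
) -> tuple[float, Panel, WeightMatrix]:
    """Map a panel-length budget L to a kappa2, panel and first-fit weights.

    Walks the kappa2 grid from large to small with warm starts.  Reported
    panel lengths are made monotone (running maximum) so an occasional
    non-monotone wobble of the raw path cannot flip the selection; the
    chosen grid point is the one with the largest reported length <= L,
    ties broken toward larger kappa2 (sparsest weights).
    """
    include = include or Panel.empty()
    if L < include.total_length:
        raise ValueError(f"budget L={L} below mandatory panel length "
                         f"{include.total_length}")
    if grid is None:
        grid = default_kappa2_grid(rates, lengths, include)
    grid = np.sort(np.asarray(grid, float))[::-1]
    fits: list[WeightMatrix] = []
    panels: list[Panel] = []
    W_prev: np.ndarray | None = None
    for k2 in grid:
        wm = first_fit(rates, lengths, k2, include, exclude, init=W_prev,
                       **solver_kwargs)
        W_prev = wm.w
        fits.append(wm)
        pan = panel_of(wm, lengths)
        if include.genes and not set(include.genes) <= set(pan.genes):
            # mandatory genes are sequenced regardless of weight
            pan = Panel.from_genes(
                tuple(dict.fromkeys(pan.genes + include.genes)), lengths)
        panels.append(pan)
    raw_lengths = np.array([p.total_length for p in panels])
    reported = np.maximum.accumulate(raw_lengths)
    if np.any(reported != raw_lengths):
        logger.info("non-monotone panel-length step on the kappa2 path; "
                    "reported lengths use the running maximum")
    ok = np.flatnonzero(reported <= L)
    if ok.size == 0:
        # even the sparsest grid point exceeds L (only possible with P0)
        raise ValueError(f"no grid point yields a panel within budget {L}")
    best_len = reported[ok].max()
    j = int(ok[np.flatnonzero(reported[ok] == best_len)[0]])  # largest kappa2
    return float(grid[j]), panels[j], fits[j]
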