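"""Penalized Poisson generative model of exome mutation counts.

Counts M_igs (sample i, gene g, variant group s) are modelled as
independent Poisson variables with log-rate

    log phi_igs = mu_i + log(l_g) + lambda_g + nu_s + eta_gs,

where mu_i is the per-sample background mutation rate (BMR) on the log
scale, l_g the coding length of gene g, lambda_g a gene effect, nu_s a
variant-group effect and eta_gs a gene-by-group interaction.  For
identifiability eta_{g,s1} = 0 for a reference group s1, and we
additionally pin nu_{s1} = 0 so the overall level lives in mu.

Fitting minimizes the Poisson negative log-likelihood plus an l1 penalty
kappa1 * (sum_g |lambda_g| + sum_{g,s} |eta_gs|); mu and nu are
unpenalized.  The tuning parameter kappa1 is chosen by cell-wise
10-fold cross-validation on held-out Poisson deviance.

The optimizer exploits the separability of the problem: holding the other
blocks fixed, the partial objective of each mu_i (and each nu_s,
lambda_g, eta_gs) is a one-dimensional convex function of the form
A*exp(x) - B*x (+ kappa1*|x| for penalized blocks) whose exact minimizer
is available in closed form (a log ratio, soft-thresholded for the
penalized blocks).  Block coordinate descent over the four blocks with
these exact updates decreases the penalized objective monotonically and
converges to the global minimum of the convex objective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .mutation_data import CountTensor, GeneCatalog

logger = logging.getLogger(__name__)

#: Floor applied to log-rates diverging to -inf (samples with no mutations).
MU_FLOOR = -30.0
#: Floor applied to predicted rates when evaluating held-out deviance.
DEVIANCE_RATE_FLOOR = 1e-12


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters (mu, lambda, nu, eta) of the Poisson mutation model."""

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    groups: tuple[str, ...]  # reference group first
    mu: np.ndarray      # (n,)
    lam: np.ndarray     # (G,)
    nu: np.ndarray      # (S,), nu[0] == 0
    eta: np.ndarray     # (G, S), eta[:, 0] == 0

    def __post_init__(self) -> None:
        n, G, S = len(self.samples), len(self.genes), len(self.groups)
        for name, arr, shape in (("mu", self.mu, (n,)), ("lam", self.lam, (G,)),
                                 ("nu", self.nu, (S,)), ("eta", self.eta, (G, S))):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, arr)
        if not (np.all(self.eta[:, 0] == 0) and self.nu[0] == 0):
            raise ValueError("reference-group constraints violated: "
                             "eta[:, 0] and nu[0] must be zero")

    @property
    def reference_group(self) -> str:
        return self.groups[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": list(self.samples), "genes": list(self.genes),
            "groups": list(self.groups),
            "identifiability": "eta[:, reference]=0, nu[reference]=0; "
                               "reference group listed first",
            "mu": self.mu.tolist(), "lam": self.lam.tolist(),
            "nu": self.nu.tolist(), "eta": self.eta.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeParams":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["samples"]), tuple(d["genes"]), tuple(d["groups"]),
                   np.array(d["mu"]), np.array(d["lam"]),
                   np.array(d["nu"]), np.array(d["eta"]))


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the penalized fit and its cross-validation."""

    kappa1_grid: Sequence[float] | None = None  # decreasing; None -> automatic
    n_grid: int = 50
    grid_decades: float = 4.0
    n_folds: int = 10
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.kappa1_grid is not None:
            grid = np.asarray(self.kappa1_grid, dtype=float)
            if grid.size == 0 or np.any(grid < 0):
                raise ValueError("kappa1 grid must be non-empty and >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class CVResult:
    """Cross-validation deviance profile over the kappa1 grid."""

    kappa1_grid: np.ndarray
    mean_deviance: np.ndarray
    selected_kappa1: float
    n_folds: int
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"kappa1": self.kappa1_grid,
                      "mean_deviance": self.mean_deviance}
                     ).to_csv(path, sep="\t", index=False)


def rate(params: GenerativeParams, lengths: GeneCatalog) -> np.ndarray:
    """Poisson rates phi_igs = exp(mu_i + log l_g + lambda_g + nu_s + eta_gs).

    Returns the full (n, G, S) rate array.
    """
    log_phi = (params.mu[:, None, None]
               + (np.log(lengths.lengths) + params.lam)[None, :, None]
               + (params.nu[None, :] + params.eta)[None, :, :])
    return np.exp(log_phi)


def negative_log_likelihood(
    params: GenerativeParams,
    tensor: CountTensor,
    lengths: GeneCatalog,
    cells: np.ndarray | None = None,
) -> float:
    """Poisson NLL sum(phi - m*log(phi)) over the included cells.

    ``cells`` is an optional boolean mask of shape (n, G, S); constant
    log(m!) terms are omitted.
    """
    m = tensor.counts
    if np.any(m < 0):
        raise ValueError("counts must be non-negative")
    phi = rate(params, lengths)
    log_phi = np.log(phi)
    contrib = phi - m * log_phi
    if cells is not None:
        contrib = contrib[cells]
    return float(np.sum(contrib))


def _penalty(lam: np.ndarray, eta: np.ndarray, kappa1: float) -> float:
    total = np.abs(lam).sum() + np.abs(eta).sum()
    if np.isinf(kappa1):  # used to force the two-factor null fit
        return 0.0 if total == 0 else np.inf
    return kappa1 * total


def _soft_log_update(A: np.ndarray, B: np.ndarray, kappa1: float,
                     floor: float = MU_FLOOR) -> np.ndarray:
    """Exact minimizer of A*exp(x) - B*x + kappa1*|x| elementwise.

    A > 0 and B >= 0 are the rate mass and count mass of the coordinate.
    The unpenalized stationary point is log(B/A); the l1 term zeroes the
    coordinate whenever |B - A| <= kappa1 (KKT condition at x = 0).
    """
    x = np.zeros_like(A)
    pos = B - A > kappa1  # minimizer > 0: solve A e^x = B - kappa1
    neg = A - B > kappa1  # minimizer < 0: solve A e^x = B + kappa1
    with np.errstate(divide="ignore"):
        x[pos] = np.log((B[pos] - kappa1) / A[pos])
        x[neg] = np.log((B[neg] + kappa1) / A[neg])
    return np.maximum(x, floor)


def _masked(arr: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    return arr if mask is None else arr * mask


def fit_penalized(
    tensor: CountTensor,
    lengths: GeneCatalog,
    kappa1: float,
    config: FitConfig | None = None,
    cells: np.ndarray | None = None,
    *,
    init: GenerativeParams | None = None,
) -> GenerativeParams:
    """Fit the l1-penalized Poisson model by exact block coordinate descent.

    Parameters
    ----------
    tensor
        Training counts, shape (n, G, S) with the reference group first.
    kappa1
        Non-negative l1 penalty level on lambda and eta.
    cells
        Optional boolean mask of training cells (True = include); every
        sample and every group must retain at least one training cell.
    init
        Warm-start parameters (used along cross-validation paths).
    """
    cfg = config or FitConfig()
    if kappa1 < 0:
        raise ValueError("kappa1 must be >= 0")
    m = tensor.counts.astype(float)
    n, G, S = m.shape
    mask = None
    if cells is not None:
        mask = cells.astype(float)
        if np.any(mask.sum(axis=(1, 2)) == 0):
            raise ValueError("a sample has no training cells; mu not estimable")
        if np.any(mask.sum(axis=(0, 1)) == 0):
            raise ValueError("a group has no training cells; nu not estimable")
    ell = lengths.lengths

    if init is not None:
        mu, lam = init.mu.copy(), init.lam.copy()
        nu, eta = init.nu.copy(), init.eta.copy()
    else:
        mu = np.full(n, MU_FLOOR / 2)
        total = float(_masked(m, mask).sum())
        denom = (mask.sum() if mask is not None else m.size) * float(np.mean(ell))
        mu[:] = np.log(max(total, 0.5) / denom)
        lam = np.zeros(G)
        nu = np.zeros(S)
        eta = np.zeros((G, S))

    mw = _masked(m, mask)
    B_mu = mw.sum(axis=(1, 2))            # counts per sample
    B_nu = mw.sum(axis=(0, 1))            # counts per group
    B_lam = mw.sum(axis=(0, 2))           # counts per gene
    B_eta = mw.sum(axis=0)                # counts per gene x group
    if np.any(B_mu == 0):
        warnings.warn("samples with zero training mutations: mu floored at "
                      f"{MU_FLOOR}", stacklevel=2)

    def rates() -> np.ndarray:
        return np.exp(mu[:, None, None] + (np.log(ell) + lam)[None, :, None]
                      + (nu[None, :] + eta)[None, :, :])

    def objective() -> float:
        phi = rates()
        phim = _masked(phi, mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = mw * np.log(phi)
        ll = np.where(mw > 0, ll, 0.0)
        return float(phim.sum() - ll.sum()) + _penalty(lam, eta, kappa1)

    obj = objective()
    for sweep in range(cfg.max_iter):
        # block mu: A_i = sum over cells of phi_igs / exp(mu_i)
        base_gs = np.exp((np.log(ell) + lam)[:, None] + nu[None, :] + eta)  # (G,S)
        if mask is None:
            A_mu = np.full(n, base_gs.sum())
        else:
            A_mu = np.einsum("igs,gs->i", mask, base_gs)
        mu = _soft_log_update(A_mu, B_mu, 0.0)

        # block nu (s >= 1): A_s = sum_i,g exp(mu_i) l_g e^{lam_g} e^{eta_gs}
        emu = np.exp(mu)
        gl = ell * np.exp(lam)  # (G,)
        if mask is None:
            A_nu = emu.sum() * (gl[:, None] * np.exp(eta)).sum(axis=0)
        else:
            A_nu = np.einsum("igs,i,g,gs->s", mask, emu, gl, np.exp(eta))
        upd = _soft_log_update(A_nu[1:], B_nu[1:], 0.0)
        nu = np.concatenate([[0.0], upd])

        # block lambda: A_g = sum_i,s exp(mu_i) l_g e^{nu_s + eta_gs}
        ens = np.exp(nu[None, :] + eta)  # (G,S)
        if mask is None:
            A_lam = emu.sum() * ell * ens.sum(axis=1)
        else:
            A_lam = ell * np.einsum("igs,i,gs->g", mask, emu, ens)
        lam = _soft_log_update(A_lam, B_lam, kappa1)

        # block eta (s >= 1): A_gs = sum_i exp(mu_i) l_g e^{lam_g + nu_s}
        gl = ell * np.exp(lam)
        if mask is None:
            A_eta = emu.sum() * gl[:, None] * np.exp(nu)[None, :]
        else:
            A_eta = (np.einsum("igs,i->gs", mask, emu)
                     * gl[:, None] * np.exp(nu)[None, :])
        eta[:, 1:] = _soft_log_update(A_eta[:, 1:], B_eta[:, 1:], kappa1)

        new_obj = objective()
        if new_obj > obj + 1e-9 * (1 + abs(obj)):
            logger.warning("objective increased at sweep %d (%g -> %g)",
                           sweep, obj, new_obj)
        if abs(obj - new_obj) <= cfg.tol * (1 + abs(new_obj)):
            obj = new_obj
            break
        obj = new_obj
    else:
        logger.warning("fit_penalized reached max_iter=%d without meeting "
                       "tol=%g", cfg.max_iter, cfg.tol)

    return GenerativeParams(tensor.samples, tensor.genes, tensor.groups,
                            mu, lam, nu, eta)


def full_shrinkage_kappa1(
    tensor: CountTensor,
    lengths: GeneCatalog,
    cells: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> float:
    """Smallest kappa1 at which lambda-hat = eta-hat = 0.

    At the null fit (lambda = eta = 0, mu and nu at their two-factor MLE)
    the KKT condition zeroes coordinate x whenever |B - A| <= kappa1,
    where B is the coordinate's count mass and A its fitted rate mass;
    the threshold is the largest such gap.
    """
    cfg = config or FitConfig()
    base = fit_penalized(tensor, lengths, kappa1=np.inf, config=cfg, cells=cells)
    m = tensor.counts.astype(float)
    mask = cells.astype(float) if cells is not None else None
    mw = _masked(m, mask)
    ell = lengths.lengths
    emu = np.exp(base.mu)
    ens = np.exp(base.nu)[None, :] * np.ones((len(ell), len(base.nu)))
    if mask is None:
        A_lam = emu.sum() * ell * ens.sum(axis=1)
        A_eta = emu.sum() * ell[:, None] * np.exp(base.nu)[None, :]
    else:
        A_lam = ell * np.einsum("igs,i,gs->g", mask, emu, ens)
        A_eta = (np.einsum("igs,i->gs", mask, emu)
                 * ell[:, None] * np.exp(base.nu)[None, :])
    gap_lam = np.abs(mw.sum(axis=(0, 2)) - A_lam).max()
    gap_eta = np.abs(mw.sum(axis=0)[:, 1:] - A_eta[:, 1:]).max() if m.shape[2] > 1 else 0.0
    return float(max(gap_lam, gap_eta))


def default_kappa1_grid(
    tensor: CountTensor,
    lengths: GeneCatalog,
    config: FitConfig | None = None,
) -> np.ndarray:
    """Decreasing log-spaced kappa1 grid from the full-shrinkage threshold."""
    cfg = config or FitConfig()
    kmax = full_shrinkage_kappa1(tensor, lengths, config=cfg)
    kmax = max(kmax, 1e-8)
    return np.logspace(np.log10(kmax), np.log10(kmax) - cfg.grid_decades,
                       cfg.n_grid)


def poisson_deviance(m: np.ndarray, phi: np.ndarray) -> float:
    """Total Poisson deviance 2*sum[m*log(m/phi) - (m - phi)], 0*log0 = 0."""
    phi = np.maximum(phi, DEVIANCE_RATE_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = m * np.log(m / phi)
    term = np.where(m > 0, term, 0.0)
    return float(2.0 * np.sum(term - (m - phi)))


def cross_validate_kappa1(
    tensor: CountTensor,
    lengths: GeneCatalog,
    config: FitConfig | None = None,
) -> CVResult:
    """Choose kappa1 by cell-wise K-fold cross-validation.

    The full set of (i, g, s) cells — not the sample set — is split
    uniformly at random into folds.  For each fold the model is fit on
    the complement over the kappa1 grid (large to small, warm-started)
    and scored by held-out Poisson deviance; the kappa1 with the smallest
    mean deviance wins, ties going to the larger (sparser) value.
    """
    cfg = config or FitConfig()
    n, G, S = tensor.counts.shape
    n_cells = n * G * S
    if n_cells < cfg.n_folds:
        raise ValueError("fewer cells than folds")
    if cfg.kappa1_grid is not None:
        grid = np.sort(np.asarray(cfg.kappa1_grid, float))[::-1]
    else:
        grid = default_kappa1_grid(tensor, lengths, cfg)
    rng = np.random.default_rng(cfg.seed)
    fold_of = rng.permuted(np.arange(n_cells) % cfg.n_folds).reshape(n, G, S)
    m = tensor.counts.astype(float)
    deviance = np.zeros((cfg.n_folds, len(grid)))
    for fold in range(cfg.n_folds):
        held = fold_of == fold
        train = ~held
        if np.any(train.sum(axis=(1, 2)) == 0) or np.any(train.sum(axis=(0, 1)) == 0):
            raise ValueError(f"fold {fold} starves a sample or group of "
                             "training cells; use fewer folds")
        params = None
        for j, k1 in enumerate(grid):
            params = fit_penalized(tensor, lengths, k1, cfg, cells=train,
                                   init=params)
            phi = rate(params, lengths)
            deviance[fold, j] = poisson_deviance(m[held], phi[held])
    mean_dev = deviance.mean(axis=0)
    best = np.flatnonzero(mean_dev == mean_dev.min())[0]  # grid descending
    return CVResult(kappa1_grid=grid, mean_deviance=mean_dev,
                    selected_kappa1=float(grid[best]),
                    n_folds=cfg.n_folds, seed=cfg.seed)


def sparsity_report(params: GenerativeParams) -> tuple[float, float]:
    """Fractions of exactly-zero lambda_g and eta_gs (non-reference) entries."""
    lam_zero = float(np.mean(params.lam == 0.0))
    if params.eta.shape[1] > 1:
        eta_zero = float(np.mean(params.eta[:, 1:] == 0.0))
    else:
        eta_zero = 1.0
    return lam_zero, eta_zero
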