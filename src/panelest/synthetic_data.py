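"""Synthetic cohorts drawn from the Poisson generative model.

The generator emulates the structure of a whole-exome NSCLC cohort:
log-normal gene coding lengths, a heavy-tailed spread of per-sample
background mutation rates (normal on the log scale, so burdens are
log-normal across samples), sparse gene effects lambda and sparse
gene-by-group indel effects eta, and a group offset nu_indel calibrated
so the cohort's expected mean TMB and TIB match the 252 / 9.25 training
averages of the reference cohort.  Defaults are desk-scale (n = 200,
500 genes); a ``wes_scale`` profile with n = 800 and 17,358 genes is
provided for completeness but takes far longer to fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generative_model import GenerativeParams
from .mutation_data import (CountTensor, GeneCatalog, VariantCatalog)

#: Rates above this are rejected: they signal a mis-configured scenario.
MAX_RATE = 1e9


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario parameters for the synthetic cohort generator.

    Lengths are drawn log-normally (median ~1.3 kb coding sequence);
    ``mu_scale`` is the standard deviation of the log background rate
    across samples (1.0 reproduces a realistically heavy-tailed burden
    distribution).  ``target_mean_tmb``/``target_mean_tib`` fix the
    cohort-level expected burdens; the group offset and the centre of the
    mu distribution are solved from them analytically.
    """

    n_samples: int = 200
    n_genes: int = 500
    seed: int = 0
    length_log_mean: float = np.log(1300.0)
    length_log_sd: float = 0.6
    mu_scale: float = 1.0
    lambda_sparsity: float = 0.05   # fraction of genes with lambda != 0
    lambda_scale: float = 1.0       # |lambda| for the non-zero genes
    eta_sparsity: float = 0.05
    eta_scale: float = 1.0
    target_mean_tmb: float = 252.0
    target_mean_tib: float = 9.25
    variants: VariantCatalog = field(default_factory=VariantCatalog)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("need at least one sample and one gene")
        for frac in (self.lambda_sparsity, self.eta_sparsity):
            if not 0 <= frac <= 1:
                raise ValueError("sparsity fractions must lie in [0, 1]")
        if not 0 < self.target_mean_tib < self.target_mean_tmb:
            raise ValueError("need 0 < mean TIB < mean TMB")


def wes_scale(seed: int = 0) -> SyntheticConfig:
    """Cohort sized like a full whole-exome NSCLC training set
    (800 samples, 17,358 observed genes).  Fitting at this scale takes
    minutes to hours; the desk-scale defaults are used everywhere else."""
    return SyntheticConfig(n_samples=800, n_genes=17_358, seed=seed)


def sample_params(config: SyntheticConfig) -> tuple[GenerativeParams, GeneCatalog]:
    """Draw ground-truth parameters and a gene catalog for one scenario.

    The indel offset is nu = log(TIB / (TMB - TIB)) so indels are the
    configured fraction of the burden, and the centre of the mu law is
    solved so that E[mean TMB] hits the target exactly (accounting for
    the log-normal mean factor exp(mu_scale^2 / 2) and the realized
    lengths and lambda draws).
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    groups = config.variants.group_labels
    S = len(groups)
    lengths = np.maximum(
        1, np.round(rng.lognormal(config.length_log_mean,
                                  config.length_log_sd, G))).astype(int)
    genes = tuple(f"G{i:05d}" for i in range(G))
    catalog = GeneCatalog(genes, lengths.astype(float))

    lam = np.zeros(G)
    nz = rng.random(G) < config.lambda_sparsity
    lam[nz] = rng.choice([-1.0, 1.0], nz.sum()) * config.lambda_scale

    nu = np.zeros(S)
    eta = np.zeros((G, S))
    if S > 1:
        # all non-reference groups share the indel-like offset
        nu[1:] = np.log(config.target_mean_tib
                        / (config.target_mean_tmb - config.target_mean_tib))
        nz_eta = rng.random((G, S - 1)) < config.eta_sparsity
        draws = rng.choice([-1.0, 1.0], nz_eta.sum()) * config.eta_scale
        eta_rest = np.zeros((G, S - 1))
        eta_rest[nz_eta] = draws
        eta[:, 1:] = eta_rest

    # expected mean TMB for a sample with mu = m:
    #   e^m * sum_{g,s} l_g exp(lam_g + nu_s + eta_gs)
    mass = float((lengths[:, None] * np.exp(lam[:, None] + nu[None, :] + eta)).sum())
    mu_loc = (np.log(config.target_mean_tmb / mass)
              - 0.5 * config.mu_scale ** 2)
    mu = rng.normal(mu_loc, config.mu_scale, config.n_samples)

    samples = tuple(f"S{i:04d}" for i in range(config.n_samples))
    params = GenerativeParams(samples, genes, groups, mu, lam, nu, eta)
    return params, catalog


def sample_counts(params: GenerativeParams, lengths: GeneCatalog,
                  n_samples: int | None = None, seed: int = 0,
                  mu: np.ndarray | None = None) -> CountTensor:
    """Draw a count tensor of independent Poisson cells from the model.

    By default uses the per-sample ``mu`` stored in ``params``; pass
    ``mu`` (with matching ``n_samples``) to draw fresh test samples.
    """
    rng = np.random.default_rng(seed)
    if mu is None:
        mu = params.mu
        samples = params.samples
    else:
        mu = np.asarray(mu, float)
        samples = tuple(f"T{i:04d}" for i in range(len(mu)))
    if n_samples is not None and n_samples != len(mu):
        raise ValueError("n_samples inconsistent with mu")
    log_phi = (mu[:, None, None]
               + (np.log(lengths.lengths) + params.lam)[None, :, None]
               + (params.nu[None, :] + params.eta)[None, :, :])
    phi = np.exp(log_phi)
    if phi.max() > MAX_RATE:
        raise ValueError(
            f"cell rate {phi.max():.3g} exceeds {MAX_RATE:.0e}; lower "
            "target burdens or the mu/lambda scales in the scenario")
    counts = rng.poisson(phi)
    return CountTensor(samples, params.genes, params.groups, counts)


def draw_test_cohort(params: GenerativeParams, lengths: GeneCatalog,
                     config: SyntheticConfig, n_test: int,
                     seed: int) -> CountTensor:
    """Fresh test samples: new mu draws from the scenario's BMR law."""
    rng = np.random.default_rng(seed)
    mass = float((lengths.lengths[:, None]
                  * np.exp(params.lam[:, None] + params.nu[None, :]
                           + params.eta)).sum())
    mu_loc = (np.log(config.target_mean_tmb / mass)
              - 0.5 * config.mu_scale ** 2)
    mu = rng.normal(mu_loc, config.mu_scale, n_test)
    return sample_counts(params, lengths, seed=rng.integers(2**31), mu=mu)


#: Representative raw MAF classification emitted per variant group.
_GROUP_TO_CLASS = {"other": "Missense_Mutation", "indel": "Frame_Shift_Del"}


def write_maf(tensor: CountTensor, path, variants: VariantCatalog | None = None
              ) -> None:
    """Expand a count tensor into a MAF-style TSV fixture.

    Each count becomes that many rows carrying a representative raw
    classification for its group, so the reader code path (classification
    -> group -> aggregation) is exercised end to end.
    """
    catalog = variants or VariantCatalog()
    class_of: dict[str, str] = {}
    for s in tensor.groups:
        if s in _GROUP_TO_CLASS:
            class_of[s] = _GROUP_TO_CLASS[s]
        else:  # first raw class mapping to this group
            class_of[s] = next(c for c, grp in catalog.groups.items()
                               if grp == s)
    i, g, s = np.nonzero(tensor.counts)
    reps = tensor.counts[i, g, s]
    rows = {
        "Hugo_Symbol": np.repeat([tensor.genes[k] for k in g], reps),
        "Tumor_Sample_Barcode": np.repeat([tensor.samples[k] for k in i], reps),
        "Variant_Classification": np.repeat(
            [class_of[tensor.groups[k]] for k in s], reps),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
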