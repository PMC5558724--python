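"""Hybrid inference: EM to convergence, then a short warm-started MCMC.

The EM stage supplies point estimates (g, Pr, beta, v, sigma_e2) that
initialize a single Gibbs chain, cutting the chain length from tens of
thousands of iterations to a few thousand. A speed-up rule prunes the
model during sampling: after a fixed number of iterations (default 500),
SNPs whose running probability of the zero-variance class exceeds a
threshold (default 0.90) are set to zero and skipped for the remainder
of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bayesr import (GibbsConfig, GibbsData, MixturePrior, PosteriorSummary,
                     run_gibbs)
from .em import EMConfig, EMState, run_em
from .gblup import compute_pev_u, solve_mme

logger = logging.getLogger(__name__)


@dataclass
class HybridConfig:
    iters: int = 4000
    burnin: int = 1000
    exclude_at: int = 500
    exclude_threshold: float = 0.90
    seed: int = 0
    include_polygenic_in_gebv: bool = False
    em: EMConfig = field(default_factory=EMConfig)


@dataclass
class HybridResult:
    summary: PosteriorSummary
    em_state: EMState
    excluded: np.ndarray


def run_hybrid(data: GibbsData, prior: MixturePrior,
               config: HybridConfig | None = None, G=None,
               hooks=None) -> HybridResult:
    """Run the full hybrid pipeline on prepared data.

    ``G`` is needed when the EM PEV correction is active (the default): a
    GBLUP fit of the phenotypes provides the prediction error variance of
    the whole-genome genetic values, which the EM stage uses to discount
    apparent information. The MCMC stage then runs the marker model
    without the u correction; its residual signal is re-absorbed by the
    sampled SNP effects.
    """
    config = config or HybridConfig()
    pev_u = u_hat = None
    if config.em.pev_correction:
        if G is None:
            raise ValueError("hybrid with PEV correction needs G")
        sol = solve_mme(data.y, data.X, G, data.A, data.E_diag, data.vc)
        pev_u = compute_pev_u(sol)
        u_hat = sol.u
    em_state = run_em(data, prior, config.em, pev_u=pev_u, u_hat=u_hat)
    logger.info("EM converged=%s after %d iterations (stat=%.3e)",
                em_state.converged, em_state.iteration, em_state.stat)

    init = dict(g=em_state.g, cls=em_state.cls, beta=em_state.beta,
                v=em_state.v, Pr=em_state.Pr, sigma_e2=em_state.sigma_e2)
    exclusion = None
    if config.exclude_at and config.exclude_at < config.iters:
        exclusion = {"at_iteration": config.exclude_at,
                     "threshold": config.exclude_threshold}
    mcmc_cfg = GibbsConfig(
        iters=config.iters, burnin=config.burnin, chains=1, seed=config.seed,
        include_polygenic_in_gebv=config.include_polygenic_in_gebv)
    summary = run_gibbs(data, prior, mcmc_cfg, init=init,
                        exclusion=exclusion, hooks=hooks)
    excluded = (exclusion or {}).get("excluded_mask",
                                    np.zeros(data.m, dtype=bool))
    return HybridResult(summary=summary, em_state=em_state, excluded=excluded)
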