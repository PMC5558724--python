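"""Gibbs sampler for the four-component mixture model of SNP effects.

Model: y = X beta + Z^s g + W v + e, where each SNP effect is drawn from
a mixture of four normals with variances {0, 0.0001, 0.001, 0.01} x
sigma_g2 and Dirichlet-distributed mixing proportions. sigma_g2 and
sigma_a2 are fixed inputs; the residual variance is sampled. The sweep
over SNPs runs in a compiled kernel; everything around it (fixed
effects, proportions, polygenic block, residual variance) is plain
numpy, one update set per iteration:

    [beta WLS update] -> [all SNP updates in input order] ->
    [Pr ~ Dirichlet] -> [v full conditional] -> [sigma_e2 ~ scaled inv-chi2]

Multiple chains are run sequentially with seeds base_seed + chain index
and their post-burn-in summaries averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import _kernels
from .data_model import VarianceComponents

logger = logging.getLogger(__name__)

GAMMA = np.array([0.0, 1e-4, 1e-3, 1e-2])


@dataclass
class MixturePrior:
    """Four-class scale mixture: class variances gamma * sigma_g2."""

    sigma_g2: float
    gamma: np.ndarray = field(default_factory=lambda: GAMMA.copy())
    alpha: np.ndarray = field(default_factory=lambda: np.ones(4))
    Pr: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, float)
        self.alpha = np.asarray(self.alpha, float)
        self.Pr = np.asarray(self.Pr, float)
        if self.Pr.min() < 0 or abs(self.Pr.sum() - 1.0) > 1e-8:
            raise ValueError("Pr must lie on the 4-simplex")

    @property
    def class_var(self) -> np.ndarray:
        return self.gamma * self.sigma_g2


@dataclass
class GibbsConfig:
    iters: int = 40_000
    burnin: int = 20_000
    chains: int = 5
    seed: int = 0
    update_proportions: bool = True
    update_sigma_e2: bool = True
    include_polygenic_in_gebv: bool = False
    nu0: float = -2.0           # flat prior on sigma_e2
    S0: float = 0.0
    resync_tol: float = 1e-6


@dataclass
class PosteriorSummary:
    """Post-burn-in averages over all chains."""

    g_mean: np.ndarray
    P: np.ndarray               # m x 4 class-membership frequencies
    Pr_mean: np.ndarray
    gebv: np.ndarray
    n_samples: int
    beta_mean: np.ndarray | None = None
    v_mean: np.ndarray | None = None
    sigma_e2_mean: float | None = None
    variant_ids: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos_bp: np.ndarray | None = None


class GibbsData:
    """Preprocessed inputs shared by the MCMC and EM engines.

    Zs must be the standardized genotype matrix (Fortran order preferred);
    E_diag the residual-variance diagonal; A the pedigree relationship
    matrix for the polygenic term (None to drop it).
    """

    def __init__(self, y, X, Zs, E_diag, vc: VarianceComponents, A=None):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.Zs = np.asfortranarray(np.asarray(Zs, float))
        self.E_diag = np.asarray(E_diag, float)
        self.vc = vc
        self.A = A
        self.n, self.m = self.Zs.shape
        self.w = 1.0 / self.E_diag                      # E^-1 diagonal
        self.l = np.einsum("ji,ji,j->i", self.Zs, self.Zs, self.w)
        Xw = self.X * self.w[:, None]
        self.XtWX = self.X.T @ Xw
        self.XtW = Xw.T
        self._polygenic_eig = None
        if A is not None and vc.sigma_a2 > 0:
            # precision of v is A^-1/sa2 + D/se2 with D = E^-1 fixed:
            # diagonalize B = D^-1/2 A^-1 D^-1/2 once, then each draw is
            # two matrix-vector products regardless of sigma_e2.
            A_inv = linalg.inv(A, check_finite=False)
            d_isqrt = 1.0 / np.sqrt(self.w)
            B = A_inv * np.outer(d_isqrt, d_isqrt)
            lam, U = linalg.eigh(B, check_finite=False)
            self._polygenic_eig = (np.maximum(lam, 0.0), U, d_isqrt)

    def beta_update(self, e, beta):
        """WLS on the partial residual; returns new beta, updates e in place."""
        if self.X.shape[1] == 0:
            return beta
        partial = e + self.X @ beta
        beta_new = np.linalg.solve(self.XtWX, self.XtW @ partial)
        e[:] = partial - self.X @ beta_new
        return beta_new

    def sample_polygenic(self, e, v, sigma_e2, rng=None):
        """Full-conditional update of v given current residuals.

        With rng=None returns the conditional mean (the EM/BLUP update);
        otherwise a draw from the multivariate-normal full conditional.
        """
        if self._polygenic_eig is None:
            return np.zeros(self.n)
        lam, U, d_isqrt = self._polygenic_eig
        partial = e + v
        rhs = self.w * partial / sigma_e2
        c = U.T @ (d_isqrt * rhs)
        M = lam / self.vc.sigma_a2 + 1.0 / sigma_e2
        mean_t = c / M
        if rng is not None:
            mean_t = mean_t + rng.standard_normal(self.n) / np.sqrt(M)
        v_new = d_isqrt * (U @ mean_t)
        e[:] = partial - v_new
        return v_new

    def residual(self, beta, g, v):
        return self.y - self.X @ beta - self.Zs @ g - v


def sample_mixture_proportions(class_counts, alpha, rng) -> np.ndarray:
    """Pr ~ Dirichlet(alpha + class counts)."""
    counts = np.asarray(class_counts, float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    return rng.dirichlet(alpha + counts)


def sample_residual_variance(e, w, nu0, S0, rng) -> float:
    """sigma_e2 ~ scaled inverse chi-square(nu0 + n, S0 + e'E^-1 e)."""
    ss = S0 + float(e @ (w * e))
    if ss <= 0:
        raise ValueError("non-positive residual sum of squares")
    df = nu0 + e.shape[0]
    return ss / rng.chisquare(df)


def sample_snp_effect(i, g, cls, e, data: GibbsData, prior: MixturePrior,
                      sigma_e2):
    """Single-SNP Gibbs update (class then effect); updates g, cls, e."""
    with np.errstate(divide="ignore"):
        log_pr = np.log(prior.Pr)
    k, gnew = _kernels.sample_snp_effect_kernel(
        np.ascontiguousarray(data.Zs[:, i]), data.w, e, g[i], log_pr,
        prior.class_var, sigma_e2, data.l[i])
    g[i] = gnew
    cls[i] = k
    return k, gnew


def _run_chain(data: GibbsData, prior: MixturePrior, config: GibbsConfig,
               chain_seed: int, init=None, exclusion=None, hooks=None):
    """One chain; returns accumulated post-burn-in sums and sample count."""
    n, m = data.n, data.m
    rng = np.random.default_rng(chain_seed)
    _kernels.seed_kernel_rng(chain_seed % (2**32 - 1))

    if init is None:
        g = np.zeros(m)
        cls = np.zeros(m, dtype=np.int64)
        beta = np.zeros(data.X.shape[1])
        v = np.zeros(n)
        Pr = prior.Pr.copy()
        sigma_e2 = data.vc.sigma_e2
    else:
        g = init["g"].copy()
        cls = init.get("cls", np.zeros(m, dtype=np.int64)).copy()
        beta = init["beta"].copy()
        v = init.get("v", np.zeros(n)).copy()
        Pr = init["Pr"].copy()
        sigma_e2 = float(init["sigma_e2"])
    e = data.residual(beta, g, v)
    active = np.ones(m, dtype=np.bool_)
    counts = np.zeros(4, dtype=np.int64)

    g_sum = np.zeros(m)
    P_count = np.zeros((m, 4))
    Pr_sum = np.zeros(4)
    beta_sum = np.zeros_like(beta)
    v_sum = np.zeros(n)
    se2_sum = 0.0
    n_samples = 0
    p1_running = np.zeros(m)

    for it in range(1, config.iters + 1):
        beta = data.beta_update(e, beta)
        with np.errstate(divide="ignore"):
            log_pr = np.log(Pr)
        _kernels.gibbs_sweep(data.Zs, data.w, e, g, cls, log_pr,
                             prior.class_var, sigma_e2, data.l, active,
                             counts)
        if config.update_proportions:
            Pr = sample_mixture_proportions(counts, prior.alpha, rng)
        v = data.sample_polygenic(e, v, sigma_e2, rng)
        if config.update_sigma_e2:
            sigma_e2 = sample_residual_variance(e, data.w, config.nu0,
                                                config.S0, rng)

        if exclusion is not None:
            p1_running += (cls == 0)
            if it == exclusion["at_iteration"]:
                frac1 = p1_running / it
                freeze = active & (frac1 > exclusion["threshold"])
                if freeze.any():
                    # zero out frozen effects and restore their residual signal
                    e += data.Zs[:, freeze] @ g[freeze]
                    g[freeze] = 0.0
                    cls[freeze] = 0
                    active[freeze] = False
                    logger.info("excluded %d SNPs with running P(i,1) > %.2f",
                                int(freeze.sum()), exclusion["threshold"])
                exclusion["excluded_mask"] = ~active

        if it % 1000 == 0:
            e_true = data.residual(beta, g, v)
            drift = np.max(np.abs(e - e_true))
            if drift > config.resync_tol:
                logger.warning("residual drift %.2e at iteration %d; "
                               "resynchronizing", drift, it)
                e = e_true

        if it > config.burnin:
            g_sum += g
            P_count[np.arange(m), cls] += 1.0
            Pr_sum += Pr
            beta_sum += beta
            v_sum += v
            se2_sum += sigma_e2
            n_samples += 1
        if hooks is not None:
            for hook in hooks:
                hook(it, g=g, cls=cls, active=active, Pr=Pr,
                     sigma_e2=sigma_e2, e=e, beta=beta, v=v)
    return dict(g_sum=g_sum, P_count=P_count, Pr_sum=Pr_sum,
                beta_sum=beta_sum, v_sum=v_sum, se2_sum=se2_sum,
                n_samples=n_samples)


def run_gibbs(data: GibbsData, prior: MixturePrior,
              config: GibbsConfig | None = None, init=None, exclusion=None,
              hooks=None) -> PosteriorSummary:
    """Run the Gibbs sampler and return post-burn-in posterior summaries.

    ``exclusion`` (used by the hybrid engine) is a dict with keys
    at_iteration / threshold activating the SNP-exclusion speed-up; None
    disables it (the full-sampler default). GEBV is Z^s g_mean, plus the
    posterior-mean polygenic value when configured.
    """
    config = config or GibbsConfig()
    if config.burnin >= config.iters:
        raise ValueError("burn-in must be smaller than the iteration count")
    m = data.m
    acc = None
    for chain in range(config.chains):
        res = _run_chain(data, prior, config, config.seed + chain, init=init,
                         exclusion=exclusion, hooks=hooks)
        if acc is None:
            acc = res
        else:
            for k in acc:
                acc[k] = acc[k] + res[k]
    ns = acc["n_samples"]
    g_mean = acc["g_sum"] / ns
    P = acc["P_count"] / ns
    gebv = data.Zs @ g_mean
    v_mean = acc["v_sum"] / ns
    if config.include_polygenic_in_gebv:
        gebv = gebv + v_mean
    return PosteriorSummary(
        g_mean=g_mean, P=P, Pr_mean=acc["Pr_sum"] / ns, gebv=gebv,
        n_samples=ns, beta_mean=acc["beta_sum"] / ns, v_mean=v_mean,
        sigma_e2_mean=acc["se2_sum"] / ns)
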