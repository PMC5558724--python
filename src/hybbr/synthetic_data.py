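"""Synthetic genotype/phenotype generator under the model's own assumptions.

Genotypes are sums of two haplotypes sampled from a Gaussian-copula
first-order Markov chain along each chromosome, giving a controllable
decay of linkage disequilibrium via the latent autocorrelation ld_rho.
SNP effects follow the four-class normal mixture used by the inference
engines; phenotypes add an optional pedigree polygenic term and
heterogeneous-precision noise generated from the same record-weight
formulas the estimators use (bull daughter counts vs cow record counts).

A single global rescaling pins the realized genic variance to the target
additive genetic variance; the rescaled mixture remains an exact
four-class normal mixture whose scale is recorded in
``SimTruth.mixture_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayesr import GAMMA
from .data_model import (GenotypeMatrix, VarianceComponents, compute_weights,
                         build_error_matrix, filter_monomorphic,
                         standardize_genotypes)

DEFAULT_PR = np.array([0.99, 0.007, 0.002, 0.001])
DEFAULT_N = 2000
DEFAULT_M = 5000
DEFAULT_H2 = 0.4


@dataclass
class SimTruth:
    g_true: np.ndarray
    class_true: np.ndarray
    Pr_true: np.ndarray
    qtl_idx: np.ndarray
    v_true: np.ndarray | None = None
    h2_target: float | None = None
    draw_sigma_g2: float = 1.0
    mixture_scale: float | None = None
    realized_genic_var: float | None = None
    realized_h2: float | None = None
    qtl_ids: np.ndarray = field(default_factory=lambda: np.array([], object))


def simulate_genotypes(n, m, maf=0.05, ld_rho=0.0, n_chrom=5,
                       seed=0) -> GenotypeMatrix:
    """Dosage matrix from 2n Markov-chain haplotypes.

    Allele frequencies are uniform on [maf, 1-maf]. Adjacent variants on a
    chromosome share a latent AR(1) Gaussian state with autocorrelation
    ld_rho in [0, 1); chains restart at chromosome boundaries.
    """
    if maf <= 0 or maf >= 0.5:
        raise ValueError("maf must be in (0, 0.5)")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf, 1.0 - maf, size=m)
    chrom_of = np.minimum(np.arange(m) * n_chrom // m, n_chrom - 1)
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom_of[1:] != chrom_of[:-1]

    x = np.empty((2 * n, m))
    innov = rng.standard_normal((2 * n, m))
    carry = np.sqrt(1.0 - ld_rho**2)
    for i in range(m):
        if new_chrom[i]:
            x[:, i] = innov[:, i]
        else:
            x[:, i] = ld_rho * x[:, i - 1] + carry * innov[:, i]
    alleles = (x < stats.norm.ppf(p)).astype(np.float64)
    dosages = alleles[:n] + alleles[n:]

    pos_within = np.zeros(m, dtype=np.int64)
    run = 0
    for i in range(m):
        run = 1 if new_chrom[i] else run + 1
        pos_within[i] = run
    variant_ids = np.array([f"snp{c + 1}_{j}" for c, j in
                            zip(chrom_of, pos_within)], dtype=object)
    return GenotypeMatrix(
        dosages, variant_ids, (chrom_of + 1).astype(str),
        pos_within * 10_000, np.array([f"id{k}" for k in range(n)], object))


def simulate_effects(m, Pr_true=None, sigma_g2=1.0, seed=0, n_qtl=0,
                     qtl_var_frac=0.0) -> SimTruth:
    """Draw SNP effects from the four-class mixture.

    class k ~ Multinomial(Pr_true); g | class k ~ N(0, gamma_k * sigma_g2).
    Optionally plant ``n_qtl`` large-effect variants jointly carrying
    ``qtl_var_frac`` of the genic variance (equal magnitudes, random
    signs, forced into the largest-variance class).
    """
    Pr_true = DEFAULT_PR if Pr_true is None else np.asarray(Pr_true, float)
    if abs(Pr_true.sum() - 1.0) > 1e-8 or Pr_true.min() < 0:
        raise ValueError("Pr_true must lie on the simplex")
    rng = np.random.default_rng(seed)
    cls = rng.choice(4, size=m, p=Pr_true)
    g = np.where(cls > 0, rng.standard_normal(m), 0.0)
    g *= np.sqrt(GAMMA[cls] * sigma_g2)
    qtl_idx = np.array([], dtype=np.int64)
    if n_qtl > 0:
        if not 0.0 < qtl_var_frac < 1.0:
            raise ValueError("qtl_var_frac must be in (0,1) when planting QTL")
        qtl_idx = np.sort(rng.choice(m, size=n_qtl, replace=False))
        g[qtl_idx] = 0.0
        rest_var = float(g @ g)
        if rest_var == 0.0:
            rest_var = sigma_g2 * (1.0 - qtl_var_frac)
        qtl_var = rest_var * qtl_var_frac / (1.0 - qtl_var_frac)
        mag = np.sqrt(qtl_var / n_qtl)
        g[qtl_idx] = mag * rng.choice((-1.0, 1.0), size=n_qtl)
        cls[qtl_idx] = 3
    return SimTruth(g_true=g, class_true=cls + 1, Pr_true=Pr_true,
                    qtl_idx=qtl_idx, draw_sigma_g2=float(sigma_g2))


def simulate_phenotypes(geno: GenotypeMatrix, truth: SimTruth,
                        vc: VarianceComponents, A=None, bull_frac=0.25,
                        seed=0, breeds=("HOL",), breed_probs=None,
                        weighting="garrick"):
    """Phenotypes y = X beta + Z^s g + v + e with weighted residuals.

    The effects in ``truth`` are rescaled (globally) so the realized genic
    variance equals vc.sigma_g2, then residuals are drawn as
    e_i ~ N(0, sigma_e2 / w_i) with w_i from the bull/cow weighting
    formulas (daughter counts ~ 20-300, cow records ~ 1-6), or w_i = 1
    with ``weighting="unit"`` (equal-precision records). beta is zero:
    phenotypes emulate pre-corrected trait deviations. Returns
    (phenotype DataFrame, E_diag); ``truth`` is updated in place with
    v_true, mixture_scale, and realized variance summaries.
    """
    rng = np.random.default_rng(seed)
    n = geno.n
    geno_f, freq, kept = filter_monomorphic(geno)
    Zs = standardize_genotypes(geno_f, freq)
    g = truth.g_true[kept]
    genic = Zs @ g
    realized = float(np.var(genic))
    if realized <= 0:
        raise ValueError("degenerate genic variance; no non-zero effects")
    scale = np.sqrt(vc.sigma_g2 / realized)
    truth.g_true = truth.g_true * scale
    # the rescaled effects are still an exact four-class mixture, with
    # class variances gamma_k * mixture_scale
    truth.mixture_scale = truth.draw_sigma_g2 * scale**2
    genic *= scale
    truth.realized_genic_var = float(np.var(genic))
    if truth.qtl_idx.size:
        truth.qtl_ids = geno.variant_ids[truth.qtl_idx]

    if A is not None and vc.sigma_a2 > 0:
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        v = np.sqrt(vc.sigma_a2) * (L @ rng.standard_normal(n))
    else:
        v = np.zeros(n)
    truth.v_true = v

    sex = np.where(rng.random(n) < bull_frac, "bull", "cow")
    d = np.where(sex == "bull", rng.integers(20, 301, size=n), 0)
    r = np.where(sex == "cow", 1 + rng.poisson(2.0, size=n), 0)
    if breed_probs is None:
        breed_probs = np.full(len(breeds), 1.0 / len(breeds))
    breed = rng.choice(np.asarray(breeds, object), size=n, p=breed_probs)
    pheno = pd.DataFrame({"animal_id": geno.sample_ids, "sex": sex,
                          "breed": breed, "d": d, "r": r})
    h2 = vc.h2
    if weighting == "unit":
        w = np.ones(n)
    elif weighting == "garrick":
        w = compute_weights(pheno, h2=h2, c=vc.c, t=vc.t)
    else:
        raise ValueError("weighting must be 'garrick' or 'unit'")
    E_diag = build_error_matrix(w)
    e = rng.standard_normal(n) * np.sqrt(vc.sigma_e2 * E_diag)
    y = genic + v + e
    pheno.insert(1, "trait", y)
    pheno["weight"] = w
    sv = float(np.var(v)) if v.any() else vc.sigma_a2
    truth.h2_target = h2
    truth.realized_h2 = truth.realized_genic_var / (
        truth.realized_genic_var + sv + vc.sigma_e2)
    return pheno, E_diag


def inference_inputs(geno: GenotypeMatrix, pheno: pd.DataFrame,
                     vc: VarianceComponents, E_diag: np.ndarray,
                     n_validation: int = 0, design: bool = True):
    """Package a simulated scenario for the inference engines.

    The last ``n_validation`` animals are held out of the reference set;
    both sets are standardized with whole-sample allele frequencies.
    Returns (GibbsData for the reference animals, aux dict with the
    validation pieces and the kept-variant mask).
    """
    from .bayesr import GibbsData
    from .data_model import build_fixed_design

    geno_f, freq, kept = filter_monomorphic(geno)
    n = geno_f.n
    ref = np.arange(n) < n - n_validation
    pheno_ref = pheno.iloc[ref.nonzero()[0]].reset_index(drop=True)
    Zs_ref = standardize_genotypes(geno_f.subset_samples(ref), freq)
    if design:
        X = build_fixed_design(pheno_ref).X
    else:
        X = np.ones((int(ref.sum()), 1))
    data = GibbsData(pheno_ref["trait"].to_numpy(float), X, Zs_ref,
                     E_diag[ref], vc)
    aux = {"kept": kept, "freq": freq, "pheno_ref": pheno_ref}
    if n_validation:
        val = ~ref
        aux["Zs_val"] = standardize_genotypes(geno_f.subset_samples(val),
                                              freq)
        aux["y_val"] = pheno["trait"].to_numpy(float)[val]
        aux["pheno_val"] = pheno.iloc[val.nonzero()[0]].reset_index(drop=True)
    return data, aux


def variance_components_for_h2(h2, sigma_g2=1.0, sigma_a2=0.0, t=0.6,
                               c=0.1) -> VarianceComponents:
    """Back out sigma_e2 so that h2 = sigma_g2/(sigma_g2+sigma_a2+sigma_e2)."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0,1)")
    sigma_e2 = sigma_g2 * (1.0 - h2) / h2 - sigma_a2
    if sigma_e2 <= 0:
        raise ValueError("h2/sigma_a2 combination implies non-positive sigma_e2")
    return VarianceComponents(sigma_g2, sigma_a2, sigma_e2, t=t, c=c)


def simulate_dataset(n=DEFAULT_N, m=DEFAULT_M, Pr_true=None, h2=DEFAULT_H2,
                     ld_rho=0.0, seed=0, n_qtl=0, qtl_var_frac=0.0,
                     sigma_g2=1.0, sigma_a2=0.0, A=None, bull_frac=0.25,
                     maf=0.05, n_chrom=5, weighting="garrick"):
    """One-stop scenario generator; returns (geno, pheno, truth, vc, E_diag).

    Defaults emulate the desk-scale analogue of a multi-breed dairy
    reference: n=2000 animals, m=5000 variants, a 99/0.7/0.2/0.1%
    four-class architecture, h2=0.4.
    """
    vc = variance_components_for_h2(h2, sigma_g2, sigma_a2)
    geno = simulate_genotypes(n, m, maf=maf, ld_rho=ld_rho, n_chrom=n_chrom,
                              seed=seed)
    truth = simulate_effects(m, Pr_true, sigma_g2=sigma_g2, seed=seed + 1,
                             n_qtl=n_qtl, qtl_var_frac=qtl_var_frac)
    pheno, E_diag = simulate_phenotypes(geno, truth, vc, A=A,
                                        bull_frac=bull_frac, seed=seed + 2,
                                        weighting=weighting)
    return geno, pheno, truth, vc, E_diag
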