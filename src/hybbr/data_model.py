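"""Core data containers and matrix builders for mixture-model genomic prediction.

This module holds the pieces every inference engine shares: the genotype
container and its standardization, the genomic (G) and pedigree (A)
relationship matrices, record weights for heterogeneous phenotype
precision (bull daughter-trait deviations vs cow trait deviations), the
diagonal error matrix E, and the fixed-effect design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ridge added to G before any inversion
GRM_RIDGE = 1e-6


@dataclass
class GenotypeMatrix:
    """n x m allele-dosage matrix with per-variant metadata.

    Dosages are counts of the alternate allele in {0, 1, 2}; missing calls
    are NaN. Variants are kept in input order; positions are 1-based.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x variants)")
        n, m = self.dosages.shape
        for name in ("variant_ids", "chrom", "pos_bp"):
            v = np.asarray(getattr(self, name))
            if v.shape[0] != m:
                raise ValueError(f"{name} length {v.shape[0]} != m={m}")
            setattr(self, name, v)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape[0] != n:
            raise ValueError("sample_ids length does not match dosage rows")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or missing (NaN)")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, mask], self.variant_ids[mask],
                              self.chrom[mask], self.pos_bp[mask],
                              self.sample_ids)

    def subset_samples(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[idx, :], self.variant_ids,
                              self.chrom, self.pos_bp, self.sample_ids[idx])


@dataclass
class Pedigree:
    """Animal / sire / dam triples; unknown parents are None (founders)."""

    animal_id: np.ndarray
    sire_id: np.ndarray
    dam_id: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        def col(name):
            v = df[name].to_numpy(dtype=object)
            v = np.where(pd.isna(v) | (v == "0") | (v == 0), None, v)
            return v

        return cls(df["animal_id"].to_numpy(dtype=object), col("sire_id"),
                   col("dam_id"))


@dataclass
class VarianceComponents:
    """Input variance components (estimated externally, e.g. by REML).

    sigma_g2: additive genetic variance captured by markers.
    sigma_a2: additive polygenic (pedigree) variance.
    sigma_e2: base error variance of a unit-weight record.
    t: repeatability (for cow record weights); c: fraction of additive
    genetic variance not captured by the markers.
    """

    sigma_g2: float
    sigma_a2: float
    sigma_e2: float
    t: float = 0.6
    c: float = 0.1

    def __post_init__(self):
        if min(self.sigma_g2, self.sigma_a2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        return heritability(self.sigma_g2, self.sigma_a2, self.sigma_e2)


@dataclass
class DesignMatrices:
    X: np.ndarray
    column_names: list = field(default_factory=list)
    E_diag: np.ndarray | None = None
    fixed_variant_ids: list = field(default_factory=list)


def compute_allele_freqs(geno: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency p_i = mean(dosage_i)/2 over non-missing calls.

    All-missing variants get p=NaN and should be dropped before analysis.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(geno.dosages, axis=0) / 2.0
    n_missing = np.isnan(geno.dosages).sum(axis=0)
    all_missing = n_missing == geno.n
    if all_missing.any():
        logger.warning("%d variants have no genotype calls", all_missing.sum())
        p = np.where(all_missing, np.nan, p)
    return p


def monomorphic_mask(freq: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """True where a variant is monomorphic (p <= tol or p >= 1-tol) or uncalled."""
    return ~((freq > tol) & (freq < 1.0 - tol))


def filter_monomorphic(geno: GenotypeMatrix,
                       freq: np.ndarray | None = None):
    """Drop monomorphic / all-missing variants; returns (geno, freq, kept_mask)."""
    if freq is None:
        freq = compute_allele_freqs(geno)
    bad = monomorphic_mask(freq)
    if bad.any():
        logger.info("excluding %d monomorphic or uncalled variants", bad.sum())
    keep = ~bad
    return geno.subset_variants(keep), freq[keep], keep


def standardize_genotypes(geno: GenotypeMatrix,
                          freq: np.ndarray | None = None) -> np.ndarray:
    """Column-standardized dosage matrix Z^s_ij = (Z_ij - 2p_i)/sqrt(2p_i(1-p_i)).

    Missing dosages are imputed to 2p_i (zero after centring). Pass ``freq``
    to standardize validation animals with reference-set frequencies.
    Returns a Fortran-ordered float64 array (column-contiguous for the
    per-SNP sweeps).
    """
    if freq is None:
        freq = compute_allele_freqs(geno)
    freq = np.asarray(freq, dtype=np.float64)
    if monomorphic_mask(freq).any():
        raise ValueError(
            "monomorphic variants present; run filter_monomorphic first")
    Z = np.array(geno.dosages, dtype=np.float64, order="F")
    mu = 2.0 * freq
    sd = np.sqrt(2.0 * freq * (1.0 - freq))
    miss = np.isnan(Z)
    if miss.any():
        Z[miss] = np.broadcast_to(mu, Z.shape)[miss]
    Z -= mu
    Z /= sd
    return np.asfortranarray(Z)


def build_grm(Zs: np.ndarray, divisor: float | None = None,
              ridge: float = GRM_RIDGE) -> np.ndarray:
    """Genomic relationship matrix G = Z^s Z^s' / m (+ ridge on the diagonal).

    The divisor defaults to the number of variants, which makes the
    expected diagonal ~1 for an outbred sample. A small ridge keeps G
    invertible when animals are duplicated or m < n.
    """
    n, m = Zs.shape
    if m == 0:
        raise ValueError("cannot build G from zero variants")
    if divisor is None:
        divisor = float(m)
    G = (Zs @ Zs.T) / divisor
    if ridge:
        G[np.diag_indices(n)] += ridge
    return G


def build_nrm(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Pedigree numerator relationship matrix by the tabular method.

    Henderson's recursion after a topological sort:
    A_ii = 1 + 0.5 * A(sire, dam); A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i)).
    Unknown parents are unrelated founders. Returns (A, animal order used).

    Raises ValueError on a pedigree cycle.
    """
    from graphlib import CycleError, TopologicalSorter

    ids = list(ped.animal_id)
    known = set(ids)
    ts = TopologicalSorter()
    parents = {}
    for a, s, d in zip(ped.animal_id, ped.sire_id, ped.dam_id):
        preds = [p for p in (s, d) if p is not None and p in known]
        ts.add(a, *preds)
        parents[a] = (s if s in known else None, d if d in known else None)
    try:
        order = list(ts.static_order())
    except CycleError as err:
        raise ValueError(f"pedigree contains a cycle: {err.args}") from err
    pos = {a: i for i, a in enumerate(order)}
    q = len(order)
    A = np.zeros((q, q))
    for a in order:
        i = pos[a]
        s, d = parents[a]
        si = pos[s] if s is not None else -1
        di = pos[d] if d is not None else -1
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * A[j, si]
            if di >= 0:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    return A, np.array(order, dtype=object)


def heritability(sigma_g2: float, sigma_a2: float, sigma_e2: float) -> float:
    """Narrow-sense h2 = sigma_g2 / (sigma_g2 + sigma_a2 + sigma_e2)."""
    total = sigma_g2 + sigma_a2 + sigma_e2
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sigma_g2 / total


def garrick_weight(sex: str, h2: float, c: float, d: float | None = None,
                   r: float | None = None, t: float | None = None) -> float:
    """Record weight for heterogeneous phenotype precision.

    Bulls (daughter trait deviations from d daughters):
        w = (1 - h2) / (c*h2 + (4 - h2)/d)
    Cows (trait deviations from r own records with repeatability t):
        w = (1 - h2) / (c*h2 + [1 + (r-1)*t]/r - h2)
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must be in (0,1), got {h2}")
    if sex == "bull":
        if d is None or d < 1:
            raise ValueError("bulls need a daughter count d >= 1")
        denom = c * h2 + (4.0 - h2) / d
    elif sex == "cow":
        if r is None or r < 1:
            raise ValueError("cows need a record count r >= 1")
        if t is None:
            raise ValueError("cows need the repeatability t")
        denom = c * h2 + (1.0 + (r - 1.0) * t) / r - h2
    else:
        raise ValueError(f"sex must be 'bull' or 'cow', got {sex!r}")
    if denom <= 0:
        raise ValueError(
            f"non-positive weight denominator ({denom:.4g}) for sex={sex}, "
            f"h2={h2}, c={c}, d={d}, r={r}, t={t}")
    return (1.0 - h2) / denom


def compute_weights(pheno: pd.DataFrame, h2: float, c: float,
                    t: float) -> np.ndarray:
    """Vector of Garrick weights for a phenotype table (sex, d, r columns)."""
    w = np.empty(len(pheno))
    for i, row in enumerate(pheno.itertuples(index=False)):
        if row.sex == "bull":
            w[i] = garrick_weight("bull", h2, c, d=row.d)
        else:
            w[i] = garrick_weight("cow", h2, c, r=row.r, t=t)
    return w


def build_error_matrix(weights: np.ndarray) -> np.ndarray:
    """Diagonal of E: residual variance multiplier 1/w_i per record."""
    weights = np.asarray(weights, dtype=np.float64)
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    return 1.0 / weights


def build_fixed_design(pheno: pd.DataFrame,
                       fixed_variants: list | None = None,
                       geno: GenotypeMatrix | None = None) -> DesignMatrices:
    """Fixed-effect design: [mean | breed indicators | sex indicator | fixed-variant dosages].

    Single-level breed/sex factors contribute no column (they are absorbed
    by the mean); collinear columns are pruned with a warning. Variants
    fitted as fixed effects must afterwards be removed from the random-SNP
    set (their ids are echoed in ``fixed_variant_ids``).
    """
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["mean"]
    if "breed" in pheno.columns:
        levels = pd.unique(pheno["breed"])
        for lev in levels[1:]:
            cols.append((pheno["breed"] == lev).to_numpy(float))
            names.append(f"breed={lev}")
    if "sex" in pheno.columns:
        levels = pd.unique(pheno["sex"])
        for lev in levels[1:]:
            cols.append((pheno["sex"] == lev).to_numpy(float))
            names.append(f"sex={lev}")
    fixed_ids = []
    if fixed_variants:
        if geno is None:
            raise ValueError("fixed variants requested but no genotypes given")
        vid = list(geno.variant_ids)
        for v in fixed_variants:
            if v not in vid:
                raise KeyError(f"fixed variant {v!r} not in genotype matrix")
            j = vid.index(v)
            col = geno.dosages[:, j].copy()
            col[np.isnan(col)] = np.nanmean(col)
            cols.append(col)
            names.append(f"variant:{v}")
            fixed_ids.append(v)
    X = np.column_stack(cols)
    # prune rank-deficient columns, keeping earlier ones
    keep = []
    rank = 0
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > rank:
            keep.append(j)
            rank += 1
        else:
            logger.warning("pruning collinear design column %r", names[j])
    X = X[:, keep]
    names = [names[j] for j in keep]
    return DesignMatrices(X=X, column_names=names,
                          fixed_variant_ids=fixed_ids)
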