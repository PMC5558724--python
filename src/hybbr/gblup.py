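"""GBLUP: Henderson mixed-model equations with genomic and polygenic effects.

Model: y = X beta + S u + W v + e, with u ~ N(0, G sigma_g2),
v ~ N(0, A sigma_a2), e ~ N(0, E sigma_e2). Solved by direct factorization
of the dense coefficient matrix, which also yields the inverse blocks
needed for prediction error variances (PEV). Intended scale is up to a
few tens of thousands of animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data_model import VarianceComponents


@dataclass
class MMESolution:
    """Solution of the mixed-model equations plus the pieces PEV needs."""

    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray | None
    C_inv: np.ndarray          # inverse of the full coefficient matrix
    blocks: dict               # slices of (beta, u, v) within C_inv
    sigma_e2: float

    @property
    def pev_u(self) -> np.ndarray:
        """Var(u - u_hat): the u-block of the inverted coefficient matrix."""
        s = self.blocks["u"]
        return self.C_inv[s, s]


def solve_mme(y: np.ndarray, X: np.ndarray, G: np.ndarray,
              A: np.ndarray | None, E_diag: np.ndarray,
              vc: VarianceComponents,
              obs_idx: np.ndarray | None = None) -> MMESolution:
    """Solve the mixed-model equations.

    ``obs_idx`` maps phenotype rows to rows of G/A (defaults to identity,
    i.e. every relationship-matrix animal has one record). The polygenic
    block is dropped when sigma_a2 = 0 or A is None. Raises
    ``np.linalg.LinAlgError`` naming the degenerate block if the
    coefficient matrix cannot be factorized.
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    q = G.shape[0]
    if obs_idx is None:
        if n != q:
            raise ValueError("y length != G size; pass obs_idx")
        obs_idx = np.arange(n)
    if vc.sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    w = 1.0 / (np.asarray(E_diag, float) * vc.sigma_e2)  # R^-1 diagonal
    b = X.shape[1]
    use_v = A is not None and vc.sigma_a2 > 0

    # S'R^-1 S is diagonal-scatter: accumulate record weights per animal
    su_w = np.zeros(q)
    np.add.at(su_w, obs_idx, w)
    Xw = X * w[:, None]
    XtX = X.T @ Xw
    XtS = np.zeros((b, q))
    np.add.at(XtS.T, obs_idx, Xw)   # X'R^-1 S
    Xty = Xw.T @ y
    Sty = np.zeros(q)
    np.add.at(Sty, obs_idx, w * y)

    dim = b + q + (q if use_v else 0)
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    sb = slice(0, b)
    su = slice(b, b + q)
    C[sb, sb] = XtX
    C[sb, su] = XtS
    C[su, sb] = XtS.T
    try:
        G_inv = linalg.inv(G, check_finite=False)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"G block not invertible: {err}") from err
    if vc.sigma_g2 <= 0:
        # prior variance zero: u is identically zero; solve WLS for beta
        beta = np.linalg.solve(XtX, Xty)
        C_inv = np.zeros((b + q, b + q))
        C_inv[sb, sb] = np.linalg.inv(XtX)
        return MMESolution(beta, np.zeros(q), None, C_inv,
                           {"beta": sb, "u": su, "v": None}, vc.sigma_e2)
    C[su, su] = np.diag(su_w) + G_inv / vc.sigma_g2
    rhs[sb] = Xty
    rhs[su] = Sty
    sv = None
    if use_v:
        sv = slice(b + q, b + 2 * q)
        try:
            A_inv = linalg.inv(A, check_finite=False)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"A block not invertible: {err}") from err
        C[sv, sv] = np.diag(su_w) + A_inv / vc.sigma_a2
        C[su, sv] = np.diag(su_w)
        C[sv, su] = np.diag(su_w)
        C[sb, sv] = XtS
        C[sv, sb] = XtS.T
        rhs[sv] = Sty
    try:
        C_inv = linalg.inv(C, check_finite=False)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "mixed-model coefficient matrix is singular "
            f"(b={b}, q={q}, polygenic={use_v}): {err}") from err
    sol = C_inv @ rhs
    return MMESolution(sol[sb], sol[su], sol[sv] if use_v else None,
                       C_inv, {"beta": sb, "u": su, "v": sv}, vc.sigma_e2)


def compute_pev_u(sol: MMESolution) -> np.ndarray:
    """Prediction error variance of u (dense q x q block)."""
    return sol.pev_u


def predict_gebv(u_hat: np.ndarray, G_val_ref: np.ndarray,
                 G_ref_ref: np.ndarray) -> np.ndarray:
    """Conditional-mean genomic prediction for animals without phenotypes.

    GEBV_val = G_val,ref G_ref,ref^-1 u_hat. Both G blocks must come from
    the same variant set (same standardization frequencies).
    """
    if G_val_ref.shape[1] != G_ref_ref.shape[0]:
        raise ValueError("G_val_ref and G_ref_ref dimensions do not match")
    return G_val_ref @ np.linalg.solve(G_ref_ref, u_hat)
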