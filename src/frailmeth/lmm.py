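"""Restricted-maximum-likelihood linear mixed models with crossed random
intercepts.

The region-classification stage fits, per region, a model with fixed terms
(logFI and/or age) and two *crossed* random intercepts: mouse (repeated
measures) and CpG (region members share a fixed design but differ in
baseline level).  The covariance is

    V = sigma^2 (I + sum_k gamma_k Z_k Z_k')

with one-hot ``Z_k`` per grouping factor.  Because the number of random
levels q is small (tens) while n can be in the thousands, the REML
criterion is evaluated from the cross-product matrices via the Woodbury
identity; each evaluation costs O(q^3) after an O(n q^2) setup, so fitting
hundreds of regions is cheap.  The residual scale is profiled out and the
variance ratios gamma_k are optimised on the log scale with Nelder-Mead.

Inference on fixed effects is a Wald test against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class LmmFit:
    """REML fit: fixed effects, Wald inference and variance components."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2: float
    vcomp: dict[str, float]
    converged: bool
    nobs: int
    df_resid: int

    def wald_p(self, name: str) -> float:
        return float(self.pvalues[name])

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        c, s = float(self.params[name]), float(self.bse[name])
        return c - z * s, c + z * s


def _one_hot(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    _, idx = np.unique(codes, return_inverse=True)
    q = idx.max() + 1
    Z = np.zeros((codes.size, q))
    Z[np.arange(codes.size), idx] = 1.0
    return Z


def fit_reml(
    y,
    X: pd.DataFrame,
    groups: dict[str, np.ndarray],
    maxiter: int = 500,
) -> LmmFit:
    """Fit ``y = X b + sum_k Z_k u_k + e`` by REML.

    ``groups`` maps a factor name to per-row level codes; each factor
    contributes an independent random intercept.  Factors with a single
    level are dropped (no estimable variance).
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("fixed-effect design is rank deficient")

    blocks: list[tuple[str, np.ndarray]] = []
    for name, codes in groups.items():
        Z = _one_hot(np.asarray(codes))
        if Z.shape[1] >= 2:
            blocks.append((name, Z))

    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    yty = float(y @ y)

    if not blocks:
        beta = np.linalg.solve(XtX, Xty)
        rss = yty - beta @ Xty
        sigma2 = rss / max(n - p, 1)
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
        z = beta / np.where(se > 0, se, np.nan)
        pv = 2 * stats.norm.sf(np.abs(z))
        return LmmFit(
            pd.Series(beta, index=names), pd.Series(se, index=names),
            pd.Series(pv, index=names), float(sigma2), {}, True, n, n - p,
        )

    # order blocks so the largest factor comes last: its ZtZ block is
    # diagonal (one-hot columns), so it can be Schur-eliminated cheaply and
    # the Cholesky runs only on the small remainder
    blocks.sort(key=lambda b: b[1].shape[1])
    Z = np.hstack([b for _, b in blocks])
    sizes = [b.shape[1] for _, b in blocks]
    q = Z.shape[1]
    ZtX = Z.T @ Xm
    Zty = Z.T @ y

    sizes_arr = np.asarray(sizes)
    ZtXy = np.column_stack([ZtX, Zty])
    nb = sizes[-1]                    # eliminated (largest) factor
    nr = q - nb
    Zr, Zb = Z[:, :nr], Z[:, nr:]
    Arr0 = Zr.T @ Zr
    Arb = Zr.T @ Zb                   # nr x nb
    counts_b = np.einsum("ij,ij->j", Zb, Zb)
    rhs_r, rhs_b = ZtXy[:nr], ZtXy[nr:]
    rep_r = np.repeat(np.arange(len(sizes) - 1), sizes_arr[:-1])
    diag_r = np.arange(nr)

    def pieces(theta):
        gam = np.exp(theta)
        d_b = counts_b + 1.0 / gam[-1]
        W = Arb / d_b[None, :]
        if nr:
            S = Arr0 - W @ Arb.T
            S[diag_r, diag_r] += 1.0 / gam[rep_r]
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                return None
            from scipy.linalg import cho_solve

            t = rhs_r - W @ rhs_b
            z_r = cho_solve((L, True), t, check_finite=False)
            z_b = (rhs_b - Arb.T @ z_r) / d_b[:, None]
            logdet_a = float(np.log(d_b).sum()) + 2.0 * np.log(np.diag(L)).sum()
        else:
            z_r = np.zeros((0, ZtXy.shape[1]))
            z_b = rhs_b / d_b[:, None]
            logdet_a = float(np.log(d_b).sum())
        AinvZtXy = np.vstack([z_r, z_b])
        # [X y]' W [X y] = [X y]'[X y] - (Z'[X y])' A^-1 (Z'[X y])
        corr = ZtXy.T @ AinvZtXy      # (p+1) x (p+1)
        XtWX = XtX - corr[:p, :p]
        XtWy = Xty - corr[:p, p]
        ytWy = yty - corr[p, p]
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return None
        rss = max(ytWy - beta @ XtWy, 1e-300)
        # log|I + D Z'Z| = log|A| + sum_k q_k log gamma_k
        logdet_v = logdet_a + float(sizes_arr @ theta)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return None
        crit = (n - p) * np.log(rss) + logdet_v + logdet_xwx
        return crit, beta, rss, XtWX

    def objective(theta):
        out = pieces(np.clip(theta, -14.0, 10.0))
        return np.inf if out is None else out[0]

    k = len(blocks)
    x0 = np.zeros(k)
    simplex = np.vstack([x0, x0 + 1.5 * np.eye(k)])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 5e-3, "fatol": 1e-4,
                 "initial_simplex": simplex},
    )
    theta = np.clip(res.x, -14.0, 10.0)
    out = pieces(theta)
    if out is None:
        raise FloatingPointError("REML criterion undefined at optimum")
    _, beta, rss, XtWX = out
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / np.where(se > 0, se, np.nan)
    pv = 2 * stats.norm.sf(np.abs(z))
    gam = np.exp(theta)
    vcomp = {
        name: float(g * sigma2) for (name, _), g in zip(blocks, gam)
    }
    return LmmFit(
        pd.Series(beta, index=names), pd.Series(se, index=names),
        pd.Series(pv, index=names), float(sigma2), vcomp, bool(res.success),
        n, n - p,
    )


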