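"""Repeated-measures epigenome-wide association of M-values with logFI.

Per probe, M-values are regressed on a group-means design (sex indicators
plus per-sex logFI slopes in the sex-inclusive mode; intercept plus logFI
when stratified) by generalized least squares under a block
compound-symmetry covariance: samples from the same mouse share a single
consensus correlation ``rho`` estimated across probes.  Residual variances
are then shrunk by empirical Bayes (scaled inverse-chi-square prior fitted
by method of moments on log s^2), giving moderated t statistics for the
stratified logFI slope and a moderated F over the two sex-specific logFI
slopes in the sex-inclusive mode.  DMPs are probes below a
Benjamini-Hochberg FDR threshold.

Missing betas are excluded pairwise: each probe is fitted on its observed
samples, with the block whitening recomputed from that probe's observed
block sizes.  All probes are processed simultaneously via batched linear
algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma, psi

from .core_data import MethylationMatrix, bh_adjust, log_fi

DEFAULT_FI_FLOOR = 0.5 / 62  # half the smallest positive value on the FI grid


@dataclass
class DesignSpec:
    """EWAS design: mode, exclusions and the logFI floor.

    ``sex_inclusive`` uses group-means coding (sexF, sexM, sexF:logFI,
    sexM:logFI -- no reference level) and by default drops male samples at
    the last timepoint, mirroring the unbalanced survivorship of aged male
    mice.  Stratified modes use intercept + logFI on one sex.
    """

    mode: str = "sex_inclusive"
    drop_male_t5: bool = True
    fi_floor: float = DEFAULT_FI_FLOOR

    def __post_init__(self) -> None:
        if self.mode not in ("sex_inclusive", "female_only", "male_only"):
            raise ValueError(f"unknown design mode {self.mode!r}")

    @property
    def focal_columns(self) -> list[str]:
        if self.mode == "sex_inclusive":
            return ["sexF_logFI", "sexM_logFI"]
        return ["logFI"]


def build_design(samples: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Design matrix (rows = retained samples) for the requested mode."""
    sheet = samples
    if spec.mode == "female_only":
        sheet = sheet[sheet["sex"] == "F"]
    elif spec.mode == "male_only":
        sheet = sheet[sheet["sex"] == "M"]
    elif spec.drop_male_t5:
        last_t = sheet["timepoint"].max()
        sheet = sheet[~((sheet["sex"] == "M") & (sheet["timepoint"] == last_t))]
    if sheet.empty:
        raise ValueError("no samples left after design exclusions")
    lfi = log_fi(sheet["fi"].to_numpy(), floor=spec.fi_floor)
    if spec.mode == "sex_inclusive":
        f = (sheet["sex"] == "F").to_numpy(dtype=float)
        m = 1.0 - f
        if f.sum() == 0 or m.sum() == 0:
            raise ValueError("sex_inclusive design requires both sexes")
        X = pd.DataFrame(
            {"sexF": f, "sexM": m, "sexF_logFI": f * lfi, "sexM_logFI": m * lfi},
            index=sheet.index,
        )
    else:
        X = pd.DataFrame({"intercept": 1.0, "logFI": lfi}, index=sheet.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# Batched GLS under block compound symmetry


def _block_indicator(blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(np.asarray(blocks), return_inverse=True)
    ind = np.zeros((codes.size, levels.size))
    ind[np.arange(codes.size), codes] = 1.0
    return ind, codes


def _whiten(Mv, X, blocks, rho):
    """Whitened response/design per probe under its observed block sizes.

    Within a block of k observed samples the correlation matrix
    ``(1-rho) I + rho J`` has square-root inverse acting as
    ``(y - ybar)/sqrt(1-rho) + ybar/sqrt(1+(k-1) rho)`` where ybar is the
    block mean; this is applied with the block counts recomputed per probe
    from its missingness pattern.  Masked entries are zeroed so batched
    cross-products skip them.
    """
    P, S = Mv.shape
    C = X.shape[1]
    ind, codes = _block_indicator(blocks)
    obs = ~np.isnan(Mv)
    k_pb = obs @ ind                      # P x B observed block sizes
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pb = (np.nan_to_num(Mv) @ ind) / np.where(k_pb > 0, k_pb, 1.0)
        s1 = 1.0 / np.sqrt(1.0 - rho)
        s2_pb = 1.0 / np.sqrt(1.0 + (k_pb - 1.0) * rho)
    mean_ps = mean_pb[:, codes]
    s2_ps = s2_pb[:, codes]
    Yw = (np.nan_to_num(Mv) - mean_ps) * s1 + mean_ps * s2_ps
    Yw[~obs] = 0.0

    # per-probe block means of each design column over observed samples
    xmean = np.empty((P, ind.shape[1], C))
    for c in range(C):
        with np.errstate(invalid="ignore", divide="ignore"):
            xmean[:, :, c] = ((obs * X[:, c][None, :]) @ ind) / np.where(
                k_pb > 0, k_pb, 1.0
            )
    xmean_ps = xmean[:, codes, :]                       # P x S x C
    Xw = (X[None, :, :] - xmean_ps) * s1 + xmean_ps * s2_ps[:, :, None]
    Xw[~obs] = 0.0
    return Yw, Xw, obs


def fit_probe_models(
    M: pd.DataFrame,
    X: pd.DataFrame,
    blocks,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Per-probe GLS fits; returns coefficients, s2, residual df and the
    unscaled coefficient (co)variances needed for moderated statistics.

    With ``rho = 0`` this reduces exactly to ordinary least squares.
    """
    cols = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient (columns: {bad})")
    Mv = M.to_numpy(dtype=float)
    P, S = Mv.shape
    C = Xm.shape[1]
    Yw, Xw, obs = _whiten(Mv, Xm, np.asarray(blocks), rho)

    XtX = np.einsum("psc,psd->pcd", Xw, Xw)
    Xty = np.einsum("psc,ps->pc", Xw, Yw)
    yty = np.einsum("ps,ps->p", Yw, Yw)
    XtX_inv = np.linalg.pinv(XtX)
    beta = np.einsum("pcd,pd->pc", XtX_inv, Xty)
    rss = np.maximum(yty - np.einsum("pc,pc->p", beta, Xty), 0.0)
    n_obs = obs.sum(axis=1)
    df = n_obs - C
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)

    out = pd.DataFrame(beta, index=M.index, columns=[f"coef_{c}" for c in cols])
    out["s2"] = s2
    out["df_resid"] = df
    for i, c in enumerate(cols):
        out[f"uvar_{c}"] = XtX_inv[:, i, i]
    # unscaled covariance between the two focal columns (for the F test)
    out.attrs["columns"] = cols
    out.attrs["xtx_inv"] = XtX_inv
    return out


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    cols = list(X.columns)
    for i in range(1, len(cols) + 1):
        if np.linalg.matrix_rank(X[cols[:i]].to_numpy()) < i:
            bad.append(cols[i - 1])
    return bad


def estimate_consensus_correlation(
    M: pd.DataFrame, X: pd.DataFrame, blocks
) -> tuple[float, int]:
    """Consensus intra-block (within-mouse) correlation shared across probes.

    Per probe: OLS residuals of the design are decomposed by a one-way
    random-intercept moment estimator (between/within mouse mean squares);
    the per-probe correlations are Fisher-z transformed, 10%-trimmed-mean
    averaged, and transformed back.
    """
    Xm = X.to_numpy(dtype=float)
    Mv = M.to_numpy(dtype=float)
    ind, codes = _block_indicator(np.asarray(blocks))
    if (ind.sum(axis=0) <= 1).all():
        warnings.warn("all blocks are singletons; consensus correlation is 0")
        return 0.0, 0
    fits = fit_probe_models(M, X, blocks, rho=0.0)
    beta = fits[[c for c in fits.columns if c.startswith("coef_")]].to_numpy()
    resid = Mv - beta @ Xm.T
    obs = ~np.isnan(Mv)
    R0 = np.nan_to_num(resid)

    k_pb = obs @ ind
    sum_pb = R0 @ ind
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pb = sum_pb / np.where(k_pb > 0, k_pb, 1.0)
    n_p = obs.sum(axis=1).astype(float)
    grand = R0.sum(axis=1) / n_p
    ssb = np.einsum("pb,pb->p", k_pb, (mean_pb - grand[:, None]) ** 2 * (k_pb > 0))
    sst = np.einsum("ps,ps->p", R0 - grand[:, None] * obs, R0 - grand[:, None] * obs)
    ssw = sst - ssb
    b_p = (k_pb > 0).sum(axis=1).astype(float)
    ok = (b_p > 1) & (n_p - b_p > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb / (b_p - 1)
        msw = ssw / (n_p - b_p)
        n0 = (n_p - (k_pb**2).sum(axis=1) / n_p) / (b_p - 1)
        rho_p = (msb - msw) / (msb + (n0 - 1) * msw)
    rho_p = rho_p[ok & np.isfinite(rho_p)]
    if rho_p.size == 0:
        warnings.warn("no probe provided a within-block correlation; using 0")
        return 0.0, 0
    z = np.arctanh(np.clip(rho_p, -0.95, 0.95))
    rho = float(np.tanh(stats.trim_mean(z, 0.1)))
    return rho, int(rho_p.size)


# ---------------------------------------------------------------------------
# Empirical Bayes variance moderation


def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for y by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse needs a positive argument")
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * abs(y):
            break
    return float(y)


D0_CAP = 1e7


def moderate_variances(s2, df) -> tuple[float, float, np.ndarray]:
    """Fit the scaled inverse-chi-square prior for residual variances.

    Method of moments on ``log s^2`` via digamma/trigamma inversion, as in
    empirical-Bayes variance shrinkage for expression/methylation arrays.
    Returns ``(d0, s0^2, posterior variances)``; probes with zero or
    missing s^2 are excluded from the moment fit and assigned the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 positive variances; moment fit unstable")
    e = np.log(s2[ok]) - psi(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        d0 = min(d0, D0_CAP)
        s02 = float(np.exp(emean + psi(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion in log s^2: point-mass prior, plain mean scale
        d0 = D0_CAP
        s02 = float(np.mean(s2[ok]))
    post = np.where(
        ok,
        (d0 * s02 + df * np.nan_to_num(s2)) / (d0 + df),
        s02,
    )
    return d0, s02, post


@dataclass
class EwasResult:
    table: pd.DataFrame
    spec: DesignSpec
    rho: float
    d0: float
    s02: float
    design: pd.DataFrame


def run_ewas(
    mat: MethylationMatrix,
    spec: DesignSpec | None = None,
    moderate: bool = True,
    rho: float | None = None,
    clip_eps: float = 1e-6,
) -> EwasResult:
    """Full EWAS: design, consensus correlation, GLS, moderation, p-values.

    Set ``moderate=False`` (d0 = 0) for ordinary (unmoderated) statistics,
    or pass ``rho`` explicitly to skip the consensus estimate.
    """
    spec = spec or DesignSpec()
    X = build_design(mat.samples, spec)
    M = mat.m_values(clip_eps)[X.index]
    blocks = mat.samples.loc[X.index, "mouse_id"].to_numpy()
    if rho is None:
        rho, _ = estimate_consensus_correlation(M, X, blocks)
    fits = fit_probe_models(M, X, blocks, rho=rho)
    s2 = fits["s2"].to_numpy()
    df = fits["df_resid"].to_numpy().astype(float)
    if moderate:
        d0, s02, post = moderate_variances(s2, df)
    else:
        d0, s02 = 0.0, float("nan")
        post = s2
    total_df = np.minimum(d0 + df, 1e7)

    focal = spec.focal_columns
    xtx_inv = fits.attrs["xtx_inv"]
    cols = fits.attrs["columns"]
    if len(focal) == 1:
        j = cols.index(focal[0])
        se = np.sqrt(post * xtx_inv[:, j, j])
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = fits[f"coef_{focal[0]}"].to_numpy() / se
        p = 2 * stats.t.sf(np.abs(stat), total_df)
        weight = np.abs(stat)
        effect = fits[f"coef_{focal[0]}"].to_numpy()
        stat_name = "t"
    else:
        idx = [cols.index(c) for c in focal]
        sub = xtx_inv[np.ix_(np.arange(len(fits)), idx, idx)]
        b = fits[[f"coef_{c}" for c in focal]].to_numpy()
        sub_inv = np.linalg.pinv(sub)
        quad = np.einsum("pc,pcd,pd->p", b, sub_inv, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = quad / (len(focal) * post)
        p = stats.f.sf(stat, len(focal), total_df)
        weight = np.sqrt(np.maximum(stat, 0.0))
        effect = b.mean(axis=1)
        stat_name = "F"

    table = pd.DataFrame(
        {
            "chrom": mat.probes["chrom"],
            "pos": mat.probes["pos"],
            "stat": stat,
            "p": p,
            "weight": weight,
            "effect": effect,
            "s2": s2,
            "post_var": post,
            "df_resid": df,
        },
        index=fits.index,
    )
    for c in cols:
        table[f"coef_{c}"] = fits[f"coef_{c}"]
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table.attrs["stat_name"] = stat_name
    return EwasResult(table, spec, rho, d0, s02, X)


def call_dmps(result: EwasResult | pd.DataFrame, fdr: float = 0.05) -> pd.Index:
    """Probes significant at the BH-adjusted threshold."""
    table = result.table if isinstance(result, EwasResult) else result
    return table.index[table["adj_p"] < fdr]


def context_enrichment(
    dmps: pd.Index, annotation: pd.DataFrame, context: str
) -> dict:
    """2x2 Pearson chi-square (1 df, no continuity correction) comparing the
    genomic-context proportion among DMPs against all annotated probes."""
    if context == "island":
        in_ctx = annotation["island_relation"] == "island"
    elif context == "TSS200":
        in_ctx = annotation["tss_relation"] == "TSS200"
    elif context.startswith("chr"):
        in_ctx = annotation["chrom"] == context
    else:
        raise ValueError(f"unknown context {context!r}")
    is_dmp = annotation.index.isin(dmps)
    table = np.array(
        [
            [np.sum(is_dmp & in_ctx), np.sum(is_dmp & ~in_ctx)],
            [np.sum(~is_dmp & in_ctx), np.sum(~is_dmp & ~in_ctx)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "chi2": float(chi2),
        "p": float(p),
        "prop_dmp": float(table[0, 0] / table[0].sum()),
        "prop_all": float(in_ctx.mean()),
        "table": table,
    }


def pca_variance_partition(
    M: pd.DataFrame,
    samples: pd.DataFrame,
    factors: tuple[str, ...] = ("mouse_id", "timepoint", "sex", "cage", "age",
                                "fi_residual"),
    var_threshold: float = 0.95,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> dict:
    """Variance partitioning of M-value PCs across sample-level factors.

    PCA is run on probe-centered M-values (probe means imputed for the few
    missing entries); the smallest PC set explaining ``var_threshold`` of
    the variance is retained.  Each retained PC is regressed on each factor
    alone; the factor's share is the PC-variance-weighted sum of R^2.
    ``fi_residual`` is the residual of logFI on age.
    """
    Mv = M.to_numpy(dtype=float)
    means = np.nanmean(Mv, axis=1)
    Mv = np.where(np.isnan(Mv), means[:, None], Mv) - means[:, None]
    Xs = Mv.T  # samples x probes, probe-centered
    n = Xs.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    var = S**2
    w = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(w), var_threshold) + 1)
    n_keep = min(n_keep, len(w))
    scores = U[:, :n_keep] * S[:n_keep]
    w = w[:n_keep]

    sheet = samples.loc[M.columns]
    values: dict[str, np.ndarray] = {}
    for f in factors:
        if f == "age":
            values[f] = sheet["age_months"].to_numpy(dtype=float)
        elif f == "fi_residual":
            lfi = log_fi(sheet["fi"].to_numpy(), floor=fi_floor)
            age = sheet["age_months"].to_numpy(dtype=float)
            A = np.column_stack([np.ones(n), age])
            values[f] = lfi - A @ np.linalg.lstsq(A, lfi, rcond=None)[0]
        elif f in sheet.columns:
            values[f] = sheet[f].to_numpy()
        else:
            warnings.warn(f"factor {f!r} not in the sample sheet; skipped")

    shares: dict[str, float] = {}
    pmat = pd.DataFrame(index=[f"PC{k + 1}" for k in range(n_keep)],
                        columns=list(values), dtype=float)
    r2mat = pmat.copy()
    for name, v in values.items():
        if _is_constant(v):
            warnings.warn(f"factor {name!r} is constant; share set to 0")
            shares[name] = 0.0
            pmat[name] = np.nan
            continue
        D = _factor_design(v)
        q = D.shape[1]
        H, _, _, _ = np.linalg.lstsq(D, scores, rcond=None)
        fitted = D @ H
        resid = scores - fitted
        sst = ((scores - scores.mean(axis=0)) ** 2).sum(axis=0)
        sse = (resid**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
        df1 = q - 1
        df2 = n - q
        if df1 <= 0 or df2 <= 0:
            pvals = np.full(n_keep, np.nan)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                fstat = (r2 / df1) / np.maximum((1 - r2) / df2, 1e-300)
            pvals = stats.f.sf(fstat, df1, df2)
        shares[name] = float(np.sum(w * r2))
        pmat[name] = pvals
        r2mat[name] = r2

    order = list(pmat.columns)
    finite = pmat.dropna(axis=1, how="all")
    if finite.shape[1] > 2:
        from scipy.cluster.hierarchy import leaves_list, linkage

        logp = -np.log10(np.clip(finite.to_numpy(dtype=float).T, 1e-300, 1.0))
        logp = np.nan_to_num(logp)
        order = [finite.columns[i] for i in leaves_list(linkage(logp, "average"))]
    return {
        "shares": shares,
        "pc_weights": w,
        "n_pcs": n_keep,
        "p_values": pmat,
        "r2": r2mat,
        "cluster_order": order,
    }


def _is_constant(v) -> bool:
    arr = np.asarray(v)
    return np.unique(arr.astype(str)).size < 2


def _factor_design(v) -> np.ndarray:
    arr = np.asarray(v)
    if arr.dtype.kind in "fi" and np.unique(arr).size > 12:
        return np.column_stack([np.ones(arr.size), arr.astype(float)])
    _, codes = np.unique(arr.astype(str), return_inverse=True)
    D = np.zeros((arr.size, codes.max() + 1))
    D[np.arange(arr.size), codes] = 1.0
    return D
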