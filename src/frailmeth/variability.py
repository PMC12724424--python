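"""Methylation variability with frailty: random-slope decomposition,
Breusch-Pagan variably methylated probes (VMPs), signal-to-noise classes
and per-sample Shannon entropy.

Inter-individual variability is decomposed per CpG by a mixed model with
correlated random intercept and slope on logFI per mouse (baseline level
vs trajectory heterogeneity).  Intra-group heteroscedasticity is detected
by the Breusch-Pagan test on the per-probe mean model (squared residuals
regressed on logFI; LM statistic n R^2 against chi-square(1)); VMPs at
BH-adjusted p < 0.1 are then split into deterministic (SNR > 10),
stochastic (SNR < 1) and intermediate classes, where SNR is the variance
of the fitted frailty component over the residual variance.  Shannon
entropy summarizes per-sample disorder over a CpG set, in [0, 1] with log
base 2 and per-site averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import bh_adjust, log_fi
from .ewas import DEFAULT_FI_FLOOR


@dataclass
class VarianceDecomposition:
    probe_id: str
    intercept_var: float
    slope_var: float
    residual_var: float
    correlated: bool  # False when the fit fell back to independent effects
    converged: bool


def random_slope_decomposition(
    long: pd.DataFrame, probe_id: str = ""
) -> VarianceDecomposition:
    """REML fit of M ~ logFI with correlated random intercept + slope per
    mouse; falls back to independent random effects on non-convergence.

    ``long`` needs columns M, logFI and mouse_id with >= 5 mice observed
    >= 2 times each.
    """
    import statsmodels.formula.api as smf

    counts = long.groupby("mouse_id").size()
    if (counts >= 2).sum() < 5:
        raise ValueError("need at least 5 mice with repeated observations")
    data = long.rename(columns={"M": "m_val", "logFI": "logfi"}).copy()

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "m_val ~ logfi", data, groups=data["mouse_id"],
                re_formula=re_formula,
            )
            return model.fit(reml=True, method="lbfgs", maxiter=200)

    correlated, converged = True, True
    try:
        res = _fit("~logfi")
        converged = bool(res.converged)
        if not converged:
            raise ValueError
    except Exception:
        correlated = False
        res = _fit("0 + logfi")
        converged = bool(res.converged)
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    if correlated:
        ivar, svar = float(cov_re[0, 0]), float(cov_re[1, 1])
    else:
        ivar, svar = 0.0, float(cov_re[0, 0])
    return VarianceDecomposition(
        probe_id=probe_id,
        intercept_var=ivar,
        slope_var=svar,
        residual_var=float(res.scale),
        correlated=correlated,
        converged=converged,
    )


def _mean_model(y, lfi, sex=None, mouse=None):
    """OLS mean model M ~ logFI (+ sex; + mouse fixed effects).

    With repeated measures, per-mouse intercepts absorb the baseline
    heterogeneity between mice; otherwise the within-mouse correlation of
    residuals inflates the heteroscedasticity statistic.
    """
    X = [np.ones_like(lfi), lfi]
    if sex is not None and np.unique(sex).size > 1:
        X.append((np.asarray(sex) == "M").astype(float))
    if mouse is not None:
        levels, codes = np.unique(np.asarray(mouse), return_inverse=True)
        if levels.size > 1 and levels.size < lfi.size:
            D = np.zeros((lfi.size, levels.size - 1))
            sel = codes > 0
            D[np.flatnonzero(sel), codes[sel] - 1] = 1.0
            X.append(D)
    X = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return beta, fitted, y - fitted


def breusch_pagan_vmp(
    M: pd.DataFrame,
    samples: pd.DataFrame,
    alpha_adj: float = 0.1,
    adjust_sex: bool = True,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> pd.DataFrame:
    """Breusch-Pagan heteroscedasticity scan across probes.

    Per probe the mean model M ~ logFI (+ sex in a mixed cohort) is fitted
    by OLS; the BP statistic is n R^2 from regressing squared residuals on
    logFI, with p from chi-square(1).  VMPs are probes with BH-adjusted
    p < ``alpha_adj``.
    """
    lfi_all = log_fi(samples.loc[M.columns, "fi"].to_numpy(), floor=fi_floor)
    if np.unique(lfi_all).size < 2:
        raise ValueError("frailty is constant; BP test undefined")
    sex_all = samples.loc[M.columns, "sex"].to_numpy()
    mouse_all = samples.loc[M.columns, "mouse_id"].to_numpy()
    repeated = pd.Series(mouse_all).value_counts().max() > 1
    rows = []
    vals = M.to_numpy(dtype=float)
    for i, probe in enumerate(M.index):
        y = vals[i]
        mask = ~np.isnan(y)
        if mask.sum() < 10:
            rows.append((probe, np.nan, np.nan))
            continue
        lfi = lfi_all[mask]
        _, _, resid = _mean_model(
            y[mask], lfi, sex_all[mask] if adjust_sex else None,
            mouse_all[mask] if repeated else None,
        )
        u = resid**2
        A = np.column_stack([np.ones_like(lfi), lfi])
        g, *_ = np.linalg.lstsq(A, u, rcond=None)
        fitted = A @ g
        sst = float(((u - u.mean()) ** 2).sum())
        ssr = float(((fitted - u.mean()) ** 2).sum())
        # constant squared residuals (up to float dust) carry no signal
        degenerate = sst <= len(u) * (1e-10 * (u.mean() + 1e-300)) ** 2
        r2 = ssr / sst if sst > 0 and not degenerate else 0.0
        n = int(mask.sum())
        bp = n * r2
        from scipy.stats import chi2

        rows.append((probe, bp, float(chi2.sf(bp, 1))))
    out = pd.DataFrame(rows, columns=["probe_id", "bp_statistic", "p"])
    out = out.set_index("probe_id")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["is_vmp"] = out["adj_p"] < alpha_adj
    return out


def snr_classify(
    M: pd.DataFrame,
    samples: pd.DataFrame,
    adjust_sex: bool = True,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> pd.DataFrame:
    """Signal-to-noise ratio per probe and its class.

    SNR = variance of the fitted frailty component (logFI coefficient times
    logFI) across samples, over the residual variance of the mean model.
    Classes use strict thresholds: deterministic (> 10), stochastic (< 1),
    intermediate otherwise; zero residual variance gives SNR = inf,
    deterministic, flagged.
    """
    lfi_all = log_fi(samples.loc[M.columns, "fi"].to_numpy(), floor=fi_floor)
    sex_all = samples.loc[M.columns, "sex"].to_numpy()
    mouse_all = samples.loc[M.columns, "mouse_id"].to_numpy()
    repeated = pd.Series(mouse_all).value_counts().max() > 1
    rows = []
    vals = M.to_numpy(dtype=float)
    for i, probe in enumerate(M.index):
        y = vals[i]
        mask = ~np.isnan(y)
        lfi = lfi_all[mask]
        beta, _, resid = _mean_model(
            y[mask], lfi, sex_all[mask] if adjust_sex else None,
            mouse_all[mask] if repeated else None,
        )
        signal = float(np.var(beta[1] * lfi, ddof=1))
        noise = float(np.var(resid, ddof=1))
        y_scale = float(np.var(y[mask], ddof=1)) + 1e-300
        flagged = noise <= 1e-12 * y_scale
        snr = np.inf if flagged else signal / noise
        rows.append((probe, snr, snr_label(snr), flagged))
    return pd.DataFrame(
        rows, columns=["probe_id", "snr", "snr_class", "zero_residual"]
    ).set_index("probe_id")


def snr_label(snr: float) -> str:
    if snr > 10.0:
        return "deterministic"
    if snr < 1.0:
        return "stochastic"
    return "intermediate"


def shannon_entropy(betas: pd.DataFrame) -> pd.Series:
    """Mean per-site binary entropy of beta values, per sample, in [0, 1].

    H = mean over sites of -[b log2 b + (1-b) log2(1-b)] with 0 log 0 = 0;
    missing betas are skipped, all-missing samples return NaN.
    """
    vals = betas.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(
            np.where(vals > 0, vals * np.log2(vals), 0.0)
            + np.where(vals < 1, (1 - vals) * np.log2(1 - vals), 0.0)
        )
    h[np.isnan(vals)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(h, axis=0)
    return pd.Series(out, index=betas.columns, name="entropy")


def entropy_frailty_slope(
    betas: pd.DataFrame,
    samples: pd.DataFrame,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> dict:
    """OLS slope of per-sample entropy on logFI over a CpG set."""
    ent = shannon_entropy(betas)
    lfi = log_fi(samples.loc[betas.columns, "fi"].to_numpy(), floor=fi_floor)
    mask = ~ent.isna().to_numpy()
    from scipy.stats import linregress

    res = linregress(lfi[mask], ent.to_numpy()[mask])
    return {"slope": float(res.slope), "p": float(res.pvalue),
            "r": float(res.rvalue)}
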