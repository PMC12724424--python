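"""Elastic-net epigenetic frailty clocks.

Two clocks predict the frailty index from CpG M-values of the top-ranked
frailty DMRs: EFC1 includes age and sex as unpenalized covariates, EFC2
only sex.  Because scikit-learn's elastic net has no per-feature penalty
factors, the unpenalized covariates are handled exactly by partialling
them out of both the response and the CpG features before the penalized
fit (valid for any convex penalty), then recovering the covariate
coefficients from the residual regression.  The penalty is chosen on a
grouped 5-fold cross-validation path -- folds split by mouse, never by
sample -- with the 1-SE rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV, LinearRegression
from sklearn.model_selection import GroupKFold


def select_top_dmrs(
    classification: pd.DataFrame,
    members_by_dmr: dict[str, list[str]],
    k: int = 100,
) -> tuple[list[str], list[str]]:
    """Top-k DMRs by absolute frailty coefficient and their member CpGs.

    Ties break by adjusted p (lower first) then dmr_id.  Returns
    (dmr ids, deduplicated member CpG ids).
    """
    import warnings

    table = classification.copy()
    if k > len(table):
        warnings.warn(f"k={k} exceeds the {len(table)} available DMRs; using all")
        k = len(table)
    table["_abs"] = table["fi_coef"].abs()
    table["_adj"] = table.get("fi_adj_p", pd.Series(1.0, index=table.index))
    # deterministic tie-break: |coef| desc, adjusted p asc, dmr_id asc
    order = table.iloc[
        np.lexsort(
            (table.index.to_numpy(), table["_adj"].to_numpy(),
             -table["_abs"].to_numpy())
        )
    ]
    top = list(order.index[:k])
    cpgs: list[str] = []
    seen = set()
    for dmr_id in top:
        for cpg in members_by_dmr.get(dmr_id, []):
            if cpg not in seen:
                seen.add(cpg)
                cpgs.append(cpg)
    return top, cpgs


@dataclass
class ClockModel:
    """Fitted frailty clock: covariates unpenalized, CpGs elastic-net."""

    name: str
    cpg_ids: list[str]
    include_age: bool
    intercept: float
    covariate_coefs: dict[str, float]
    cpg_coefs: pd.Series          # nonzero coefficients on the M scale
    alpha: float
    l1_ratio: float
    n_folds: int
    seed: int
    feature_means: pd.Series      # training means, also used for imputation
    train_r2: float = float("nan")

    @property
    def n_cpgs(self) -> int:
        return int((self.cpg_coefs != 0).sum())

    def covariate_frame(self, sheet: pd.DataFrame) -> pd.DataFrame:
        cov = pd.DataFrame(index=sheet.index)
        cov["sexM"] = (sheet["sex"] == "M").astype(float)
        if self.include_age:
            cov["age"] = sheet["age_months"].astype(float)
        return cov

    def predict(self, M: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
        X = M.reindex(self.cpg_ids).T.loc[sheet.index]
        X = X.fillna(self.feature_means)
        cov = self.covariate_frame(sheet)
        yhat = (
            self.intercept
            + X.to_numpy() @ self.cpg_coefs.reindex(self.cpg_ids).fillna(0).to_numpy()
            + sum(cov[c].to_numpy() * v for c, v in self.covariate_coefs.items())
        )
        return pd.Series(yhat, index=sheet.index, name=self.name)

    def to_json(self, path) -> None:
        import json

        payload = {
            "name": self.name,
            "cpg_ids": self.cpg_ids,
            "include_age": self.include_age,
            "intercept": self.intercept,
            "covariate_coefs": self.covariate_coefs,
            "cpg_coefs": self.cpg_coefs.to_dict(),
            "alpha": self.alpha,
            "l1_ratio": self.l1_ratio,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "feature_means": self.feature_means.to_dict(),
            "train_r2": self.train_r2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def grouped_folds(groups, n_splits: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
    """GroupKFold splits by mouse; asserts no mouse straddles train/test."""
    groups = np.asarray(groups)
    gkf = GroupKFold(n_splits=min(n_splits, np.unique(groups).size))
    splits = list(gkf.split(np.zeros(groups.size), groups=groups))
    for train, test in splits:
        assert not set(groups[train]) & set(groups[test]), \
            "a mouse appears in both train and test folds"
    return splits


def fit_efc(
    M: pd.DataFrame,
    sheet: pd.DataFrame,
    cpg_ids: list[str],
    include_age: bool,
    name: str | None = None,
    l1_ratio: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
    target: str = "fi",
    adaptive: bool = True,
) -> ClockModel:
    """Train a frailty clock on the discovery samples in ``sheet``.

    CpG M-values (training-mean imputed where missing) are partialled
    against [1, covariates], standardized and fitted by elastic net along a
    CV alpha path (grouped by mouse, 1-SE rule).  The returned model stores
    coefficients on the original M scale.
    """
    if len(sheet) < 30:
        raise ValueError("need at least 30 training samples")
    y = sheet[target].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("constant outcome")
    X = M.reindex(cpg_ids).T.loc[sheet.index]
    means = X.mean(axis=0)
    X = X.fillna(means).to_numpy(dtype=float)

    cov = pd.DataFrame(index=sheet.index)
    cov["sexM"] = (sheet["sex"] == "M").astype(float)
    if include_age:
        cov["age"] = sheet["age_months"].astype(float)
    C = np.column_stack([np.ones(len(sheet)), cov.to_numpy(dtype=float)])
    H = np.linalg.pinv(C)
    y_r = y - C @ (H @ y)
    X_r = X - C @ (H @ X)
    scale = X_r.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    X_s = X_r / scale

    groups = sheet["mouse_id"].to_numpy()
    splits = grouped_folds(groups, n_folds)

    def _one_se_fit(features, response):
        cv = ElasticNetCV(
            l1_ratio=l1_ratio, cv=splits, alphas=100, max_iter=20000,
            random_state=seed,
        )
        cv.fit(features, response)
        mse = cv.mse_path_.mean(axis=1)
        sem = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
        best = int(np.argmin(mse))
        # alphas_ descend, so the first index within 1 SE is the largest alpha
        one_se = int(np.flatnonzero(mse <= mse[best] + sem[best])[0])
        alpha = float(cv.alphas_[one_se])
        net = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50000)
        net.fit(features, response)
        return net, alpha

    net, alpha = _one_se_fit(X_s, y_r)
    coef_s = net.coef_.copy()
    keep = np.flatnonzero(coef_s)
    if adaptive and keep.size:
        # adaptive refinement: reweight surviving features by their initial
        # coefficients (gamma = 2) -- prediction-optimal penalties alone
        # over-select, the adaptive step recovers a sparse support
        wts = (1.0 / np.abs(coef_s[keep])) ** 2.0
        wts /= wts.min()
        net2, alpha = _one_se_fit(X_s[:, keep] / wts[None, :], y_r)
        coef_s = np.zeros_like(coef_s)
        coef_s[keep] = net2.coef_ / wts

    beta_m = coef_s / scale  # back to the M scale
    resid = y - X @ beta_m
    gamma = H @ resid  # intercept + covariates given the penalized part
    cpg_coefs = pd.Series(beta_m, index=cpg_ids)
    cov_coefs = {c: float(g) for c, g in zip(cov.columns, gamma[1:])}
    model = ClockModel(
        name=name or ("EFC1" if include_age else "EFC2"),
        cpg_ids=list(cpg_ids),
        include_age=include_age,
        intercept=float(gamma[0]),
        covariate_coefs=cov_coefs,
        cpg_coefs=cpg_coefs[cpg_coefs != 0],
        alpha=alpha,
        l1_ratio=l1_ratio,
        n_folds=n_folds,
        seed=seed,
        feature_means=means,
    )
    yhat = model.predict(M, sheet)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - yhat.to_numpy()) ** 2).sum())
    model.train_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return model


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1); undefined (NaN) when n <= p + 1."""
    if n <= p + 1:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def evaluate_clock(
    model: ClockModel,
    M: pd.DataFrame,
    sheet: pd.DataFrame,
    target: str = "fi",
) -> pd.DataFrame:
    """R^2 / adjusted R^2 of the clock vs the age+sex baseline, per sex and
    pooled, on the given evaluation samples (baseline refitted there)."""
    y = sheet[target].to_numpy(dtype=float)
    yhat = model.predict(M, sheet).to_numpy()
    base_X = np.column_stack([
        sheet["age_months"].to_numpy(dtype=float),
        (sheet["sex"] == "M").to_numpy(dtype=float),
    ])
    base = LinearRegression().fit(base_X, y)
    ybase = base.predict(base_X)
    p_clock = model.n_cpgs + len(model.covariate_coefs)
    rows = []
    subsets = {"pooled": np.ones(len(sheet), dtype=bool)}
    for s in ("F", "M"):
        subsets[s] = (sheet["sex"] == s).to_numpy()
    for label, mask in subsets.items():
        if mask.sum() < 3:
            continue
        for which, pred, p in (
            (model.name, yhat, p_clock),
            ("baseline", ybase, 2),
        ):
            r2 = _r2(y[mask], pred[mask])
            rows.append(
                {
                    "subset": label,
                    "model": which,
                    "n": int(mask.sum()),
                    "n_predictors": p,
                    "r2": r2,
                    "adj_r2": adjusted_r2(r2, int(mask.sum()), p),
                }
            )
    return pd.DataFrame(rows)


def _r2(y, yhat) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def lifespan_variance(
    predictions: pd.Series,
    sheet: pd.DataFrame,
) -> dict:
    """R^2 of time-to-death on predicted frailty vs conventional FI vs
    age+sex, over uncensored (dead) samples."""
    dead = sheet["dead"].astype(bool) & sheet["age_at_death"].notna()
    sub = sheet[dead]
    n_mice = sub["mouse_id"].nunique()
    if n_mice < 10:
        raise ValueError("need observed deaths for at least 10 mice")
    ttd = (sub["age_at_death"] - sub["age_months"]).to_numpy(dtype=float)
    out = {"n_uncensored": int(len(sub)), "n_censored": int((~dead).sum())}
    preds = {
        "clock": predictions.loc[sub.index].to_numpy(dtype=float)[:, None],
        "fi": sub["fi"].to_numpy(dtype=float)[:, None],
        "age_sex": np.column_stack(
            [sub["age_months"].to_numpy(dtype=float),
             (sub["sex"] == "M").to_numpy(dtype=float)]
        ),
    }
    for nm, X in preds.items():
        fit = LinearRegression().fit(X, ttd)
        out[f"r2_{nm}"] = _r2(ttd, fit.predict(X))
    return out
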