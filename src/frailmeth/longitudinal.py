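"""Associations of DMR methylation (M) and methylation change (dM) with
current, future and change-in frailty.

Per mouse, consecutive assessment pairs (current, future) and triples
(past, current, future) define the outcome frames: ``M_c`` is the DMR
methylation summary at the current age, ``dM = M_c - M_p`` its change from
the previous assessment, and the outcomes are ``logFI_c``, ``logFI_f`` and
``dlogFI = logFI_f - logFI_c``.  Each DMR is tested by a linear mixed model
(mouse random intercept whenever a mouse contributes multiple rows)
adjusted for age and sex, plus the assessment-gap terms ``dAge1``
(current - past, with dM) and ``dAge2`` (future - current, with future
outcomes).  DMRs whose predictor interacts with age (BH-adjusted) are
flagged and excluded from the significant set; a sensitivity refit with
baseline logFI adjustment is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import bh_adjust, log_fi
from .ewas import DEFAULT_FI_FLOOR
from .lmm import fit_reml

OUTCOMES = ("logFI_c", "logFI_f", "dlogFI")
PREDICTORS = ("M", "dM")

#: the four future-facing analyses entering the multi-analysis intersection
MAIN_ANALYSES = (
    ("M", "logFI_f"),
    ("M", "dlogFI"),
    ("dM", "logFI_f"),
    ("dM", "dlogFI"),
)


@dataclass
class OutcomeFrames:
    """Consecutive-timepoint pairs and triples with frailty outcomes."""

    pairs: pd.DataFrame    # sample_c, sample_f per mouse, consecutive
    triples: pd.DataFrame  # sample_p, sample_c, sample_f per mouse


def dmr_summary(M: pd.DataFrame, members: list[str], how: str = "median") -> pd.Series:
    """Per-sample DMR methylation summary (median M across member CpGs)."""
    sub = M.loc[members]
    if how == "median":
        return sub.median(axis=0, skipna=True)
    if how == "mean":
        return sub.mean(axis=0, skipna=True)
    raise ValueError(f"unknown summary {how!r}")


def build_outcome_frames(
    samples: pd.DataFrame,
    fi_floor: float = DEFAULT_FI_FLOOR,
    all_pairs: bool = False,
) -> OutcomeFrames:
    """Enumerate consecutive (current, future) pairs and (past, current,
    future) triples per mouse (all ordered pairs when ``all_pairs``)."""
    lfi = pd.Series(
        log_fi(samples["fi"].to_numpy(), floor=fi_floor), index=samples.index
    )
    pair_rows, triple_rows = [], []
    for mouse, grp in samples.groupby("mouse_id", sort=False):
        grp = grp.sort_values("timepoint")
        ids = list(grp.index)
        ages = grp["age_months"].to_numpy()
        sex = grp["sex"].iloc[0]
        if all_pairs:
            combos = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        else:
            combos = [(i, i + 1) for i in range(len(ids) - 1)]
        for i, j in combos:
            pair_rows.append(
                {
                    "mouse_id": mouse,
                    "sex": sex,
                    "sample_c": ids[i],
                    "sample_f": ids[j],
                    "age_c": ages[i],
                    "dAge2": ages[j] - ages[i],
                    "logFI_c": lfi[ids[i]],
                    "logFI_f": lfi[ids[j]],
                }
            )
        for i in (range(len(ids) - 2) if not all_pairs else []):
            triple_rows.append(
                {
                    "mouse_id": mouse,
                    "sex": sex,
                    "sample_p": ids[i],
                    "sample_c": ids[i + 1],
                    "sample_f": ids[i + 2],
                    "age_c": ages[i + 1],
                    "dAge1": ages[i + 1] - ages[i],
                    "dAge2": ages[i + 2] - ages[i + 1],
                    "logFI_p": lfi[ids[i]],
                    "logFI_c": lfi[ids[i + 1]],
                    "logFI_f": lfi[ids[i + 2]],
                }
            )
        if all_pairs:
            for i in range(len(ids) - 2):
                for j in range(i + 1, len(ids) - 1):
                    for k in range(j + 1, len(ids)):
                        triple_rows.append(
                            {
                                "mouse_id": mouse,
                                "sex": sex,
                                "sample_p": ids[i],
                                "sample_c": ids[j],
                                "sample_f": ids[k],
                                "age_c": ages[j],
                                "dAge1": ages[j] - ages[i],
                                "dAge2": ages[k] - ages[j],
                                "logFI_p": lfi[ids[i]],
                                "logFI_c": lfi[ids[j]],
                                "logFI_f": lfi[ids[k]],
                            }
                        )
    pairs = pd.DataFrame(pair_rows)
    triples = pd.DataFrame(triple_rows)
    for frame in (pairs, triples):
        if len(frame):
            frame["dlogFI"] = frame["logFI_f"] - frame["logFI_c"]
    return OutcomeFrames(pairs, triples)


def _analysis_frame(
    frames: OutcomeFrames, summary: pd.Series, outcome: str, predictor: str
) -> pd.DataFrame:
    """Join one DMR's methylation summary onto the right frame."""
    if predictor == "M":
        df = frames.pairs.copy()
        df["x"] = summary.reindex(df["sample_c"]).to_numpy()
    elif predictor == "dM":
        df = frames.triples.copy()
        df["x"] = (
            summary.reindex(df["sample_c"]).to_numpy()
            - summary.reindex(df["sample_p"]).to_numpy()
        )
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    df["y"] = df[outcome]
    return df.dropna(subset=["x", "y"])


def _fit_row(df: pd.DataFrame, predictor: str, outcome: str,
             extra_cols: list[str]) -> "fit_reml":
    X = pd.DataFrame({"intercept": 1.0, "x": df["x"].to_numpy()}, index=df.index)
    X["age_c"] = df["age_c"].to_numpy()
    if df["sex"].nunique() > 1:
        X["sexM"] = (df["sex"] == "M").astype(float).to_numpy()
    # assessment-gap adjustments only enter when the gaps actually vary
    # (with perfectly regular assessments they are constant, hence collinear)
    if predictor == "dM" and df["dAge1"].nunique() > 1:
        X["dAge1"] = df["dAge1"].to_numpy()
    if outcome in ("logFI_f", "dlogFI") and df["dAge2"].nunique() > 1:
        X["dAge2"] = df["dAge2"].to_numpy()
    for c in extra_cols:
        X[c] = df[c].to_numpy()
    groups = {}
    if df["mouse_id"].value_counts().max() > 1:
        groups["mouse"] = df["mouse_id"].to_numpy()
    return fit_reml(df["y"].to_numpy(dtype=float), X, groups)


def test_outcome_associations(
    frames: OutcomeFrames,
    summaries: pd.DataFrame,
    outcome: str,
    predictor: str,
    alpha: float = 0.05,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Per-DMR association of ``predictor`` with ``outcome``.

    ``summaries`` is DMRs x samples (output of :func:`dmr_summary` stacked).
    Returns coef, 95% CI, raw/adjusted p, the age-interaction p (parallel
    fit with a predictor x age term; DMRs with BH-adjusted interaction
    p < alpha carry ``excluded=True``), and a baseline-logFI sensitivity
    coefficient.
    """
    rows = []
    for dmr_id in summaries.index:
        df = _analysis_frame(frames, summaries.loc[dmr_id], outcome, predictor)
        if len(df) < 10:
            raise ValueError(
                f"analysis ({predictor} -> {outcome}) has fewer than 10 rows"
            )
        fit = _fit_row(df, predictor, outcome, [])
        lo, hi = fit.conf_int("x")
        # parallel fit with predictor x age interaction
        df2 = df.copy()
        df2["x_age"] = df2["x"] * (df2["age_c"] - df2["age_c"].mean())
        fit_int = _fit_row(df2, predictor, outcome, ["x_age"])
        # sensitivity: adjust for baseline logFI
        coef_sens = np.nan
        if outcome != "logFI_c":
            fit_sens = _fit_row(df, predictor, outcome, ["logFI_c"])
            coef_sens = float(fit_sens.params["x"])
        rows.append(
            {
                "dmr_id": dmr_id,
                "outcome": outcome,
                "predictor": predictor,
                "cohort": cohort,
                "coef": float(fit.params["x"]),
                "ci_low": lo,
                "ci_high": hi,
                "p": float(fit.pvalues["x"]),
                "age_interaction_p": float(fit_int.pvalues["x_age"]),
                "coef_baseline_adj": coef_sens,
                "n": len(df),
            }
        )
    table = pd.DataFrame(rows).set_index("dmr_id")
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["age_interaction_adj_p"] = bh_adjust(
        table["age_interaction_p"].to_numpy()
    )
    table["excluded"] = table["age_interaction_adj_p"] < alpha
    table["significant"] = (table["adj_p"] < alpha) & ~table["excluded"]
    return table


def run_outcome_associations(
    frames: OutcomeFrames,
    summaries: pd.DataFrame,
    analyses=MAIN_ANALYSES,
    alpha: float = 0.05,
    cohort: str = "discovery",
) -> dict[tuple[str, str], pd.DataFrame]:
    return {
        (pred, out): test_outcome_associations(
            frames, summaries, out, pred, alpha=alpha, cohort=cohort
        )
        for pred, out in analyses
    }


def intersect_multi_analysis(
    assocs: dict[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    """DMRs significant in more than one analysis, with sign consistency."""
    sig: dict[str, dict[str, float]] = {}
    for (pred, out), table in assocs.items():
        name = f"{pred}->{out}"
        for dmr_id, row in table[table["significant"]].iterrows():
            sig.setdefault(dmr_id, {})[name] = float(row["coef"])
    rows = []
    for dmr_id, hits in sig.items():
        if len(hits) < 2:
            continue
        signs = {np.sign(v) for v in hits.values()}
        rows.append(
            {
                "dmr_id": dmr_id,
                "n_analyses": len(hits),
                "analyses": ";".join(sorted(hits)),
                "coefs": ";".join(f"{k}={v:.4g}" for k, v in sorted(hits.items())),
                "consistency": "same" if len(signs) == 1 else "opposite",
            }
        )
    return pd.DataFrame(
        rows, columns=["dmr_id", "n_analyses", "analyses", "coefs", "consistency"]
    )


def validate_concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Label each discovery-significant (DMR, analysis) by its validation
    behavior: consistent (significant, same sign), flipped (significant,
    opposite sign) or not_replicated; plus a global sign-agreement summary
    stratified by discovery |coef| quartile."""
    key = ["outcome", "predictor"]
    if not set(discovery.index) & set(validation.index):
        raise ValueError("discovery and validation DMR sets are disjoint")
    val = validation.reset_index().set_index(["dmr_id"] + key)
    rows = []
    for dmr_id, drow in discovery.reset_index().set_index("dmr_id").iterrows():
        k = (dmr_id, drow["outcome"], drow["predictor"])
        if k not in val.index:
            continue
        vrow = val.loc[k]
        same_sign = np.sign(drow["coef"]) == np.sign(vrow["coef"])
        if drow["significant"]:
            if vrow["adj_p"] < alpha and same_sign:
                label = "consistent"
            elif vrow["adj_p"] < alpha:
                label = "flipped"
            else:
                label = "not_replicated"
        else:
            label = "not_tested"
        rows.append(
            {
                "dmr_id": dmr_id,
                "outcome": drow["outcome"],
                "predictor": drow["predictor"],
                "coef_discovery": drow["coef"],
                "coef_validation": float(vrow["coef"]),
                "same_sign": bool(same_sign),
                "label": label,
            }
        )
    report = pd.DataFrame(rows)
    summary: dict = {"frac_same_sign": float("nan"), "by_quartile": {}}
    if len(report):
        summary["frac_same_sign"] = float(report["same_sign"].mean())
        if len(report) >= 4:
            absc = report["coef_discovery"].abs()
            quart = pd.qcut(absc.rank(method="first"), 4, labels=False,
                            duplicates="drop")
            summary["by_quartile"] = {
                int(qq): float(report.loc[quart == qq, "same_sign"].mean())
                for qq in sorted(pd.unique(quart)) if pd.notna(qq)
            }
    return report, summary
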