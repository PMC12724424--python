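"""Classify co-methylated DMRs by mixed-model association with
age-independent (AIFI) and age-dependent (ADFI) frailty.

Per region, the member-CpG M-values in long format (one row per CpG x
sample) are fitted by REML linear mixed models with crossed random
intercepts for mouse and CpG, under three fixed-effect models:

* ``aifi``: M ~ logFI + age   (focal: logFI -- frailty beyond age)
* ``adfi``: M ~ age           (focal: age)
* ``fi``:   M ~ logFI         (focal: logFI -- reported effect/direction)

Wald p-values of the focal coefficient are BH-adjusted across regions
within each model and subgroup; regions significant only for AIFI are
aiDMRs, only for ADFI adDMRs, for both dualDMRs, otherwise none.  The
module also provides the sex residualization used before the rdrop filter
in the sex-inclusive subgroup, the sex-interaction scan, and assembly of
the joint fiDMR set across subgroups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import MethylationMatrix, bh_adjust, log_fi
from .dmr import Dmr, rdrop_filter
from .ewas import DEFAULT_FI_FLOOR
from .lmm import fit_reml

MODELS = {
    "aifi": (["intercept", "logFI", "age"], "logFI"),
    "adfi": (["intercept", "age"], "age"),
    "fi": (["intercept", "logFI"], "logFI"),
}

CLASSES = ("aiDMR", "adDMR", "dualDMR", "none")


def subgroup_sample_ids(
    samples: pd.DataFrame, subgroup: str, drop_male_t5: bool = True
) -> pd.Index:
    """Samples entering a subgroup analysis (sex-inclusive drops male T5)."""
    if subgroup == "female":
        return samples.index[samples["sex"] == "F"]
    if subgroup == "male":
        return samples.index[samples["sex"] == "M"]
    if subgroup != "sex_inclusive":
        raise ValueError(f"unknown subgroup {subgroup!r}")
    keep = pd.Series(True, index=samples.index)
    if drop_male_t5:
        last_t = samples["timepoint"].max()
        keep &= ~((samples["sex"] == "M") & (samples["timepoint"] == last_t))
    return samples.index[keep]


def sex_residualize(M: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Remove the per-probe sex effect, re-centering at the grand mean.

    Per probe, the fitted sex means are subtracted and the grand mean over
    observed samples added back; missing entries stay missing.
    """
    sex = samples.loc[M.columns, "sex"].to_numpy()
    if np.unique(sex).size < 2:
        raise ValueError("sex residualization requires both sexes")
    vals = M.to_numpy(dtype=float)
    out = vals.copy()
    grand = np.nanmean(vals, axis=1)
    for s in np.unique(sex):
        cols = sex == s
        with np.errstate(invalid="ignore"):
            mean_s = np.nanmean(vals[:, cols], axis=1)
        out[:, cols] = vals[:, cols] - mean_s[:, None] + grand[:, None]
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def comethylation_filter(
    M: pd.DataFrame,
    regions: list[Dmr],
    samples: pd.DataFrame,
    sex_inclusive: bool = True,
    threshold: float = 0.4,
    min_cpgs: int = 5,
) -> dict[str, list[str]]:
    """Apply the rdrop co-methylation filter to every region.

    In the sex-inclusive subgroup M-values are sex-residualized first;
    stratified subgroups pass through unadjusted.  Returns the retained
    member CpGs per region id; regions falling below ``min_cpgs`` drop out.
    """
    work = sex_residualize(M, samples) if sex_inclusive else M
    kept: dict[str, list[str]] = {}
    for dmr in regions:
        sub = work.loc[dmr.probe_ids].T  # samples x members
        retained = rdrop_filter(sub, threshold=threshold, min_cpgs=min_cpgs)
        if retained:
            kept[dmr.dmr_id] = retained
    return kept


def make_long(
    M: pd.DataFrame,
    members: list[str],
    samples: pd.DataFrame,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> pd.DataFrame:
    """Long-format frame (one row per CpG x sample) for the region LMMs."""
    sub = M.loc[members, samples.index]
    long = sub.stack().rename("M").reset_index()
    long.columns = ["cpg_id", "sample_id", "M"]
    meta = samples[["mouse_id", "sex", "age_months", "fi"]]
    long = long.join(meta, on="sample_id")
    long["logFI"] = log_fi(long["fi"].to_numpy(), floor=fi_floor)
    long["age"] = long["age_months"]
    return long


def fit_dmr_lmm(long: pd.DataFrame, fixed: list[str], focal: str,
                sample_effect: bool = True):
    """REML LMM with crossed mouse and CpG random intercepts.

    ``fixed`` names columns of the long frame ("intercept" is added as a
    constant).  By default a third, per-sample random intercept is
    included: member CpGs of a region are co-methylated, so within one
    sample they share a regional deviation and are not independent
    replicates -- without the sample term the Wald tests on sample-level
    covariates (logFI, age) are badly anti-conservative.  Returns the
    :class:`~frailmeth.lmm.LmmFit`; a fit that did not converge carries
    ``converged=False`` and a missing focal p-value.
    """
    if long["mouse_id"].nunique() < 3:
        raise ValueError("need at least 3 mice")
    X = pd.DataFrame(index=long.index)
    for term in fixed:
        X[term] = 1.0 if term == "intercept" else long[term].to_numpy(dtype=float)
    groups = _region_groups(long, sample_effect)
    fit = fit_reml(long["M"].to_numpy(dtype=float), X, groups)
    if not fit.converged:
        fit.pvalues[focal] = np.nan
    return fit


def _region_groups(long: pd.DataFrame, sample_effect: bool = True) -> dict:
    groups = {"mouse": long["mouse_id"].to_numpy()}
    if long["cpg_id"].nunique() >= 2:
        groups["cpg"] = long["cpg_id"].to_numpy()
        if sample_effect:
            groups["sample"] = long["sample_id"].to_numpy()
    return groups


def classify_regions(
    M: pd.DataFrame,
    members_by_dmr: dict[str, list[str]],
    samples: pd.DataFrame,
    subgroup: str,
    alpha: float = 0.05,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> pd.DataFrame:
    """Fit the three LMMs for every region and classify.

    Returns one row per DMR with coefficients, raw and BH-adjusted p-values
    per model (adjusted within this subgroup across the regions tested),
    the class label, and the direction (sign of the logFI-only effect).
    """
    rows = []
    for dmr_id, members in members_by_dmr.items():
        long = make_long(M, members, samples, fi_floor)
        long = long.dropna(subset=["M"])
        row: dict = {"dmr_id": dmr_id, "subgroup": subgroup,
                     "n_cpgs": len(members)}
        for model, (fixed, focal) in MODELS.items():
            fit = fit_dmr_lmm(long, fixed, focal)
            row[f"{model}_coef"] = float(fit.params[focal])
            row[f"{model}_p"] = float(fit.pvalues[focal])
            row[f"{model}_converged"] = fit.converged
        rows.append(row)
    table = pd.DataFrame(rows).set_index("dmr_id")
    if table.empty:
        return table
    for model in MODELS:
        table[f"{model}_adj_p"] = bh_adjust(table[f"{model}_p"].to_numpy())
    table["class"] = classify_labels(
        table["aifi_adj_p"].to_numpy(), table["adfi_adj_p"].to_numpy(), alpha
    )
    table["direction"] = np.sign(table["fi_coef"]).astype(int)
    return table


def classify_labels(aifi_adj_p, adfi_adj_p, alpha: float = 0.05) -> np.ndarray:
    """aiDMR / adDMR / dualDMR / none from the two adjusted p-values."""
    ai = np.asarray(aifi_adj_p) < alpha
    ad = np.asarray(adfi_adj_p) < alpha
    return np.select(
        [ai & ad, ai & ~ad, ~ai & ad], ["dualDMR", "aiDMR", "adDMR"], "none"
    )


def classify_dmrs(
    aifi_results: pd.DataFrame,
    adfi_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine separately computed AIFI and ADFI Wald tables into classes.

    Both tables are indexed by dmr_id with columns ``coef`` and ``adj_p``
    and must cover the same DMRs.
    """
    if not set(aifi_results.index) == set(adfi_results.index):
        raise ValueError("AIFI and ADFI result sets cover different DMRs")
    adfi = adfi_results.loc[aifi_results.index]
    out = pd.DataFrame(index=aifi_results.index)
    out["aifi_coef"] = aifi_results["coef"]
    out["aifi_adj_p"] = aifi_results["adj_p"]
    out["adfi_coef"] = adfi["coef"]
    out["adfi_adj_p"] = adfi["adj_p"]
    out["class"] = classify_labels(
        out["aifi_adj_p"].to_numpy(), out["adfi_adj_p"].to_numpy(), alpha
    )
    return out


def sex_interaction_scan(
    M: pd.DataFrame,
    members_by_dmr: dict[str, list[str]],
    samples: pd.DataFrame,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> pd.DataFrame:
    """Per-DMR sex x logFI interaction in the combined cohort.

    The LMM has fixed sexM, logFI and sexM:logFI terms with mouse and CpG
    random intercepts.  Female slope = logFI coefficient, male slope =
    logFI + interaction; interaction Wald p is BH-adjusted across DMRs and
    concordance is labeled from the slope signs.
    """
    if samples["sex"].nunique() < 2:
        raise ValueError("sex interaction scan requires both sexes")
    rows = []
    for dmr_id, members in members_by_dmr.items():
        long = make_long(M, members, samples, fi_floor).dropna(subset=["M"])
        male = (long["sex"] == "M").astype(float).to_numpy()
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "sexM": male,
                "logFI": long["logFI"].to_numpy(),
                "sexM_logFI": male * long["logFI"].to_numpy(),
            },
            index=long.index,
        )
        fit = fit_reml(
            long["M"].to_numpy(dtype=float), X, _region_groups(long)
        )
        female_eff = float(fit.params["logFI"])
        male_eff = float(fit.params["logFI"] + fit.params["sexM_logFI"])
        rows.append(
            {
                "dmr_id": dmr_id,
                "female_effect": female_eff,
                "male_effect": male_eff,
                "interaction_p": float(fit.pvalues["sexM_logFI"]),
                "concordance": "same" if female_eff * male_eff >= 0 else "opposite",
            }
        )
    table = pd.DataFrame(rows).set_index("dmr_id")
    if len(table):
        table["interaction_adj_p"] = bh_adjust(table["interaction_p"].to_numpy())
    return table


def assemble_joint_set(
    classifications: dict[str, pd.DataFrame],
    intervals: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union of fiDMRs across subgroups with provenance, plus a merged view.

    ``classifications`` maps subgroup ("sex_inclusive", "female", "male") to
    a classification table (class column; index dmr_id).  Provenance:
    significant in both stratified sexes -> both_sexes; one sex ->
    female_only / male_only; only in the sex-inclusive analysis ->
    inclusive_only.  The merged view unions genomic intervals overlapping
    by >= 1 bp on one chromosome (dmr_id encodes chrom:start-end).
    """
    hits: dict[str, dict] = {}
    for subgroup, table in classifications.items():
        if table is None or len(table) == 0:
            continue
        fi = table[table["class"] != "none"]
        for dmr_id, row in fi.iterrows():
            rec = hits.setdefault(
                dmr_id, {"subgroups": set(), "classes": {}}
            )
            rec["subgroups"].add(subgroup)
            rec["classes"][subgroup] = row["class"]
    rows = []
    for dmr_id, rec in hits.items():
        sgs = rec["subgroups"]
        if "female" in sgs and "male" in sgs:
            prov = "both_sexes"
        elif "female" in sgs:
            prov = "female_only"
        elif "male" in sgs:
            prov = "male_only"
        else:
            prov = "inclusive_only"
        chrom, span = dmr_id.split(":")
        start, end = (int(x) for x in span.split("-"))
        rows.append(
            {
                "dmr_id": dmr_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "provenance": prov,
                "subgroups": ";".join(sorted(sgs)),
                "classes": ";".join(
                    f"{k}={v}" for k, v in sorted(rec["classes"].items())
                ),
            }
        )
    joint = pd.DataFrame(
        rows, columns=["dmr_id", "chrom", "start", "end", "provenance",
                       "subgroups", "classes"]
    )
    if len(joint):
        joint = joint.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    merged = merge_intervals(joint)
    return joint, merged


def merge_intervals(table: pd.DataFrame) -> pd.DataFrame:
    """Union intervals overlapping by >= 1 bp on the same chromosome."""
    rows = []
    for chrom, grp in table.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        members: list[str] = []
        for _, r in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = r["start"], r["end"], [r["dmr_id"]]
            elif r["start"] <= cur_end:
                cur_end = max(cur_end, r["end"])
                members.append(r["dmr_id"])
            else:
                rows.append({"chrom": chrom, "start": cur_start, "end": cur_end,
                             "n_members": len(members),
                             "members": ";".join(members)})
                cur_start, cur_end, members = r["start"], r["end"], [r["dmr_id"]]
        if cur_start is not None:
            rows.append({"chrom": chrom, "start": cur_start, "end": cur_end,
                         "n_members": len(members), "members": ";".join(members)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members",
                                       "members"])
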