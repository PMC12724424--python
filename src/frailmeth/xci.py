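"""X-chromosome inactivation calls from sexed beta values.

Female mice carry two X chromosomes of which one is inactivated (and
methylated) at most loci; males carry one active X.  Comparing per-sex
mean beta values and ranges therefore separates probes *subject to* XCI
(females intermediate, males unmethylated, disjoint ranges), probes that
*escape* XCI (both sexes unmethylated) and *variably escaping* probes
(mean difference above 10% but overlapping ranges).  Thresholds follow the
published decision tree: "unmethylated" is beta < 0.15 and the sex
difference cut is 0.10, both strict inequalities (boundary ties fall
through to unclassified).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CALLS = ("escape", "inactivated", "variable_escape", "unclassified")


def classify_xci(
    betas: pd.DataFrame,
    samples: pd.DataFrame,
    chrom: pd.Series | None = None,
    unmeth_thresh: float = 0.15,
    diff_thresh: float = 0.10,
    range_quantile: float = 0.0,
) -> pd.DataFrame:
    """XCI status per chrX probe from per-sex beta summaries.

    ``betas`` is probes x samples (chrX probes only, or pass ``chrom`` to
    verify); ``range_quantile`` > 0 swaps min/max for symmetric quantile
    ranges.  Decision order: (1) escape if both sex means < unmeth_thresh
    and the ranges overlap or the mean difference < diff_thresh;
    (2) inactivated if the difference > diff_thresh and the ranges are
    disjoint; (3) variable_escape if the difference > diff_thresh and the
    ranges overlap; (4) unclassified otherwise.
    """
    if chrom is not None:
        off = chrom.reindex(betas.index) != "chrX"
        if off.any():
            raise ValueError("probes not on chrX passed to classify_xci")
    sex = samples.loc[betas.columns, "sex"].to_numpy()
    if not ({"F", "M"} <= set(sex)):
        raise ValueError("XCI classification requires samples of both sexes")
    lo_q, hi_q = range_quantile, 1.0 - range_quantile
    rows = []
    vals = betas.to_numpy(dtype=float)
    fcols, mcols = sex == "F", sex == "M"
    for i, probe in enumerate(betas.index):
        f = vals[i, fcols]
        m = vals[i, mcols]
        f = f[~np.isnan(f)]
        m = m[~np.isnan(m)]
        if f.size == 0 or m.size == 0:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, "unclassified"))
            continue
        mean_f, mean_m = float(f.mean()), float(m.mean())
        if range_quantile > 0:
            lo_f, hi_f = np.quantile(f, [lo_q, hi_q])
            lo_m, hi_m = np.quantile(m, [lo_q, hi_q])
        else:
            lo_f, hi_f = float(f.min()), float(f.max())
            lo_m, hi_m = float(m.min()), float(m.max())
        diff = abs(mean_f - mean_m)
        overlap = (lo_f <= hi_m) and (lo_m <= hi_f)
        if (mean_f < unmeth_thresh and mean_m < unmeth_thresh
                and (overlap or diff < diff_thresh)):
            call = "escape"
        elif diff > diff_thresh and not overlap:
            call = "inactivated"
        elif diff > diff_thresh and overlap:
            call = "variable_escape"
        else:
            call = "unclassified"
        rows.append((probe, mean_f, mean_m, lo_f, hi_f, lo_m, hi_m, diff, call))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "mean_f", "mean_m", "range_f_lo", "range_f_hi",
                 "range_m_lo", "range_m_hi", "diff", "call"],
    ).set_index("probe_id")


def xca_frailty_overlap(
    calls: pd.DataFrame,
    female_dmps: pd.Index,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Probes escaping (or variably escaping) XCI that are also female
    frailty DMPs, with gene annotations when available."""
    escaping = calls.index[calls["call"].isin(["escape", "variable_escape"])]
    hits = escaping.intersection(pd.Index(female_dmps))
    out = calls.loc[hits, ["call", "mean_f", "mean_m", "diff"]].copy()
    if annotation is not None and "genes" in annotation.columns:
        out["genes"] = [
            ";".join(sorted(annotation.loc[p, "genes"])) if p in annotation.index
            else "" for p in out.index
        ]
    return out
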