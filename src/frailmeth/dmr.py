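"""Kernel-smoothed region calling over per-probe EWAS statistics.

Per-probe squared statistics (t^2, or F from the joint sex-slope test) are
smoothed along each chromosome with a Gaussian kernel (bandwidth
``lambda``, kernel SD ``lambda / C``, support truncated at 3 SD).  Under
the null each squared statistic is treated as chi-square(1), so the
smoothed value -- a normalized positive combination -- is approximated by a
scaled chi-square via Satterthwaite moment matching, giving a per-probe
p-value that is BH-adjusted genome-wide.  Significant probes are chained
into regions while consecutive gaps stay within ``lambda``; chains with at
least ``min_cpgs`` members whose Stouffer-combined p-value passes 0.05
become DMRs.  The coMethDMR-style ``rdrop`` filter then drops region CpGs
poorly correlated with the rest of their region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SmoothParams:
    lam: float = 1000.0  # bandwidth in bp; also the max chaining gap
    C: float = 2.0       # kernel SD = lam / C

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.C <= 0:
            raise ValueError("lambda and C must be positive")

    @property
    def sigma(self) -> float:
        return self.lam / self.C


@dataclass
class Dmr:
    """A differentially methylated region (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    stouffer_p: float
    min_adj_p: float
    direction: int

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def n_cpgs(self) -> int:
        return len(self.probe_ids)


def stouffer(pvals, weights=None) -> float:
    """Stouffer combination: z_i = Phi^-1(1 - p_i), combined
    z = sum(w z) / sqrt(sum w^2), returned as an upper-tail p."""
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0 or 1 clipped to [1e-15, 1 - 1e-15]")
        p = np.clip(p, 1e-15, 1.0 - 1e-15)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    z = stats.norm.isf(p)
    combined = float(w @ z / np.sqrt(w @ w))
    return float(stats.norm.sf(combined))


def smooth_statistics(
    table: pd.DataFrame, params: SmoothParams | None = None
) -> pd.DataFrame:
    """Gaussian-kernel smoothing of squared statistics with Satterthwaite
    p-values.

    ``table`` needs columns ``chrom``, ``pos`` and ``stat`` and must be
    sorted by (chrom, pos).  Returns the input plus ``smoothed``
    (kernel-weighted mean of stat^2), ``satt_df``, ``smooth_p`` and
    BH-adjusted ``smooth_adj_p``.
    """
    params = params or SmoothParams()
    pos_sorted = table.sort_values(["chrom", "pos"]).index
    if not pos_sorted.equals(table.index):
        raise ValueError("probes must be sorted by (chrom, pos)")
    if not np.isfinite(table["stat"].to_numpy()).all():
        raise ValueError("statistics must be finite")
    sigma = params.sigma
    reach = 3.0 * sigma
    sm = np.empty(len(table))
    nu = np.empty(len(table))
    for _, grp in table.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        st2 = grp["stat"].to_numpy(dtype=float) ** 2
        loc = table.index.get_indexer(grp.index)
        lo = np.searchsorted(pos, pos - reach, side="left")
        hi = np.searchsorted(pos, pos + reach, side="right")
        for i in range(pos.size):
            d = (pos[lo[i]:hi[i]] - pos[i]) / sigma
            k = np.exp(-0.5 * d * d)
            w = k / k.sum()
            sm[loc[i]] = w @ st2[lo[i]:hi[i]]
            nu[loc[i]] = 1.0 / (w @ w)
    # Y ~ a chi2_nu with a = sum w^2, nu = 1 / sum w^2 (normalized weights)
    p = stats.chi2.sf(sm * nu, nu)
    out = table.copy()
    out["smoothed"] = sm
    out["satt_df"] = nu
    out["smooth_p"] = p
    from .core_data import bh_adjust

    out["smooth_adj_p"] = bh_adjust(p)
    return out


def form_regions(
    smoothed: pd.DataFrame,
    params: SmoothParams | None = None,
    sig_fdr: float = 0.05,
    min_cpgs: int = 5,
    stouffer_threshold: float = 0.05,
) -> list[Dmr]:
    """Chain significant probes into DMRs.

    Probes with ``smooth_adj_p < sig_fdr`` on one chromosome are chained
    while consecutive gaps are at most ``lambda``; chains with at least
    ``min_cpgs`` members and a Stouffer-combined per-CpG p below the
    threshold become DMRs, ordered by (chrom, start).
    """
    params = params or SmoothParams()
    sig = smoothed[smoothed["smooth_adj_p"] < sig_fdr]
    regions: list[Dmr] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > params.lam)
        bounds = np.concatenate([[0], breaks + 1, [pos.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = grp.iloc[a:b]
            if len(chunk) < min_cpgs:
                continue
            sp = stouffer(np.clip(chunk["smooth_p"].to_numpy(), 1e-15, 1 - 1e-15))
            if sp >= stouffer_threshold:
                continue
            direction = int(np.sign(chunk["effect"].mean())) if "effect" in chunk else 0
            regions.append(
                Dmr(
                    chrom=str(chrom),
                    start=int(chunk["pos"].iloc[0]),
                    end=int(chunk["pos"].iloc[-1]),
                    probe_ids=list(chunk.index),
                    stouffer_p=float(sp),
                    min_adj_p=float(chunk["smooth_adj_p"].min()),
                    direction=direction,
                )
            )
    regions.sort(key=lambda d: (d.chrom, d.start))
    return regions


def rdrop_filter(
    M_sub: pd.DataFrame,
    threshold: float = 0.4,
    min_cpgs: int = 5,
    recursive: bool = False,
) -> list[str]:
    """Co-methylation filter: keep CpGs correlated with their region.

    ``M_sub`` is samples x member CpGs.  Each CpG's ``rdrop`` is its Pearson
    correlation (pairwise-complete) with the row-sum of the other member
    CpGs; CpGs with rdrop below the threshold are removed in a single pass
    (or iteratively until stable when ``recursive``).  Returns the retained
    CpG ids, or an empty list if fewer than ``min_cpgs`` survive.
    """
    if M_sub.shape[1] < 2:
        raise ValueError("rdrop needs at least two member CpGs")
    cols = list(M_sub.columns)
    while True:
        vals = M_sub[cols].to_numpy(dtype=float)
        keep = []
        for j, c in enumerate(cols):
            others = np.delete(vals, j, axis=1)
            other_sum = np.nansum(others, axis=1)
            other_sum[np.isnan(others).all(axis=1)] = np.nan
            x, y = vals[:, j], other_sum
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.nanstd(x[mask]) == 0 or np.nanstd(y[mask]) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x[mask], y[mask])[0, 1])
            if r >= threshold:
                keep.append(c)
        if not recursive or keep == cols or len(keep) < 2:
            cols = keep
            break
        cols = keep
    if len(cols) < min_cpgs:
        return []
    return cols


def regions_to_frame(regions: list[Dmr]) -> pd.DataFrame:
    rows = [
        {
            "dmr_id": d.dmr_id,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "n_cpgs": d.n_cpgs,
            "stouffer_p": d.stouffer_p,
            "min_adj_p": d.min_adj_p,
            "direction": d.direction,
            "probe_ids": ";".join(d.probe_ids),
        }
        for d in regions
    ]
    return pd.DataFrame(
        rows,
        columns=["dmr_id", "chrom", "start", "end", "n_cpgs", "stouffer_p",
                 "min_adj_p", "direction", "probe_ids"],
    )


def write_dmrs_bed(regions: list[Dmr], path) -> None:
    """BED export: 0-based half-open (internal model is 1-based inclusive)."""
    with open(path, "w") as fh:
        for d in regions:
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.dmr_id}\t"
                     f"{d.stouffer_p:.3g}\t{'+' if d.direction >= 0 else '-'}\n")
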