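"""Shared data model and primitive operations.

The package works on three tabular inputs:

* a **sample sheet** (one row per mouse x timepoint, with sex, cohort,
  treatment, age in months, the 31-item frailty index and survival data),
* a **beta-value matrix** (probes x samples, values in [0, 1], missing
  entries allowed), and
* a **probe manifest** (probe id, chromosome, 1-based position, CpG-island
  and TSS relation, linked genes).

This module defines the in-memory containers for these inputs, their
readers/writers, the beta <-> M-value logit transform, probe filtering,
Benjamini-Hochberg adjustment, the logFI transform and a generic
hypergeometric probe-set enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SEXES = ("F", "M")
COHORTS = ("discovery", "validation")
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
TSS_RELATIONS = ("TSS200", "TSS1500", "body", "other")

N_FI_ITEMS = 31

SAMPLE_SHEET_COLUMNS = [
    "mouse_id",
    "sex",
    "cohort",
    "treatment",
    "timepoint",
    "age_months",
    "fi",
    "age_at_death",
    "dead",
]


@dataclass
class FilterReport:
    """Accounting of a probe-filtering pass; every probe is counted once."""

    n_input: int
    n_removed_flagged: int
    n_removed_detection: int
    n_removed_variance: int
    n_retained: int
    min_detection_frac: float
    min_variance: float

    def __post_init__(self) -> None:
        total = (
            self.n_removed_flagged
            + self.n_removed_detection
            + self.n_removed_variance
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("filter report does not account for every probe")


@dataclass
class MethylationMatrix:
    """Probes x samples beta values plus probe annotation and sample sheet.

    ``betas`` is a DataFrame indexed by probe id with sample ids as columns;
    missing measurements are NaN.  ``probes`` is the manifest indexed by
    probe id (columns ``chrom``, ``pos``, ``island_relation``,
    ``tss_relation``, ``genes`` and optional ``is_cpg`` / ``is_snp`` flags).
    ``samples`` is the sample sheet indexed by sample id, aligned with the
    beta columns.
    """

    betas: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.probes.index):
            raise ValueError("beta rows and probe manifest are not aligned")
        if not self.betas.columns.equals(self.samples.index):
            raise ValueError("beta columns and sample sheet are not aligned")
        vals = self.betas.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("beta values outside [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def m_values(self, clip_eps: float = 1e-6) -> pd.DataFrame:
        """Logit-transformed methylation (M-values), NaN preserved."""
        return pd.DataFrame(
            beta_to_m(self.betas.to_numpy(dtype=float), clip_eps=clip_eps),
            index=self.betas.index,
            columns=self.betas.columns,
        )

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(
            self.betas.loc[probe_ids], self.probes.loc[probe_ids], self.samples
        )

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(
            self.betas[sample_ids], self.probes, self.samples.loc[sample_ids]
        )


def beta_to_m(beta, clip_eps: float = 1e-6):
    """Convert beta values (proportions) to M-values, ``log2(b / (1 - b))``.

    Betas are clipped into ``[clip_eps, 1 - clip_eps]`` first so boundary
    values map to finite M-values.  NaN (missing) propagates; any other
    non-finite input raises.
    """
    if not 0.0 < clip_eps <= 0.01:
        raise ValueError("clip_eps must lie in (0, 0.01]")
    arr = np.asarray(beta, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("non-finite beta value")
    with np.errstate(invalid="ignore"):
        if ((arr < 0.0) | (arr > 1.0)).any():
            raise ValueError("beta outside [0, 1]")
    b = np.clip(arr, clip_eps, 1.0 - clip_eps)
    out = np.log2(b / (1.0 - b))
    if np.ndim(beta) == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``2**m / (1 + 2**m)``."""
    arr = np.asarray(m, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("non-finite M-value")
    out = 1.0 / (1.0 + np.exp2(-arr))
    if np.ndim(m) == 0:
        return float(out)
    return out


def log_fi(fi, floor: float | None = None):
    """Natural log of the frailty index.

    FI is a proportion in (0, 1]; a zero FI has no log.  If ``floor`` is
    given, values below it are raised to the floor before the log;
    otherwise fi <= 0 raises.
    """
    arr = np.asarray(fi, dtype=float)
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        arr = np.maximum(arr, floor)
    if arr.size and np.nanmin(arr) <= 0:
        raise ValueError(
            "fi <= 0 has no log; pass floor= to apply a configured floor offset"
        )
    out = np.log(arr)
    if np.ndim(fi) == 0:
        return float(out)
    return out


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values.

    Output order matches input; NaN entries propagate and are excluded from
    the number of tests.  Values outside [0, 1] raise.
    """
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-value outside [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def filter_probes(
    mat: MethylationMatrix,
    min_detection_frac: float = 0.95,
    min_variance: float = 1e-10,
    drop_non_cpg: bool = True,
    drop_snp: bool = True,
) -> tuple[MethylationMatrix, FilterReport]:
    """Remove flagged, poorly detected and near-invariant probes.

    Rules are applied in order (first failing rule wins): (1) manifest flags
    (non-CpG probes when ``drop_non_cpg``, SNP probes when ``drop_snp``),
    (2) detection -- the non-missing fraction across samples must be at
    least ``min_detection_frac``, (3) variance -- the beta variance across
    non-missing samples must exceed ``min_variance``.
    """
    if mat.n_probes == 0 or mat.n_samples == 0:
        raise ValueError("empty methylation matrix")
    if not 0.0 <= min_detection_frac <= 1.0:
        raise ValueError("min_detection_frac must lie in [0, 1]")
    if min_variance < 0:
        raise ValueError("min_variance must be non-negative")

    vals = mat.betas.to_numpy(dtype=float)
    flagged = np.zeros(mat.n_probes, dtype=bool)
    if drop_non_cpg and "is_cpg" in mat.probes.columns:
        flagged |= ~mat.probes["is_cpg"].astype(bool).to_numpy()
    if drop_snp and "is_snp" in mat.probes.columns:
        flagged |= mat.probes["is_snp"].astype(bool).to_numpy()

    detected = np.mean(~np.isnan(vals), axis=1)
    fail_det = ~flagged & (detected < min_detection_frac)
    with np.errstate(invalid="ignore"):
        var = np.array(
            [np.nanvar(row) if np.isfinite(row).any() else 0.0 for row in vals]
        )
    fail_var = ~flagged & ~fail_det & (var <= min_variance)

    keep = ~(flagged | fail_det | fail_var)
    report = FilterReport(
        n_input=mat.n_probes,
        n_removed_flagged=int(flagged.sum()),
        n_removed_detection=int(fail_det.sum()),
        n_removed_variance=int(fail_var.sum()),
        n_retained=int(keep.sum()),
        min_detection_frac=min_detection_frac,
        min_variance=min_variance,
    )
    if report.n_retained == 0:
        err = ValueError("all probes removed by filtering")
        err.report = report
        raise err
    return mat.subset_probes(mat.betas.index[keep]), report


def enrich_probe_sets(
    hit_probes: set,
    universe: set,
    sets: dict[str, set],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``hit_probes`` in each set.

    Sets are intersected with the universe first; sets disjoint from the
    universe are skipped (with a warning column in the output they simply
    do not appear).  BH adjustment is applied across the tested sets.
    """
    import warnings

    if not universe:
        raise ValueError("empty universe")
    hit_probes = set(hit_probes)
    if not hit_probes <= set(universe):
        raise ValueError("hit_probes must be a subset of the universe")
    M = len(universe)
    n_hits = len(hit_probes)
    rows = []
    for name, probes in sets.items():
        in_universe = set(probes) & set(universe)
        if not in_universe:
            warnings.warn(f"probe set {name!r} is disjoint from the universe; skipped")
            continue
        K = len(in_universe)
        k = len(in_universe & hit_probes)
        # P(X >= k) for X ~ Hypergeom(M, K, n_hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_hits))
        expected = K * n_hits / M
        fold = k / expected if expected > 0 else np.nan
        rows.append((name, k, K, fold, p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "fold", "p"]
    )
    if len(table):
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
    else:
        table["adj_p"] = []
    return table


# ---------------------------------------------------------------------------
# File formats: CSV sample sheet, TSV beta matrix, CSV manifest.


def _sample_id(mouse_id, timepoint) -> str:
    return f"{mouse_id}_T{int(timepoint)}"


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    """Check the sample-sheet invariants; raises ValueError on violation."""
    if not set(sheet["sex"]) <= set(SEXES):
        raise ValueError("sex must be F or M")
    if ((sheet["fi"] < 0) | (sheet["fi"] > 1)).any():
        raise ValueError("fi must lie in [0, 1]")
    item_cols = [c for c in sheet.columns if c.startswith("item_")]
    if item_cols:
        items = sheet[item_cols].to_numpy(dtype=float)
        if not np.isin(items[~np.isnan(items)], [0.0, 0.5, 1.0]).all():
            raise ValueError("item scores must be 0, 0.5 or 1")
        implied = np.nansum(items, axis=1) / N_FI_ITEMS
        has_items = ~np.isnan(items).all(axis=1)
        if np.max(np.abs(implied[has_items] - sheet["fi"].to_numpy()[has_items]),
                  initial=0.0) > 1e-12:
            raise ValueError("fi does not equal the mean of the 31 item scores")
    for mouse, grp in sheet.groupby("mouse_id"):
        ages = grp.sort_values("timepoint")["age_months"].to_numpy()
        if not (np.diff(ages) > 0).all():
            raise ValueError(f"ages not strictly increasing for mouse {mouse}")
        aad = grp["age_at_death"]
        if aad.notna().any():
            if (aad.dropna() < grp.loc[aad.notna(), "age_months"]).any():
                raise ValueError(f"age_at_death precedes an observation for {mouse}")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    sheet["dead"] = sheet["dead"].astype(bool)
    sheet.index = pd.Index(
        [_sample_id(m, t) for m, t in zip(sheet["mouse_id"], sheet["timepoint"])],
        name="sample_id",
    )
    validate_sample_sheet(sheet)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_beta_matrix(path) -> pd.DataFrame:
    betas = pd.read_csv(path, sep="\t", index_col=0)
    betas.index.name = "probe_id"
    return betas


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, index_col="probe_id")
    if not manifest.index.is_unique:
        raise ValueError("probe_id not unique in manifest")
    if (manifest["pos"] < 1).any():
        raise ValueError("positions are 1-based; pos >= 1 required")
    manifest["genes"] = [
        frozenset(str(g).split(";")) - {"", "nan"} if pd.notna(g) else frozenset()
        for g in manifest["genes"]
    ]
    return manifest


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    out["genes"] = [";".join(sorted(g)) for g in out["genes"]]
    out.to_csv(path, index_label="probe_id")


def read_methylation(beta_path, manifest_path, sheet_path) -> MethylationMatrix:
    """Load the three input files into an aligned :class:`MethylationMatrix`."""
    betas = read_beta_matrix(beta_path)
    manifest = read_manifest(manifest_path)
    sheet = read_sample_sheet(sheet_path)
    manifest = manifest.loc[betas.index]
    sheet = sheet.loc[betas.columns]
    return MethylationMatrix(betas, manifest, sheet)
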