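"""Synthetic longitudinal mouse cohorts with planted methylation effects.

The generator emulates the structure of a two-cohort aging study: a
discovery cohort (20 female / 25 male untreated mice) and a validation
cohort (20 female / 24 male NMN-treated mice) assessed at up to five
timepoints, with

* a 31-item frailty index scored 0 / 0.5 / 1 per item (so FI lies on the
  grid k/62), driven by a latent trajectory ``a + b*age + u_i + q_i(t)``
  where ``u_i`` is a mouse intercept and ``q_i(t)`` a per-mouse Gaussian
  random walk -- the *age-independent* frailty driver,
* mortality as a discrete-time logistic hazard in current FI, truncating
  each dead mouse's record,
* methylation on the logit (M) scale with planted co-methylated regions of
  5-12 CpGs: age-only (``ad``), frailty-beyond-age (``ai``, coupled to
  ``q``), ``dual``, ``null``, sex-gated and opposite-sign classes, plus
  X-inactivation dosage patterns on chrX, male heteroscedastic (VMP-like)
  probes and Y-chromosome probes missing in females,
* completely-at-random missingness.

Ground truth (region classes and effects, probe labels, latent drivers) is
exported so every downstream stage is testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .core_data import MethylationMatrix, N_FI_ITEMS, m_to_beta

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))

REGION_CLASSES = ("ai", "ad", "dual", "null", "sex_F_only", "sex_M_only",
                  "opposite_sign")


@dataclass
class CohortPlan:
    name: str = "discovery"
    n_female: int = 20
    n_male: int = 25
    treatment: str = "control"


@dataclass
class RegionPlan:
    """Planted-region counts and geometry (span kept within the smoothing
    bandwidth so each region forms a single chainable cluster)."""

    n_ai: int = 40
    n_ad: int = 40
    n_dual: int = 40
    n_null: int = 40
    n_sex_f: int = 15
    n_sex_m: int = 15
    n_opposite: int = 10
    min_probes: int = 5
    max_probes: int = 12
    max_span: int = 1000


@dataclass
class XciPlan:
    n_subject: int = 60
    n_escape: int = 20
    n_variable: int = 20
    n_variable_frailty: int = 8  # variable-escape probes also coupled to q in females


@dataclass
class VmpPlan:
    n_vmp: int = 40
    variance_slope: float = 3.0  # residual SD factor grows as (1 + slope*FI) in males


@dataclass
class SimConfig:
    cohorts: tuple[CohortPlan, ...] = (
        CohortPlan("discovery", 20, 25, "control"),
        CohortPlan("validation", 20, 24, "NMN"),
    )
    timepoint_ages: tuple[float, ...] = (21.0, 24.0, 27.0, 30.0, 33.0)
    regions: RegionPlan = field(default_factory=RegionPlan)
    xci: XciPlan = field(default_factory=XciPlan)
    vmp: VmpPlan = field(default_factory=VmpPlan)
    n_background: int = 2500
    n_chry: int = 25
    # latent frailty trajectory: eta = a + b*age + u_i + q_i(t)
    fi_intercept: float = -1.9125
    fi_age_slope: float = 0.0625
    item_thresholds: tuple[float, float] = (0.0, 1.2)
    item_noise_sd: float = 1.0
    mouse_frailty_sd: float = 0.25
    q_step_sd: float = 0.22
    # mortality: P(death before next assessment) = expit(h0 + h1 * FI)
    hazard_intercept: float = -3.0
    hazard_fi_slope: float = 4.0
    # methylation model on the M scale
    age_effect: float = 0.10    # M per month, ad/dual regions
    q_effect: float = 2.0       # M per unit q, ai/dual regions
    sex_offset_sd: float = 0.25
    mouse_meth_sd: float = 0.20
    region_noise_sd: float = 0.10
    probe_offset_sd: float = 0.30
    measurement_sd: float = 0.25
    age_center: float = 27.0
    missing_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("item_noise_sd", "mouse_frailty_sd", "q_step_sd",
                     "sex_offset_sd", "mouse_meth_sd", "region_noise_sd",
                     "probe_offset_sd", "measurement_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth: regions, per-probe labels and latent drivers."""

    regions: pd.DataFrame      # region_id, chrom, start, end, cls, alpha, phi, sex_gate
    probe_labels: pd.DataFrame  # probe_id -> region_id, kind, is_vmp, xci_class
    latent: pd.DataFrame       # per sample: mouse_id, q, u

    def to_json(self, path) -> None:
        payload = {
            "regions": self.regions.to_dict(orient="list"),
            "probe_labels": self.probe_labels.reset_index().to_dict(orient="list"),
            "latent": self.latent.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        regions = pd.DataFrame(payload["regions"])
        probe_labels = pd.DataFrame(payload["probe_labels"]).set_index("probe_id")
        latent = pd.DataFrame(payload["latent"]).set_index("sample_id")
        return cls(regions, probe_labels, latent)


@dataclass
class SimResult:
    matrix: MethylationMatrix
    truth: SyntheticTruth


def expected_item_score(eta, config: SimConfig) -> np.ndarray:
    """Analytic mean item score (hence mean FI) at latent level ``eta``."""
    t1, t2 = config.item_thresholds
    s = config.item_noise_sd
    return 0.5 * (ndtr((np.asarray(eta) - t1) / s) + ndtr((np.asarray(eta) - t2) / s))


def simulate_frailty(
    config: SimConfig, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the frailty sample sheet for all cohorts (before mortality).

    Returns ``(sheet, latent)``; the sheet has one row per mouse x
    timepoint with the 31 item scores and FI, the latent frame records the
    age-independent driver ``q`` and mouse intercept ``u`` per row.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ages = np.asarray(config.timepoint_ages, dtype=float)
    n_t = ages.size
    t1, t2 = config.item_thresholds

    rows, latents = [], []
    counter = 0
    for cohort in config.cohorts:
        sexes = ["F"] * cohort.n_female + ["M"] * cohort.n_male
        cages = _assign_cages(len(sexes), rng)
        for j, sex in enumerate(sexes):
            counter += 1
            mouse = f"{cohort.name[:3]}{counter:03d}"
            u = rng.normal(0.0, config.mouse_frailty_sd)
            q = np.cumsum(rng.normal(0.0, config.q_step_sd, n_t))
            for k in range(n_t):
                eta = config.fi_intercept + config.fi_age_slope * ages[k] + u + q[k]
                lat = eta + rng.normal(0.0, config.item_noise_sd, N_FI_ITEMS)
                items = np.where(lat < t1, 0.0, np.where(lat < t2, 0.5, 1.0))
                fi = items.sum() / N_FI_ITEMS
                row = {
                    "mouse_id": mouse,
                    "sex": sex,
                    "cohort": cohort.name,
                    "treatment": cohort.treatment,
                    "timepoint": k + 1,
                    "age_months": ages[k],
                    "fi": fi,
                    "cage": cages[j],
                    "age_at_death": np.nan,
                    "dead": False,
                }
                row.update({f"item_{i + 1}": items[i] for i in range(N_FI_ITEMS)})
                rows.append(row)
                latents.append(
                    {"mouse_id": mouse, "timepoint": k + 1, "q": q[k], "u": u,
                     "eta": eta}
                )
    sheet = pd.DataFrame(rows)
    sheet.index = pd.Index(
        [f"{m}_T{t}" for m, t in zip(sheet["mouse_id"], sheet["timepoint"])],
        name="sample_id",
    )
    latent = pd.DataFrame(latents, index=sheet.index)
    return sheet, latent


def _assign_cages(n_mice: int, rng: np.random.Generator) -> list[str]:
    cages, cage_no = [], 0
    i = 0
    while i < n_mice:
        size = int(rng.integers(4, 6))
        cage_no += 1
        cages.extend([f"cage{cage_no:02d}"] * size)
        i += size
    return cages[:n_mice]


def apply_mortality(
    sheet: pd.DataFrame,
    seed: int | np.random.Generator,
    hazard_intercept: float = -3.0,
    hazard_fi_slope: float = 4.0,
) -> pd.DataFrame:
    """Discrete-time logistic mortality on current FI.

    After each assessment (except the last) a mouse dies before the next
    one with probability ``expit(h0 + h1 * FI)``; dead mice contribute no
    later records and carry ``age_at_death`` on every retained row.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = sheet.copy()
    drop: list[str] = []
    for mouse, grp in sheet.groupby("mouse_id", sort=False):
        grp = grp.sort_values("timepoint")
        ages = grp["age_months"].to_numpy()
        fis = grp["fi"].to_numpy()
        death_age = np.nan
        for k in range(len(grp) - 1):
            p = expit(hazard_intercept + hazard_fi_slope * fis[k])
            if rng.random() < p:
                death_age = ages[k] + rng.uniform(0.0, ages[k + 1] - ages[k])
                drop.extend(grp.index[k + 1:])
                break
        if np.isfinite(death_age):
            keep = [ix for ix in grp.index if ix not in set(drop)]
            out.loc[keep, "age_at_death"] = death_age
            out.loc[keep, "dead"] = True
    out = out.drop(index=drop)
    return out


# ---------------------------------------------------------------------------
# Methylation


def _region_classes(plan: RegionPlan) -> list[str]:
    return (
        ["ai"] * plan.n_ai + ["ad"] * plan.n_ad + ["dual"] * plan.n_dual
        + ["null"] * plan.n_null + ["sex_F_only"] * plan.n_sex_f
        + ["sex_M_only"] * plan.n_sex_m + ["opposite_sign"] * plan.n_opposite
    )


def _draw_baseline_m(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal baselines: most probes near 0 or 1 on the beta scale."""
    u = rng.random(n)
    beta = np.where(
        u < 0.45, rng.beta(1.5, 12.0, n),
        np.where(u < 0.90, rng.beta(12.0, 1.5, n), rng.beta(5.0, 5.0, n)),
    )
    beta = np.clip(beta, 0.03, 0.97)
    return np.log2(beta / (1.0 - beta))


def simulate_methylation(
    sheet: pd.DataFrame,
    latent: pd.DataFrame,
    config: SimConfig,
    seed: int | np.random.Generator,
) -> SimResult:
    """Generate the beta matrix with planted regional effects and truth."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples = sheet.index.to_numpy()
    n_s = samples.size
    male = (sheet["sex"] == "M").to_numpy(dtype=float)
    age_c = sheet["age_months"].to_numpy() - config.age_center
    fi = sheet["fi"].to_numpy()
    q = latent.loc[sheet.index, "q"].to_numpy()
    mice = sheet["mouse_id"].to_numpy()
    mouse_levels, mouse_idx = np.unique(mice, return_inverse=True)
    n_mice = mouse_levels.size

    # --- probe layout ------------------------------------------------------
    classes = _region_classes(config.regions)
    rng.shuffle(classes)
    region_rows, probe_rows = [], []
    cursor = {c: 1_000_000 for c in AUTOSOMES}
    pid = 0

    def new_pid():
        nonlocal pid
        pid += 1
        return f"cg{pid:06d}"

    region_members: list[list[int]] = []  # row indices into probe table
    for r, cls in enumerate(classes):
        chrom = AUTOSOMES[r % len(AUTOSOMES)]
        n_p = int(rng.integers(config.regions.min_probes,
                               config.regions.max_probes + 1))
        gaps = rng.integers(60, 91, n_p - 1)
        while gaps.sum() > config.regions.max_span:
            gaps = rng.integers(60, 91, n_p - 1)
        start = cursor[chrom]
        pos = start + np.concatenate([[0], np.cumsum(gaps)])
        cursor[chrom] = int(pos[-1]) + 30_000
        sign_a = rng.choice([-1.0, 1.0])
        # dual regions drift concordantly with age and frailty: opposite
        # signs would cancel in the marginal logFI association
        sign_p = sign_a if cls == "dual" else rng.choice([-1.0, 1.0])
        alpha = config.age_effect * sign_a if cls in ("ad", "dual") else 0.0
        phi = config.q_effect * sign_p if cls in (
            "ai", "dual", "sex_F_only", "sex_M_only", "opposite_sign") else 0.0
        gate = {"sex_F_only": "F", "sex_M_only": "M"}.get(cls, "")
        region_id = f"R{r + 1:03d}"
        members = []
        for p in pos:
            members.append(len(probe_rows))
            probe_rows.append(
                dict(probe_id=new_pid(), chrom=chrom, pos=int(p), kind="region",
                     region_id=region_id, is_vmp=False, xci_class="")
            )
        region_members.append(members)
        region_rows.append(
            dict(region_id=region_id, chrom=chrom, start=int(pos[0]),
                 end=int(pos[-1]), cls=cls, alpha=alpha, phi=phi,
                 sex_gate=gate, n_probes=n_p,
                 gene=f"Gene{r + 1}")
        )

    n_bg = config.n_background
    vmp_flags = np.zeros(n_bg, dtype=bool)
    vmp_flags[: config.vmp.n_vmp] = True
    rng.shuffle(vmp_flags)
    for i in range(n_bg):
        chrom = AUTOSOMES[i % len(AUTOSOMES)]
        cursor[chrom] += int(rng.integers(8_000, 15_001))
        probe_rows.append(
            dict(probe_id=new_pid(), chrom=chrom, pos=cursor[chrom],
                 kind="background", region_id="", is_vmp=bool(vmp_flags[i]),
                 xci_class="")
        )

    xci_classes = (
        ["subject"] * config.xci.n_subject + ["escape"] * config.xci.n_escape
        + ["variable_escape"] * config.xci.n_variable
    )
    xpos = 3_000_000
    xci_frail = np.zeros(len(xci_classes), dtype=bool)
    var_idx = [i for i, c in enumerate(xci_classes) if c == "variable_escape"]
    for i in var_idx[: config.xci.n_variable_frailty]:
        xci_frail[i] = True
    for i, c in enumerate(xci_classes):
        xpos += int(rng.integers(8_000, 15_001))
        probe_rows.append(
            dict(probe_id=new_pid(), chrom="chrX", pos=xpos, kind="xci",
                 region_id="", is_vmp=False, xci_class=c,
                 xci_frailty=bool(xci_frail[i]))
        )
    ypos = 3_000_000
    for _ in range(config.n_chry):
        ypos += int(rng.integers(8_000, 15_001))
        probe_rows.append(
            dict(probe_id=new_pid(), chrom="chrY", pos=ypos, kind="chrY",
                 region_id="", is_vmp=False, xci_class="")
        )

    probes = pd.DataFrame(probe_rows).set_index("probe_id")
    if "xci_frailty" not in probes.columns:
        probes["xci_frailty"] = False
    probes["xci_frailty"] = (
        probes["xci_frailty"].astype(object).where(
            probes["xci_frailty"].notna(), False
        ).astype(bool)
    )
    regions = pd.DataFrame(region_rows)
    n_p_total = len(probes)

    # --- generate M values -------------------------------------------------
    M = np.empty((n_p_total, n_s))
    mu = _draw_baseline_m(rng, n_p_total)
    sex_off = rng.normal(0.0, config.sex_offset_sd, n_p_total)
    M[:] = mu[:, None] + sex_off[:, None] * male[None, :]

    kind = probes["kind"].to_numpy()
    # region probes: shared effects + per-(mouse, region) intercept + shared
    # per-sample region noise + probe offset
    for members, reg in zip(region_members, region_rows):
        idx = np.array(members)
        gate_vec = np.ones(n_s)
        if reg["sex_gate"] == "F":
            gate_vec = 1.0 - male
        elif reg["sex_gate"] == "M":
            gate_vec = male
        phi_vec = reg["phi"] * gate_vec
        if reg["cls"] == "opposite_sign":
            phi_vec = reg["phi"] * np.where(male == 1.0, -1.0, 1.0)
        signal = reg["alpha"] * gate_vec * age_c + phi_vec * q
        shared = (
            signal
            + rng.normal(0.0, config.region_noise_sd, n_s)
            + rng.normal(0.0, config.mouse_meth_sd, n_mice)[mouse_idx]
        )
        probe_off = rng.normal(0.0, config.probe_offset_sd, idx.size)
        M[idx] += shared[None, :] + probe_off[:, None]

    bg_mask = kind == "background"
    n_bg_probes = int(bg_mask.sum())
    # per-(mouse, probe) intercepts for background probes
    M[bg_mask] += rng.normal(0.0, config.mouse_meth_sd, (n_bg_probes, n_mice))[
        :, mouse_idx
    ]

    # measurement noise, heteroscedastic at VMP probes in males
    eps = rng.normal(0.0, 1.0, (n_p_total, n_s)) * config.measurement_sd
    vmp_mask = probes["is_vmp"].to_numpy()
    scale = 1.0 + config.vmp.variance_slope * fi
    eps[np.ix_(vmp_mask, male == 1.0)] *= scale[male == 1.0][None, :]
    M += eps

    # chrX probes follow the XCI dosage plan, overriding the generic model
    xmask = kind == "xci"
    xcls = probes.loc[xmask, "xci_class"].to_numpy()
    xfr = probes.loc[xmask, "xci_frailty"].to_numpy()
    fem = male == 0.0
    targets = {
        "subject": ((0.45, 0.04), (0.07, 0.02)),
        "escape": ((0.07, 0.02), (0.07, 0.02)),
        "variable_escape": ((0.30, 0.10), (0.10, 0.03)),
    }
    Mx = np.empty((int(xmask.sum()), n_s))
    for i, c in enumerate(xcls):
        (mf, sf), (mm, sm) = targets[c]
        beta_row = np.where(
            fem,
            rng.normal(mf, sf, n_s),
            rng.normal(mm, sm, n_s),
        )
        beta_row = np.clip(beta_row, 0.01, 0.99)
        row = np.log2(beta_row / (1.0 - beta_row))
        if xfr[i]:
            row = row + config.q_effect * q * fem
        Mx[i] = row
    M[xmask] = Mx

    # chrY: present in males, missing in females
    ymask = kind == "chrY"
    M[np.ix_(ymask, fem)] = np.nan

    betas = m_to_beta(M)
    miss = rng.random(betas.shape) < config.missing_rate
    betas[miss] = np.nan

    manifest = probes.copy()
    manifest["island_relation"] = rng.choice(
        ["island", "shore", "shelf", "open_sea"], n_p_total,
        p=[0.30, 0.25, 0.10, 0.35],
    )
    manifest["tss_relation"] = rng.choice(
        ["TSS200", "TSS1500", "body", "other"], n_p_total,
        p=[0.10, 0.15, 0.50, 0.25],
    )
    gene_map = dict(zip(regions["region_id"], regions["gene"]))
    manifest["genes"] = [
        frozenset([gene_map[r]]) if r else frozenset()
        for r in manifest["region_id"]
    ]
    manifest["is_cpg"] = True
    manifest["is_snp"] = False
    manifest_cols = ["chrom", "pos", "island_relation", "tss_relation", "genes",
                     "is_cpg", "is_snp"]

    mat = MethylationMatrix(
        pd.DataFrame(betas, index=probes.index, columns=samples),
        manifest[manifest_cols],
        sheet,
    )
    truth = SyntheticTruth(
        regions=regions,
        probe_labels=probes[["region_id", "kind", "is_vmp", "xci_class",
                             "xci_frailty", "chrom", "pos"]],
        latent=latent.loc[sheet.index, ["mouse_id", "q", "u"]],
    )
    return SimResult(mat, truth)


def simulate_cohort(config: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Full generator: frailty trajectories, mortality, methylation, truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    sheet, latent = simulate_frailty(config, rng)
    sheet = apply_mortality(
        sheet, rng, config.hazard_intercept, config.hazard_fi_slope
    )
    latent = latent.loc[sheet.index]
    return simulate_methylation(sheet, latent, config, rng)


def simulate_planted_outcome(
    n_mice: int = 45,
    n_dmrs: int = 20,
    coef: float = 0.3,
    age_interaction: float = 0.0,
    noise_sd: float = 0.05,
    timepoint_ages: tuple[float, ...] = (21.0, 24.0, 27.0, 30.0, 33.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort with a directly planted dM -> dlogFI regression coefficient.

    Useful for exercising the future-frailty machinery with a known truth:
    per mouse, DMR summary M-values evolve as a random walk and the change
    in logFI between consecutive assessments equals ``coef`` times the
    methylation change (plus ``age_interaction`` times its product with
    centered current age) plus noise.  Returns (sample sheet, summaries
    DMRs x samples); FI values are continuous here, not on the item grid.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(timepoint_ages)
    rows, m_cols = [], {}
    for i in range(n_mice):
        mouse = f"pm{i:03d}"
        n_t = int(rng.integers(3, len(ages) + 1))
        M = np.cumsum(rng.normal(0.0, 0.3, n_t)) + rng.normal(0.0, 0.5)
        lfi = np.empty(n_t)
        lfi[0] = rng.normal(-1.6, 0.2)
        if n_t > 1:
            lfi[1] = lfi[0] + rng.normal(0.0, noise_sd)
        # future FI change driven by the *preceding* methylation change:
        # dlogFI(c -> f) = slope(age_c) * dM(p -> c) + noise
        for t in range(1, n_t - 1):
            dM = M[t] - M[t - 1]
            slope = coef + age_interaction * (ages[t] - ages.mean())
            lfi[t + 1] = lfi[t] + slope * dM + rng.normal(0.0, noise_sd)
        fi = np.clip(np.exp(lfi), 1e-3, 0.999)
        for t in range(n_t):
            sid = f"{mouse}_T{t + 1}"
            rows.append(
                {"mouse_id": mouse, "sex": "F" if i % 2 else "M",
                 "cohort": "discovery", "treatment": "control",
                 "timepoint": t + 1, "age_months": ages[t], "fi": fi[t],
                 "age_at_death": np.nan, "dead": False}
            )
            m_cols[sid] = M[t]
    sheet = pd.DataFrame(rows)
    sheet.index = pd.Index(
        [f"{m}_T{t}" for m, t in zip(sheet["mouse_id"], sheet["timepoint"])],
        name="sample_id",
    )
    base = pd.Series(m_cols)
    summaries = pd.DataFrame(
        {sid: base[sid] for sid in sheet.index}, index=["d0"]
    ).reindex([f"d{j}" for j in range(n_dmrs)])
    # every DMR shares the mouse-level M path up to independent probe noise
    vals = np.tile(base[sheet.index].to_numpy(), (n_dmrs, 1))
    vals += rng.normal(0.0, 0.02, vals.shape)
    summaries = pd.DataFrame(vals, index=[f"d{j}" for j in range(n_dmrs)],
                             columns=sheet.index)
    return sheet, summaries


def write_simulation(result: SimResult, outdir) -> dict[str, str]:
    """Write sample sheet, beta matrix, manifest and truth JSON to a directory."""
    import os

    from . import core_data as cd

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sample_sheet": os.path.join(outdir, "sample_sheet.csv"),
        "betas": os.path.join(outdir, "betas.tsv"),
        "manifest": os.path.join(outdir, "manifest.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    cd.write_sample_sheet(result.matrix.samples, paths["sample_sheet"])
    cd.write_beta_matrix(result.matrix.betas, paths["betas"])
    cd.write_manifest(result.matrix.probes, paths["manifest"])
    result.truth.to_json(paths["truth"])
    return paths
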