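"""Pipeline orchestration: simulate/load -> filter -> EWAS -> DMR ->
co-methylation filter -> classification -> downstream analyses, from a
single config with deterministic re-runs and provenance logging.

Each stage writes its artifacts under the output directory together with a
run manifest (config hash + per-file content hash); re-running with an
identical config skips stages whose outputs are already up to date, and a
stage requested without its upstream artifacts fails with the missing
dependency named.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import clock as clock_mod
from . import core_data as cd
from . import longitudinal as lg
from . import variability as vb
from . import xci as xci_mod
from .classify import (
    classify_regions,
    comethylation_filter,
    assemble_joint_set,
    subgroup_sample_ids,
)
from .dmr import SmoothParams, form_regions, regions_to_frame, smooth_statistics
from .ewas import DEFAULT_FI_FLOOR, DesignSpec, call_dmps, run_ewas
from .simulate import SimConfig, simulate_cohort, write_simulation

SUBGROUPS = ("sex_inclusive", "female", "male")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "frailmeth_out"
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    sample_sheet: str | None = None
    betas: str | None = None
    manifest: str | None = None
    # stage parameters
    fdr: float = 0.05
    lam: float = 1000.0
    C: float = 2.0
    min_cpgs: int = 5
    rdrop_threshold: float = 0.4
    alpha: float = 0.05
    vmp_alpha_adj: float = 0.1
    clock_top_k: int = 100
    clock_l1_ratio: float = 0.5
    clock_folds: int = 5
    fi_floor: float = DEFAULT_FI_FLOOR
    subgroups: tuple[str, ...] = SUBGROUPS

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subgroups" in raw:
            raw["subgroups"] = tuple(raw["subgroups"])
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _log(stage: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[frailmeth] {stage} elapsed={time.time() - t0:.1f}s {extra}",
          file=sys.stderr)


def _sha(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_subgroup(
    mat: cd.MethylationMatrix,
    subgroup: str,
    fdr: float = 0.05,
    lam: float = 1000.0,
    C: float = 2.0,
    min_cpgs: int = 5,
    rdrop_threshold: float = 0.4,
    alpha: float = 0.05,
    fi_floor: float = DEFAULT_FI_FLOOR,
) -> dict:
    """EWAS -> smoothing -> regions -> rdrop -> classification, one subgroup."""
    mode = {"sex_inclusive": "sex_inclusive", "female": "female_only",
            "male": "male_only"}[subgroup]
    spec = DesignSpec(mode=mode, fi_floor=fi_floor)
    ewas = run_ewas(mat, spec)
    table = ewas.table.sort_values(["chrom", "pos"])
    stat_table = table.rename(columns={"weight": "stat_w"})
    stat_table = stat_table.assign(stat=stat_table["stat_w"])
    params = SmoothParams(lam=lam, C=C)
    smoothed = smooth_statistics(stat_table, params)
    regions = form_regions(smoothed, params, sig_fdr=fdr, min_cpgs=min_cpgs)

    ids = subgroup_sample_ids(mat.samples, subgroup)
    M = mat.m_values()[ids]
    samples = mat.samples.loc[ids]
    members = comethylation_filter(
        M, regions, samples, sex_inclusive=(subgroup == "sex_inclusive"),
        threshold=rdrop_threshold, min_cpgs=min_cpgs,
    )
    work_M = M
    if subgroup == "sex_inclusive":
        from .classify import sex_residualize

        work_M = sex_residualize(M, samples)
    classification = classify_regions(
        work_M, members, samples, subgroup, alpha=alpha, fi_floor=fi_floor
    )
    return {
        "ewas": ewas,
        "smoothed": smoothed,
        "regions": regions,
        "members": members,
        "classification": classification,
        "samples": samples,
        "M": work_M,
    }


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    force: bool = False,
) -> dict:
    """Execute the stage graph; returns the run manifest.

    ``stages`` restricts execution (downstream of missing prerequisites is
    an error); ``force`` disables up-to-date skipping.
    """
    os.makedirs(config.outdir, exist_ok=True)
    chash = config.config_hash()
    manifest_path = os.path.join(config.outdir, "run_manifest.json")
    manifest: dict = {"config_hash": chash, "config": asdict(config),
                      "artifacts": {}}
    old: dict = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") != chash:
            if stages is not None:
                raise DependencyError(
                    "existing artifacts come from a different config; "
                    "refusing to mix (re-run the full pipeline)"
                )
            old = {}

    def up_to_date(names: list[str]) -> bool:
        if force or old.get("config_hash") != chash:
            return False
        for n in names:
            rec = old.get("artifacts", {}).get(n)
            path = os.path.join(config.outdir, n)
            if rec is None or not os.path.exists(path) or _sha(path) != rec:
                return False
        return True

    def record(names: list[str]) -> None:
        for n in names:
            manifest["artifacts"][n] = _sha(os.path.join(config.outdir, n))

    all_stages = ["simulate", "filter"]
    all_stages += [f"analysis_{sg}" for sg in config.subgroups]
    all_stages += ["joint", "longitudinal", "xci", "variability", "clock"]
    requested = stages or all_stages
    for st in requested:
        if st not in all_stages:
            raise ValueError(f"unknown stage {st!r}")

    def want(st: str) -> bool:
        return st in requested

    sim_files = ["sample_sheet.csv", "betas.tsv", "manifest.csv", "truth.json"]
    t0 = time.time()
    if config.simulate:
        if want("simulate") and not up_to_date(sim_files):
            from .simulate import RegionPlan, VmpPlan, XciPlan

            overrides = dict(config.sim_overrides)
            for key, cls in (("regions", RegionPlan), ("vmp", VmpPlan),
                             ("xci", XciPlan)):
                if key in overrides and isinstance(overrides[key], dict):
                    overrides[key] = cls(**overrides[key])
            result = simulate_cohort(
                SimConfig(**overrides), stage_seed(config.seed, "simulate")
            )
            write_simulation(result, config.outdir)
            record(sim_files)
            _log("simulate", t0, probes=result.matrix.n_probes,
                 samples=result.matrix.n_samples)
        elif want("simulate"):
            record(sim_files)
            _log("simulate", t0, skipped=True)
        paths = {k: os.path.join(config.outdir, f) for k, f in
                 zip(("sheet", "betas", "manifest"), sim_files)}
    else:
        if not (config.sample_sheet and config.betas and config.manifest):
            missing = [k for k in ("sample_sheet", "betas", "manifest")
                       if not getattr(config, k)]
            raise DependencyError(f"missing input paths: {missing}")
        for k in ("sample_sheet", "betas", "manifest"):
            if not os.path.exists(getattr(config, k)):
                raise DependencyError(f"input file not found: {getattr(config, k)}")
        paths = {"sheet": config.sample_sheet, "betas": config.betas,
                 "manifest": config.manifest}
    for f in sim_files[:3]:
        src = paths[("sheet", "betas", "manifest")[sim_files.index(f)]]
        if not os.path.exists(src):
            raise DependencyError(f"required artifact missing: {src}")

    mat = cd.read_methylation(paths["betas"], paths["manifest"], paths["sheet"])

    t0 = time.time()
    mat, report = cd.filter_probes(mat)
    if want("filter"):
        with open(os.path.join(config.outdir, "filter_report.json"), "w") as fh:
            json.dump(asdict(report), fh, indent=1)
        record(["filter_report.json"])
        _log("filter", t0, retained=report.n_retained)

    disc = mat.subset_samples(
        mat.samples.index[mat.samples["cohort"] == "discovery"]
    )
    results: dict[str, dict] = {}
    classification_tables: dict[str, pd.DataFrame] = {}
    for sg in config.subgroups:
        st = f"analysis_{sg}"
        if not want(st):
            continue
        t0 = time.time()
        res = analyze_subgroup(
            disc, sg, fdr=config.fdr, lam=config.lam, C=config.C,
            min_cpgs=config.min_cpgs, rdrop_threshold=config.rdrop_threshold,
            alpha=config.alpha, fi_floor=config.fi_floor,
        )
        results[sg] = res
        classification_tables[sg] = res["classification"]
        if want(st):
            files = [f"ewas_{sg}.tsv", f"dmrs_{sg}.tsv", f"classification_{sg}.tsv"]
            res["ewas"].table.to_csv(
                os.path.join(config.outdir, files[0]), sep="\t")
            regions_to_frame(res["regions"]).to_csv(
                os.path.join(config.outdir, files[1]), sep="\t", index=False)
            tbl = res["classification"].copy()
            if len(tbl):
                tbl["members"] = [";".join(res["members"][d]) for d in tbl.index]
            tbl.to_csv(os.path.join(config.outdir, files[2]), sep="\t")
            record(files)
            _log(st, t0, dmps=len(call_dmps(res["ewas"], config.fdr)),
                 dmrs=len(res["regions"]),
                 fidmrs=int((tbl["class"] != "none").sum()) if len(tbl) else 0)

    if want("joint"):
        t0 = time.time()
        if not classification_tables:
            raise DependencyError("joint stage requires classification outputs")
        joint, merged = assemble_joint_set(classification_tables)
        joint.to_csv(os.path.join(config.outdir, "joint_fidmrs.tsv"),
                     sep="\t", index=False)
        merged.to_csv(os.path.join(config.outdir, "joint_merged.tsv"),
                      sep="\t", index=False)
        record(["joint_fidmrs.tsv", "joint_merged.tsv"])
        _log("joint", t0, fidmrs=len(joint), merged=len(merged))

    if want("longitudinal"):
        t0 = time.time()
        if "sex_inclusive" not in results:
            raise DependencyError(
                "longitudinal stage requires the sex_inclusive classification"
            )
        res = results["sex_inclusive"]
        fidmrs = res["classification"]
        fidmrs = fidmrs[fidmrs["class"] != "none"] if len(fidmrs) else fidmrs
        members = {d: res["members"][d] for d in fidmrs.index}
        reports = {}
        M_all = mat.m_values()
        for cohort in ("discovery", "validation"):
            ids = mat.samples.index[mat.samples["cohort"] == cohort]
            if not len(ids) or not members:
                continue
            sheet = mat.samples.loc[ids]
            frames = lg.build_outcome_frames(sheet, fi_floor=config.fi_floor)
            summaries = pd.DataFrame(
                {d: lg.dmr_summary(M_all[ids], m) for d, m in members.items()}
            ).T
            assocs = lg.run_outcome_associations(
                frames, summaries, alpha=config.alpha, cohort=cohort)
            reports[cohort] = pd.concat(assocs.values())
            reports[cohort].to_csv(
                os.path.join(config.outdir, f"assoc_{cohort}.tsv"), sep="\t")
            if cohort == "discovery":
                lg.intersect_multi_analysis(assocs).to_csv(
                    os.path.join(config.outdir, "intersection.tsv"),
                    sep="\t", index=False)
        files = ["intersection.tsv"]
        if "discovery" in reports and "validation" in reports:
            conc, summary = lg.validate_concordance(
                reports["discovery"], reports["validation"], alpha=config.alpha)
            conc.to_csv(os.path.join(config.outdir, "concordance.tsv"),
                        sep="\t", index=False)
            files += ["concordance.tsv", "assoc_discovery.tsv",
                      "assoc_validation.tsv"]
        record([f for f in files if os.path.exists(os.path.join(config.outdir, f))])
        _log("longitudinal", t0, dmrs=len(members))

    if want("xci"):
        t0 = time.time()
        x_probes = mat.probes.index[mat.probes["chrom"] == "chrX"]
        if len(x_probes):
            calls = xci_mod.classify_xci(
                mat.betas.loc[x_probes], mat.samples,
                chrom=mat.probes["chrom"])
            calls.to_csv(os.path.join(config.outdir, "xci_calls.tsv"), sep="\t")
            if "female" in results:
                dmps = call_dmps(results["female"]["ewas"], config.fdr)
                overlap = xci_mod.xca_frailty_overlap(calls, dmps, mat.probes)
                overlap.to_csv(
                    os.path.join(config.outdir, "xca_overlap.tsv"), sep="\t")
                record(["xci_calls.tsv", "xca_overlap.tsv"])
            else:
                record(["xci_calls.tsv"])
            _log("xci", t0, probes=len(calls))

    if want("variability"):
        t0 = time.time()
        if "male" not in results:
            raise DependencyError("variability stage requires the male subgroup")
        male = results["male"]
        ficpgs = sorted(
            {c for d in male["classification"].index
             if male["classification"].loc[d, "class"] != "none"
             for c in male["members"][d]}
        )
        if ficpgs:
            vmp = vb.breusch_pagan_vmp(
                male["M"].loc[ficpgs], male["samples"],
                alpha_adj=config.vmp_alpha_adj, adjust_sex=False,
                fi_floor=config.fi_floor)
            snr = vb.snr_classify(male["M"].loc[ficpgs], male["samples"],
                                  adjust_sex=False, fi_floor=config.fi_floor)
            vmp.join(snr).to_csv(
                os.path.join(config.outdir, "vmp_male.tsv"), sep="\t")
            record(["vmp_male.tsv"])
        si = results.get("sex_inclusive")
        if si is not None and len(si["classification"]):
            all_ficpgs = sorted(
                {c for d in si["classification"].index
                 if si["classification"].loc[d, "class"] != "none"
                 for c in si["members"][d]}
            )
            if all_ficpgs:
                ent = vb.shannon_entropy(disc.betas.loc[all_ficpgs])
                ent.to_frame().to_csv(
                    os.path.join(config.outdir, "entropy.tsv"), sep="\t")
                record(["entropy.tsv"])
        _log("variability", t0, ficpgs=len(ficpgs))

    if want("clock"):
        t0 = time.time()
        si = results.get("sex_inclusive")
        if si is None or not len(si["classification"]):
            raise DependencyError("clock stage requires sex_inclusive fiDMRs")
        fidmrs = si["classification"]
        fidmrs = fidmrs[fidmrs["class"] != "none"]
        fidmrs = fidmrs.assign(fi_adj_p=fidmrs["fi_adj_p"])
        _, cpgs = clock_mod.select_top_dmrs(
            fidmrs, si["members"], k=config.clock_top_k)
        M_all = mat.m_values()
        d_sheet = disc.samples
        metrics = []
        files = []
        for name, include_age in (("EFC1", True), ("EFC2", False)):
            model = clock_mod.fit_efc(
                M_all, d_sheet, cpgs, include_age=include_age, name=name,
                l1_ratio=config.clock_l1_ratio, n_folds=config.clock_folds,
                seed=stage_seed(config.seed, f"clock_{name}"),
            )
            model.to_json(os.path.join(config.outdir, f"{name.lower()}.json"))
            files.append(f"{name.lower()}.json")
            for cohort in ("discovery", "validation"):
                ids = mat.samples.index[mat.samples["cohort"] == cohort]
                if not len(ids):
                    continue
                ev = clock_mod.evaluate_clock(
                    model, M_all[ids], mat.samples.loc[ids])
                ev.insert(0, "cohort", cohort)
                metrics.append(ev)
        pd.concat(metrics).to_csv(
            os.path.join(config.outdir, "clock_metrics.tsv"), sep="\t",
            index=False)
        files.append("clock_metrics.tsv")
        record(files)
        _log("clock", t0, n_features=len(cpgs))

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
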