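"""End-to-end synthetic reproduction pipeline.

Chains the package's stages on self-generated data: coalescent simulation of
a two-deme panel, VCF export and hard filtering, windowed diversity
statistics and the joint folded SFS, composite-likelihood demographic
fitting with AIC model choice, sweep scanning with simulation-calibrated
cutoffs and two-method consensus regions, and an F2 QTL mapping demo.  Every
stage writes its artifacts into the run directory and is recorded, with
checksums, in a JSON manifest; identical configurations produce identical
manifests.

The default budgets are desk-scale (minutes, one CPU); warnings are logged
wherever a budget is reduced relative to the full study configuration
(e.g. fewer than 10,000 null simulations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as akio
from .coalescent import child_seed_sequence, simulate_null_set, simulate_panel
from .filters import FilterConfig, density_filter
from .models import DemographicModel, reference_models
from .qtl import (QtlModel, arabidopsis_style_map, interval_mapping,
                  permutation_threshold, simulate_f2, variance_explained)
from .sfsfit import compare_models, composite_log_likelihood, expected_sfs, fit_model
from .stats import (WindowConfig, hudson_fst, joint_folded_sfs,
                    nucleotide_diversity, watterson_theta)
from .sweep import (OmegaConfig, calibrate_cutoff, clr_scan, folded_background,
                    intersect_methods, merge_regions, omega_scan)

logger = logging.getLogger("adaptkit.pipeline")

__all__ = ["RunConfig", "run_pipeline", "make_report"]

FULL_STUDY_NULLS = 10_000


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults are a fast demo)."""

    seed: int = 1
    outdir: str = "adaptkit_run"
    model: str = "M4_two_windows"
    n_popY: int = 86
    n_popN: int = 25
    sequence_length: int = 50_000
    window: WindowConfig = field(default_factory=lambda: WindowConfig(20_000, 5_000))
    filter: FilterConfig = field(default_factory=FilterConfig)
    # demographic fit budget (per model)
    fit_free_params: tuple[str, ...] = ("divergence_time",)
    fit_runs: int = 2
    fit_cycles: int = 3
    fit_sims: tuple[int, int] = (1_000, 4_000)
    fit_n_snps: int = 30_000
    expected_sfs_sims: int = 20_000
    # sweep stage
    n_nulls: int = 20
    scan_fpr: float = 0.05
    omega: OmegaConfig = field(default_factory=lambda: OmegaConfig(5_000, 2_000, 20_000))
    clr_grid: int = 10
    # qtl stage
    qtl_n: int = 86
    qtl_perms: int = 200
    stages: tuple[str, ...] = ("simulate", "filter", "stats", "fit", "scan", "qtl")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = [self.window.window_size, self.window.step]
        d["filter"] = dataclasses.asdict(self.filter)
        d["omega"] = [self.omega.grid_interval, self.omega.minwin, self.omega.maxwin]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "window" in d:
            d["window"] = WindowConfig(*d["window"])
        if "filter" in d:
            d["filter"] = FilterConfig(**d["filter"])
        if "omega" in d:
            d["omega"] = OmegaConfig(*d["omega"])
        for key in ("fit_free_params", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("fit_sims",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seed_sequence(cfg.seed, 16)
    models = {m.name: m for m in reference_models()}
    if cfg.model not in models:
        raise ValueError(f"unknown model {cfg.model!r}")
    model = models[cfg.model]
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "files": {}}
    enabled = set(cfg.stages)
    deps = {"filter": "simulate", "stats": "filter", "fit": "stats", "scan": "stats"}
    for stage, needed in deps.items():
        if stage in enabled and needed not in enabled:
            enabled.discard(stage)
            manifest["stages"][stage] = {
                "status": "skipped", "reason": f"requires disabled stage {needed!r}",
            }
            logger.warning("stage %s disabled: depends on %s", stage, needed)

    def record(stage, t0, **info):
        manifest["stages"][stage] = {"status": "done",
                                     "seconds": round(time.time() - t0, 3), **info}

    def declare(name, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    panel = None
    if "simulate" in enabled:
        t0 = time.time()
        panel = simulate_panel(model, (cfg.n_popY, cfg.n_popN), cfg.sequence_length,
                               seed=seeds[0])
        vcf_path = out / "panel.vcf"
        akio.write_panel_vcf(panel, vcf_path)
        declare("panel_vcf", vcf_path)
        record("simulate", t0, n_sites=panel.n_sites, seed=seeds[0])
    else:
        manifest["stages"].setdefault("simulate", {"status": "skipped"})

    if "filter" in enabled and panel is not None:
        t0 = time.time()
        kept = density_filter(panel.positions, cfg.filter.density_max_snps,
                              cfg.filter.density_window)
        keep_mask = np.isin(panel.positions, kept)
        panel = dataclasses.replace(panel, matrix=panel.matrix[:, keep_mask],
                                    positions=panel.positions[keep_mask])
        record("filter", t0, n_removed_density=int((~keep_mask).sum()),
               n_sites=panel.n_sites)
    else:
        manifest["stages"].setdefault("filter", {"status": "skipped"})

    sfs = None
    if "stats" in enabled and panel is not None:
        t0 = time.time()
        _, pi_win = nucleotide_diversity(panel, cfg.window)
        theta_win = watterson_theta(panel, cfg.window)
        fst_win = hudson_fst(panel, ("popY", "popN"), cfg.window)
        for name, tab in [("pi", pi_win), ("theta", theta_win), ("fst", fst_win)]:
            p = out / f"windows_{name}.tsv"
            akio.write_windows_tsv(tab, p, name)
            declare(f"windows_{name}", p)
        sfs = joint_folded_sfs(panel, ("popY", "popN"))
        sfs_path = out / "joint_sfs.txt"
        sfs.to_text(sfs_path)
        declare("joint_sfs", sfs_path)
        record("stats", t0, n_snps_in_sfs=int(sfs.total))
    else:
        manifest["stages"].setdefault("stats", {"status": "skipped"})

    if "fit" in enabled and sfs is not None:
        t0 = time.time()
        fits = []
        for i, (name, template) in enumerate(models.items()):
            bounds = {p: _default_bounds(p) for p in cfg.fit_free_params}
            fit = fit_model(sfs, template, bounds, n_runs=cfg.fit_runs,
                            sims_schedule=cfg.fit_sims, max_cycles=cfg.fit_cycles,
                            seed=seeds[2] + i, min_support=10)
            fits.append(fit)
        comparison = compare_models(fits)
        fit_path = out / "fits.json"
        fit_path.write_text(json.dumps({
            "fits": [{"model": f.model_name, "params": f.params, "loglik": f.loglik,
                      "k": f.k, "converged": f.converged} for f in fits],
            "aic": dict(zip(comparison.model_names, comparison.aic.tolist())),
            "akaike_weights": dict(zip(comparison.model_names, comparison.weights.tolist())),
            "best": comparison.best(),
        }, indent=2))
        declare("fits", fit_path)
        record("fit", t0, best_model=comparison.best())
    else:
        manifest["stages"].setdefault("fit", {"status": "skipped"})

    if "scan" in enabled and panel is not None and sfs is not None:
        t0 = time.time()
        if cfg.n_nulls < FULL_STUDY_NULLS:
            logger.warning("sweep null budget reduced: %d datasets (full study: %d)",
                           cfg.n_nulls, FULL_STUDY_NULLS)
        popY = panel.subset(panel.deme_rows("popY"))
        background = folded_background(popY)
        nulls = simulate_null_set(model, cfg.n_nulls, cfg.sequence_length,
                                  (cfg.n_popY, cfg.n_popN), seed=seeds[3])
        null_clr, null_omega = [], []
        for np_ in nulls:
            ny = np_.subset(np_.deme_rows("popY"))
            null_clr.append(clr_scan(ny, background, n_grid=cfg.clr_grid))
            null_omega.append(omega_scan(ny, cfg.omega))
        clr = clr_scan(popY, background, n_grid=cfg.clr_grid)
        omg = omega_scan(popY, cfg.omega)
        clr.cutoff = calibrate_cutoff(null_clr, cfg.scan_fpr)
        clr.fpr = cfg.scan_fpr
        omg.cutoff = calibrate_cutoff(null_omega, cfg.scan_fpr)
        omg.fpr = cfg.scan_fpr
        regions_clr = merge_regions(clr)
        regions_omega = merge_regions(omg)
        consensus = intersect_methods(regions_clr, regions_omega)
        scan_path = out / "sweep_scans.json"
        scan_path.write_text(json.dumps({
            "clr": {"positions": clr.grid_positions.tolist(),
                    "values": clr.values.tolist(), "cutoff": clr.cutoff},
            "omega": {"positions": omg.grid_positions.tolist(),
                      "values": np.nan_to_num(omg.values, nan=-1.0).tolist(),
                      "cutoff": omg.cutoff},
            "regions_clr": regions_clr, "regions_omega": regions_omega,
            "consensus": consensus,
        }, indent=2))
        declare("sweep_scans", scan_path)
        record("scan", t0, n_consensus=len(consensus),
               clr_cutoff=clr.cutoff, omega_cutoff=omg.cutoff)
    else:
        manifest["stages"].setdefault("scan", {"status": "skipped"})

    if "qtl" in enabled:
        t0 = time.time()
        gmap = arabidopsis_style_map()
        truth = QtlModel(qtls=(("chr2", float(gmap.positions["chr2"][2]), 7.978, 0.0),
                               ("chr5", float(gmap.positions["chr5"][3]), 4.752, 0.0)),
                         residual_sd=3.024, grand_mean=37.6)
        cross = simulate_f2(cfg.qtl_n, gmap, truth, seed=seeds[4])
        curve = interval_mapping(cross)
        thr = permutation_threshold(cross, n_perm=max(100, cfg.qtl_perms), seed=seeds[5])
        peaks = (curve.loc[curve.groupby("chrom")["lod"].idxmax()]
                 .sort_values("lod", ascending=False))
        top = peaks[peaks["lod"] > thr]
        pve = variance_explained(cross, [(r.chrom, r.cM) for r in top.itertuples()]) \
            if len(top) else {"per_qtl_pve": [], "joint_pve": 0.0}
        qtl_path = out / "qtl.json"
        qtl_path.write_text(json.dumps({
            "lod_threshold": thr,
            "peaks": [{"chrom": r.chrom, "cM": r.cM, "lod": r.lod}
                      for r in peaks.itertuples()],
            "pve": pve["per_qtl_pve"], "joint_pve": pve.get("joint_pve"),
        }, indent=2))
        curve.to_csv(out / "lod_curve.tsv", sep="\t", index=False)
        declare("qtl", qtl_path)
        declare("lod_curve", out / "lod_curve.tsv")
        record("qtl", t0, lod_threshold=thr, n_significant=int(len(top)))
    else:
        manifest["stages"].setdefault("qtl", {"status": "skipped"})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _default_bounds(param: str) -> tuple[float, float]:
    if param == "divergence_time":
        return (10_000.0, 200_000.0)
    if param == "ancestral_size":
        return (20_000.0, 1_000_000.0)
    if param.startswith("size:"):
        return (5_000.0, 500_000.0)
    if param.startswith("mig:"):
        return (1e-8, 1e-3)
    raise ValueError(f"no default bounds for {param!r}")


def make_report(manifest: dict) -> str:
    """Human-readable summary of a pipeline manifest (deterministic text)."""
    lines = ["adaptkit pipeline report", "=" * 24, ""]
    missing = []
    for stage in ("simulate", "filter", "stats", "fit", "scan", "qtl"):
        info = manifest["stages"].get(stage, {"status": "absent"})
        lines.append(f"[{stage}] status={info.get('status')}")
        for k, v in sorted(info.items()):
            if k in ("status",):
                continue
            lines.append(f"    {k}: {v}")
    outdir = Path(manifest["config"]["outdir"])
    if "fits" in manifest["files"]:
        fp = Path(manifest["files"]["fits"]["path"])
        if fp.exists():
            fits = json.loads(fp.read_text())
            lines += ["", "Model comparison (AIC / Akaike weight):"]
            for name in fits["aic"]:
                lines.append(f"    {name}: AIC={fits['aic'][name]:.1f} "
                             f"w={fits['akaike_weights'][name]:.3f}")
            lines.append(f"    best: {fits['best']}")
        else:
            missing.append(str(fp))
    if "qtl" in manifest["files"]:
        qp = Path(manifest["files"]["qtl"]["path"])
        if qp.exists():
            q = json.loads(qp.read_text())
            lines += ["", f"QTL: LOD threshold {q['lod_threshold']:.2f}; "
                          f"PVE {['%.1f%%' % p for p in q['pve']]}"]
        else:
            missing.append(str(qp))
    if missing:
        lines += ["", "missing artifacts:"] + [f"    {m}" for m in missing]
    return "\n".join(lines) + "\n"
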