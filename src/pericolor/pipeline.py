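"""End-to-end orchestration: simulate -> segment -> phenotype -> segregate ->
analyze -> scan, under one validated configuration with recorded seeds.

The pipeline is deliberately thin: every stage is a call into the library
modules, stage outputs are plain CSV/JSON files in the run directory, and
the run manifest records seeds, stage toggles and record counts so a run
is reproducible byte for byte from its config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import color as color_mod
from . import geometry, phenotype, qtl, segmentation
from .segregation import STANDARD_MODELS, pigment_frequency, select_best_model
from .simulate import ScanSpec, SimTruth, default_marker_map, generate_kernel_scan, simulate_dh_population

__all__ = [
    "PipelineConfig",
    "extract_kernel_table",
    "run_pipeline",
    "make_report",
]


class SegmentationParams(BaseModel):
    n_subsamples: int = 3000
    seed: int = 0
    min_luminance: float = 0.4
    clean_size: int = 1
    fill_size: int = 7
    final_clean: int = 5
    use_watershed: bool = True


class QCParams(BaseModel):
    shape_iqr_mult: float = 1.5
    color_iqr_mult: float = 1.5
    cut_tip: float = 0.30
    cut_base: float = 0.15
    angle_tol: float = 5.0

    @field_validator("shape_iqr_mult", "color_iqr_mult")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("IQR multiplier must be nonnegative")
        return v


class PopulationParams(BaseModel):
    n_individuals: int = 150
    n_chrom: int = 3
    markers_per_chrom: int = 40
    spacing_cm: float = 2.5
    model_name: str = "Single gene"
    causal_markers: dict[str, str] = Field(default_factory=lambda: {"A": "c1m10"})
    qtl: list[tuple[str, float]] = Field(default_factory=lambda: [("c1m10", 2.0)])
    baseline_hue: float = 34.0
    replicate_sd: float = 0.5
    residual_sd: float = 1.0
    n_reps: int = 2
    two_rep_fraction: float = 0.33
    missing_rate: float = 0.02
    error_rate: float = 0.002


class ImagingParams(BaseModel):
    enabled: bool = False        # image-based phenotyping is slow; opt in
    kernels_per_image: int = 12
    height: int = 420
    width: int = 560
    kernel_hue_sd: float = 1.0   # kernel-to-kernel hue spread within a line


class ScanParams(BaseModel):
    n_perm: int = 1000
    alpha: float = 0.05
    error_rate: float = 0.002
    interval_method: str = "bayes"
    interval_prob: float = 0.95


class StageToggles(BaseModel):
    simulate: bool = True
    phenotype: bool = True
    segregate: bool = True
    analyze: bool = True
    scan: bool = True


class PipelineConfig(BaseModel):
    """Validated, file-round-trippable configuration for one run."""

    seed: int = 1
    out_dir: str = "pericolor_run"
    stages: StageToggles = Field(default_factory=StageToggles)
    population: PopulationParams = Field(default_factory=PopulationParams)
    imaging: ImagingParams = Field(default_factory=ImagingParams)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    qc: QCParams = Field(default_factory=QCParams)
    scan: ScanParams = Field(default_factory=ScanParams)
    counts_csv: str | None = None   # observed pigment counts for segregate-only runs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def extract_kernel_table(
    image: np.ndarray,
    image_id: str,
    seg: SegmentationParams | None = None,
    qc: QCParams | None = None,
) -> pd.DataFrame:
    """Segment one scan and measure every kernel.

    Returns one row per labeled component: geometry (length, width), mean
    region RGB and hue, a ``retained`` flag and the removal reason for
    kernels failing any geometric QC step.
    """
    seg = seg or SegmentationParams()
    qc = qc or QCParams()
    labeled, _thr = segmentation.segment_image(
        image,
        n_subsamples=min(seg.n_subsamples, image.shape[0] * image.shape[1]),
        seed=seg.seed,
        min_luminance=seg.min_luminance,
        clean_size=seg.clean_size,
        fill_size=seg.fill_size,
        final_clean=seg.final_clean,
        use_watershed=seg.use_watershed,
    )
    rows = []
    for k in range(1, labeled.n_components + 1):
        mask = labeled.component_mask(k)
        row: dict = {"image_id": image_id, "kernel_id": f"{image_id}_k{k}"}
        try:
            lm = geometry.measure_kernel(
                mask, image=image, cut_tip=qc.cut_tip, cut_base=qc.cut_base,
                angle_tol=qc.angle_tol,
            )
            kc = color_mod.region_mean_color(image, lm.axial_region)
            row.update(
                length_px=lm.length_px, width_px=lm.width_px,
                lw_ratio=lm.lw_ratio, mean_r=kc.mean_r, mean_g=kc.mean_g,
                mean_b=kc.mean_b, hue=kc.hue,
                n_region_pixels=kc.n_region_pixels,
                retained=True, removal_reason="",
            )
        except geometry.KernelGeometryError as err:
            row.update(
                length_px=np.nan, width_px=np.nan, lw_ratio=np.nan,
                mean_r=np.nan, mean_g=np.nan, mean_b=np.nan, hue=np.nan,
                n_region_pixels=0, retained=False, removal_reason=err.reason,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_stage(cfg: PipelineConfig, out: Path, manifest: dict):
    pop_cfg = cfg.population
    model = next(m for m in STANDARD_MODELS if m.name == pop_cfg.model_name)
    mm = default_marker_map(pop_cfg.n_chrom, pop_cfg.markers_per_chrom,
                            pop_cfg.spacing_cm)
    truth = SimTruth(
        model=model,
        causal_markers=pop_cfg.causal_markers,
        qtl=list(pop_cfg.qtl),
        baseline_hue=pop_cfg.baseline_hue,
        replicate_sd=pop_cfg.replicate_sd,
        residual_sd=pop_cfg.residual_sd,
        seed=cfg.seed,
    )
    sim = simulate_dh_population(
        pop_cfg.n_individuals, mm, truth,
        n_reps=pop_cfg.n_reps, two_rep_fraction=pop_cfg.two_rep_fraction,
        missing_rate=pop_cfg.missing_rate, error_rate=pop_cfg.error_rate,
    )
    sim.population.genotypes.to_csv(out / "geno.csv", na_rep="NA")
    mm.to_csv(out / "map.csv", index=False)
    sim.pheno.to_csv(out / "pheno.csv", index=False)
    manifest["stages"]["simulate"] = {
        "n_individuals": pop_cfg.n_individuals,
        "n_markers": len(mm),
        "model": model.name,
        "seed": cfg.seed,
    }
    return sim


def _phenotype_stage(cfg: PipelineConfig, sim, out: Path, manifest: dict):
    """Image-based hue recovery for the simulated lines (optional, slow)."""
    rng = np.random.default_rng(cfg.seed + 1)
    img_cfg = cfg.imaging
    tables, meta_rows = [], []
    for _, rec in sim.pheno.iterrows():
        image_id = f"{rec.line_id}_rep{int(rec.replicate)}"
        hues = np.clip(
            rng.normal(rec.hue, img_cfg.kernel_hue_sd, img_cfg.kernels_per_image),
            1.0, 59.0,
        )
        spec = ScanSpec(
            height=img_cfg.height, width=img_cfg.width,
            n_kernels=img_cfg.kernels_per_image, body_hues=list(hues),
        )
        image, _truth = generate_kernel_scan(spec, seed=int(rng.integers(2**31)))
        tables.append(extract_kernel_table(image, image_id, cfg.segmentation, cfg.qc))
        meta_rows.append(
            {"image_id": image_id, "line_id": rec.line_id,
             "population_id": sim.population.population_id,
             "replicate": int(rec.replicate)}
        )
    kernels = pd.concat(tables, ignore_index=True)
    retained = kernels[kernels["retained"]]
    retained, shape_log = color_mod.shape_qc(retained, cfg.qc.shape_iqr_mult)
    retained, color_log = color_mod.color_qc(retained, cfg.qc.color_iqr_mult)
    line_table, warn = color_mod.aggregate_line_hue(
        retained, pd.DataFrame(meta_rows)
    )
    kernels.to_csv(out / "kernels.csv", index=False)
    line_table.to_csv(out / "line_hue.csv", index=False)
    manifest["stages"]["phenotype"] = {
        "n_images": len(meta_rows),
        "n_kernels_segmented": len(kernels),
        "n_kernels_retained": len(retained),
        "n_shape_removed": len(shape_log),
        "n_color_removed": len(color_log),
        "warnings": warn,
    }
    return line_table


def _segregate_stage(cfg: PipelineConfig, sim, out: Path, manifest: dict):
    if cfg.counts_csv:
        counts = pd.read_csv(cfg.counts_csv)
    elif sim is not None:
        per_line = sim.pheno.groupby("line_id")["pigment_class"].first()
        counts = pd.DataFrame(
            [{
                "population": sim.population.population_id,
                "pigmented": int(per_line.sum()),
                "clear": int((1 - per_line).sum()),
            }]
        )
    else:
        raise FileNotFoundError(
            "segregate stage needs counts_csv or an upstream simulate stage"
        )
    rows = []
    for _, rec in counts.iterrows():
        ranked = select_best_model(int(rec.pigmented), int(rec.clear))
        best = ranked[ranked["best"]].iloc[0]
        row = {
            "population": rec.population,
            "ratio": pigment_frequency(int(rec.pigmented),
                                       int(rec.pigmented) + int(rec.clear)),
            "pigmented": int(rec.pigmented),
            "clear": int(rec.clear),
            "genetic_model": best["model"],
            "p_value": best["p_value"],
        }
        for _, mrow in ranked.iterrows():
            row[f"p_{mrow['model']}"] = mrow["p_value"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "segregation.csv", index=False)
    manifest["stages"]["segregate"] = {"n_populations": len(table)}
    return table


def _analyze_stage(cfg: PipelineConfig, pheno: pd.DataFrame, out: Path,
                   manifest: dict):
    blue_set = phenotype.fit_line_blues(pheno)
    h2 = phenotype.cullis_h2(blue_set.sigma_g2, blue_set.avsed)
    per_line = pheno.groupby("line_id").agg(
        hue=("hue", "mean"), visual_rating=("visual_rating", "first")
    ) if "visual_rating" in pheno else None
    rho = pval = float("nan")
    if per_line is not None and per_line["visual_rating"].nunique() > 1:
        rho, pval = phenotype.spearman_validation(
            per_line["hue"].to_numpy(), per_line["visual_rating"].to_numpy()
        )
    blue_set.blues.to_csv(out / "blues.csv", index=False)
    summary = {
        "heritability": h2.h2,
        "spearman_rho": rho,
        "spearman_p": pval,
        "mean": float(blue_set.blues["blue"].mean()),
        "min": float(blue_set.blues["blue"].min()),
        "max": float(blue_set.blues["blue"].max()),
        "avsed": blue_set.avsed,
        "sigma_g2": blue_set.sigma_g2,
        "sigma_rep2": blue_set.sigma_rep2,
        "sigma_e2": blue_set.sigma_e2,
    }
    with open(out / "phenotypic_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["stages"]["analyze"] = {"n_lines": blue_set.n_lines,
                                     "heritability": h2.h2}
    return blue_set, summary


def _scan_stage(cfg: PipelineConfig, sim, blues: pd.DataFrame, out: Path,
                manifest: dict):
    pop, qc_report = qtl.filter_markers_individuals(
        sim.population.genotypes, sim.population.marker_map,
        population_id=sim.population.population_id,
        parents=sim.population.parents,
    )
    pheno = blues.set_index("line_id")["blue"]
    probs = qtl.dh_genotype_probabilities(pop, error_rate=cfg.scan.error_rate)
    lod = qtl.hk_scan(probs, pheno)
    threshold, _ = qtl.permutation_threshold(
        probs, pheno, n_perm=cfg.scan.n_perm, alpha=cfg.scan.alpha,
        seed=cfg.seed + 2,
    )
    peaks = qtl.peak_intervals(lod, threshold, method=cfg.scan.interval_method,
                               prob=cfg.scan.interval_prob)
    marker_idx = {m: i for i, m in enumerate(probs.marker_map["marker"])}
    y = pheno.reindex(probs.individuals).to_numpy(dtype=float)
    for pk in peaks:
        eff, donor = qtl.blup_allele_effect(
            probs.p_a[:, marker_idx[pk.marker]], y, parents=pop.parents
        )
        pk.allele_effect = eff
        pk.donor_parent = donor
    lod.to_csv(out / "scan_lod.csv", index=False)
    peaks_df = pd.DataFrame(
        [{
            "population": pop.population_id, "negative_allele": p.donor_parent,
            "chromosome": p.chrom, "pos_cm": p.pos_cm, "lod": p.lod,
            "interval_lo": p.interval_lo, "interval_hi": p.interval_hi,
            "allele_effect": p.allele_effect,
        } for p in peaks]
    )
    peaks_df.to_csv(out / "peaks.csv", index=False)
    qc_report.removed_markers.to_csv(out / "qc_markers.csv", index=False)
    qc_report.removed_individuals.to_csv(out / "qc_individuals.csv", index=False)
    manifest["stages"]["scan"] = {
        "threshold": threshold, "n_perm": cfg.scan.n_perm,
        "n_peaks": len(peaks),
        "n_markers": qc_report.n_markers_kept,
        "n_individuals": qc_report.n_individuals_kept,
        "perm_seed": cfg.seed + 2,
    }
    return {"lod": lod, "threshold": threshold, "peaks": peaks_df}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    Stage results are written under ``config.out_dir`` and key tables are
    attached to the manifest under ``results`` for programmatic use.
    Raises when a stage's upstream output is missing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "results": {}}

    sim = None
    if config.stages.simulate:
        sim = _simulate_stage(config, out, manifest)
        manifest["results"]["sim_pheno"] = sim.pheno

    line_table = None
    if config.stages.phenotype:
        if config.imaging.enabled:
            if sim is None:
                raise FileNotFoundError("phenotype stage needs the simulate stage")
            line_table = _phenotype_stage(config, sim, out, manifest)
        elif sim is not None:
            # direct use of simulated per-replicate hue (fast path)
            line_table = sim.pheno.rename(columns={})
            manifest["stages"]["phenotype"] = {"mode": "simulated-direct",
                                               "n_records": len(line_table)}
        else:
            raise FileNotFoundError("phenotype stage needs the simulate stage")

    if config.stages.segregate:
        table = _segregate_stage(config, sim, out, manifest)
        manifest["results"]["segregation"] = table

    blue_set = None
    if config.stages.analyze:
        if line_table is None:
            raise FileNotFoundError("analyze stage needs the phenotype stage")
        pheno_for_blues = line_table
        if "replicate" not in pheno_for_blues:
            raise FileNotFoundError("phenotype output lacks replicate labels")
        if sim is not None and "visual_rating" not in pheno_for_blues:
            ratings = sim.pheno[["line_id", "replicate", "visual_rating"]]
            pheno_for_blues = pheno_for_blues.merge(
                ratings, on=["line_id", "replicate"], how="left"
            )
        blue_set, summary = _analyze_stage(config, pheno_for_blues, out, manifest)
        manifest["results"]["phenotypic_summary"] = summary
        manifest["results"]["blues"] = blue_set.blues

    if config.stages.scan:
        if sim is None:
            raise FileNotFoundError("scan stage needs the simulate stage")
        if blue_set is None:
            raise FileNotFoundError("scan stage needs the analyze stage")
        manifest["results"]["scan"] = _scan_stage(
            config, sim, blue_set.blues, out, manifest
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {k: v for k, v in manifest.items() if k != "results"},
            fh, indent=2, default=str,
        )
    return manifest


def make_report(manifest: dict) -> str:
    """Human-readable summary of a completed run (idempotent)."""
    lines = [f"pericolor run (seed {manifest['seed']})", "=" * 40]
    res = manifest.get("results", {})
    if "segregation" in res:
        lines += ["", "Segregation analysis", "-" * 20,
                  res["segregation"].to_string(index=False)]
    if "phenotypic_summary" in res:
        s = res["phenotypic_summary"]
        lines += ["", "Phenotypic summary", "-" * 20]
        lines += [f"  heritability (Cullis): {s['heritability']:.3f}",
                  f"  spearman vs rating:    {s['spearman_rho']:.3f}",
                  f"  mean / min / max hue:  {s['mean']:.2f} / "
                  f"{s['min']:.2f} / {s['max']:.2f}"]
    if "scan" in res:
        peaks = res["scan"]["peaks"]
        lines += ["", "QTL peaks", "-" * 20,
                  f"  LOD threshold: {res['scan']['threshold']:.2f}"]
        if len(peaks) == 0:
            lines.append("  no peaks")
        else:
            lines.append(peaks.to_string(index=False))
    return "\n".join(lines) + "\n"
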