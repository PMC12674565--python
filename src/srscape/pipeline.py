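"""End-to-end pipeline orchestration: simulate/load -> extract -> prune ->
select -> fit -> predict -> calibrate -> assess, with on-disk intermediates
and a content-hashed artifact manifest for reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import covariates as cov
from . import forest, grids, provenance, samples, selection, stacking, synthetic

log = logging.getLogger("srscape")


@dataclasses.dataclass
class PipelineConfig:
    output_dir: str = "results/pipeline"
    seed: int = 0
    # synthetic-world stage (used when no external inputs are given)
    simulate: bool = True
    sim: dict = dataclasses.field(default_factory=dict)
    # external inputs (optional)
    sample_table: str | None = None
    covariate_dir: str | None = None
    site_table: str | None = None
    # stage toggles and parameters
    run_select: bool = True
    run_eml: bool = False
    run_calibration: bool = False
    run_assess: bool = True
    prune_threshold: float = 0.9
    max_fallback_km: float = 50.0
    n_trees: int = 3000
    cv_folds: int = 10
    cv_repeats: int = 5
    select_params: dict = dataclasses.field(default_factory=dict)
    calibration_params: dict = dataclasses.field(default_factory=dict)
    radii_km: tuple[float, ...] = provenance.DEFAULT_RADII_KM
    n_assess_sites: int = 12   # synthetic assessment sites when no site table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for attr in ("sample_table", "covariate_dir", "site_table"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if not self.simulate and (self.sample_table is None or self.covariate_dir is None):
            raise ValueError("without simulate, sample_table and covariate_dir are required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the artifact manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def register(path: Path, stage: str) -> None:
        manifest[str(path.relative_to(out))] = {"stage": stage, "sha256": _sha256(path)}

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        log.info("stage simulate: generating synthetic world")
        sim_cfg = synthetic.SimConfig(**{**config.sim, "seed": config.seed})
        world = synthetic.generate_world(sim_cfg)
        stack = dict(world.covariates)
        records = world.samples
        p = samples.write_sample_table(records, out / "samples.csv", include_truth=True)
        register(p, "simulate")
        for name, g in {**stack, "truth": world.truth}.items():
            p = grids.write_raster(g, out / f"cov_{name}.tif")
            register(p, "simulate")
    else:
        log.info("stage load: reading external inputs")
        parsed = samples.read_sample_table(config.sample_table, schema="sm1")
        records = parsed.records
        stack = {}
        for tif in sorted(Path(config.covariate_dir).glob("*.tif")):
            stack[tif.stem] = grids.read_raster(tif)
        world = None

    # --- extract + prune --------------------------------------------------
    log.info("stage extract: %d sites x %d covariates", len(records), len(stack))
    matrix = cov.extract_at_points(stack, records, config.max_fallback_km)
    matrix.frame().assign(sr_ratio=matrix.response).to_csv(out / "covariate_matrix.csv")
    register(out / "covariate_matrix.csv", "extract")

    prune = cov.prune_correlated(matrix.frame(), config.prune_threshold)
    (out / "prune_report.json").write_text(json.dumps(prune.as_dict(), indent=2))
    register(out / "prune_report.json", "prune")
    pruned = matrix.subset(prune.retained)

    # --- select -----------------------------------------------------------
    if config.run_select and len(prune.retained) >= 2:
        log.info("stage select: three-step selection over %d predictors", len(prune.retained))
        sel = selection.select_variables(pruned, seed=config.seed + 1,
                                         **config.select_params)
        chosen = sel.prediction or sel.interpretation or prune.retained
        (out / "selection.json").write_text(json.dumps(sel.as_dict(), indent=2))
        register(out / "selection.json", "select")
    else:
        chosen = prune.retained

    # --- fit + evaluate + predict ----------------------------------------
    log.info("stage fit: forest on %s", chosen)
    model = forest.fit_rf(pruned, chosen, n_trees=config.n_trees, seed=config.seed + 2)
    model.cv_metrics = forest.cross_validate(
        pruned, chosen, k=min(config.cv_folds, len(records)),
        repeats=config.cv_repeats, n_trees=config.n_trees, seed=config.seed + 3)
    metrics = {
        "cv": {k: v for k, v in model.cv_metrics.items() if k != "per_repeat"},
        "per_repeat": model.cv_metrics["per_repeat"],
        "importance": model.importance().to_dict(),
        "covariates": chosen,
    }
    (out / "rf_metrics.json").write_text(json.dumps(metrics, indent=2))
    register(out / "rf_metrics.json", "fit")
    model.importance().rename("importance").to_csv(out / "importance.csv")
    register(out / "importance.csv", "fit")
    for name in chosen:
        pdp = forest.partial_dependence(model, name)
        pdp.to_csv(out / f"pdp_{name}.csv", index=False)
        register(out / f"pdp_{name}.csv", "fit")

    log.info("stage predict: rasterising prediction + SD")
    product = forest.predict_raster(model, stack)
    register(grids.write_raster(product.prediction, out / "isoscape_rf.tif"), "predict")
    register(grids.write_raster(product.sd, out / "isoscape_rf_sd.tif"), "predict")

    if config.run_eml:
        log.info("stage fit-eml: stacked ensemble")
        spec = stacking.StackSpec(seed=config.seed + 4)
        fstack = stacking.fit_stack(pruned.frame()[chosen], pruned.response,
                                    pruned.lon, pruned.lat, spec)
        eml = stacking.predict_raster_stack(fstack, stack)
        register(grids.write_raster(eml.prediction, out / "isoscape_eml.tif"), "fit-eml")
        register(grids.write_raster(eml.sd, out / "isoscape_eml_sd.tif"), "fit-eml")
        (out / "eml_metrics.json").write_text(json.dumps(fstack.cv_metrics, indent=2))
        register(out / "eml_metrics.json", "fit-eml")

    if config.run_calibration:
        log.info("stage calibrate: incremental sampling effort")
        rng = np.random.default_rng(config.seed + 5)
        n = len(matrix.site_ids)
        new_idx = rng.choice(n, size=max(2, n // 2), replace=False)
        base_idx = np.setdiff1d(np.arange(n), new_idx)
        def _sub(idx):
            return cov.CovariateMatrix(
                [matrix.site_ids[i] for i in idx], list(matrix.names),
                matrix.values[idx], matrix.provenance[idx],
                matrix.response[idx], matrix.lon[idx], matrix.lat[idx])
        curve = cal.incremental_calibration(_sub(base_idx), _sub(new_idx),
                                            seed=config.seed + 6,
                                            **config.calibration_params)
        curve.table.to_csv(out / "calibration_curve.csv", index=False)
        register(out / "calibration_curve.csv", "calibrate")

    # --- assess -----------------------------------------------------------
    if config.run_assess:
        log.info("stage assess: buffer-based local/non-local assessment")
        if config.site_table is not None:
            table = samples.read_sample_table(config.site_table, schema="sm2")
        else:
            table = _synthetic_site_table(records, config.n_assess_sites, config.seed + 7)
        assessments = provenance.assess_sites(product, table, config.radii_km)
        provenance.assessment_table(assessments, config.radii_km).to_csv(
            out / "site_assessment.csv", index=False)
        register(out / "site_assessment.csv", "assess")
        detail = {a.site + "/" + a.material + "/" + a.epoch_class: {
            "ranges": {f"{r:g}km": list(v) for r, v in a.ranges.items()},
            "proportions": {f"{r:g}km": a.proportions[r] for r in a.ranges},
            "deviation_category": a.category,
        } for a in assessments}
        (out / "site_assessment.json").write_text(json.dumps(detail, indent=2))
        register(out / "site_assessment.json", "assess")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _synthetic_site_table(records, n_sites: int, seed: int) -> samples.SiteTable:
    """Group a random subset of sample records into an sm2-style site table."""
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(records), size=min(n_sites, len(records)), replace=False)
    from collections import OrderedDict
    sites = OrderedDict()
    for k, i in enumerate(sorted(chosen)):
        r = records[i]
        site = samples.Site(f"site_{k:02d}", r.longitude, r.latitude, "exact")
        site.samples.append(dataclasses_replace(r, id=site.site_id))
        sites[site.site_id] = site
    return samples.SiteTable(sites)


def dataclasses_replace(rec, **kw):
    return dataclasses.replace(rec, **kw)
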