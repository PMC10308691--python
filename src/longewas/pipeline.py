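"""End-to-end orchestration: simulate -> describe -> preprocess -> ewas -> infer.

Every stage writes plain-text artifacts into the run directory and the run
closes with a provenance manifest (stage list, seed, parameter hash,
library versions).  Re-running with the same configuration reproduces
byte-identical association tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, glycemia, inference, io, lmm, preprocess, simcohort
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "describe", "preprocess", "ewas", "infer")


@dataclass
class PipelineConfig:
    """All pipeline parameters with the published defaults where one exists
    (detection 0.05 in >= 5% of samples, alpha 0.05, suggestive 1e-5)."""

    simulation: simcohort.SimulationConfig = field(
        default_factory=simcohort.SimulationConfig
    )
    detection_alpha: float = 0.05
    max_fail_fraction: float = 0.05
    alpha: float = 0.05
    suggestive: float = 1e-5
    dmr_maxgap: int = 500
    dmr_p_candidate: float = 0.05
    exposures: tuple[str, ...] = ("auc", "fasting", "1h", "2h")
    include_linear: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simcohort.SimulationConfig(**raw.pop("simulation", {}))
        try:
            cfg = cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"unknown pipeline option: {exc}") from exc
        cfg.simulation.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposures"] = list(self.exposures)
        return d

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute all stages; returns (and writes) the provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(
            config, simulation=dataclasses.replace(config.simulation, seed=seed)
        )
    manifest: dict = {
        "stages": [],
        "seed": config.simulation.seed,
        "param_hash": config.param_hash(),
        "versions": {
            "longewas": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        sim = simcohort.simulate_study(config.simulation)
        io.write_study(out, sim)

        stage("describe")
        table1 = glycemia.summarize_cohort(sim.subjects)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)

        stage("preprocess")
        prep = preprocess.preprocess_study(
            sim.study,
            sim.panels,
            detection_alpha=config.detection_alpha,
            max_fail_fraction=config.max_fail_fraction,
        )
        prep.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
        for tp, res in prep.residuals.items():
            io.write_residuals(out / f"residuals_{tp}.tsv", res, tp)
        for tp, comp in prep.composition.items():
            comp.proportions.to_csv(out / f"cells_{tp}.tsv", sep="\t", index_label="sample_id")

        stage("ewas")
        annotation = prep.study.cpg_annotation
        tables = lmm.run_all_exposures(
            prep.residuals,
            prep.study.sample_metadata,
            annotation=annotation,
            include_linear=config.include_linear,
            exposures=config.exposures,
        )
        for exposure, models in tables.items():
            for model, table in models.items():
                table.to_csv(out / f"ewas_{exposure}_{model}.tsv", sep="\t", index=False)

        stage("infer")
        primary = tables[config.exposures[0]]["lmm"]
        inflation = inference.genomic_lambda(primary)
        flagged, counts = inference.flag_significance(
            primary, config.alpha, config.suggestive
        )
        flagged.to_csv(out / "ewas_primary_tiers.tsv", sep="\t", index=False)
        stacked = pd.concat(
            [prep.residuals[tp] for tp in ("birth", "5y")], axis=1
        )
        dmrs = inference.find_dmrs(
            primary, stacked, maxgap=config.dmr_maxgap, p_candidate=config.dmr_p_candidate
        )
        dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)
        overlap = inference.overlap_sets(
            {e: tables[e]["lmm"] for e in config.exposures},
            alpha=config.alpha,
            suggestive=config.suggestive,
        )
        overlap.counts().to_csv(out / "overlaps.tsv", sep="\t", index=False)
        inference.export_plots(
            primary, out / "plots", inflation, config.alpha, config.suggestive
        )
        manifest["lambda"] = inflation.lam
        manifest["tier_counts"] = counts
        manifest["n_dmr_candidates"] = int(len(dmrs))
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
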