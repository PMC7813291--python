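"""End-to-end orchestration: validate -> effects -> RoB -> comparisons ->
summaries -> models, as a single reproducible run.

Every run serialises its configuration and an input manifest (SHA-256 of
each table) into the output directory, logs per-stage timings and exclusion
counts, and writes deterministic CSV/Markdown reports, so two runs with the
same inputs and seed produce identical artefacts.  A stage failure aborts
the run with a stage-named message and leaves partial outputs under a
``FAILED`` marker file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import (
    attribute_model,
    comparison_builder,
    effect_engine,
    rob_scoring,
    summarizer,
    synthetic_data,
)
from .study_db import SCHEMA, StudyDatabase, load_database, save_database

logger = logging.getLogger("hcpmeta")

STAGES = ("validate", "effects", "rob", "comparisons", "summaries", "models")


@dataclass
class RunConfig:
    """Self-describing settings of one pipeline run."""

    input_dir: Optional[str] = None  # None => simulate
    output_dir: str = "hcpmeta_run"
    seed: int = 0
    simulate: bool = False
    n_studies: int = 150
    stages: tuple[str, ...] = STAGES
    quantile_convention: str = "linear"  # numpy default (R type 7)
    ceiling_rule: str = "intervention"  # or "either"
    tiers: tuple[str, ...] = attribute_model.TIERS
    model_covariates: tuple[str, ...] = ("onsite", "clinical_practice")

    def validate(self) -> "RunConfig":
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        bad = set(self.tiers) - set(attribute_model.TIERS)
        if bad:
            raise ValueError(f"unknown tiers: {sorted(bad)}")
        if self.ceiling_rule not in ("intervention", "either"):
            raise ValueError(f"unknown ceiling rule {self.ceiling_rule!r}")
        if self.quantile_convention != "linear":
            raise ValueError("only the linear (type 7) quantile convention is implemented")
        if self.input_dir is None and not self.simulate:
            raise ValueError("either input_dir or simulate must be given")
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, input_dir: Path) -> None:
    manifest = {
        f"{name}.csv": _sha256(input_dir / f"{name}.csv")
        for name in SCHEMA
        if (input_dir / f"{name}.csv").exists()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of result tables.

    Deterministic given the seed; exits only through an exception if any
    validation fails.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True)
    )
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    results: dict = {}
    stage = "setup"
    t_start = time.perf_counter()
    try:
        if config.simulate:
            stage = "simulate"
            gen = synthetic_data.GeneratorConfig(
                n_studies=config.n_studies, seed=config.seed
            )
            db, truth = synthetic_data.generate_database(gen)
            input_dir = out / "simulated_db"
            save_database(db, input_dir)
            truth.save(out / "ground_truth.json")
        else:
            stage = "validate"
            input_dir = Path(config.input_dir)
            db = load_database(input_dir, validate="validate" in config.stages)
        _write_manifest(out, input_dir)
        results["db"] = db

        stage = "comparisons"
        comparisons = comparison_builder.build_all_comparisons(db)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        results["comparisons"] = comparisons

        stage = "rob"
        rob = rob_scoring.score_database(db)
        rob.to_csv(out / "risk_of_bias.csv", index=False)
        results["rob"] = rob

        stage = "effects"
        effects = effect_engine.compute_effects(db, comparisons,
                                                ceiling_rule=config.ceiling_rule)
        effects.to_csv(out / "effect_sizes.csv", index=False)
        results["effects"] = effects
        excl = effects[effects["status"] != "included"]
        logger.info("exclusions by rule: %s",
                    excl.groupby("status").size().to_dict() if len(excl) else {})

        if "summaries" in config.stages:
            stage = "summaries"
            mes = summarizer.collapse_mes(effects, comparisons, db.studies, rob)
            mes.to_csv(out / "mes.csv", index=False)
            strata = summarizer.summarize_strata(mes)
            strata.to_csv(out / "strata_summary.csv", index=False)
            rob_split = summarizer.rob_sensitivity(mes)
            rob_split.to_csv(out / "rob_sensitivity.csv", index=False)
            costs = summarizer.cost_summary(db, strata=("country_income",))
            costs.to_csv(out / "cost_summary.csv", index=False)
            _write_markdown_summary(out, strata, costs)
            results.update(mes=mes, strata=strata, rob_split=rob_split, costs=costs)

        if "models" in config.stages:
            stage = "models"
            fits = {}
            coef_rows = []
            for tier in config.tiers:
                table = attribute_model.build_model_database(
                    db, effects, comparisons, tier=tier
                )
                spec = attribute_model.ModelSpec(
                    tier=tier, covariates=config.model_covariates
                )
                fit = attribute_model.fit_random_effects(table, spec)
                fits[tier] = fit
                frame = fit.to_frame().reset_index(names="term")
                frame.insert(0, "tier", tier)
                frame["adjusted_r2"] = fit.adjusted_r2
                frame["n_studies"] = fit.n_studies
                frame["n_effect_sizes"] = fit.n_effect_sizes
                coef_rows.append(frame)
            coefs = pd.concat(coef_rows, ignore_index=True)
            coefs.to_csv(out / "model_coefficients.csv", index=False)
            results["fits"] = fits
            results["model_coefficients"] = coefs
    except Exception:
        failed_marker.write_text(f"failed during stage: {stage}\n")
        logger.exception("pipeline failed during stage %s", stage)
        raise
    finally:
        logger.info("pipeline finished in %.2f s (last stage: %s)",
                    time.perf_counter() - t_start, stage)
    return results


def _write_markdown_summary(out: Path, strata: pd.DataFrame, costs: pd.DataFrame) -> None:
    lines = ["# Strategy effectiveness summary", "",
             "Median MES (%-points) by stratum; IQR suppressed for n < 3.", ""]
    lines.append(strata.to_markdown(index=False))
    lines += ["", "## Cost per HCP per day of training (USD)", "",
              costs.to_markdown(index=False), ""]
    (out / "summary.md").write_text("\n".join(lines))
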