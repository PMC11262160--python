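"""End-to-end pipeline: survey -> usual intake -> salt -> fortification ->
adequacy (-> rate optimisation), with every intermediate persisted as CSV,
a sidecar schema JSON, and a provenance record (config hash, seed,
versions).  Re-running any stage from its persisted inputs reproduces its
persisted outputs; a fixed seed makes the machine-readable outputs
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .adequacy import render, summarize
from .fortify import FortificationSpec, apply_fortification, baseline_rows
from .optimize import DEFAULT_GRIDS, optimize_rate
from .recall import compute_day_intake
from .reference import FORTIFICANT_RATES, NutrientReferences
from .salt import SaltScenarioParams, build_scenario
from .synthetic import PopulationConfig, default_config, generate_population, \
    split_ground_truth
from .usual import estimate_population_usual

log = logging.getLogger(__name__)

#: units for the sidecar schema
COLUMN_UNITS = {
    "energy_kcal_d": "kcal/d",
    "total_salt_g_d": "g/d",
    "discretionary_salt_g_d": "g/d",
    "zinc_mg_d": "mg/d",
    "folate_ug_dfe_d": "ug DFE/d",
    "usual_intake": "mg/d (zinc) or ug DFE/d (folate)",
    "baseline_usual": "mg/d (zinc) or ug DFE/d (folate)",
    "delivered": "mg/d (zinc) or ug DFE/d (folate; folic acid as DFE)",
    "fortified_usual": "mg/d (zinc) or ug DFE/d (folate)",
    "median_intake": "mg/d (zinc) or ug DFE/d (folate)",
}


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``synthetic`` (a :class:`PopulationConfig`) or
    ``survey_path`` must be set.  ``specs`` maps scenario name ->
    :class:`FortificationSpec`; by default the two reference designs.
    """

    output_dir: str = "results"
    synthetic: PopulationConfig | None = None
    survey_path: str | None = None
    recall_path: str | None = None
    fct_path: str | None = None
    ear_ul_path: str | None = None
    variance_path: str | None = None
    fct_mode: str = "strict"
    salt_params: SaltScenarioParams = field(default_factory=SaltScenarioParams)
    specs: dict = field(
        default_factory=lambda: {
            name: FortificationSpec(
                zinc_mg_per_g=r["zinc_mg_per_g"],
                folic_acid_ug_per_g=r["folic_acid_ug_per_g"],
            )
            for name, r in FORTIFICANT_RATES.items()
        }
    )
    strata: tuple = ("region", "life_stage")
    min_stratum_n: int = 30
    optimize: bool = False
    optimize_scenario: str = "recommended"
    rate_grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    excess_threshold: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.survey_path is None):
            raise ValueError(
                "exactly one of synthetic config or survey_path must be set"
            )
        unknown = set(self.specs) - {"calculated", "recommended"}
        if unknown:
            raise ValueError(f"unknown scenario names: {sorted(unknown)}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    schema = {
        "columns": [
            {
                "name": c,
                "dtype": str(df[c].dtype),
                "units": COLUMN_UNITS.get(c, ""),
            }
            for c in df.columns
        ]
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the in-memory report bundle.

    Writes under ``config.output_dir``: survey.csv (+ground_truth.csv when
    synthetic), usual_intake.csv, usual_models.json, salt_scenarios.csv,
    fortified_intake.csv, adequacy_full.csv, adequacy_rendered.csv,
    optimization_*.csv (optional), provenance.json, run.log.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("saltfort")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    references = NutrientReferences.from_files(
        config.ear_ul_path, config.variance_path
    )

    # --- stage 1: survey --------------------------------------------------
    if config.synthetic is not None:
        pop = dataclasses.replace(config.synthetic, seed=config.seed)
        survey, truth = split_ground_truth(generate_population(pop))
        _write_csv(truth, outdir / "ground_truth.csv")
    else:
        survey = pd.read_csv(config.survey_path)
        if config.recall_path is not None:
            items = pd.read_csv(config.recall_path)
            fct = pd.read_csv(config.fct_path)
            intakes = compute_day_intake(
                items, fct, mode=config.fct_mode,
                participant_ids=survey["participant_id"],
            )
            survey = survey.drop(
                columns=[c for c in intakes.columns if c != "participant_id"],
                errors="ignore",
            ).merge(intakes, on="participant_id", validate="one_to_one")
    _write_csv(survey, outdir / "survey.csv")
    log.info("survey: %d participants", len(survey))

    # --- stage 2: usual intake -------------------------------------------
    usual_long, models = estimate_population_usual(
        survey, references, min_n=config.min_stratum_n
    )
    _write_csv(usual_long, outdir / "usual_intake.csv")
    (outdir / "usual_models.json").write_text(
        json.dumps({f"{k[0]}|{k[1]}": m.to_dict() for k, m in models.items()},
                   indent=1, sort_keys=True) + "\n"
    )

    # --- stage 3: salt scenarios -----------------------------------------
    scenarios = {
        name: build_scenario(survey, name, config.salt_params)
        for name in config.specs
    }
    _write_csv(
        pd.concat([s.salt for s in scenarios.values()], ignore_index=True),
        outdir / "salt_scenarios.csv",
    )

    # --- stage 4: fortification ------------------------------------------
    fortified = pd.concat(
        [baseline_rows(usual_long)]
        + [
            apply_fortification(usual_long, scenarios[name], spec)
            for name, spec in config.specs.items()
        ],
        ignore_index=True,
    )
    _write_csv(fortified, outdir / "fortified_intake.csv")

    # --- stage 5: adequacy -----------------------------------------------
    report = summarize(fortified, survey, references, by=list(config.strata))
    _write_csv(report, outdir / "adequacy_full.csv")
    _write_csv(render(report), outdir / "adequacy_rendered.csv")

    # --- stage 6: optimisation (optional) --------------------------------
    results = {
        "survey": survey, "usual": usual_long, "models": models,
        "scenarios": scenarios, "fortified": fortified, "report": report,
    }
    if config.optimize:
        scenario = scenarios[config.optimize_scenario]
        opts = {}
        for nutrient, grid in config.rate_grids.items():
            res = optimize_rate(
                usual_long, survey, scenario, nutrient, grid, references,
                excess_threshold=config.excess_threshold,
                strata=config.strata,
            )
            opts[nutrient] = res
            _write_csv(res.grid_trace, outdir / f"optimization_{nutrient}.csv")
            log.info(
                "optimize %s: rate=%s objective=%.2f max_excess=%.2f feasible=%s",
                nutrient, res.chosen_rate, res.objective,
                res.constraint_margin, res.feasible,
            )
        results["optimization"] = opts

    # --- provenance -------------------------------------------------------
    cfg_json = json.dumps(_config_dict(config), sort_keys=True, default=str)
    provenance = {
        "saltfort_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "pandas_version": pd.__version__,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1) + "\n")
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["rate_grids"] = {k: [float(x) for x in v] for k, v in d["rate_grids"].items()}
    return d


def default_run_config(seed: int = 0, output_dir: str = "results",
                       optimize: bool = False) -> RunConfig:
    """Synthetic default study conditions, both reference scenarios."""
    return RunConfig(
        output_dir=output_dir,
        synthetic=default_config(seed=seed),
        optimize=optimize,
        seed=seed,
    )
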