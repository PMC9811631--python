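"""End-to-end orchestration: simulate or load, validate, fit, report.

A single :class:`RunConfig` (YAML-loadable) drives the whole analysis so
that a simulate-then-recover experiment is one call.  All randomness flows
from one seed through named substreams; the same config and seed reproduce
byte-identical machine-readable outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .deviation import DeviationModelResult, deviation_table, fit_deviation_model, records_frame
from .discrimination import DiscriminationReport, discrimination_report
from .sge import TRAITS, TraitAnalysis, analyze_trait, default_spec, variance_table
from .simulate import NoduleVariances, ShootVariances, SimulationConfig, simulate_experiment
from .tables import ExperimentData, read_tables, validate, write_tables

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs (exactly one of simulation / table paths), toggles and outputs."""

    seed: int = 0
    out_dir: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    plants_path: Optional[str] = None
    nodules_path: Optional[str] = None
    cfu_path: Optional[str] = None
    schema: Optional[Mapping] = None
    traits: tuple[str, ...] = TRAITS
    run_discrimination: bool = True
    run_deviation: bool = True
    deviation_fitness: str = "shoot_mass"

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.plants_path is not None
        if has_sim == has_paths:
            raise ValueError("give exactly one of a simulation config or input paths")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown trait(s) {sorted(unknown)}")

    @staticmethod
    def from_dict(raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            if "nodule_var" in sim:
                sim["nodule_var"] = NoduleVariances(**sim["nodule_var"])
            if "shoot_var" in sim:
                sim["shoot_var"] = ShootVariances(**sim["shoot_var"])
            if "strain_quality" in sim and sim["strain_quality"] is not None:
                sim["strain_quality"] = tuple(sim["strain_quality"])
            sim = SimulationConfig(**sim)
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return RunConfig(simulation=sim, **raw)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """Everything one run computed, plus provenance."""

    provenance: dict
    variance_partition: Optional[pd.DataFrame] = None
    trait_analyses: dict[str, TraitAnalysis] = field(default_factory=dict)
    discrimination: Optional[DiscriminationReport] = None
    deviation_model: Optional[DeviationModelResult] = None
    deviation_records: Optional[pd.DataFrame] = None
    excluded: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        out: dict[str, Any] = {"provenance": self.provenance, "notes": self.notes,
                               "excluded": self.excluded}
        if self.variance_partition is not None:
            out["variance_partition"] = json.loads(
                self.variance_partition.to_json(orient="records", double_precision=10))
        if self.discrimination is not None:
            out["discrimination"] = {
                name: dataclasses.asdict(res)
                for name, res in self.discrimination.results.items()
            }
        if self.deviation_model is not None:
            dm = self.deviation_model
            out["deviation_model"] = {
                "slope": dm.slope, "intercept": dm.intercept, "n": dm.n,
                "chi2": dm.lrt.chi2, "df": dm.lrt.df, "p_value": dm.lrt.p_value,
            }
        return out

    def text_report(self) -> str:
        lines = [
            "co-inoculation discrimination analysis",
            f"  package rhizosge {self.provenance['version']}, "
            f"seed {self.provenance['seed']}, source {self.provenance['source']}",
            "",
        ]
        if self.variance_partition is not None:
            lines.append("variance partition (percent of phenotypic variance; LRT chi2, p):")
            lines.append(self.variance_partition.round(3).to_string(index=False))
            lines.append("")
        if self.discrimination is not None:
            lines.append("genotypic-mean regressions:")
            lines.append(self.discrimination.frame().round(4).to_string(index=False))
            lines.append("")
        else:
            lines.append("genotypic-mean regressions: not computed")
        if self.deviation_model is not None:
            dm = self.deviation_model
            lines.append(
                "deviation from neutral expectation ~ occupancy of the better strain: "
                f"slope {dm.slope:.4f}, chi2(1) = {dm.lrt.chi2:.2f}, p = {dm.lrt.p_value:.4g} "
                f"(n = {dm.n} pots)"
            )
        else:
            lines.append("deviation model: not computed")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def _load(config: RunConfig) -> tuple[ExperimentData, str]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        ds = simulate_experiment(sim)
        return ds.data, f"simulation(seed={sim.seed})"
    data = read_tables(config.plants_path, config.nodules_path, config.cfu_path,
                       schema=config.schema)
    return data, str(config.plants_path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute validate -> variance partition -> regressions -> deviation model."""
    stage = "load"
    try:
        data, source = _load(config)
        stage = "validate"
        validate(data)
        report = RunReport(provenance={
            "version": __version__, "seed": config.seed, "source": source,
        })

        stage = "variance_partition"
        analyses: dict[str, TraitAnalysis] = {}
        for trait in config.traits:
            analyses[trait] = analyze_trait(data, default_spec(trait))
            if analyses[trait].n_excluded:
                report.excluded[trait] = analyses[trait].n_excluded
        if analyses:
            report.trait_analyses = analyses
            report.variance_partition = variance_table(analyses)

        stage = "discrimination"
        if config.run_discrimination:
            report.discrimination = discrimination_report(data)
            if not data.cfus:
                report.notes.append("sanctions regressions not computed (no CFU table)")

        stage = "deviation"
        if config.run_deviation:
            records = deviation_table(data, fitness=config.deviation_fitness)
            report.deviation_records = records_frame(records)
            report.deviation_model = fit_deviation_model(records)

        stage = "write"
        if config.out_dir is not None:
            _write_outputs(config, data, report)
        return report
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_outputs(config: RunConfig, data: ExperimentData, report: RunReport) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        write_tables(data, out / "tables")
    if report.variance_partition is not None:
        report.variance_partition.to_csv(out / "variance_partition.csv", index=False)
    if report.discrimination is not None:
        report.discrimination.frame().to_csv(out / "regressions.csv", index=False)
    if report.deviation_records is not None:
        report.deviation_records.to_csv(out / "deviation_records.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
    (out / "report.txt").write_text(report.text_report())
    logger.info("outputs written to %s", out)
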