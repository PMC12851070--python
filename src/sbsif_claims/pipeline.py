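"""End-to-end run orchestration: generate -> cohort -> project -> characterize.

A :class:`RunConfig` (built in code or loaded from YAML) names the input
tables, code-set registry, census table, definitions, years, and the
handful of analytic mode flags.  :func:`run_pipeline` validates the config
up front (fail-fast, before any computation), executes every requested
stage, writes delimited artifacts plus a plain-text summary, and records
every flag in effect in ``run.log`` so a run is reproducible from its
artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characterization import (
    demographics_table,
    grouped_condition_table,
    medication_class_table,
    nutrition_combination_table,
)
from .cohort_engine import (
    ContinuousWindow,
    build_cohort,
    get_definition,
)
from .data_model import ClaimsDatabase, CodeSetRegistry, read_claims_database
from .projection import (
    compute_stratum_rates,
    growth_metrics,
    project_to_population,
    read_census,
)
from .synthetic import (
    CONDITION_GROUP_CODES,
    MEDICATION_CLASS_CODES,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(ValueError):
    """Configuration or stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    claims_path: str
    enrollment_path: str
    demographics_path: str
    registry_path: str
    output_dir: str
    definitions: list[str] = field(default_factory=lambda: ["primary"])
    years: list[int] = field(default_factory=lambda: [2019, 2020, 2021])
    census_path: str | None = None
    seed: int = 0
    project: bool = True
    characterize: bool = True
    condition_groups: list[str] | None = None
    medication_classes: list[str] | None = None
    # analytic mode flags (paper-gap decisions, all overridable)
    grace_days: int = 0
    continuous_window: str = "calendar_year"
    chronic_gap_days: int = 183
    allow_same_day_before: bool = False
    assessment_window_days: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def validate(self) -> None:
        for stage, p in (
            ("claims", self.claims_path),
            ("enrollment", self.enrollment_path),
            ("demographics", self.demographics_path),
            ("registry", self.registry_path),
        ):
            if not Path(p).exists():
                raise PipelineError(f"[config] {stage} file not found: {p}")
        if self.project:
            if self.census_path is None:
                raise PipelineError(
                    "[config] projection requested but no census_path given"
                )
            if not Path(self.census_path).exists():
                raise PipelineError(
                    f"[config] census file not found: {self.census_path}"
                )
        for name in self.definitions:
            get_definition(name)  # raises for unknown names
        if self.grace_days < 0:
            raise PipelineError("[config] grace_days must be >= 0")
        ContinuousWindow(self.continuous_window)


def _definition_for(config: RunConfig, name: str):
    return get_definition(name).with_options(
        continuous_window=ContinuousWindow(config.continuous_window),
        chronic_gap_days=config.chronic_gap_days,
        allow_same_day_before=config.allow_same_day_before,
    )


def _write_members(members, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "index_date": m.index_date.isoformat(),
                "definition": m.definition_name,
                "age_at_index": m.age_at_index,
                "age_at_year_start": m.age_at_year_start,
                "gender": m.gender.value,
            }
            for m in members
        ],
        columns=[
            "patient_id",
            "index_date",
            "definition",
            "age_at_index",
            "age_at_year_start",
            "gender",
        ],
    ).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute cohort construction and downstream stages; return artifact paths."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = [f"sbsif-claims {__version__}"]
    log_lines.append(f"config: {vars(config)}")

    try:
        db: ClaimsDatabase = read_claims_database(
            config.claims_path, config.enrollment_path, config.demographics_path
        )
        registry = CodeSetRegistry.from_yaml(config.registry_path)
    except Exception as exc:
        raise PipelineError(f"[read] {exc}") from exc
    log_lines.append(
        f"inputs: {db.n_patients} patients, {len(db.claims)} claims, "
        f"{len(db.enrollment)} enrollment spans"
    )

    census = None
    if config.project:
        census = read_census(config.census_path)

    summary: list[str] = []
    for name in config.definitions:
        definition = _definition_for(config, name)
        log_lines.append(f"definition {name}: {definition}")
        cohorts = {}
        for year in config.years:
            try:
                members, waterfall = build_cohort(
                    db, registry, definition, year, grace_days=config.grace_days
                )
            except Exception as exc:
                raise PipelineError(f"[cohort {name}/{year}] {exc}") from exc
            cohorts[year] = members
            mpath = out / f"members_{name}_{year}.csv"
            _write_members(members, mpath)
            artifacts[f"members_{name}_{year}"] = mpath
            wpath = out / f"waterfall_{name}_{year}.csv"
            pd.DataFrame(waterfall.to_records()).to_csv(wpath, index=False)
            artifacts[f"waterfall_{name}_{year}"] = wpath
            summary.append(f"{name} {year}: cohort size {len(members)}")

        if config.project:
            totals = {}
            rows = []
            for year, members in cohorts.items():
                try:
                    rates = compute_stratum_rates(
                        members, db, year, grace_days=config.grace_days
                    )
                    result = project_to_population(rates, census, year)
                except Exception as exc:
                    raise PipelineError(f"[project {name}/{year}] {exc}") from exc
                totals[year] = result.total
                rows.append(
                    {
                        "year": year,
                        "cohort_size": len(members),
                        "projected_total": result.total,
                        "projected_total_unrounded": round(result.total_unrounded, 2),
                        "census_total": result.census_total,
                        "per_million": result.per_million,
                    }
                )
                summary.append(
                    f"{name} {year}: projected {result.total} "
                    f"({result.per_million}/million)"
                )
            ppath = out / f"projection_{name}.csv"
            pd.DataFrame(rows).to_csv(ppath, index=False)
            artifacts[f"projection_{name}"] = ppath
            if len(totals) >= 2 and min(totals.values()) > 0:
                growth = growth_metrics(totals)
                summary.append(
                    f"{name}: overall growth {growth.overall_pct}% "
                    f"({min(totals)}-{max(totals)}); year-on-year "
                    + ", ".join(
                        f"{y}: {p}%" for y, p in sorted(growth.year_on_year_pct.items())
                    )
                )

        if config.characterize:
            year = max(config.years)
            members = cohorts[year]
            if members:
                tables = [
                    demographics_table(members),
                    nutrition_combination_table(
                        members, db, registry, config.assessment_window_days
                    ),
                ]
                groups = config.condition_groups or [
                    k for k in CONDITION_GROUP_CODES if k in registry
                ]
                if groups:
                    tables.append(
                        grouped_condition_table(
                            members, db, registry, config.assessment_window_days,
                            row_order=groups,
                        )
                    )
                classes = config.medication_classes or [
                    k for k in MEDICATION_CLASS_CODES if k in registry
                ]
                if classes:
                    tables.append(
                        medication_class_table(
                            members, db, registry, config.assessment_window_days,
                            row_order=classes,
                        )
                    )
                for table in tables:
                    tpath = out / f"{table.table_name}_{name}_{year}.csv"
                    table.to_csv(tpath)
                    artifacts[f"{table.table_name}_{name}_{year}"] = tpath
                    summary.append("")
                    summary.append(str(table))

    spath = out / "summary.txt"
    spath.write_text("\n".join(summary) + "\n")
    artifacts["summary"] = spath
    lpath = out / "run.log"
    lpath.write_text("\n".join(log_lines) + "\n")
    artifacts["run_log"] = lpath
    return artifacts
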