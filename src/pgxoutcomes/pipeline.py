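"""Configuration-driven orchestration of the full analysis.

Stages: annotate diplotypes -> read and classify records -> derive
outcomes -> fit association models -> export summary, results and forest
tables, plus a run log with all exclusion counts and the effective
configuration (defaults included).  Every stage is also callable directly;
the pipeline adds nothing beyond composition and bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import association, records
from .alleles import AlleleFunctionTable, annotate_cohort
from .outcomes import OutcomeParams, build_outcome_table, build_timelines, write_outcome_table
from .records import CodeList, dedupe, read_clinical_events, read_prescriptions

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table convention."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentages(
    counts: dict[str, int], total: int | None = None, ndigits: int = 1
) -> dict[str, float]:
    """100 x count / total, rounded half-up; empty input gives empty output.

    ``total`` defaults to the sum of the counts; pass the column total
    explicitly when categories do not exhaust it.
    """
    total = sum(counts.values()) if total is None else total
    if total == 0:
        return {}
    return {k: round_half_up(100.0 * v / total, ndigits) for k, v in counts.items()}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown YAML keys are rejected."""

    diplotypes: str = "diplotypes.csv"
    prescriptions: str = "prescriptions.csv"
    events: str = "events.csv"
    covariates: str = "covariates.csv"
    allele_table: str | None = None
    drug_codes: str | None = None
    uku_codes: str | None = None
    date_dialect: str = "auto"
    outcome_params: dict = field(default_factory=dict)
    predictor_modes: tuple = ("phenotype_categorical", "activity_score")
    covariate_set: tuple = association.DEFAULT_COVARIATES
    subgroup: str = "all"
    output_dir: str = "pgx_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        op = raw.get("outcome_params", {})
        op_known = {f.name for f in dataclasses.fields(OutcomeParams)}
        bad = set(op) - op_known
        if bad:
            raise ValueError(f"unknown outcome_params keys: {sorted(bad)}")
        for key in ("predictor_modes", "covariate_set"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_params"] = dataclasses.asdict(self.build_outcome_params())
        return d

    def build_outcome_params(self) -> OutcomeParams:
        op = dict(self.outcome_params)
        if "switch_tolerances" in op:
            op["switch_tolerances"] = {int(k): v for k, v in op["switch_tolerances"].items()}
        for key in ("switch_windows", "side_effect_windows"):
            if key in op:
                op[key] = tuple(op[key])
        return OutcomeParams(**op)


def read_covariates(path: str | Path, date_dialect: str = "auto") -> pd.DataFrame:
    """Covariate/registration table: ``eid, sex, year_of_birth, batch,
    broad_depression, record_start, record_end``."""
    df = pd.read_csv(path, dtype={"eid": str})
    missing = {"eid", "sex", "year_of_birth", "batch"} - set(df.columns)
    if missing:
        raise records.SchemaError(f"covariate file {path} missing columns {sorted(missing)}")
    df = df.rename(columns={"eid": "person_id"})
    for col in ("record_start", "record_end"):
        if col in df.columns:
            df[col] = records._parse_dates(df[col].astype(str), date_dialect)
    return df


def summarize_cohort(
    outcome_table: pd.DataFrame, ndigits: int = 1
) -> pd.DataFrame:
    """Study-demographics summary: per-SSRI and total columns.

    Rows: N and percentage per metaboliser phenotype, total N, mean and SD
    of age at first prescription, percent female.  A person prescribed two
    SSRIs contributes to both columns, so the total column is smaller than
    the column sum.  Percentages use half-up rounding at one decimal.
    """
    if outcome_table.empty:
        return pd.DataFrame()
    blocks = {}
    groups = {ssri: df for ssri, df in outcome_table.groupby("ssri")}
    groups["total"] = outcome_table.drop_duplicates("person_id")
    for name, df in groups.items():
        persons = df.drop_duplicates("person_id")
        counts = persons["phenotype"].value_counts().to_dict()
        pct = percentages(counts, total=len(persons), ndigits=ndigits)
        block = {}
        for ph in ("poor", "intermediate", "normal", "fast"):
            block[f"{ph}_n"] = int(counts.get(ph, 0))
            block[f"{ph}_pct"] = pct.get(ph, 0.0)
        block["n"] = len(persons)
        block["age_mean"] = round_half_up(persons["age_at_first_rx"].mean(), ndigits)
        block["age_sd"] = round_half_up(persons["age_at_first_rx"].std(), ndigits)
        if "sex" in persons.columns:
            block["female_pct"] = round_half_up(
                100.0 * persons["sex"].mean(), ndigits
            )
        blocks[name] = block
    return pd.DataFrame(blocks)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the artefact directory.

    Artefacts: ``summary.csv``, ``outcomes.csv``, ``results.csv``,
    ``forest_<ssri>.csv`` and ``run_log.json``.  Any stage failure raises
    with the stage name attached.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}, "effective_config": cfg.effective()}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        log["stages"][name] = "ok"
        return name

    try:
        stage("annotate")
        table = (
            AlleleFunctionTable.from_csv(cfg.allele_table)
            if cfg.allele_table
            else AlleleFunctionTable.default()
        )
        diplo = pd.read_csv(cfg.diplotypes, dtype=str)
        annotated = annotate_cohort(diplo, table)
        log["n_persons_genotyped"] = int(len(annotated))
        log["n_phenotype_excluded"] = int((~annotated["included"]).sum())
        log["phenotype_counts"] = annotated["phenotype"].value_counts().to_dict()

        stage("read")
        drug_codes = (
            CodeList.from_csv(cfg.drug_codes) if cfg.drug_codes else records.default_drug_codes()
        )
        uku = CodeList.from_csv(cfg.uku_codes) if cfg.uku_codes else records.default_uku_codes()
        rx = read_prescriptions(cfg.prescriptions, cfg.date_dialect, drug_codes)
        ev = read_clinical_events(cfg.events, cfg.date_dialect, uku)
        cov = read_covariates(cfg.covariates, cfg.date_dialect)
        log["n_prescriptions"] = int(len(rx))
        log["n_dropped_rx_dates"] = int(rx.attrs.get("n_dropped_dates", 0))
        log["n_events"] = int(len(ev))
        rx = dedupe(rx)
        log["n_prescriptions_deduped"] = int(len(rx))

        stage("derive")
        params = cfg.build_outcome_params()
        timelines = build_timelines(rx, ev, cov)
        outcome_table = build_outcome_table(timelines, cov, annotated, params)
        log["n_outcome_rows"] = int(len(outcome_table))
        log["n_missing_covariates"] = int(outcome_table.attrs.get("n_missing_covariates", 0))
        log["n_excluded_phenotype_at_derive"] = int(
            outcome_table.attrs.get("n_excluded_phenotype", 0)
        )
        write_outcome_table(outcome_table, outdir / "outcomes.csv")

        summary = summarize_cohort(outcome_table)
        summary.to_csv(outdir / "summary.csv")

        stage("fit")
        results = association.run_all(
            outcome_table,
            predictor_modes=cfg.predictor_modes,
            covariates=cfg.covariate_set,
            subgroup=cfg.subgroup,
        )
        results.to_csv(outdir / "results.csv", index=False)

        stage("export")
        for ssri, sub in results.groupby("ssri"):
            association.export_forest(sub, outdir / f"forest_{ssri}.csv")
    except Exception as exc:
        failed = [s for s in log["stages"]][-1] if log["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return outdir
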