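"""Reading, validating and drug-classifying primary-care record tables.

Two table dialects are supported, mirroring the UK primary-care extract
layout: a prescription table (``eid, data_provider, issue_date, read_2,
bnf_code, dmd_code, drug_name, quantity``) and a clinical-event table
(``eid, data_provider, event_dt, read_2, read_3``).  Dates may be day-first
("dd/mm/yyyy", the UK convention) or ISO 8601; the "auto" dialect tries
both with day-first priority.  Sentinel placeholder dates (years <= 1901,
or dates in the future) are dropped and counted rather than raised.

Drug classification is driven by code lists (``system, code, label`` CSV
with an optional ``pattern`` column of case-insensitive name regexes) and
resolves each prescription to one of::

    ssri_citalopram, ssri_escitalopram, ssri_sertraline,
    other_antidepressant, antipsychotic, other

with precedence dm+d > BNF > read v2 > name pattern > other.  The shipped
side-effect code list (``uku_side_effect_codes_synthetic.csv``) is a small
synthetic stand-in representative of UKU-SERS-derived clinical codes; the
pipeline treats any such list purely as data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DRUG_CLASSES = (
    "ssri_citalopram",
    "ssri_escitalopram",
    "ssri_sertraline",
    "other_antidepressant",
    "antipsychotic",
    "other",
)

SSRI_CLASSES = ("ssri_citalopram", "ssri_escitalopram", "ssri_sertraline")
ANTIDEPRESSANT_CLASSES = SSRI_CLASSES + ("other_antidepressant",)

PRESCRIPTION_COLUMNS = [
    "eid",
    "data_provider",
    "issue_date",
    "read_2",
    "bnf_code",
    "dmd_code",
    "drug_name",
    "quantity",
]
EVENT_COLUMNS = ["eid", "data_provider", "event_dt", "read_2", "read_3"]

MIN_YEAR = 1902  # years <= 1901 and >= 2037 are UK-Biobank-style placeholders
MAX_DATE = pd.Timestamp("2036-12-31")


class SchemaError(ValueError):
    """Raised when a mandatory column is missing from an input table."""


@dataclass
class CodeList:
    """A named set of (coding system, code) entries plus name-regex patterns.

    ``entries`` maps coding system ("read2", "ctv3", "bnf", "bnf_prefix",
    "dmd") to {code: label}; ``patterns`` is a list of (compiled regex,
    label) applied case-insensitively to free-text drug names.
    """

    name: str
    entries: dict[str, dict[str, str]] = field(default_factory=dict)
    patterns: list[tuple[re.Pattern, str]] = field(default_factory=list)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "CodeList":
        df = pd.read_csv(path, dtype=str).fillna("")
        missing = {"system", "code", "label"} - set(df.columns)
        if missing:
            raise SchemaError(f"code list {path} missing columns {sorted(missing)}")
        cl = cls(name=name or Path(path).stem)
        seen = set()
        for _, row in df.iterrows():
            system = row["system"].strip().lower()
            code = row["code"].strip()
            label = row["label"].strip()
            pattern = row.get("pattern", "").strip() if "pattern" in df.columns else ""
            if system == "name" or (pattern and not code):
                cl.patterns.append((re.compile(pattern, re.IGNORECASE), label))
                continue
            key = (system, code)
            if key in seen:
                raise ValueError(f"duplicate code-list entry {key} in {path}")
            seen.add(key)
            cl.entries.setdefault(system, {})[code] = label
        return cl

    def match_code(self, system: str, code: str) -> str | None:
        if not code:
            return None
        label = self.entries.get(system, {}).get(code)
        if label is not None:
            return label
        if system == "bnf":
            for prefix, lab in self.entries.get("bnf_prefix", {}).items():
                if code.startswith(prefix):
                    return lab
        return None

    def match_name(self, name: str) -> str | None:
        if not name:
            return None
        for pattern, label in self.patterns:
            if pattern.search(name):
                return label
        return None

    def codes(self, system: str) -> set[str]:
        return set(self.entries.get(system, {}))


def default_drug_codes() -> CodeList:
    with resources.as_file(resources.files("pgxoutcomes.data") / "drug_codes.csv") as p:
        return CodeList.from_csv(p, name="drug_codes")


def default_uku_codes() -> CodeList:
    """Synthetic stand-in for the UKU-SERS-derived clinical-code list."""
    with resources.as_file(
        resources.files("pgxoutcomes.data") / "uku_side_effect_codes_synthetic.csv"
    ) as p:
        return CodeList.from_csv(p, name="uku_side_effects")


def _parse_dates(raw: pd.Series, dialect: str = "auto") -> pd.Series:
    """Parse a date column under the given dialect.

    "iso" expects ISO 8601; "uk" expects day-first; "auto" tries day-first
    then ISO per element.  Unparseable entries become NaT.
    """
    raw = raw.astype(str).str.strip()
    if dialect == "iso":
        return pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    if dialect == "uk":
        return pd.to_datetime(raw, format="%d/%m/%Y", errors="coerce")
    if dialect != "auto":
        raise ValueError(f"unknown date dialect {dialect!r}")
    out = pd.to_datetime(raw, format="%d/%m/%Y", errors="coerce")
    mask = out.isna()
    if mask.any():
        out[mask] = pd.to_datetime(raw[mask], format="%Y-%m-%d", errors="coerce")
    return out


def _drop_bad_dates(df: pd.DataFrame, col: str, label: str) -> pd.DataFrame:
    n0 = len(df)
    ok = df[col].notna() & (df[col].dt.year >= MIN_YEAR) & (df[col] <= MAX_DATE)
    dropped = n0 - int(ok.sum())
    if dropped:
        logger.info("%s: dropped %d rows with missing/sentinel dates", label, dropped)
    out = df[ok].copy()
    out.attrs["n_dropped_dates"] = dropped
    return out


def read_prescriptions(
    path: str | Path,
    date_dialect: str = "auto",
    drug_codes: CodeList | None = None,
) -> pd.DataFrame:
    """Read and classify a prescription table.

    Returns a DataFrame with columns ``person_id, issue_date, read_2,
    bnf_code, dmd_code, drug_name, drug_class``, dates normalised to
    datetime, rows with sentinel/unparseable dates dropped (count kept in
    ``.attrs["n_dropped_dates"]``) and rows lacking every code/name field
    dropped (``.attrs["n_dropped_empty"]``).
    """
    if drug_codes is None:
        drug_codes = default_drug_codes()
    df = pd.read_csv(path, dtype=str)
    missing = set(PRESCRIPTION_COLUMNS) - {"quantity"} - set(df.columns)
    if missing:
        raise SchemaError(
            f"prescription file {path} missing columns {sorted(missing)}; "
            f"expected header {PRESCRIPTION_COLUMNS}"
        )
    df = df.fillna("")
    df["issue_date"] = _parse_dates(df["issue_date"], date_dialect)
    df = _drop_bad_dates(df, "issue_date", "prescriptions")

    has_content = (
        (df["read_2"].str.strip() != "")
        | (df["bnf_code"].str.strip() != "")
        | (df["dmd_code"].str.strip() != "")
        | (df["drug_name"].str.strip() != "")
    )
    n_empty = int((~has_content).sum())
    if n_empty:
        logger.info("prescriptions: dropped %d rows with no code or name", n_empty)
    df = df[has_content].copy()
    df.attrs["n_dropped_empty"] = n_empty

    df["drug_class"] = classify_drugs(df, drug_codes)
    out = df.rename(columns={"eid": "person_id"})[
        ["person_id", "issue_date", "read_2", "bnf_code", "dmd_code", "drug_name", "drug_class"]
    ].reset_index(drop=True)
    out.attrs.update(df.attrs)
    return out


def read_clinical_events(
    path: str | Path,
    date_dialect: str = "auto",
    uku_codes: CodeList | None = None,
) -> pd.DataFrame:
    """Read a clinical-event table; flags rows matching the side-effect list.

    Returns columns ``person_id, event_date, read_2, ctv3, is_uku_event``.
    """
    if uku_codes is None:
        uku_codes = default_uku_codes()
    df = pd.read_csv(path, dtype=str)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"clinical-event file {path} missing columns {sorted(missing)}; "
            f"expected header {EVENT_COLUMNS}"
        )
    df = df.fillna("")
    df["event_dt"] = _parse_dates(df["event_dt"], date_dialect)
    df = _drop_bad_dates(df, "event_dt", "clinical events")

    has_code = (df["read_2"].str.strip() != "") | (df["read_3"].str.strip() != "")
    n_nocode = int((~has_code).sum())
    if n_nocode:
        logger.info("clinical events: dropped %d rows with no code", n_nocode)
    df = df[has_code].copy()
    df.attrs["n_dropped_nocode"] = n_nocode

    read2_codes = uku_codes.codes("read2")
    ctv3_codes = uku_codes.codes("ctv3")
    df["is_uku_event"] = df["read_2"].isin(read2_codes) | df["read_3"].isin(ctv3_codes)
    out = df.rename(columns={"eid": "person_id", "event_dt": "event_date", "read_3": "ctv3"})[
        ["person_id", "event_date", "read_2", "ctv3", "is_uku_event"]
    ].reset_index(drop=True)
    out.attrs.update(df.attrs)
    return out


def classify_drug(
    read_2: str = "",
    bnf_code: str = "",
    dmd_code: str = "",
    drug_name: str = "",
    drug_codes: CodeList | None = None,
) -> str:
    """Resolve one prescription record to a drug class.

    Precedence: dm+d code > BNF code (exact, then chapter prefix) > read v2
    code > case-insensitive name pattern > "other".  Name patterns are
    word-bounded, so escitalopram records never match the citalopram
    pattern.
    """
    if drug_codes is None:
        drug_codes = default_drug_codes()
    for system, code in (("dmd", dmd_code), ("bnf", bnf_code), ("read2", read_2)):
        label = drug_codes.match_code(system, (code or "").strip())
        if label:
            return label
    label = drug_codes.match_name((drug_name or "").strip())
    return label if label else "other"


def classify_drugs(df: pd.DataFrame, drug_codes: CodeList | None = None) -> pd.Series:
    """Vectorised :func:`classify_drug` over a prescription DataFrame."""
    if drug_codes is None:
        drug_codes = default_drug_codes()
    # classify each distinct (dmd, bnf, read2, name) tuple once
    key = list(zip(df["dmd_code"], df["bnf_code"], df["read_2"], df["drug_name"]))
    cache: dict[tuple, str] = {}
    out = []
    for k in key:
        if k not in cache:
            cache[k] = classify_drug(
                read_2=k[2], bnf_code=k[1], dmd_code=k[0], drug_name=k[3], drug_codes=drug_codes
            )
        out.append(cache[k])
    return pd.Series(out, index=df.index, name="drug_class")


def dedupe(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact duplicates on (person_id, issue_date, drug_class).

    Repeat same-day issue lines of the same agent would otherwise inflate
    count-based duration arbitrarily.  Output is stably sorted by person,
    date, then class; the operation is idempotent.
    """
    out = prescriptions.drop_duplicates(
        subset=["person_id", "issue_date", "drug_class"], keep="first"
    )
    out = out.sort_values(
        ["person_id", "issue_date", "drug_class"], kind="stable"
    ).reset_index(drop=True)
    return out


def write_prescriptions(df: pd.DataFrame, path: str | Path) -> None:
    """Write records back in the input dialect (ISO dates); round-trips
    through :func:`read_prescriptions`."""
    out = df.rename(columns={"person_id": "eid"}).copy()
    out["issue_date"] = out["issue_date"].dt.strftime("%Y-%m-%d")
    out["data_provider"] = out.get("data_provider", 1)
    out["quantity"] = out.get("quantity", "")
    out[PRESCRIPTION_COLUMNS].to_csv(path, index=False)
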