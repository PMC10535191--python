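"""CYP2C19 star-allele diplotypes, metaboliser phenotypes and activity scores.

A *star allele* is a named haplotype of a pharmacogene with a characterised
effect on enzyme function (e.g. CYP2C19 ``*2`` is a no-function allele,
``*17`` an increased-function allele).  An individual carries two star
alleles — a *diplotype* — from which a categorical metaboliser phenotype
(poor / intermediate / normal / rapid / ultrarapid) and a numeric activity
score are derived.  Rapid and ultrarapid are collapsed into a single "fast"
category for analysis, mirroring their comparable pharmacokinetics; alleles
of unknown function yield an "indeterminate" call and alleles missing from
the function table yield "not_available", both of which are excluded from
analysis cohorts.

The allele-to-function assignment is data, not logic: it is read from a
CSV (``star_allele, function[, activity]``) and the shipped default follows
CPIC/DPWG convention for the common CYP2C19 alleles.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: function vocabulary -> default per-allele activity value (each in [0, 2])
DEFAULT_ACTIVITY_VALUES: dict[str, float] = {
    "no_function": 0.0,
    "decreased": 0.5,
    "normal": 1.0,
    "increased": 2.0,
}

FUNCTION_CATEGORIES = ("no_function", "decreased", "normal", "increased", "unknown")

#: analysis categories; rapid/ultrarapid only ever appear as raw categories
PHENOTYPES = ("poor", "intermediate", "normal", "fast", "indeterminate", "not_available")
RAW_PHENOTYPES = (
    "poor",
    "intermediate",
    "normal",
    "rapid",
    "ultrarapid",
    "indeterminate",
    "not_available",
)

_ALLELE_RE = re.compile(r"^\*(\d+)(?:[xX](\d+))?$")


class DiplotypeParseError(ValueError):
    """Raised for a malformed diplotype or star-allele string."""


@dataclass(frozen=True, order=True)
class StarAllele:
    """One star allele with a positive copy count (2 = duplicated)."""

    name: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not re.match(r"^\*\d+$", self.name):
            raise DiplotypeParseError(f"invalid star-allele name: {self.name!r}")
        if self.multiplicity < 1:
            raise DiplotypeParseError(
                f"multiplicity must be >= 1, got {self.multiplicity} for {self.name}"
            )

    def __str__(self) -> str:  # round-trips through parse_diplotype
        if self.multiplicity == 1:
            return self.name
        return f"{self.name}x{self.multiplicity}"


@dataclass(frozen=True)
class Diplotype:
    """An order-normalised pair of star alleles."""

    allele_a: StarAllele
    allele_b: StarAllele

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        # normalise order (by numeric allele id, then multiplicity) so that
        # *17/*1 and *1/*17 compare and hash equal
        key = lambda s: (int(s.name[1:]), s.multiplicity)
        if key(a) > key(b):
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @property
    def alleles(self) -> tuple[StarAllele, StarAllele]:
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"


@dataclass(frozen=True)
class MetaboliserPhenotype:
    """Raw five-level call plus the collapsed analysis category.

    ``category`` is "fast" iff ``raw_category`` is rapid or ultrarapid;
    otherwise the two coincide.
    """

    raw_category: str

    def __post_init__(self) -> None:
        if self.raw_category not in RAW_PHENOTYPES:
            raise ValueError(f"unknown raw phenotype {self.raw_category!r}")

    @property
    def category(self) -> str:
        if self.raw_category in ("rapid", "ultrarapid"):
            return "fast"
        return self.raw_category

    @property
    def in_analysis(self) -> bool:
        return self.category not in ("indeterminate", "not_available")


def parse_star_allele(text: str) -> StarAllele:
    m = _ALLELE_RE.match(text.strip())
    if not m:
        raise DiplotypeParseError(f"cannot parse star allele token {text!r}")
    mult = int(m.group(2)) if m.group(2) else 1
    if mult == 0:
        raise DiplotypeParseError(f"multiplicity 0 in {text!r}")
    return StarAllele(name=f"*{m.group(1)}", multiplicity=mult)


def parse_diplotype(text: str) -> Diplotype:
    """Parse a diplotype string such as ``"*1/*17"`` or ``"*1x2/*2"``.

    An ``xN`` suffix gives the copy number of an allele (default 1).
    Order is normalised, so ``"*17/*1"`` equals ``"*1/*17"``.
    """
    parts = str(text).split("/")
    if len(parts) != 2:
        raise DiplotypeParseError(
            f"diplotype {text!r} must contain exactly one '/' separator"
        )
    return Diplotype(parse_star_allele(parts[0]), parse_star_allele(parts[1]))


class AlleleFunctionTable:
    """Mapping of star alleles to function categories and activity values.

    Parameters
    ----------
    functions :
        Mapping from star-allele name (``"*1"``) to a function category in
        ``{"no_function", "decreased", "normal", "increased", "unknown"}``.
    activity_values :
        Per-category per-allele activity value.  Must satisfy
        ``no_function == 0`` and ``decreased < normal < increased``.
    allele_activity :
        Optional explicit per-allele override of the category value.
    """

    def __init__(
        self,
        functions: Mapping[str, str],
        activity_values: Mapping[str, float] | None = None,
        allele_activity: Mapping[str, float] | None = None,
    ):
        self.functions = dict(functions)
        for allele, fn in self.functions.items():
            if fn not in FUNCTION_CATEGORIES:
                raise ValueError(f"unknown function category {fn!r} for {allele}")
        vals = dict(DEFAULT_ACTIVITY_VALUES)
        if activity_values:
            vals.update(activity_values)
        if vals["no_function"] != 0:
            raise ValueError("no_function must map to activity 0")
        if not (vals["decreased"] < vals["normal"] < vals["increased"]):
            raise ValueError("activity values must be ordered decreased < normal < increased")
        for cat, v in vals.items():
            if not 0 <= v <= 2:
                raise ValueError(f"per-allele activity for {cat!r} outside [0, 2]: {v}")
        self.activity_values = vals
        self.allele_activity = dict(allele_activity or {})

    def function_of(self, allele: StarAllele | str) -> str | None:
        name = allele.name if isinstance(allele, StarAllele) else allele
        return self.functions.get(name)

    def activity_of(self, allele: StarAllele) -> float | None:
        """Per-copy activity of one allele, or None if unknown/absent."""
        if allele.name in self.allele_activity:
            return self.allele_activity[allele.name]
        fn = self.functions.get(allele.name)
        if fn is None or fn == "unknown":
            return None
        return self.activity_values[fn]

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "AlleleFunctionTable":
        """Load from a CSV with columns ``star_allele, function[, activity]``."""
        df = pd.read_csv(path, dtype=str)
        required = {"star_allele", "function"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"allele table {path} missing columns {sorted(missing)}")
        functions = dict(zip(df["star_allele"].str.strip(), df["function"].str.strip()))
        allele_activity = {}
        if "activity" in df.columns:
            for _, row in df.iterrows():
                if pd.notna(row["activity"]) and str(row["activity"]).strip() != "":
                    allele_activity[row["star_allele"].strip()] = float(row["activity"])
        return cls(functions, allele_activity=allele_activity, **kwargs)

    @classmethod
    def default(cls) -> "AlleleFunctionTable":
        """The shipped CPIC/DPWG-style CYP2C19 table."""
        with resources.as_file(
            resources.files("pgxoutcomes.data") / "cyp2c19_allele_function.csv"
        ) as p:
            return cls.from_csv(p)


def call_phenotype(d: Diplotype, table: AlleleFunctionTable) -> MetaboliserPhenotype:
    """Translate a diplotype into a metaboliser phenotype.

    Classification uses the unordered pair of allele function categories:

    * two no-function alleles -> poor
    * any no-function or decreased allele combined with anything short of
      two no-function alleles -> intermediate
    * two normal -> normal; normal + increased -> rapid;
      two increased -> ultrarapid

    Any allele of unknown function gives "indeterminate"; any allele absent
    from the table gives "not_available".  Copy number does not enter the
    categorical call (it only scales the activity score).
    """
    fns = [table.function_of(a) for a in d.alleles]
    if any(f is None for f in fns):
        return MetaboliserPhenotype("not_available")
    if any(f == "unknown" for f in fns):
        return MetaboliserPhenotype("indeterminate")
    pair = tuple(sorted(fns))
    if pair == ("no_function", "no_function"):
        raw = "poor"
    elif "no_function" in pair or "decreased" in pair:
        raw = "intermediate"
    elif pair == ("normal", "normal"):
        raw = "normal"
    elif pair == ("increased", "normal"):
        raw = "rapid"
    elif pair == ("increased", "increased"):
        raw = "ultrarapid"
    else:  # pragma: no cover - vocabulary is closed
        raise AssertionError(f"unclassifiable function pair {pair}")
    return MetaboliserPhenotype(raw)


def activity_score(d: Diplotype, table: AlleleFunctionTable) -> float | None:
    """Sum of per-allele activity times copy number; None if any allele
    has unknown or missing function (the person is then dropped from
    activity-score analyses).  Doubling both copy numbers doubles the score.
    """
    total = 0.0
    for a in d.alleles:
        v = table.activity_of(a)
        if v is None:
            return None
        total += v * a.multiplicity
    return total


def annotate_cohort(
    diplotypes: pd.DataFrame, table: AlleleFunctionTable | None = None
) -> pd.DataFrame:
    """Annotate a per-person diplotype table with phenotype and activity score.

    Parameters
    ----------
    diplotypes :
        DataFrame with columns ``person_id`` and ``diplotype`` (string
        dialect as accepted by :func:`parse_diplotype`).  Person ids must
        be unique.
    table :
        Allele function table; defaults to the shipped CYP2C19 table.

    Returns
    -------
    DataFrame with columns ``person_id, diplotype, phenotype, raw_phenotype,
    activity_score, included, exclusion_reason``.  Persons whose call is
    indeterminate or not_available are flagged ``included=False``.
    """
    if table is None:
        table = AlleleFunctionTable.default()
    if diplotypes["person_id"].duplicated().any():
        dups = diplotypes.loc[diplotypes["person_id"].duplicated(), "person_id"]
        raise ValueError(f"duplicate person ids in diplotype table: {list(dups[:5])}")

    # parse/call once per distinct diplotype string, then broadcast
    rows = {}
    for text in diplotypes["diplotype"].unique():
        d = parse_diplotype(text)
        ph = call_phenotype(d, table)
        rows[text] = (
            ph.category,
            ph.raw_category,
            activity_score(d, table),
            ph.in_analysis,
            None if ph.in_analysis else ph.category,
        )
    ann = diplotypes[["person_id", "diplotype"]].copy()
    cols = ann["diplotype"].map(rows)
    ann["phenotype"] = [c[0] for c in cols]
    ann["raw_phenotype"] = [c[1] for c in cols]
    ann["activity_score"] = [c[2] for c in cols]
    ann["included"] = [c[3] for c in cols]
    ann["exclusion_reason"] = [c[4] for c in cols]

    counts = ann["phenotype"].value_counts().to_dict()
    logger.info("phenotype counts: %s (excluded: %d)", counts, (~ann["included"]).sum())
    return ann


class PhenotypeCaller(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`annotate_cohort` for pipeline use.

    Parameters
    ----------
    allele_table : str, Path or AlleleFunctionTable, optional
        Path to a ``star_allele, function[, activity]`` CSV, or a table
        instance.  Defaults to the shipped CYP2C19 table.
    drop_excluded : bool, default False
        If True, transform() drops indeterminate / not-available persons.
    """

    def __init__(self, allele_table=None, drop_excluded: bool = False):
        self.allele_table = allele_table
        self.drop_excluded = drop_excluded

    def fit(self, X: pd.DataFrame, y=None) -> "PhenotypeCaller":
        if isinstance(self.allele_table, AlleleFunctionTable):
            self.table_ = self.allele_table
        elif self.allele_table is None:
            self.table_ = AlleleFunctionTable.default()
        else:
            self.table_ = AlleleFunctionTable.from_csv(self.allele_table)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "table_"):
            self.fit(X)
        ann = annotate_cohort(X, self.table_)
        if self.drop_excluded:
            ann = ann[ann["included"]].reset_index(drop=True)
        return ann
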