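"""Adjusted association models between metaboliser status and outcomes.

Binary outcomes (switching, discontinuation, side effects) are analysed
with maximum-likelihood logistic regression; duration outcomes with OLS on
the natural log of duration + 1 (single-prescription persons have zero
weeks, hence the offset).  The predictor is either the categorical
metaboliser phenotype with normal metabolisers as the reference level, or
the continuous activity score.  Default covariates: age at first index
prescription, sex, genotyping batch (unordered factor) and binary overlap
with an antipsychotic prescription; confidence intervals and p-values are
two-sided Wald.

Degenerate fits (complete separation, non-convergence, no cases or no
controls, zero-variance response) are reported as flagged, inestimable
results rather than raised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_at_first_rx", "sex", "batch", "antipsychotic_overlap")

BINARY_OUTCOMES = (
    "switch_30",
    "switch_60",
    "switch_90",
    "disc_def1",
    "disc_def2",
    "side_effect_30",
    "side_effect_60",
)
DURATION_OUTCOMES = ("duration_count", "duration_weeks")

PHENOTYPE_LEVELS = ("normal", "poor", "intermediate", "fast")

RESULT_COLUMNS = [
    "ssri",
    "outcome",
    "predictor",
    "term",
    "estimate",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "p",
    "n_cases",
    "n_controls",
    "subgroup",
    "flags",
]


@dataclass
class AssociationResult:
    """One predictor-outcome effect estimate.

    ``estimate`` is on the link scale (log-odds for logistic fits, the
    coefficient for linear fits); ``or_`` = exp(estimate) for logistic
    fits only.  CI bounds are estimate +/- 1.96 x SE on the link scale.
    """

    ssri: str
    outcome: str
    predictor: str
    term: str
    estimate: float = np.nan
    se: float = np.nan
    or_: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    n_cases: int = 0
    n_controls: int = 0
    subgroup: str = "all"
    flags: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["or"] = d.pop("or_")
        return d


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results], columns=RESULT_COLUMNS)


def _formula(outcome: str, predictor_mode: str, covariates: tuple[str, ...]) -> str:
    if predictor_mode == "phenotype_categorical":
        pred = 'C(phenotype, Treatment(reference="normal"))'
    elif predictor_mode == "activity_score":
        pred = "activity_score"
    else:
        raise ValueError(f"unknown predictor mode {predictor_mode!r}")
    terms = [pred]
    for c in covariates:
        terms.append(f"C({c})" if c == "batch" else c)
    return f"Q('{outcome}') ~ " + " + ".join(terms)


def _term_name(param: str) -> str | None:
    """Map a patsy parameter name to a reportable term, or None to skip."""
    if param.startswith("C(phenotype"):
        level = param.split("T.")[-1].rstrip("]")
        return f"{level} vs normal"
    if param == "activity_score":
        return "activity_score"
    return None


def _subset(table: pd.DataFrame, ssri: str | None, subgroup: str) -> pd.DataFrame:
    df = table if ssri is None else table[table["ssri"] == ssri]
    if subgroup == "broad_depression":
        df = df[df["broad_depression"].astype(bool)]
    elif subgroup != "all":
        raise ValueError(f"unknown subgroup {subgroup!r}")
    return df


def _prepare(df: pd.DataFrame, covariates) -> pd.DataFrame:
    df = df.copy()
    if "antipsychotic_overlap" in df.columns:
        df["antipsychotic_overlap"] = df["antipsychotic_overlap"].astype(int)
    needed = [c for c in covariates if c in df.columns]
    return df.dropna(subset=needed)


def fit_binary(
    table: pd.DataFrame,
    outcome: str,
    predictor_mode: str = "phenotype_categorical",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ssri: str | None = None,
    subgroup: str = "all",
) -> list[AssociationResult]:
    """Adjusted logistic regression for one binary outcome.

    Excluded rows (status NA / "excluded") are dropped; one result is
    returned per non-reference phenotype level (or one for the activity
    score).  Zero cases or zero controls, perfect separation and
    non-convergence yield flagged inestimable results.
    """
    df = _subset(table, ssri, subgroup)
    df = _prepare(df, covariates)
    status = df[outcome]
    if status.dtype == object:
        y = status.map({"case": 1.0, "control": 0.0})
    else:
        y = status.astype(float)
    df = df.assign(**{outcome: y}).dropna(subset=[outcome])
    if predictor_mode == "activity_score":
        df = df.dropna(subset=["activity_score"])
    n_cases = int((df[outcome] == 1).sum())
    n_controls = int((df[outcome] == 0).sum())

    def _terms() -> list[str]:
        if predictor_mode == "activity_score":
            return ["activity_score"]
        levels = [l for l in PHENOTYPE_LEVELS if l != "normal" and l in set(df["phenotype"])]
        return [f"{l} vs normal" for l in levels] or [
            f"{l} vs normal" for l in PHENOTYPE_LEVELS if l != "normal"
        ]

    def _inestimable(flag: str) -> list[AssociationResult]:
        return [
            AssociationResult(
                ssri=ssri or "all", outcome=outcome, predictor=predictor_mode,
                term=t, n_cases=n_cases, n_controls=n_controls,
                subgroup=subgroup, flags=flag,
            )
            for t in _terms()
        ]

    if n_cases == 0 or n_controls == 0:
        return _inestimable("no_cases" if n_cases == 0 else "no_controls")

    formula = _formula(outcome, predictor_mode, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.logit(formula, data=df)
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # separation, singular design, ...
        logger.warning("logit fit failed for %s/%s: %s", ssri, outcome, exc)
        return _inestimable("inestimable:" + type(exc).__name__)
    converged = bool(res.mle_retvals.get("converged", True))
    results = []
    for param, est in res.params.items():
        term = _term_name(param)
        if term is None:
            continue
        se = float(res.bse[param])
        flags = []
        if not converged:
            flags.append("nonconvergence")
        if not np.isfinite(se) or se > 50 or abs(est) > 15:
            flags.append("separation_suspect")
        with np.errstate(over="ignore"):
            odds_ratio = float(np.exp(est))
        results.append(
            AssociationResult(
                ssri=ssri or "all",
                outcome=outcome,
                predictor=predictor_mode,
                term=term,
                estimate=float(est),
                se=se,
                or_=odds_ratio,
                ci_low=float(est - 1.96 * se),
                ci_high=float(est + 1.96 * se),
                p=float(2 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan,
                n_cases=n_cases,
                n_controls=n_controls,
                subgroup=subgroup,
                flags=";".join(flags),
            )
        )
    return results


def fit_duration(
    table: pd.DataFrame,
    definition: str = "count",
    predictor_mode: str = "phenotype_categorical",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ssri: str | None = None,
    subgroup: str = "all",
) -> list[AssociationResult]:
    """OLS of ln(duration + 1) on the predictor and covariates.

    ``definition`` selects the count-based (number of index prescriptions)
    or weeks-based (total weeks inside prescription windows) duration.  All
    persons with at least one index prescription contribute.
    """
    col = {"count": "duration_count", "weeks": "duration_weeks"}[definition]
    df = _subset(table, ssri, subgroup)
    df = _prepare(df, covariates)
    df = df.dropna(subset=[col])
    if predictor_mode == "activity_score":
        df = df.dropna(subset=["activity_score"])
    outcome_name = f"log_{col}"
    df = df.assign(**{outcome_name: np.log(df[col].astype(float) + 1.0)})
    n = len(df)

    def _inestimable(flag):
        terms = (
            ["activity_score"]
            if predictor_mode == "activity_score"
            else [f"{l} vs normal" for l in PHENOTYPE_LEVELS if l != "normal"]
        )
        return [
            AssociationResult(
                ssri=ssri or "all", outcome=col, predictor=predictor_mode, term=t,
                n_cases=n, n_controls=0, subgroup=subgroup, flags=flag,
            )
            for t in terms
        ]

    if n < 3 or np.isclose(df[outcome_name].var(ddof=0), 0.0):
        return _inestimable("zero_variance" if n >= 3 else "too_few_rows")

    formula = _formula(outcome_name, predictor_mode, covariates)
    res = smf.ols(formula, data=df).fit()
    results = []
    for param, est in res.params.items():
        term = _term_name(param)
        if term is None:
            continue
        se = float(res.bse[param])
        results.append(
            AssociationResult(
                ssri=ssri or "all",
                outcome=col,
                predictor=predictor_mode,
                term=term,
                estimate=float(est),
                se=se,
                or_=np.nan,
                ci_low=float(est - 1.96 * se),
                ci_high=float(est + 1.96 * se),
                p=float(2 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan,
                n_cases=n,
                n_controls=0,
                subgroup=subgroup,
            )
        )
    return results


def run_all(
    table: pd.DataFrame,
    predictor_modes: tuple[str, ...] = ("phenotype_categorical", "activity_score"),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    subgroup: str = "all",
    alpha: float = 0.05,
    n_outcome_families: int = 4,
) -> pd.DataFrame:
    """Fit every (ssri x outcome x predictor mode) combination.

    Raw p-values are reported throughout; a Bonferroni significance flag at
    alpha / n_outcome_families is emitted alongside, never replacing them.
    """
    results: list[AssociationResult] = []
    for ssri in sorted(table["ssri"].unique()):
        for mode in predictor_modes:
            for outcome in BINARY_OUTCOMES:
                if outcome in table.columns:
                    results.extend(
                        fit_binary(table, outcome, mode, covariates, ssri, subgroup)
                    )
            for definition in ("count", "weeks"):
                results.extend(
                    fit_duration(table, definition, mode, covariates, ssri, subgroup)
                )
    out = results_frame(results)
    out["bonferroni_significant"] = out["p"] < alpha / n_outcome_families
    return out


def export_forest(results: pd.DataFrame, path=None) -> pd.DataFrame:
    """Forest-style table of odds ratios with 95% CI bounds.

    One row per logistic result: ``ssri, outcome, term, or, or_low,
    or_high, p``; inestimable rows carry missing markers.  Written to
    ``path`` as CSV when given.
    """
    df = results[results["predictor"] == "phenotype_categorical"].copy()
    df = df[~df["outcome"].isin(DURATION_OUTCOMES)]
    with np.errstate(over="ignore"):  # separation-flagged rows overflow to inf
        return _forest_frame(df, path)


def _forest_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "ssri": df["ssri"],
            "outcome": df["outcome"],
            "term": df["term"],
            "or": np.exp(df["estimate"]),
            "or_low": np.exp(df["ci_low"]),
            "or_high": np.exp(df["ci_high"]),
            "p": df["p"],
            "flags": df["flags"],
        }
    ).reset_index(drop=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def plot_forest(forest: pd.DataFrame, path) -> None:
    """Simple matplotlib forest plot (one panel, OR with CI bars)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = forest.dropna(subset=["or"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(4, len(f))))
    y = np.arange(len(f))
    ax.errorbar(
        f["or"], y,
        xerr=[f["or"] - f["or_low"], f["or_high"] - f["or"]],
        fmt="o", color="black", ecolor="grey", capsize=2,
    )
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(f["ssri"] + " " + f["outcome"] + " " + f["term"], fontsize=7)
    ax.set_xlabel("odds ratio (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class _BaseOutcomeModel(BaseEstimator):
    """Shared scaffolding for the estimator-style interface."""

    def get_results(self) -> pd.DataFrame:
        return results_frame(self.results_)


class BinaryOutcomeModel(_BaseOutcomeModel):
    """Logistic model of one binary outcome against metaboliser status.

    Parameters
    ----------
    outcome : str
        One of the case/control status columns, e.g. ``"switch_60"``.
    predictor_mode : {"phenotype_categorical", "activity_score"}
    covariates : tuple of str
    ssri : str or None
        Restrict to one index SSRI (rows of the outcome table).
    subgroup : {"all", "broad_depression"}

    After ``fit(outcome_table)`` the attribute ``results_`` holds a list of
    :class:`AssociationResult`, one per non-reference term.
    """

    def __init__(
        self,
        outcome: str = "switch_60",
        predictor_mode: str = "phenotype_categorical",
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        ssri: str | None = None,
        subgroup: str = "all",
    ):
        self.outcome = outcome
        self.predictor_mode = predictor_mode
        self.covariates = covariates
        self.ssri = ssri
        self.subgroup = subgroup

    def fit(self, X: pd.DataFrame, y=None) -> "BinaryOutcomeModel":
        self.results_ = fit_binary(
            X, self.outcome, self.predictor_mode, self.covariates, self.ssri, self.subgroup
        )
        return self


class DurationModel(_BaseOutcomeModel):
    """OLS model of log-transformed duration; see :class:`BinaryOutcomeModel`."""

    def __init__(
        self,
        definition: str = "count",
        predictor_mode: str = "phenotype_categorical",
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        ssri: str | None = None,
        subgroup: str = "all",
    ):
        self.definition = definition
        self.predictor_mode = predictor_mode
        self.covariates = covariates
        self.ssri = ssri
        self.subgroup = subgroup

    def fit(self, X: pd.DataFrame, y=None) -> "DurationModel":
        self.results_ = fit_duration(
            X, self.definition, self.predictor_mode, self.covariates, self.ssri, self.subgroup
        )
        return self
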