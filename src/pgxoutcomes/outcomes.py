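"""Per-person, per-SSRI treatment-response proxies from prescription streams.

Four outcome families are derived for each index SSRI (citalopram,
escitalopram, sertraline) a person was ever prescribed:

switching
    A switch to another antidepressant within 30/60/90 days of the last
    index-SSRI issue.  The switch date is the first issue of any other
    antidepressant on or after the first index issue.  A bounded amount of
    index-SSRI prescribing is tolerated around the switch date (at most 1
    index issue in the 30 days before and the 30 days after it for the
    30/60-day windows; at most 2 for the 90-day window).  Controls have at
    least 3 index issues with no other-antidepressant issue at any point
    from the first index issue onward; everyone else is excluded.

discontinuation
    Definition 1: a complete stop after a single index prescription — no
    antidepressant of any agent afterwards, with at least ``lookahead_days``
    of observed record to guard against right-censoring.  Definition 2: an
    abrupt stop after a single prescription window spanning under 8 weeks
    (56 days, strict), irrespective of the number of issues.  Controls are
    the switching controls.

duration
    A count of deduplicated index issues, and the total weeks elapsed
    inside prescription windows (maximal runs with consecutive gaps under
    90 days — a gap of exactly 90 starts a new window).

side effects
    A listed clinical-event code in the 30 or 60 days after the first index
    issue, provided the same code does not also occur in the 30 days before
    it (which would indicate a pre-existing condition).  Requires event
    coverage of the full look-back/look-forward interval.

Binary statuses are three-valued: case / control / excluded.  The exported
CSV encodes them 1 / 0 / NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import ANTIDEPRESSANT_CLASSES, SSRI_CLASSES

logger = logging.getLogger(__name__)

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"

STATUS_COLUMNS = [
    "switch_30",
    "switch_60",
    "switch_90",
    "disc_def1",
    "disc_def2",
    "side_effect_30",
    "side_effect_60",
]


@dataclass(frozen=True)
class OutcomeParams:
    """Tunable outcome-derivation settings (days unless noted).

    Defaults are the study settings: 90-day window gap, 30/60/90-day switch
    windows with prescription tolerances 1/1/2 counted in a fixed 30-day
    interval either side of the switch date, 180-day stoppage look-ahead,
    8-week (56-day) short-period cutoff, 30/60-day side-effect windows with
    a 30-day prior-occurrence exclusion.
    """

    gap_days: int = 90
    switch_windows: tuple[int, ...] = (30, 60, 90)
    switch_tolerances: dict = field(default_factory=lambda: {30: 1, 60: 1, 90: 2})
    tolerance_window: int = 30
    lookahead_days: int = 180
    max_short_days: int = 56
    side_effect_windows: tuple[int, ...] = (30, 60)
    prior_days: int = 30
    min_control_prescriptions: int = 3


@dataclass
class PersonTimeline:
    """One person's ordered, deduplicated records as plain arrays.

    ``rx_days`` are integer days (days-since-epoch) sorted ascending with
    ``rx_class`` aligned; similarly for clinical events.  ``record_start``
    and ``record_end`` bound the observed record.
    """

    person_id: object
    rx_days: np.ndarray
    rx_class: np.ndarray
    event_days: np.ndarray
    event_codes: np.ndarray
    event_is_uku: np.ndarray
    record_start: int
    record_end: int

    def __post_init__(self):
        if len(self.rx_days) and np.any(np.diff(self.rx_days) < 0):
            order = np.argsort(self.rx_days, kind="stable")
            self.rx_days = self.rx_days[order]
            self.rx_class = self.rx_class[order]
        if len(self.event_days) and np.any(np.diff(self.event_days) < 0):
            order = np.argsort(self.event_days, kind="stable")
            self.event_days = self.event_days[order]
            self.event_codes = self.event_codes[order]
            self.event_is_uku = self.event_is_uku[order]

    def ssri_classes(self) -> list[str]:
        present = set(self.rx_class.tolist())
        return [s for s in SSRI_CLASSES if s in present]

    def index_days(self, ssri: str) -> np.ndarray:
        return np.unique(self.rx_days[self.rx_class == ssri])

    def other_ad_days(self, ssri: str) -> np.ndarray:
        mask = np.isin(self.rx_class, [c for c in ANTIDEPRESSANT_CLASSES if c != ssri])
        return np.unique(self.rx_days[mask])

    def ad_days(self) -> np.ndarray:
        mask = np.isin(self.rx_class, list(ANTIDEPRESSANT_CLASSES))
        return np.unique(self.rx_days[mask])

    def shifted(self, k: int) -> "PersonTimeline":
        """Timeline with every date translated by k days."""
        return replace(
            self,
            rx_days=self.rx_days + k,
            event_days=self.event_days + k,
            record_start=self.record_start + k,
            record_end=self.record_end + k,
        )


def build_windows(index_days: np.ndarray, gap_days: int = 90) -> list[tuple[int, int, int]]:
    """Partition sorted index-issue days into prescription windows.

    A window is a maximal run with consecutive gaps strictly below
    ``gap_days``; a gap of exactly ``gap_days`` starts a new window.
    Returns (first_day, last_day, n_prescriptions) triples.
    """
    d = np.asarray(index_days)
    if d.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(d) >= gap_days) + 1
    out = []
    for chunk in np.split(d, breaks):
        out.append((int(chunk[0]), int(chunk[-1]), int(chunk.size)))
    return out


def duration_weeks(windows: list[tuple[int, int, int]]) -> float:
    """Total weeks elapsed within prescription windows.

    Each window contributes (last - first)/7; a single-prescription window
    contributes 0.  Invariant under translating all dates.
    """
    return float(sum((last - first) for first, last, _ in windows)) / 7.0


def duration_count(timeline: PersonTimeline, ssri: str) -> int:
    """Number of deduplicated index-SSRI prescriptions."""
    return int(timeline.index_days(ssri).size)


def _switch_candidate(timeline: PersonTimeline, ssri: str):
    """First other-antidepressant issue on/after the first index issue,
    with the gap from the preceding index issue; None if no such issue."""
    idx = timeline.index_days(ssri)
    if idx.size == 0:
        return None, None
    other = timeline.other_ad_days(ssri)
    other = other[other >= idx[0]]
    if other.size == 0:
        return None, None
    d = int(other[0])
    prior = idx[idx <= d]
    gap = int(d - prior[-1])  # ties (same-day issue) give gap 0
    return d, gap


def detect_switch(
    timeline: PersonTimeline,
    ssri: str,
    window_days: int,
    params: OutcomeParams | None = None,
) -> str:
    """Classify switching at one window: case / control / excluded.

    Case: the switch candidate occurs within ``window_days`` of the
    preceding index issue and the index-issue counts within
    ``tolerance_window`` days before and after the switch date are each at
    most the window's tolerance.  Control: no other-antidepressant issue on
    or after the first index issue, and at least
    ``min_control_prescriptions`` index issues.  Otherwise excluded.
    """
    params = params or OutcomeParams()
    idx = timeline.index_days(ssri)
    if idx.size == 0:
        return EXCLUDED
    d, gap = _switch_candidate(timeline, ssri)
    if d is None:
        if idx.size >= params.min_control_prescriptions:
            return CONTROL
        return EXCLUDED
    tol = params.switch_tolerances[window_days]
    w = params.tolerance_window
    before = int(np.sum((idx >= d - w) & (idx < d)))
    after = int(np.sum((idx > d) & (idx <= d + w)))
    if gap <= window_days and before <= tol and after <= tol:
        return CASE
    return EXCLUDED


def discontinuation_def1(
    timeline: PersonTimeline, ssri: str, params: OutcomeParams | None = None
) -> str:
    """Complete stoppage after a single index prescription.

    Case: exactly one index issue ever, no antidepressant of any agent
    after it, and at least ``lookahead_days`` of record beyond it.
    Censored single-issue persons are excluded; multi-issue persons fall
    back to the control rule.
    """
    params = params or OutcomeParams()
    idx = timeline.index_days(ssri)
    if idx.size == 0:
        return EXCLUDED
    if idx.size == 1:
        d0 = int(idx[0])
        if timeline.record_end - d0 < params.lookahead_days:
            return EXCLUDED
        ad = timeline.ad_days()
        if np.any(ad > d0):
            return EXCLUDED
        return CASE
    return _switch_control(timeline, ssri, params)


def discontinuation_def2(
    timeline: PersonTimeline, ssri: str, params: OutcomeParams | None = None
) -> str:
    """Abrupt stoppage after a short prescription period.

    Case: the person's only prescription window spans under
    ``max_short_days`` (8 weeks, strict), no antidepressant of any agent
    after its last issue, and at least ``lookahead_days`` of record beyond
    it.  Controls as for switching.
    """
    params = params or OutcomeParams()
    idx = timeline.index_days(ssri)
    if idx.size == 0:
        return EXCLUDED
    windows = build_windows(idx, params.gap_days)
    if len(windows) == 1 and (windows[0][1] - windows[0][0]) < params.max_short_days:
        last = int(idx[-1])
        if timeline.record_end - last < params.lookahead_days:
            return EXCLUDED
        ad = timeline.ad_days()
        if not np.any(ad > last):
            return CASE
    return _switch_control(timeline, ssri, params)


def _switch_control(timeline: PersonTimeline, ssri: str, params: OutcomeParams) -> str:
    idx = timeline.index_days(ssri)
    d, _ = _switch_candidate(timeline, ssri)
    if d is None and idx.size >= params.min_control_prescriptions:
        return CONTROL
    return EXCLUDED


def detect_side_effects(
    timeline: PersonTimeline,
    ssri: str,
    post_days: int,
    params: OutcomeParams | None = None,
) -> str:
    """Listed clinical event shortly after the first index prescription.

    Case: a flagged event with date in (first_rx, first_rx + post_days]
    whose exact code does not also occur in [first_rx - prior_days,
    first_rx].  Excluded when the event record does not cover the whole
    interval; control otherwise.
    """
    params = params or OutcomeParams()
    idx = timeline.index_days(ssri)
    if idx.size == 0:
        return EXCLUDED
    first = int(idx[0])
    if timeline.record_start > first - params.prior_days or timeline.record_end < first + post_days:
        return EXCLUDED
    days, codes, uku = timeline.event_days, timeline.event_codes, timeline.event_is_uku
    post_mask = uku & (days > first) & (days <= first + post_days)
    if not np.any(post_mask):
        return CONTROL
    prior_mask = (days >= first - params.prior_days) & (days <= first)
    prior_codes = set(codes[prior_mask].tolist())
    for code in codes[post_mask]:
        if code not in prior_codes:
            return CASE
    return CONTROL


def antipsychotic_overlap(timeline: PersonTimeline, ssri: str) -> bool:
    """Any antipsychotic issue inside the index envelope (first to last
    index issue, inclusive)."""
    idx = timeline.index_days(ssri)
    if idx.size == 0:
        return False
    ap = timeline.rx_days[timeline.rx_class == "antipsychotic"]
    return bool(np.any((ap >= idx[0]) & (ap <= idx[-1])))


def derive_person(
    timeline: PersonTimeline, ssri: str, params: OutcomeParams
) -> dict:
    """All outcome fields for one person and one index SSRI."""
    idx = timeline.index_days(ssri)
    windows = build_windows(idx, params.gap_days)
    row = {
        "person_id": timeline.person_id,
        "ssri": ssri,
        "first_rx_day": int(idx[0]),
        "duration_count": int(idx.size),
        "duration_weeks": duration_weeks(windows),
        "antipsychotic_overlap": antipsychotic_overlap(timeline, ssri),
    }
    for w in params.switch_windows:
        row[f"switch_{w}"] = detect_switch(timeline, ssri, w, params)
    row["disc_def1"] = discontinuation_def1(timeline, ssri, params)
    row["disc_def2"] = discontinuation_def2(timeline, ssri, params)
    for w in params.side_effect_windows:
        row[f"side_effect_{w}"] = detect_side_effects(timeline, ssri, w, params)
    return row


def build_timelines(
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    bounds: pd.DataFrame,
) -> list[PersonTimeline]:
    """Assemble per-person timelines from classified record tables.

    ``prescriptions`` must carry person_id, issue_date, drug_class (already
    deduplicated); ``events`` person_id, event_date, read_2/ctv3,
    is_uku_event; ``bounds`` person_id, record_start, record_end.  Persons
    missing from ``bounds`` get bounds inferred from their own records with
    a generous margin (they then satisfy no coverage-dependent rule that
    their records cannot support).
    """
    epoch = np.datetime64("1970-01-01")
    rx = prescriptions.sort_values(["person_id", "issue_date"], kind="stable")
    rx_days = (rx["issue_date"].values.astype("datetime64[D]") - epoch).astype(np.int64)
    rx_pid = rx["person_id"].to_numpy()
    rx_cls = rx["drug_class"].to_numpy()

    ev = events.sort_values(["person_id", "event_date"], kind="stable")
    ev_days = (ev["event_date"].values.astype("datetime64[D]") - epoch).astype(np.int64)
    ev_pid = ev["person_id"].to_numpy()
    code = ev["read_2"].astype(str).to_numpy()
    ctv3 = ev["ctv3"].astype(str).to_numpy() if "ctv3" in ev.columns else np.full(len(ev), "")
    ev_codes = np.where((code == "") | (code == "nan"), ctv3, code)
    ev_uku = ev["is_uku_event"].to_numpy(dtype=bool)

    bmap = {}
    if bounds is not None and len(bounds):
        bs = (bounds["record_start"].values.astype("datetime64[D]") - epoch).astype(np.int64)
        be = (bounds["record_end"].values.astype("datetime64[D]") - epoch).astype(np.int64)
        bmap = dict(zip(bounds["person_id"].to_numpy(), zip(bs.tolist(), be.tolist())))

    def group_slices(pid_arr):
        if len(pid_arr) == 0:
            return {}
        change = np.flatnonzero(pid_arr[1:] != pid_arr[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(pid_arr)]])
        return {pid_arr[s]: (s, e) for s, e in zip(starts, ends)}

    rx_groups = group_slices(rx_pid)
    ev_groups = group_slices(ev_pid)

    timelines = []
    empty_i = np.empty(0, dtype=np.int64)
    empty_s = np.empty(0, dtype=object)
    empty_b = np.empty(0, dtype=bool)
    for pid, (s, e) in rx_groups.items():
        days = rx_days[s:e]
        cls = rx_cls[s:e]
        if pid in ev_groups:
            es, ee = ev_groups[pid]
            edays, ecodes, euku = ev_days[es:ee], ev_codes[es:ee], ev_uku[es:ee]
        else:
            edays, ecodes, euku = empty_i, empty_s, empty_b
        if pid in bmap:
            rs, re_ = bmap[pid]
        else:
            lo = min(days.min(), edays.min() if edays.size else days.min())
            hi = max(days.max(), edays.max() if edays.size else days.max())
            rs, re_ = int(lo) - 3650, int(hi) + 3650
        timelines.append(
            PersonTimeline(pid, days, cls, edays, ecodes, euku, int(rs), int(re_))
        )
    return timelines


def build_outcome_table(
    timelines: list[PersonTimeline],
    covariates: pd.DataFrame,
    phenotypes: pd.DataFrame,
    params: OutcomeParams | None = None,
) -> pd.DataFrame:
    """One row per person x index SSRI actually prescribed.

    ``covariates`` must carry person_id, sex, year_of_birth, batch and
    (optionally) broad_depression; ``phenotypes`` is the annotated cohort
    from :func:`pgxoutcomes.alleles.annotate_cohort` with indeterminate /
    not-available persons already flagged.  Persons without covariates or
    without an included phenotype are skipped with a logged count.
    """
    params = params or OutcomeParams()
    cov = covariates.set_index("person_id")
    ph = phenotypes.set_index("person_id")

    rows = []
    n_missing_cov = n_excluded_pheno = 0
    for tl in timelines:
        if tl.person_id not in cov.index:
            n_missing_cov += 1
            continue
        if tl.person_id not in ph.index or not bool(ph.at[tl.person_id, "included"]):
            n_excluded_pheno += 1
            continue
        for ssri in tl.ssri_classes():
            rows.append(derive_person(tl, ssri, params))
    if n_missing_cov or n_excluded_pheno:
        logger.info(
            "outcome table: skipped %d persons without covariates, "
            "%d without an analysable phenotype",
            n_missing_cov,
            n_excluded_pheno,
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["first_rx_date"] = pd.to_datetime(out.pop("first_rx_day"), unit="D")
    out = out.merge(
        cov.reset_index()[
            [c for c in ("person_id", "sex", "year_of_birth", "batch", "broad_depression") if c in covariates.columns]
        ],
        on="person_id",
        how="left",
    )
    out["age_at_first_rx"] = out["first_rx_date"].dt.year - out["year_of_birth"]
    out = out.merge(
        ph.reset_index()[["person_id", "phenotype", "activity_score"]],
        on="person_id",
        how="left",
    )
    out.attrs["n_missing_covariates"] = n_missing_cov
    out.attrs["n_excluded_phenotype"] = n_excluded_pheno
    return out


def encode_status(df: pd.DataFrame) -> pd.DataFrame:
    """Encode case/control/excluded status columns as 1/0/NA for export."""
    out = df.copy()
    mapping = {CASE: 1.0, CONTROL: 0.0, EXCLUDED: np.nan}
    for col in STATUS_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(mapping)
    return out


def write_outcome_table(df: pd.DataFrame, path: str | Path) -> None:
    encode_status(df).to_csv(path, index=False)


try:  # sklearn-style wrapper; the functions above are the primitives
    from sklearn.base import BaseEstimator, TransformerMixin

    class OutcomeDeriver(BaseEstimator, TransformerMixin):
        """Transformer mapping (timelines, covariates, phenotypes) to the
        outcome table.  Parameters mirror :class:`OutcomeParams`."""

        def __init__(
            self,
            gap_days: int = 90,
            lookahead_days: int = 180,
            max_short_days: int = 56,
            tolerance_window: int = 30,
            min_control_prescriptions: int = 3,
        ):
            self.gap_days = gap_days
            self.lookahead_days = lookahead_days
            self.max_short_days = max_short_days
            self.tolerance_window = tolerance_window
            self.min_control_prescriptions = min_control_prescriptions

        def _params(self) -> OutcomeParams:
            return OutcomeParams(
                gap_days=self.gap_days,
                lookahead_days=self.lookahead_days,
                max_short_days=self.max_short_days,
                tolerance_window=self.tolerance_window,
                min_control_prescriptions=self.min_control_prescriptions,
            )

        def fit(self, X, y=None):
            self.params_ = self._params()
            return self

        def transform(self, X) -> pd.DataFrame:
            """X is a (timelines, covariates, phenotypes) triple."""
            timelines, covariates, phenotypes = X
            return build_outcome_table(
                timelines, covariates, phenotypes, getattr(self, "params_", self._params())
            )

except ImportError:  # pragma: no cover
    pass
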