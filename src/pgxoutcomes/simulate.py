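"""Synthetic primary-care cohorts with known ground-truth effects.

The generator emulates the five study inputs — per-person CYP2C19
diplotypes, a prescription table, a clinical-event table, side-effect /
drug code lists (shipped as package data) and a covariate table — with
configurable metaboliser-phenotype frequencies, prescription-stream
dynamics and injectable true effect sizes, so that every pipeline stage is
testable end-to-end without access to restricted data.

Generative model, per person and assigned index SSRI:

* A metaboliser phenotype is drawn from the configured frequencies and a
  diplotype consistent with it under the shipped allele table is emitted
  (poor -> *2/*2, intermediate -> *1/*2 or *2/*17, normal -> *1/*1, fast ->
  *1/*17 or *17/*17 split by the configured rapid/ultrarapid proportions),
  so phenotype calling round-trips exactly.
* Treatment intensity is a latent log-normal: ln(count + 1) ~ N(mu_c +
  shift_c(phenotype), sd_c^2), with total window span coupled to the count
  through a mean inter-issue gap of ~28 days (monthly issue convention)
  with log-normal jitter, so ln(weeks + 1) carries its own additive
  phenotype shift.  Gaps are kept strictly below the 90-day window
  threshold so each stream forms a single prescription window.
* Binary events are injected on the latent logistic scale:
  switching (another antidepressant issued 7-29 days after the final index
  issue, with the index stream shaped to satisfy the switch tolerances),
  side effects (a listed clinical-event code 3-28 days after the first
  index issue with no prior same-code event), and — when an explicit
  discontinuation probability is configured — an abrupt-stop stream
  (1-3 issues spanning under 8 weeks, then nothing).  When no explicit
  discontinuation probability is set, short-stream stoppages arise from
  the natural left tail of the duration distribution.
* Effects are specified either as per-phenotype odds ratios (reference =
  normal) or as a log-odds slope per activity-score unit (anchored at the
  normal-metaboliser score of 2.0); duration effects are additive shifts
  on the log scale.

Alongside the record files the generator writes a truth table with the
latent indicators actually drawn and the outcome status each stream was
constructed to express, sufficient to verify parameter recovery and
derived-versus-latent agreement.

Determinism: one global seed; each person uses an independent substream
keyed by (seed, person index), so person-level output is stable when only
``n_persons`` changes, and identical configurations produce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .alleles import AlleleFunctionTable, activity_score, parse_diplotype
from .records import EVENT_COLUMNS, PRESCRIPTION_COLUMNS

EPOCH_2000 = 10957  # days from 1970-01-01 to 2000-01-01

PHENOS = ("poor", "intermediate", "normal", "fast")
SSRIS = ("ssri_citalopram", "ssri_escitalopram", "ssri_sertraline")

SSRI_NAMES = {
    "ssri_citalopram": "Citalopram 20mg tablets",
    "ssri_escitalopram": "Escitalopram 10mg tablets",
    "ssri_sertraline": "Sertraline 50mg tablets",
}
SSRI_DMD = {
    "ssri_citalopram": "321988004",
    "ssri_escitalopram": "321955008",
    "ssri_sertraline": "321962006",
}
SSRI_BNF = {
    "ssri_citalopram": "0403030D0",
    "ssri_escitalopram": "0403030X0",
    "ssri_sertraline": "0403030Q0",
}
SSRI_READ2 = {
    "ssri_citalopram": "da75.",
    "ssri_escitalopram": "da77.",
    "ssri_sertraline": "da76.",
}

OTHER_AD_NAMES = (
    "Mirtazapine 30mg tablets",
    "Venlafaxine 75mg capsules",
    "Amitriptyline 25mg tablets",
    "Fluoxetine 20mg capsules",
)
ANTIPSYCHOTIC_NAMES = ("Quetiapine 100mg tablets", "Olanzapine 5mg tablets")
OTHER_DRUG_NAMES = (
    "Simvastatin 40mg tablets",
    "Omeprazole 20mg capsules",
    "Salbutamol 100micrograms inhaler",
)

UKU_READ2 = [
    "R090.", "R0904", "1B1B.", "R0051", "1BX2.", "R0083", "1B1Q.",
    "19C..", "19E..", "1D14.", "E2781", "R0041", "1B13.", "R0502", "1612.",
]
BACKGROUND_READ2 = ["4K22.", "22A..", "65E..", "9N11.", "246..", "44P.."]


def _zero_effects() -> dict:
    return {p: 1.0 for p in PHENOS}


def _zero_shifts() -> dict:
    return {p: 0.0 for p in PHENOS}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the study conditions: phenotype frequencies 2.7 /
    26.0 / 39.6 / 31.6 percent (poor / intermediate / normal / fast) with
    the fast group split 26.9 / 4.7 into rapid and ultrarapid, 66%
    female, ~80% broad-depression prevalence, per-SSRI assignment
    probabilities proportional to the study's per-drug cohort sizes
    (allowing multi-SSRI persons), a ~28-day inter-issue gap, and null
    effects everywhere.
    """

    n_persons: int = 1000
    seed: int = 0

    phenotype_frequencies: dict = field(
        default_factory=lambda: {
            "poor": 0.027, "intermediate": 0.260, "normal": 0.396, "fast": 0.316,
        }
    )
    rapid_fraction_of_fast: float = 0.269 / 0.316  # remainder is ultrarapid
    intermediate_no_function_fraction: float = 0.9  # *1/*2 vs *2/*17

    #: per-SSRI inclusion probabilities (proportional to study cohort
    #: sizes); persons are resampled until at least one SSRI is assigned.
    ssri_probs: dict = field(
        default_factory=lambda: {
            "ssri_citalopram": 24729 / 33094,
            "ssri_escitalopram": 3012 / 33094,
            "ssri_sertraline": 12544 / 33094,
        }
    )

    # demographics
    female_frac: float = 0.662
    age_mean: float = 55.2
    age_sd: float = 8.1
    broad_depression_prev: float = 0.80

    # prescription-stream dynamics
    log_count_mean: float = 2.5   # ln(count+1) location; mean count ~ 22
    log_count_sd: float = 1.1     # matches the study's duration dispersion
    log_gap_ratio: float = float(np.log(4.0))  # weeks ~ 4 x count (28-day gap)
    gap_jitter_sd: float = 0.15
    max_count: int = 300
    min_gap_days: int = 3
    max_gap_days: int = 83  # strictly below the 90-day window threshold
    #: last day (offset from 2000-01-01) on which prescribing may start;
    #: keeps even extreme streams inside a realistic records period
    horizon_days: int = 12000

    # baseline outcome rates (probability scale, normal metabolisers)
    switch_prob: float = 0.10
    side_effect_prob: float = 0.08
    disc_prob: float | None = None  # None: stoppages emerge from short streams

    # injected true effects: per-phenotype odds ratios (reference normal)
    switch_or: dict = field(default_factory=_zero_effects)
    disc_or: dict = field(default_factory=_zero_effects)
    side_effect_or: dict = field(default_factory=_zero_effects)
    #: additive shifts on ln(duration+1); "count" also propagates to weeks
    count_shift: dict = field(default_factory=_zero_shifts)
    weeks_shift: dict = field(default_factory=_zero_shifts)
    #: optional log-odds slopes per activity-score unit; when set for an
    #: outcome they replace the per-phenotype odds ratios for it
    activity_slopes: dict = field(
        default_factory=lambda: {"switch": None, "disc": None, "side_effect": None}
    )
    activity_anchor: float = 2.0  # normal-metaboliser activity score

    # record-shape nuisance parameters
    censored_frac: float = 0.05
    antipsychotic_frac: float = 0.05
    prior_condition_frac: float = 0.02
    duplicate_frac: float = 0.02
    background_event_rate: float = 2.0
    background_rx_rate: float = 1.0

    def __post_init__(self):
        total = sum(self.phenotype_frequencies.values())
        if not 0.98 < total < 1.02:
            raise ValueError(f"phenotype frequencies sum to {total}, expected ~1")
        self.phenotype_frequencies = {
            k: v / total for k, v in self.phenotype_frequencies.items()
        }
        for name in ("switch_prob", "side_effect_prob"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Bundle:
    """In-memory simulated inputs plus ground truth."""

    diplotypes: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("diplotypes", "prescriptions", "events", "covariates", "truth"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def _days_to_uk(days: pd.Series) -> pd.Series:
    return pd.to_datetime(days, unit="D").dt.strftime("%d/%m/%Y")


def _diplotype_for(phenotype: str, rng: np.random.Generator, cfg: SimulationConfig) -> str:
    if phenotype == "poor":
        return "*2/*2"
    if phenotype == "normal":
        return "*1/*1"
    if phenotype == "intermediate":
        return "*1/*2" if rng.random() < cfg.intermediate_no_function_fraction else "*2/*17"
    if rng.random() < cfg.rapid_fraction_of_fast:
        return "*1/*17"
    return "*17/*17"


def sample_diplotypes(
    n: int, cfg: SimulationConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw a phenotype per person, emit a consistent diplotype.

    Standalone counterpart of the full cohort simulation; phenotype calling
    on the emitted diplotypes reproduces the drawn categories exactly.
    """
    cfg = cfg or SimulationConfig()
    seed = cfg.seed if seed is None else seed
    freqs = [cfg.phenotype_frequencies[p] for p in PHENOS]
    rows = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        pheno = PHENOS[rng.choice(len(PHENOS), p=freqs)]
        rows.append((f"P{i:07d}", _diplotype_for(pheno, rng, cfg), pheno))
    return pd.DataFrame(rows, columns=["person_id", "diplotype", "true_phenotype"])


def _binary_prob(base: float, ors: dict, slope, pheno: str, act: float, cfg) -> float:
    if slope is not None:
        return float(expit(logit(base) + slope * (act - cfg.activity_anchor)))
    return float(expit(logit(base) + np.log(ors.get(pheno, 1.0))))


def simulate_person(i: int, cfg: SimulationConfig, allele_table: AlleleFunctionTable):
    """Generate one person's records and truth rows.

    Returns (diplotype_row, covariate_row, rx_rows, event_rows, truth_rows)
    where record rows are plain tuples in integer-day units; the cohort
    assembler converts dates and builds DataFrames.
    """
    rng = np.random.default_rng([cfg.seed, i])
    pid = f"P{i:07d}"
    freqs = [cfg.phenotype_frequencies[p] for p in PHENOS]
    pheno = PHENOS[rng.choice(len(PHENOS), p=freqs)]
    diplotype = _diplotype_for(pheno, rng, cfg)
    act = activity_score(parse_diplotype(diplotype), allele_table)

    sex = int(rng.random() < cfg.female_frac)  # 1 = female
    batch = "batch_b1" if rng.random() < 0.5 else "batch_b2"
    broad_dep = int(rng.random() < cfg.broad_depression_prev)
    censored = rng.random() < cfg.censored_frac

    # assign at least one SSRI
    names = list(cfg.ssri_probs)
    probs = np.array([cfg.ssri_probs[s] for s in names])
    while True:
        take = rng.random(len(names)) < probs
        if take.any():
            break
    ssris = [s for s, t in zip(names, take) if t]

    rx_rows: list[tuple] = []   # (pid, day, read2, bnf, dmd, name)
    event_rows: list[tuple] = []  # (pid, day, read2, ctv3)
    truth_rows: list[dict] = []

    # first activity between 2000 and ~2005: even the longest streams
    # (max_count monthly issues, ~23 years) then stay well below the
    # future-placeholder cutoff
    t = EPOCH_2000 + int(rng.integers(0, 2000))
    shifts = {
        "count": cfg.count_shift.get(pheno, 0.0),
        "weeks": cfg.weeks_shift.get(pheno, 0.0),
    }

    def emit_rx(day: int, drug_class: str, name_only: bool = False):
        """Append a prescription row; index SSRIs carry one of the four
        coding styles to exercise classification precedence."""
        if drug_class in SSRIS and not name_only:
            style = rng.random()
            if style < 0.70:
                rx_rows.append((pid, day, "", "", "", SSRI_NAMES[drug_class]))
            elif style < 0.80:
                rx_rows.append((pid, day, "", "", SSRI_DMD[drug_class], ""))
            elif style < 0.90:
                rx_rows.append((pid, day, "", SSRI_BNF[drug_class], "", ""))
            else:
                rx_rows.append((pid, day, SSRI_READ2[drug_class], "", "", ""))
        else:
            rx_rows.append((pid, day, "", "", "", drug_class))

    horizon = EPOCH_2000 + cfg.horizon_days
    last_activity = t
    kept_ssris = []
    for seg_idx, ssri in enumerate(ssris):
        if t >= horizon:  # no records period left for further agents
            break
        kept_ssris.append(ssri)
        has_later = True  # provisional; corrected after the loop
        # latent treatment intensity
        u = rng.standard_normal()
        delta = rng.normal(0.0, cfg.gap_jitter_sd)
        y_c = cfg.log_count_mean + shifts["count"] + cfg.log_count_sd * u
        y_w = y_c + cfg.log_gap_ratio + delta + shifts["weeks"]
        n_rx = int(np.clip(np.round(np.exp(y_c) - 1.0), 1, cfg.max_count))

        p_s = _binary_prob(
            cfg.switch_prob, cfg.switch_or, cfg.activity_slopes.get("switch"),
            pheno, act, cfg,
        )
        S = bool(rng.random() < p_s)
        if cfg.disc_prob is not None:
            p_d = _binary_prob(
                cfg.disc_prob, cfg.disc_or, cfg.activity_slopes.get("disc"),
                pheno, act, cfg,
            )
            D = bool(rng.random() < p_d)
        else:
            D = None

        if D:  # explicit abrupt-stop stream; overrides switching
            S = False
            n_rx = int(rng.choice([1, 2, 3], p=[0.4, 0.3, 0.3]))
            span = 0 if n_rx == 1 else int(rng.integers(14, 51))
        else:
            if cfg.disc_prob is not None:
                # explicit mode: keep non-discontinuers clear of the
                # short-stream definition
                n_rx = max(n_rx, 3)
            span = 0 if n_rx == 1 else int(
                np.clip(
                    np.round(7.0 * (np.exp(y_w) - 1.0)),
                    cfg.min_gap_days * (n_rx - 1),
                    cfg.max_gap_days * (n_rx - 1),
                )
            )
            if cfg.disc_prob is not None and n_rx >= 2:
                span = max(span, 60)

        # fit the stream into the remaining records period
        span = min(span, horizon - t)
        if n_rx >= 2 and span < cfg.min_gap_days * (n_rx - 1):
            n_rx = max(1, int(span) // 28 + 1)
        if n_rx == 1:
            span = 0

        days = t + np.round(np.linspace(0.0, span, n_rx)).astype(int)
        first, last = int(days[0]), int(days[-1])
        for d in days:
            emit_rx(int(d), ssri)
        if rng.random() < cfg.duplicate_frac:  # duplicate issue line
            emit_rx(int(rng.choice(days)), ssri)
        last_activity = max(last_activity, last)

        switch_day = None
        if S:
            gap_last = int(days[-1] - days[-2]) if n_rx >= 2 else 999
            lo = max(7, 31 - gap_last)
            switch_day = last + int(rng.integers(lo, 30))
            # never switch onto one of the person's own index SSRIs: their
            # later stream would merge with the switch issues
            ssri_targets = [s for s in SSRIS if s != ssri and s not in ssris]
            if ssri_targets and rng.random() >= 0.6:
                switch_class = str(rng.choice(ssri_targets))
                drug = switch_class
            else:
                drug = str(rng.choice(OTHER_AD_NAMES))
                switch_class = "other_antidepressant"
            n_follow = int(rng.integers(1, 4))
            for k in range(n_follow):
                day = switch_day + 28 * k
                if switch_class in SSRIS:
                    emit_rx(day, switch_class)
                else:
                    rx_rows.append((pid, day, "", "", "", drug))
            last_activity = max(last_activity, switch_day + 28 * (n_follow - 1))

        # side effects
        p_e = _binary_prob(
            cfg.side_effect_prob, cfg.side_effect_or,
            cfg.activity_slopes.get("side_effect"), pheno, act, cfg,
        )
        E = bool(rng.random() < p_e)
        pair_code = None
        if rng.random() < cfg.prior_condition_frac:
            # same code before and after first issue: a pre-existing
            # condition, never a side-effect case
            pair_code = str(rng.choice(UKU_READ2))
            event_rows.append((pid, first - int(rng.integers(5, 26)), pair_code, ""))
            event_rows.append((pid, first + int(rng.integers(5, 26)), pair_code, ""))
        if E:
            codes = [c for c in UKU_READ2 if c != pair_code]
            code = str(rng.choice(codes))
            event_rows.append((pid, first + int(rng.integers(3, 29)), code, ""))

        # antipsychotic co-prescription
        ap_overlap = False
        if rng.random() < cfg.antipsychotic_frac:
            name = str(rng.choice(ANTIPSYCHOTIC_NAMES))
            if last > first and rng.random() < 0.8:
                rx_rows.append((pid, int(rng.integers(first, last + 1)), "", "", "", name))
                ap_overlap = True
            else:
                rx_rows.append((pid, first - int(rng.integers(100, 400)), "", "", "", name))

        truth_rows.append(
            dict(
                person_id=pid, ssri=ssri, phenotype=pheno, activity=act,
                latent_switch=S, latent_disc=D, latent_side_effect=E,
                n_rx=n_rx, span_days=last - first,
                weeks=(last - first) / 7.0,
                has_later_segment=has_later, censored=censored,
                antipsychotic_overlap=ap_overlap,
                first_day=first, last_day=last, switch_day=switch_day,
            )
        )
        seg_end = last_activity
        t = seg_end + int(rng.integers(180, 400))

    for k, tr in enumerate(truth_rows):
        tr["has_later_segment"] = k < len(truth_rows) - 1

    record_start = int(min(r[1] for r in rx_rows)) - int(rng.integers(400, 3000))
    if censored:
        record_end = int(last_activity) + int(rng.integers(10, 150))
    else:
        record_end = int(last_activity) + 180 + int(rng.integers(20, 365))

    # background noise: non-psychotropic prescriptions and non-listed events
    for _ in range(rng.poisson(cfg.background_rx_rate)):
        rx_rows.append(
            (pid, int(rng.integers(record_start, record_end + 1)), "", "", "",
             str(rng.choice(OTHER_DRUG_NAMES)))
        )
    for _ in range(rng.poisson(cfg.background_event_rate)):
        event_rows.append(
            (pid, int(rng.integers(record_start, record_end + 1)),
             str(rng.choice(BACKGROUND_READ2)), "")
        )

    first_year = 1970 + rx_rows[0][1] // 365
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 35, 75))
    yob = int(round(first_year - age))

    # expected derived statuses (the stream's construction intent)
    for tr in truth_rows:
        _expected_statuses(tr, record_start, record_end)

    diplo_row = (pid, diplotype)
    cov_row = (pid, sex, yob, batch, broad_dep, record_start, record_end)
    return diplo_row, cov_row, rx_rows, event_rows, truth_rows


def _expected_statuses(tr: dict, record_start: int, record_end: int) -> None:
    """Outcome statuses the constructed stream should derive to."""
    S, D, E = tr["latent_switch"], tr["latent_disc"], tr["latent_side_effect"]
    n, span = tr["n_rx"], tr["span_days"]
    later = tr["has_later_segment"]
    first, last = tr["first_day"], tr["last_day"]
    lookahead_ok = (record_end - last >= 180) and not later

    if S:
        switch = "case"
    elif later:
        switch = "excluded"
    else:
        switch = "control" if n >= 3 else "excluded"

    if S or later:
        disc1 = disc2 = "excluded"
    else:
        if n == 1:
            disc1 = "case" if lookahead_ok else "excluded"
        else:
            disc1 = "control" if n >= 3 else "excluded"
        if span < 56:
            disc2 = "case" if lookahead_ok else "excluded"
        else:
            disc2 = "control" if n >= 3 else "excluded"

    for w in (30, 60):
        covered = record_start <= first - 30 and record_end >= first + w
        tr[f"expected_side_effect_{w}"] = (
            ("case" if E else "control") if covered else "excluded"
        )
    tr["expected_switch"] = switch
    tr["expected_disc1"] = disc1
    tr["expected_disc2"] = disc2


def simulate_cohort(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> Bundle:
    """Generate a complete input bundle (optionally written to ``outdir``).

    Files use the primary-care dialects expected by
    :mod:`pgxoutcomes.records` with day-first dates; the truth table keeps
    integer day offsets.
    """
    allele_table = AlleleFunctionTable.default()
    diplo, cov, rx, ev, truth = [], [], [], [], []
    for i in range(cfg.n_persons):
        d, c, r, e, t = simulate_person(i, cfg, allele_table)
        diplo.append(d)
        cov.append(c)
        rx.extend(r)
        ev.extend(e)
        truth.extend(t)

    diplotypes = pd.DataFrame(diplo, columns=["person_id", "diplotype"])

    rx_df = pd.DataFrame(
        rx, columns=["eid", "day", "read_2", "bnf_code", "dmd_code", "drug_name"]
    )
    rx_df = rx_df.sort_values(["eid", "day"], kind="stable").reset_index(drop=True)
    prescriptions = pd.DataFrame(
        {
            "eid": rx_df["eid"],
            "data_provider": 1,
            "issue_date": _days_to_uk(rx_df["day"]),
            "read_2": rx_df["read_2"],
            "bnf_code": rx_df["bnf_code"],
            "dmd_code": rx_df["dmd_code"],
            "drug_name": rx_df["drug_name"],
            "quantity": 28,
        }
    )[PRESCRIPTION_COLUMNS]

    ev_df = pd.DataFrame(ev, columns=["eid", "day", "read_2", "read_3"])
    ev_df = ev_df.sort_values(["eid", "day"], kind="stable").reset_index(drop=True)
    events = pd.DataFrame(
        {
            "eid": ev_df["eid"],
            "data_provider": 1,
            "event_dt": _days_to_uk(ev_df["day"]),
            "read_2": ev_df["read_2"],
            "read_3": ev_df["read_3"],
        }
    )[EVENT_COLUMNS]

    cov_df = pd.DataFrame(
        cov,
        columns=[
            "eid", "sex", "year_of_birth", "batch", "broad_depression",
            "record_start_day", "record_end_day",
        ],
    )
    covariates = cov_df.assign(
        record_start=_days_to_uk(cov_df["record_start_day"]),
        record_end=_days_to_uk(cov_df["record_end_day"]),
    ).drop(columns=["record_start_day", "record_end_day"])

    truth_df = pd.DataFrame(truth)

    bundle = Bundle(diplotypes, prescriptions, events, covariates, truth_df)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
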