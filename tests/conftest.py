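import numpy as np
import pandas as pd
import pytest

from pgxoutcomes.alleles import AlleleFunctionTable
from pgxoutcomes.outcomes import PersonTimeline


@pytest.fixture(scope="session")
def allele_table() -> AlleleFunctionTable:
    return AlleleFunctionTable.default()


def make_timeline(
    rx=(),
    events=(),
    record_start=-2000,
    record_end=4000,
    person_id="P1",
) -> PersonTimeline:
    """Build a timeline from (day, drug_class) and (day, code, is_uku)
    tuples; days are plain integers for readability."""
    rx = sorted(rx)
    events = sorted(events)
    return PersonTimeline(
        person_id=person_id,
        rx_days=np.array([d for d, _ in rx], dtype=np.int64),
        rx_class=np.array([c for _, c in rx], dtype=object),
        event_days=np.array([d for d, *_ in events], dtype=np.int64),
        event_codes=np.array([e[1] for e in events], dtype=object),
        event_is_uku=np.array([bool(e[2]) for e in events], dtype=bool),
        record_start=record_start,
        record_end=record_end,
    )


@pytest.fixture
def timeline_factory():
    return make_timeline


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A written synthetic bundle shared by I/O-level tests."""
    from pgxoutcomes.simulate import SimulationConfig, simulate_cohort

    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(n_persons=400, seed=11)
    bundle = simulate_cohort(cfg, outdir)
    return cfg, bundle, outdir
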