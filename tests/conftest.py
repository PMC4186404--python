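import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")

from atrophysignal.report_store import (
    ChallengeCode,
    DrugEntry,
    DrugRole,
    ReportRecord,
    ReportStore,
)


def make_record(
    report_id,
    drugs=("GLIBENCLAMIDE",),
    reactions=("NAUSEA",),
    date="2012-01-01",
    serious=False,
    rechallenge=ChallengeCode.ABSENT,
    dechallenge=ChallengeCode.ABSENT,
    narrative="",
    roles=None,
):
    roles = roles or [DrugRole.PRIMARY_SUSPECT] * len(drugs)
    return ReportRecord(
        report_id=report_id,
        receive_date=date,
        drugs=[DrugEntry(d, r) for d, r in zip(drugs, roles)],
        reactions=set(reactions),
        serious=serious,
        rechallenge_code=rechallenge,
        dechallenge_code=dechallenge,
        narrative=narrative,
    )


@pytest.fixture
def small_store():
    """Six-report corpus: two glibenclamide atrophy cases, assorted others."""
    records = [
        make_record("R1", ("GLIBENCLAMIDE",), ("MUSCLE ATROPHY",)),
        make_record("R2", ("GLYBURIDE", "SIMVASTATIN"), ("MUSCLE ATROPHY", "RASH")),
        make_record("R3", ("GLIBENCLAMIDE",), ("NAUSEA",)),
        make_record("R4", ("METFORMIN",), ("MUSCLE ATROPHY",)),
        make_record("R5", ("METFORMIN",), ("HEADACHE",)),
        make_record("R6", ("ASPIRIN",), ("MUSCLE WEAKNESS",)),
    ]
    return ReportStore(records=records)
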