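from datetime import date

import pytest

from cheilitis_pv.report_store import (
    CaseReport,
    DrugEntry,
    DrugRole,
    Outcome,
    Sex,
)


def make_report(
    case_id,
    drugs=("ISOTRETINOIN",),
    events=("Cheilitis",),
    receipt=date(2020, 6, 1),
    sex=Sex.FEMALE,
    age=40.0,
    weight=70.0,
    version=1,
    onset=None,
    start=None,
    **kw,
):
    entries = []
    for i, d in enumerate(drugs):
        entries.append(
            DrugEntry(
                name=d,
                role=DrugRole.PRIMARY_SUSPECT if i == 0 else DrugRole.CONCOMITANT,
                start_date=start if i == 0 else None,
            )
        )
    return CaseReport(
        case_id=case_id,
        receipt_date=receipt,
        report_version=version,
        sex=sex,
        age_years=age,
        weight_kg=weight,
        drugs=entries,
        events=list(events),
        event_onset_date=onset,
        **kw,
    )


@pytest.fixture
def four_report_corpus():
    """The canonical {D,E}, {D}, {E}, {} corpus (empty cells use fillers)."""
    return [
        make_report("r1", drugs=("D",), events=("E",)),
        make_report("r2", drugs=("D",), events=("X",)),
        make_report("r3", drugs=("Z",), events=("E",)),
        make_report("r4", drugs=("Z",), events=("X",)),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A 4,000-report synthetic corpus with one strong planted pair."""
    from cheilitis_pv.synthetic_data import PlantedPair, SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_reports=4000,
        n_drugs=12,
        n_events=8,
        planted=[PlantedPair(drug="DRUG_001", event="Cheilitis", theta=8.0)],
        seed=20240915,
    )
    return generate(cfg)
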