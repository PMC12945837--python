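from datetime import date

import pytest

from pvscreen import (
    CaseReport,
    DrugEntry,
    MedDRAHierarchy,
    ReactionEntry,
    ReportStore,
)


def make_report(
    rid,
    drugs,
    pts,
    sex="unknown",
    age=None,
    version=1,
    receipt=date(2024, 6, 1),
    serious=False,
    weight=1,
    therapy_start=None,
    onsets=None,
):
    """Terse report builder: drugs is a list of names or (name, role) pairs,
    pts a list of PT names (optionally (pt, onset_date))."""
    drug_entries = tuple(
        DrugEntry(d, "suspect", therapy_start) if isinstance(d, str) else DrugEntry(d[0], d[1], therapy_start)
        for d in drugs
    )
    reactions = []
    for i, p in enumerate(pts):
        onset = onsets[i] if onsets else None
        if isinstance(p, tuple):
            p, onset = p
        reactions.append(ReactionEntry(p, onset))
    return CaseReport(
        report_id=rid,
        case_version=version,
        receipt_date=receipt,
        sex=sex,
        age_years=age,
        serious=serious,
        drugs=drug_entries,
        reactions=tuple(reactions),
        weight=weight,
    )


@pytest.fixture
def tiny_hierarchy():
    return MedDRAHierarchy(
        {
            "headache": "Nervous system disorders",
            "nausea": "Gastrointestinal disorders",
            "rash": "Skin and subcutaneous tissue disorders",
            "fever": "General disorders and administration site conditions",
            "fall": "Injury, poisoning and procedural complications",
        }
    )


@pytest.fixture
def four_report_store():
    """2 target-drug reports with PT 'headache' only; 2 comparator reports
    with 'nausea' only -> a=2, b=0, c=0, d=2."""
    return ReportStore(
        [
            make_report("R1", ["targetol"], ["headache"]),
            make_report("R2", ["targetol"], ["headache"]),
            make_report("R3", ["otherol"], ["nausea"]),
            make_report("R4", ["otherol"], ["nausea"]),
        ]
    )


@pytest.fixture
def mixed_store():
    """A small store with mixed drugs, sexes, ages and PT multiplicity."""
    return ReportStore(
        [
            make_report("M01", ["targetol"], ["headache", "nausea"], sex="female", age=30),
            make_report("M02", ["targetol"], ["headache"], sex="male", age=50),
            make_report("M03", ["targetol", ("adjuvin", "concomitant")], ["rash"], sex="female", age=70),
            make_report("M04", ["targetol"], ["headache", "headache"], sex="female"),
            make_report("M05", ["otherol"], ["headache"], sex="male", age=40),
            make_report("M06", ["otherol"], ["nausea", "rash"], sex="female", age=44.9),
            make_report("M07", ["otherol"], ["fever"], sex="unknown", age=65),
            make_report("M08", ["adjuvin"], ["fall"], sex="male", age=17),
            make_report("M09", ["otherol"], ["nausea"], sex="female", age=45),
            make_report("M10", ["otherol", "adjuvin"], ["fever", "fall"], sex="male"),
        ]
    )
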