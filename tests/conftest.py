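import datetime

import pytest

from metaug.corpus import Patient, Report


def make_report(
    pid: str,
    pos: int,
    impression: str,
    label: int = 0,
    organ: str = "liver",
    date: datetime.date | None = None,
    **kwargs,
) -> Report:
    return Report(
        report_id=f"{pid}-r{pos:02d}",
        patient_id=pid,
        date=date or datetime.date(2015, 1, 1) + datetime.timedelta(days=120 * pos),
        position=pos,
        impression=impression,
        label=label,
        organ=organ,
        **kwargs,
    )


def make_patient(pid: str, impressions_labels, **kwargs) -> Patient:
    reports = [
        make_report(pid, i, imp, lab, **kwargs)
        for i, (imp, lab) in enumerate(impressions_labels)
    ]
    return Patient(pid, reports)


@pytest.fixture
def liver_patient() -> Patient:
    return make_patient(
        "liver-p00000",
        [
            ("Liver is unremarkable without focal lesion. Stable exam.", 0),
            ("New hepatic metastases are identified. Small cyst noted.", 1),
            ("Interval growth of hepatic metastatic lesions seen again.", 1),
        ],
    )
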