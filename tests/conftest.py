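import datetime as dt
from pathlib import Path

import pytest

from faerspv import DrugDictionary, DrugEntry, MedDRADict, SafetyReport


@pytest.fixture
def mock_meddra() -> MedDRADict:
    return MedDRADict(
        {
            "SOMNOLENCE": "NERVOUS SYSTEM DISORDERS",
            "HEADACHE": "NERVOUS SYSTEM DISORDERS",
            "DIZZINESS": "NERVOUS SYSTEM DISORDERS",
            "PRURITUS": "SKIN DISORDERS",
            "URTICARIA": "SKIN DISORDERS",
            "RASH": "SKIN DISORDERS",
            "NAUSEA": "GASTROINTESTINAL DISORDERS",
            "PERICARDITIS": "CARDIAC DISORDERS",
            "NERVOUSNESS": "PSYCHIATRIC DISORDERS",
        },
        version_label="mock",
    )


@pytest.fixture
def drug_dictionary() -> DrugDictionary:
    return DrugDictionary(
        {
            "CETIRIZINE": "cetirizine",
            "ZYRTEC": "cetirizine",
            "REACTINE": "cetirizine",
            "LORATADINE": "loratadine",
            "CLARITIN": "loratadine",
            "CLARITIN-D": "loratadine;pseudoephedrine",
            "LEVOCETIRIZINE": "levocetirizine",
        }
    )


def make_report(
    pid: str,
    caseid: str | None = None,
    date: dt.date = dt.date(2020, 6, 15),
    drugs: list[tuple[str, str]] | None = None,  # (role, name) pairs
    reactions: set[str] | None = None,
    version: int = 1,
    **kwargs,
) -> SafetyReport:
    """Compact SafetyReport factory for unit tests."""
    entries = [
        DrugEntry(seq=i + 1, role=role, verbatim_name=name)
        for i, (role, name) in enumerate(drugs or [("PS", "CETIRIZINE")])
    ]
    return SafetyReport(
        primaryid=pid,
        caseid=caseid or pid,
        case_version=version,
        receipt_date=date,
        drugs=entries,
        reactions=reactions if reactions is not None else {"SOMNOLENCE"},
        **kwargs,
    )


def write_quarter_files(tmpdir: Path, quarter: str = "2019Q3", n_demo: int = 5,
                        n_drug: int = 9, n_reac: int = 12) -> dict[str, Path]:
    """Write a consistent tiny quarter of '$'-delimited tables."""
    suffix = quarter[2:4] + quarter[4:]
    demo_header = "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$wt$wt_cod$occp_cod$reporter_country"
    demo_rows = [
        f"{100 + i}1${100 + i}$1$20190815${30 + i}$YR$F$70$KG$CN$US" for i in range(n_demo)
    ]
    drug_header = "primaryid$drug_seq$role_cod$drugname$prod_ai$route"
    drug_rows = [
        f"{100 + i % n_demo}1${i // n_demo + 1}$PS$CETIRIZINE$CETIRIZINE$ORAL" for i in range(n_drug)
    ]
    reac_header = "primaryid$pt"
    pts = ["SOMNOLENCE", "PRURITUS", "HEADACHE"]
    reac_rows = [f"{100 + i % n_demo}1${pts[i % 3]}" for i in range(n_reac)]
    paths = {}
    for table, header, rows in (
        ("DEMO", demo_header, demo_rows),
        ("DRUG", drug_header, drug_rows),
        ("REAC", reac_header, reac_rows),
    ):
        p = tmpdir / f"{table}{suffix}.txt"
        p.write_text("\n".join([header] + rows) + "\n")
        paths[table] = p
    return paths
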