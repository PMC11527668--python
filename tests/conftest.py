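from __future__ import annotations

import pandas as pd
import pytest

from pvsignal.dictionary import DrugDictionary, PTQuerySet
from pvsignal.io import SRSDataset, TABLE_COLUMNS, TABLE_KINDS


def make_dataset(demo=None, drug=None, reac=None, outc=None, rpsr=None,
                 ther=None, indi=None, deduplicated=True) -> SRSDataset:
    """Build a dataset from lists of row dicts, defaulting absent tables to empty."""
    given = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
             "rpsr": rpsr, "ther": ther, "indi": indi}
    tables = {}
    for kind in TABLE_KINDS:
        rows = given[kind]
        if rows:
            df = pd.DataFrame(rows).astype(str)
            for col in TABLE_COLUMNS[kind]:
                if col not in df.columns:
                    df[col] = ""
            tables[kind] = df[TABLE_COLUMNS[kind]]
        else:
            tables[kind] = pd.DataFrame(columns=TABLE_COLUMNS[kind], dtype=str)
    return SRSDataset(**tables, meta={"source": "fixture",
                                      "deduplicated": deduplicated})


@pytest.fixture
def parp_dictionary() -> DrugDictionary:
    return DrugDictionary.default_parp()


@pytest.fixture
def renal_pts() -> PTQuerySet:
    return PTQuerySet.default_renal()


@pytest.fixture
def toy_dataset() -> SRSDataset:
    """Ten reports with hand-known drug/event structure.

    Reports 1-3: PS Niraparib + renal PT (a-cell).
    Reports 4-5: PS Niraparib, no renal PT (c-cell).
    Report 6: other drug + renal PT (b-cell).
    Reports 7-10: other drug, other PT (d-cell).
    Report 2 also carries a concomitant Olaparib row (role C).
    """
    demo = [dict(primaryid=str(i), caseid=f"C{i}", fda_dt="20220115",
                 event_dt="20220110", age="70", age_cod="YR", sex="F",
                 reporter_country="US") for i in range(1, 11)]
    drug = []
    for i in range(1, 6):
        drug.append(dict(primaryid=str(i), drug_seq="1", role_cod="PS",
                         drugname="ZEJULA", prod_ai="NIRAPARIB"))
    drug.append(dict(primaryid="2", drug_seq="2", role_cod="C",
                     drugname="LYNPARZA", prod_ai="OLAPARIB"))
    for i in range(6, 11):
        drug.append(dict(primaryid=str(i), drug_seq="1", role_cod="PS",
                         drugname="CARBOPLATIN", prod_ai="CARBOPLATIN"))
    reac = []
    for i in (1, 2, 3, 6):
        reac.append(dict(primaryid=str(i), pt="Acute kidney injury"))
    for i in (4, 5, 7, 8, 9, 10):
        reac.append(dict(primaryid=str(i), pt="Nausea"))
    ther = [dict(primaryid=str(i), dsg_drug_seq="1", start_dt="20220101",
                 end_dt="") for i in range(1, 11)]
    outc = [dict(primaryid="1", outc_cod="HO"),
            dict(primaryid="2", outc_cod="HO"), dict(primaryid="2", outc_cod="DE"),
            dict(primaryid="3", outc_cod="OT")]
    return make_dataset(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc)
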