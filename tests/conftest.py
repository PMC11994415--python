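import pandas as pd
import pytest

from faersig.io import OPTIONAL_COLUMNS, REQUIRED_COLUMNS, QuarterlyArchive


def make_table(kind: str, rows: list[dict]) -> pd.DataFrame:
    """All-string table of the given kind with canonical columns."""
    cols = list(REQUIRED_COLUMNS[kind] + OPTIONAL_COLUMNS[kind])
    frame = pd.DataFrame(rows, columns=cols, dtype=str).fillna("")
    return frame.astype(str)


def make_archive(quarter: str = "2023Q1", **tables: list[dict]) -> QuarterlyArchive:
    return QuarterlyArchive(
        quarter_label=quarter,
        tables={kind: make_table(kind, rows) for kind, rows in tables.items()},
    )


@pytest.fixture
def tiny_archive() -> QuarterlyArchive:
    """Five reports; the target drug RIPRETINIB is PS in 11/12/13, concomitant
    in 14 and absent from 15.  Report 13 is a brand-name row matched via
    PROD_AI, and reports 11/21 share CASEID 1 (21 is the later revision)."""
    return make_archive(
        demo=[
            dict(primaryid="11", caseid="1", fda_dt="20230110", event_dt="20230105",
                 age="60", age_cod="YR", sex="M", occp_cod="MD", reporter_country="US"),
            dict(primaryid="21", caseid="1", fda_dt="20230301", event_dt="20230105",
                 age="60", age_cod="YR", sex="M", occp_cod="MD", reporter_country="US"),
            dict(primaryid="12", caseid="2", fda_dt="20230215", event_dt="202301",
                 age="", age_cod="", sex="F", occp_cod="CN", reporter_country="US"),
            dict(primaryid="13", caseid="3", fda_dt="20230330", event_dt="20230220",
                 age="70", age_cod="YR", sex="F", occp_cod="PH", reporter_country="FR"),
            dict(primaryid="14", caseid="4", fda_dt="20230401", event_dt="20230301",
                 age="55", age_cod="YR", sex="M", occp_cod="CN", reporter_country="US"),
            dict(primaryid="15", caseid="5", fda_dt="20230410", event_dt="",
                 age="", age_cod="", sex="", occp_cod="", reporter_country="US"),
        ],
        drug=[
            dict(primaryid="11", drug_seq="1", role_cod="PS", drugname="RIPRETINIB.", prod_ai="RIPRETINIB"),
            dict(primaryid="21", drug_seq="1", role_cod="PS", drugname="RIPRETINIB", prod_ai="RIPRETINIB"),
            dict(primaryid="12", drug_seq="1", role_cod="PS", drugname="RIPRETINIB", prod_ai="RIPRETINIB"),
            dict(primaryid="13", drug_seq="1", role_cod="PS", drugname="QINLOCK", prod_ai="ripretinib"),
            dict(primaryid="13", drug_seq="2", role_cod="C", drugname="IMATINIB", prod_ai="IMATINIB"),
            dict(primaryid="14", drug_seq="1", role_cod="C", drugname="RIPRETINIB", prod_ai="RIPRETINIB"),
            dict(primaryid="14", drug_seq="2", role_cod="PS", drugname="IMATINIB", prod_ai="IMATINIB"),
            dict(primaryid="15", drug_seq="1", role_cod="PS", drugname="SUNITINIB", prod_ai="SUNITINIB"),
        ],
        reac=[
            dict(primaryid="11", pt="Alopecia"),
            dict(primaryid="11", pt="ALOPECIA"),  # repeated PT: counted once
            dict(primaryid="11", pt="Muscle spasms"),
            dict(primaryid="21", pt="Alopecia"),
            dict(primaryid="21", pt="Muscle spasms"),
            dict(primaryid="12", pt="Nausea"),
            dict(primaryid="13", pt="Dry skin"),
            dict(primaryid="13", pt="Alopecia"),
            dict(primaryid="14", pt="Fatigue"),
            dict(primaryid="15", pt="Nausea"),
        ],
        outc=[
            dict(primaryid="21", outc_cod="HO"),
            dict(primaryid="21", outc_cod="DE"),
            dict(primaryid="13", outc_cod="OT"),
        ],
        rpsr=[dict(primaryid="11", rpsr_cod="HP")],
        ther=[
            dict(primaryid="11", dsg_drug_seq="1", start_dt="20230101"),
            dict(primaryid="21", dsg_drug_seq="1", start_dt="20230101"),
            dict(primaryid="12", dsg_drug_seq="1", start_dt="202212"),
            dict(primaryid="13", dsg_drug_seq="1", start_dt="20230201"),
            dict(primaryid="13", dsg_drug_seq="2", start_dt="20220101"),
        ],
        indi=[
            dict(primaryid="11", indi_drug_seq="1", indi_pt="Gastrointestinal stromal tumour"),
            dict(primaryid="21", indi_drug_seq="1", indi_pt="Gastrointestinal stromal tumour"),
            dict(primaryid="13", indi_drug_seq="1", indi_pt="Gastric cancer"),
            dict(primaryid="13", indi_drug_seq="2", indi_pt="Hypertension"),
        ],
    )


@pytest.fixture
def tiny_tables(tiny_archive):
    return tiny_archive.tables
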