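import numpy as np
import pandas as pd
import pytest

from faersig import synthetic as syn
from faersig.cohort import match_target_drug
from faersig.dedup import deduplicate
from faersig.io import TABLE_KINDS


def small(**kw):
    defaults = dict(n_reports=800, quarters=("2023Q1",), seed=5)
    defaults.update(kw)
    return syn.SyntheticConfig(**defaults)


class TestConfig:
    def test_bad_quarter_label(self):
        with pytest.raises(ValueError):
            small(quarters=("2023Q7",))

    def test_planted_pt_must_be_in_vocabulary(self):
        with pytest.raises(ValueError, match="missing from the PT->SOC"):
            small(planted=(syn.PlantedAssociation("RIPRETINIB", "NotAPT", 5.0, 0.01),))

    def test_saturation_warns(self):
        with pytest.warns(UserWarning, match="saturates"):
            small(planted=(syn.PlantedAssociation("RIPRETINIB", "Alopecia", 300.0, 0.01),))

    def test_duplicate_rate_range(self):
        with pytest.raises(ValueError):
            small(duplicate_rate=1.0)


class TestDeterminism:
    def test_same_seed_identical_frames(self):
        a1 = syn.generate_archives(small())
        a2 = syn.generate_archives(small())
        for x, y in zip(a1, a2):
            for kind in TABLE_KINDS:
                pd.testing.assert_frame_equal(x.tables[kind], y.tables[kind])

    def test_same_seed_identical_files(self, tmp_path):
        syn.generate(small(), tmp_path / "a")
        syn.generate(small(), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seed_differs(self):
        a1 = syn.generate_archives(small(seed=1))
        a2 = syn.generate_archives(small(seed=2))
        assert not a1[0].demo.equals(a2[0].demo)


class TestDuplicates:
    def test_duplicate_injection_and_dedup_keeps_later(self):
        cfg = small(n_reports=1000, duplicate_rate=0.1)
        (archive,) = syn.generate_archives(cfg)
        demo = archive.demo
        assert len(demo) == 1100
        counts = demo["caseid"].value_counts()
        assert (counts == 2).sum() == 100  # ~10% of caseids re-emitted

        res = deduplicate(demo)
        assert res.n_kept == 1000
        # the kept copy of every duplicated case is the later re-emission
        dup_cases = set(counts[counts == 2].index)
        kept = demo[demo["primaryid"].astype(int).isin(res.kept_primaryids)]
        kept_dup = kept[kept["caseid"].isin(dup_cases)]
        assert (kept_dup["primaryid"].astype(int) % 100 == 2).all()


class TestGroundTruth:
    def test_expected_cell_arithmetic(self):
        cfg = small(
            n_reports=10_000, target_share=0.05,
            planted=(syn.PlantedAssociation("RIPRETINIB", "Alopecia", 10.0, 0.01),),
        )
        gt = syn.ground_truth(cfg)
        assert gt.loc[0, "expected_a"] == pytest.approx(50.0)
        assert gt.loc[0, "expected_c"] == pytest.approx(95.0)

    def test_observed_a_concentrates_around_expectation(self):
        cfg = small(
            n_reports=10_000, target_share=0.05, duplicate_rate=0.0, seed=3,
            planted=(syn.PlantedAssociation("RIPRETINIB", "Alopecia", 10.0, 0.01),),
        )
        (archive,) = syn.generate_archives(cfg)
        target_pids = {p for p, _ in match_target_drug(archive.drug, cfg.synonyms)}
        reac = archive.reac
        a = reac[(reac["pt"] == "Alopecia")
                 & reac["primaryid"].astype(int).isin(target_pids)]["primaryid"].nunique()
        e_a = syn.ground_truth(cfg).loc[0, "expected_a"]
        assert abs(a - e_a) <= 4 * np.sqrt(e_a)


class TestStructure:
    def test_tables_link_by_primaryid(self):
        (archive,) = syn.generate_archives(small())
        demo_ids = set(archive.demo["primaryid"])
        for kind in ("drug", "reac", "outc", "rpsr", "ther", "indi"):
            assert set(archive.tables[kind]["primaryid"]) <= demo_ids

    def test_pt_count_range(self):
        cfg = small()
        (archive,) = syn.generate_archives(cfg)
        per_report = archive.reac.groupby("primaryid")["pt"].count()
        assert per_report.min() >= cfg.bg_pts_min
        assert per_report.max() <= cfg.bg_pts_max + len(cfg.planted)

    def test_brand_rows_carry_generic_prod_ai(self):
        (archive,) = syn.generate_archives(small(n_reports=2000, target_share=0.2))
        brand = archive.drug[archive.drug["drugname"] == "QINLOCK"]
        assert len(brand) > 0
        assert (brand["prod_ai"] == "RIPRETINIB").all()

    def test_output_files(self, tmp_path):
        syn.generate(small(), tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {"DEMO23Q1.txt", "DRUG23Q1.txt", "REAC23Q1.txt", "OUTC23Q1.txt",
                "RPSR23Q1.txt", "THER23Q1.txt", "INDI23Q1.txt",
                "pt_soc.tsv", "ground_truth.tsv"} <= names
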