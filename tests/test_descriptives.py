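"""Descriptive summaries, percent reconstruction, trend, top-K, pipeline."""

import datetime as dt

import numpy as np
import pytest
import yaml
from pathlib import Path

from faerspv import (
    Cohort,
    build_cohort,
    categorical_percents,
    deduplicate,
    generate,
    recompute_reference_percents,
    standardize_drugs,
    summarize_demographics,
    top_k,
    yearly_trend,
)
from faerspv.descriptives import PipelineError, run_pipeline
from faerspv.synthetic_faers import SyntheticConfig

from conftest import make_report

CONFIGS = Path(__file__).resolve().parent.parent / "configs"


class TestPercentReconstruction:
    def test_every_reference_percent_recomputes_exactly(self):
        df = recompute_reference_percents()
        mismatches = df[df.percent_printed != df.percent_recomputed]
        assert mismatches.empty, mismatches.to_string()

    def test_female_share_example(self):
        rows = categorical_percents({"Female": 14250, "Male": 7505, "Unknown": 6296})
        assert rows[0] == ("Female", 14250, 50.80)

    def test_outcome_denominator_is_occurrence_sum(self):
        counts = {"Other serious": 6735, "Hospitalization": 2057, "Disability": 468,
                  "Life threatening": 468, "Death": 337, "Congenital anomaly": 189,
                  "Permanent impairment/damage": 38}
        rows = dict((l, p) for l, _, p in categorical_percents(counts))
        assert rows["Other serious"] == 65.44


class TestDemographics:
    def test_single_report_quartiles_collapse(self):
        cohort = Cohort("x", [make_report("1", age_years=40.0)], [])
        s = summarize_demographics(cohort)
        assert s.age_median == s.age_q1 == s.age_q3 == 40.0

    def test_outcomes_counted_once_per_report_per_code(self):
        reports = [
            make_report("1", outcomes={"HO", "DE"}),
            make_report("2", outcomes={"HO"}),
        ]
        s = summarize_demographics(Cohort("x", reports, []))
        block = dict((l, (c, p)) for l, c, p in s.blocks["outcomes"])
        assert block["Hospitalization"] == (2, 66.67)
        assert block["Death"] == (1, 33.33)

    def test_empty_cohort_summary_of_zeros(self):
        s = summarize_demographics(Cohort("x", [], []))
        assert s.n == 0 and s.age_median is None
        assert all(p == 0.0 for _, _, p in s.blocks["sex"])

    def test_emitted_percents_recompute_from_counts(self):
        reports, _ = generate(SyntheticConfig(n_reports=2000, seed=14))
        cohort = Cohort("x", reports, [])
        s = summarize_demographics(cohort)
        for block, rows in s.blocks.items():
            den = sum(c for _, c, _ in rows)
            for _, c, p in rows:
                assert abs(p - 100.0 * c / den) < 0.005


class TestTrend:
    def test_single_year_cohort(self):
        cohort = Cohort("x", [make_report(str(i), date=dt.date(2020, 3, 1)) for i in range(5)], [])
        trend = yearly_trend({"x": cohort})
        assert trend.loc[2020, "x"] == 5 and trend.shape[0] == 1

    def test_empty_cohort_all_zero(self):
        trend = yearly_trend({"x": Cohort("x", [], [])}, years=range(2004, 2006))
        assert (trend["x"] == 0).all()

    def test_uniform_dates_within_poisson_bands(self):
        reports, _ = generate(SyntheticConfig(n_reports=4000, seed=15, missingness={}))
        trend = yearly_trend({"x": Cohort("x", reports, [])})
        assert trend.index.min() == 2004 and trend.index.max() == 2023
        mean = 4000 / 20
        # 99.9% Poisson band around n/20
        lo, hi = mean - 3.3 * np.sqrt(mean), mean + 3.3 * np.sqrt(mean)
        assert ((trend["x"] >= lo) & (trend["x"] <= hi)).all()


class TestTopK:
    def _cohort(self, drug_dictionary):
        reports = []
        for i in range(10):
            drugs = [("PS", "ZYRTEC")]
            drugs.append(("C", "METFORMIN" if i < 3 else "ASPIRIN"))
            r = make_report(str(i), drugs=drugs)
            r.drugs[0].indications = {"ALLERGY"} if i < 6 else {"URTICARIA"}
            reports.append(r)
        return build_cohort(standardize_drugs(reports, drug_dictionary), "cetirizine",
                            dictionary=drug_dictionary)

    def test_concomitant_share_uses_reports_with_concomitants(self, drug_dictionary):
        df = top_k(self._cohort(drug_dictionary), "concomitants", k=5)
        row = df[df.label == "METFORMIN"].iloc[0]
        assert (row.n, row.percent) == (3, 30.00)

    def test_indications_attached_to_target_drug(self, drug_dictionary):
        df = top_k(self._cohort(drug_dictionary), "indications", k=5)
        assert df.iloc[0].label == "ALLERGY" and df.iloc[0].n == 6

    def test_k_larger_than_vocabulary_returns_all(self, drug_dictionary):
        df = top_k(self._cohort(drug_dictionary), "concomitants", k=50)
        assert len(df) == 2

    def test_tie_at_rank_k_broken_alphabetically(self):
        rows = categorical_percents({"B": 5, "A": 5, "C": 9})
        assert [r[0] for r in rows] == ["C", "A", "B"]


class TestPipeline:
    def test_demo_scenario_flags_planted_signals(self, tmp_path):
        cfg = yaml.safe_load((CONFIGS / "demo.yaml").read_text())
        artifacts = run_pipeline(cfg, tmp_path / "out")
        sig = artifacts["signals_cetirizine_PT"]
        flagged = set(sig[sig.is_signal].event)
        assert {"SOMNOLENCE", "PERICARDITIS"} <= flagged
        sig_b = artifacts["signals_loratadine_PT"]
        assert "SNEEZING" in set(sig_b[sig_b.is_signal].event)
        assert (tmp_path / "out" / "provenance.txt").exists()
        assert (tmp_path / "out" / "comparison_PT.csv").exists()

    def test_rerun_same_seed_byte_identical(self, tmp_path):
        cfg = yaml.safe_load((CONFIGS / "demo.yaml").read_text())
        cfg["simulate"]["n_reports"] = 3000
        run_pipeline(cfg, tmp_path / "a", seed=5)
        run_pipeline(cfg, tmp_path / "b", seed=5)
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files_a == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name

    def test_missing_meddra_file_aborts_naming_path(self, tmp_path):
        cfg = {
            "input": {},
            "meddra": str(tmp_path / "nope.csv"),
            "drug_dictionary": str(tmp_path / "drugs.csv"),
            "targets": ["cetirizine"],
        }
        with pytest.raises(PipelineError, match="nope.csv"):
            run_pipeline(cfg, tmp_path / "out")

    def test_provenance_counts_non_increasing(self, tmp_path):
        cfg = yaml.safe_load((CONFIGS / "demo.yaml").read_text())
        cfg["simulate"]["n_reports"] = 3000
        artifacts = run_pipeline(cfg, tmp_path / "out", seed=3)
        for cohort in artifacts["cohorts"].values():
            p = cohort.provenance
            assert p["total"] >= p["target_match"] >= p["after_exclusion"]
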