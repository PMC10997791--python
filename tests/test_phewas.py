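"""Stratified PheWAS engine: case rule, filters, regressions, pairing."""

import numpy as np
import pandas as pd
import pytest

from hetfdr.phewas import (
    CohortTable,
    PhenotypeCatalog,
    aggregate_lab,
    case_matrix,
    define_case_status,
    filter_phenotypes,
    fit_binary_association,
    fit_lab_association,
    run_stratified_phewas,
)
from hetfdr.simulate import make_effect_plan, simulate_cohort


def simple_stratum(rng, n=5000, ancestry="EUR", maf=0.4):
    return pd.DataFrame(
        {
            "subject_id": [f"{ancestry}{i}" for i in range(n)],
            "ancestry": ancestry,
            "dosage": rng.binomial(2, maf, n),
            "age": rng.normal(60, 12, n),
            "sex": rng.binomial(1, 0.9, n),
            "followup": np.abs(rng.normal(12, 5, n)) + 0.1,
            "code_total": rng.integers(5, 200, n),
        }
    )


class TestCaseDefinition:
    @pytest.mark.parametrize("count,expected", [(0, 0), (1, 0), (2, 1), (7, 1)])
    def test_at_least_two_codes_rule(self, count, expected):
        assert define_case_status(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            define_case_status(-1)


class TestFilterPhenotypes:
    @staticmethod
    def _cases(prevalences, n=1000):
        rng = np.random.default_rng(0)
        data = {}
        for code, prev in prevalences.items():
            k = int(round(prev * n))
            col = np.zeros(n, dtype=int)
            col[rng.choice(n, k, replace=False)] = 1
            data[code] = col
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(data, index=ids), ids

    def test_prevalence_boundary(self):
        cases, ids = self._cases({"100.1": 0.004, "100.2": 0.006, "100.3": 0.005})
        catalog = PhenotypeCatalog(phecodes=("100.1", "100.2", "100.3"))
        kept = filter_phenotypes(catalog, cases, ids)
        assert kept == ["100.2"]  # 0.5% or less is excluded, strictly above kept

    def test_parent_dropped_when_descendant_retained(self):
        cases, ids = self._cases({"250": 0.2, "250.1": 0.1, "250.2": 0.05, "495": 0.1})
        catalog = PhenotypeCatalog(phecodes=("250", "250.1", "250.2", "495"))
        kept = filter_phenotypes(catalog, cases, ids)
        assert "250" not in kept
        assert kept == ["250.1", "250.2", "495"]  # integer code w/o descendants kept

    def test_parent_kept_when_descendants_all_rare(self):
        cases, ids = self._cases({"250": 0.2, "250.1": 0.001})
        catalog = PhenotypeCatalog(phecodes=("250", "250.1"))
        assert filter_phenotypes(catalog, cases, ids) == ["250"]

    def test_empty_stratum_rejected(self):
        cases, _ = self._cases({"250": 0.2})
        with pytest.raises(ValueError, match="empty"):
            filter_phenotypes(PhenotypeCatalog(phecodes=("250",)), cases, [])

    def test_idempotent(self):
        cases, ids = self._cases({"250": 0.2, "250.1": 0.1, "300": 0.004})
        catalog = PhenotypeCatalog(phecodes=("250", "250.1", "300"))
        kept = filter_phenotypes(catalog, cases, ids)
        catalog2 = PhenotypeCatalog(phecodes=tuple(kept))
        assert filter_phenotypes(catalog2, cases, ids) == kept


class TestAggregateLab:
    @pytest.mark.parametrize(
        "values,expected", [((1, 2, 9), 2.0), ((1, 3), 2.0), ((5,), 5.0)]
    )
    def test_median_conventions(self, values, expected):
        assert aggregate_lab(values) == expected

    def test_empty_excluded(self):
        with pytest.raises(ValueError, match="excluded"):
            aggregate_lab([])


class TestBinaryAssociation:
    def test_parameter_recovery(self):
        """Planted log-OR 0.3 recovered within 3 SE at n = 5000."""
        rng = np.random.default_rng(42)
        stratum = simple_stratum(rng)
        eta = -2.0 + 0.3 * stratum["dosage"] + 0.01 * (stratum["age"] - 60)
        case = rng.random(len(stratum)) < 1 / (1 + np.exp(-eta))
        assoc = fit_binary_association(stratum, case.astype(int), "x")
        assert assoc is not None
        assert abs(assoc.beta - 0.3) < 3 * assoc.se

    def test_null_z_calibration(self):
        """Permuted dosage: z-scores are standard-normal-like across strata."""
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(200):
            stratum = simple_stratum(rng, n=1200)
            case = rng.random(1200) < 0.15
            assoc = fit_binary_association(stratum, case.astype(int), "null")
            zs.append(assoc.beta / assoc.se)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.2
        assert 0.7 < zs.var() < 1.3

    def test_all_control_skipped(self):
        rng = np.random.default_rng(1)
        stratum = simple_stratum(rng, n=500)
        assert fit_binary_association(stratum, np.zeros(500), "x") is None

    def test_constant_sex_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        stratum = simple_stratum(rng, n=2000)
        stratum["sex"] = 1
        case = rng.random(2000) < 0.2
        with pytest.warns(UserWarning, match="sex"):
            assoc = fit_binary_association(stratum, case.astype(int), "x")
        assert assoc is not None


class TestLabAssociation:
    @staticmethod
    def _lab_values(stratum, rng, effect=0.05, sd=0.3):
        log_val = 1.0 + effect * stratum["dosage"].to_numpy() + rng.normal(0, sd, len(stratum))
        return pd.Series(np.exp(log_val), index=stratum["subject_id"])

    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        stratum = simple_stratum(rng)
        values = self._lab_values(stratum, rng)
        assoc = fit_lab_association(stratum, values, "alt")
        assert abs(assoc.beta - 0.05) < 3 * assoc.se

    def test_scale_invariance(self):
        """Doubling every measurement only shifts the intercept."""
        rng = np.random.default_rng(9)
        stratum = simple_stratum(rng, n=800)
        values = self._lab_values(stratum, rng)
        a1 = fit_lab_association(stratum, values, "alt")
        a2 = fit_lab_association(stratum, 2.0 * values, "alt")
        assert a1.beta == pytest.approx(a2.beta, abs=1e-10)

    def test_constant_dosage_skipped(self):
        rng = np.random.default_rng(10)
        stratum = simple_stratum(rng, n=200)
        stratum["dosage"] = 1
        assert fit_lab_association(stratum, self._lab_values(stratum, rng), "alt") is None

    def test_too_few_subjects_skipped(self):
        rng = np.random.default_rng(11)
        stratum = simple_stratum(rng, n=200)
        values = self._lab_values(stratum, rng).iloc[:20]
        assert fit_lab_association(stratum, values, "alt") is None


class TestRunStratifiedPhewas:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        plan = make_effect_plan(
            n_binary=30, n_lab=6, n_active_binary=6, n_het_binary=3,
            n_active_lab=2, n_het_lab=1, n_rare=2, seed=5,
        )
        return simulate_cohort({"AFR": 1500, "EUR": 6000}, plan=plan, seed=5), plan

    def test_bookkeeping_against_manifest(self, small_cohort):
        """Paired records = phenotypes surviving filters/fits in both strata."""
        cohort, plan = small_cohort
        result = run_stratified_phewas(cohort)
        tested = {r.phenotype_id for r in result.records}
        planted = {p.name for p in plan}
        assert tested <= planted
        # rare codes (planted prevalence below the 0.5% floor) never survive
        rare = {
            p.name for p in plan
            if p.kind == "binary" and 1 / (1 + np.exp(-p.base)) <= 0.005
        }
        assert rare and not (tested & rare)
        # every tested phenotype appears exactly once and has both strata
        assert len(tested) == len(result.records)
        for r in result.records:
            assert {r.assoc_a.group_id, r.assoc_b.group_id} == {"AFR", "EUR"}

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        r1 = run_stratified_phewas(cohort)
        r2 = run_stratified_phewas(cohort)
        assert [(r.phenotype_id, r.assoc_a.beta, r.assoc_b.beta) for r in r1.records] == [
            (r.phenotype_id, r.assoc_a.beta, r.assoc_b.beta) for r in r2.records
        ]

    def test_requires_two_strata(self, small_cohort):
        cohort, _ = small_cohort
        single = CohortTable(
            subjects=cohort.subjects[cohort.subjects["ancestry"] == "EUR"],
            phecode_counts=cohort.phecode_counts,
            labs=cohort.labs,
        )
        with pytest.raises(ValueError, match="two ancestry strata"):
            run_stratified_phewas(single)


def test_case_matrix_counts_sum_per_subject():
    subjects = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "ancestry": ["AFR", "AFR", "EUR"],
            "dosage": [0, 1, 2],
            "age": [50.0, 60.0, 70.0],
            "sex": [1, 0, 1],
            "followup": [5.0, 10.0, 15.0],
            "code_total": [10, 20, 30],
        }
    )
    counts = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "c"],
            "phecode": ["250.1", "250.1", "250.1", "300"],
            "count": [1, 1, 1, 4],
        }
    )
    cohort = CohortTable(subjects, counts, pd.DataFrame(columns=["subject_id", "lab", "value"]))
    cases = case_matrix(cohort)
    assert cases.loc["a", "250.1"] == 1  # two single mentions sum to a case
    assert cases.loc["b", "250.1"] == 0
    assert cases.loc["c", "300"] == 1
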