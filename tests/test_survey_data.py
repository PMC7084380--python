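"""Clinical outcome derivation, aggregation and survey I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from msprev import (
    OUTCOMES,
    ValidationError,
    aggregate_to_province,
    derive_outcomes,
    descriptive_statistics,
    read_province_table,
    read_survey_table,
    write_province_table,
    write_survey_table,
)
from msprev.survey_data import two_proportion_pvalue

from conftest import make_individual


K_IDX = {o: k for k, o in enumerate(OUTCOMES)}


class TestDeriveOutcomes:
    @pytest.mark.parametrize(
        "clinical, outcome, expected",
        [
            # diabetes: glucose >= 126 OR self-report
            (dict(fasting_glucose=126.0, self_report_diabetes=0), "diabetes", 1),
            (dict(fasting_glucose=125.9, self_report_diabetes=0), "diabetes", 0),
            (dict(fasting_glucose=100.0, self_report_diabetes=1), "diabetes", 1),
            (dict(fasting_glucose=None, self_report_diabetes=1), "diabetes", 1),
            # obesity: BMI >= 30 (boundary included)
            (dict(bmi=30.0), "obesity", 1),
            (dict(bmi=29.9), "obesity", 0),
            # hypertension: SBP >= 140 OR DBP >= 90 OR treatment
            (dict(sbp=139.0, dbp=90.0, hta_treatment=0), "hypertension", 1),
            (dict(sbp=140.0, dbp=60.0, hta_treatment=0), "hypertension", 1),
            (dict(sbp=139.0, dbp=89.0, hta_treatment=1), "hypertension", 1),
            (dict(sbp=139.0, dbp=89.0, hta_treatment=0), "hypertension", 0),
            # LDL: strict ">" against CVR-dependent cutoff
            (dict(ldl=150.0, cvr_category="moderate_cvr"), "elevated_ldl", 1),
            (dict(ldl=150.0, cvr_category="low_cvr"), "elevated_ldl", 0),
            (dict(ldl=130.0, cvr_category="moderate_cvr"), "elevated_ldl", 0),
            (dict(ldl=101.0, cvr_category="existing_cvd"), "elevated_ldl", 1),
        ],
    )
    def test_case_definitions(self, clinical, outcome, expected):
        ov = derive_outcomes(make_individual(**clinical))
        k = K_IDX[outcome]
        assert ov.observed_mask[k]
        assert ov.y[k] == expected

    @pytest.mark.parametrize(
        "clinical, outcome",
        [
            # failed observed arm + missing arm -> cannot determine
            (dict(fasting_glucose=100.0, self_report_diabetes=None), "diabetes"),
            (dict(fasting_glucose=None, self_report_diabetes=0), "diabetes"),
            (dict(bmi=None), "obesity"),
            (dict(sbp=120.0, dbp=None, hta_treatment=0), "hypertension"),
            # LDL in the category-dependent band with CVR missing
            (dict(ldl=150.0, cvr_category=None), "elevated_ldl"),
            (dict(ldl=None), "elevated_ldl"),
        ],
    )
    def test_missing_arm_masks(self, clinical, outcome):
        ov = derive_outcomes(make_individual(**clinical))
        assert not ov.observed_mask[K_IDX[outcome]]

    def test_ldl_determined_despite_missing_cvr(self):
        # above every cutoff, or below every cutoff, CVR is irrelevant
        high = derive_outcomes(make_individual(ldl=170.0, cvr_category=None))
        low = derive_outcomes(make_individual(ldl=95.0, cvr_category=None))
        assert high.observed_mask[3] and high.y[3] == 1
        assert low.observed_mask[3] and low.y[3] == 0

    def test_negative_clinical_value_names_field_and_person(self):
        with pytest.raises(ValidationError, match="bmi.*P7|P7.*bmi"):
            make_individual(person_id="P7", bmi=-1.0)

    @given(
        glucose=st.floats(50, 400), bmi=st.floats(10, 60),
        sbp=st.floats(80, 240), dbp=st.floats(40, 140), ldl=st.floats(30, 300),
        bump=st.floats(0, 100),
        cvr=st.sampled_from(["existing_cvd", "moderate_cvr", "low_cvr"]),
    )
    def test_monotone_in_clinical_values(self, glucose, bmi, sbp, dbp, ldl, bump, cvr):
        """Raising any continuous clinical input never flips a 1 to 0."""
        lo = derive_outcomes(make_individual(
            fasting_glucose=glucose, bmi=bmi, sbp=sbp, dbp=dbp, ldl=ldl,
            cvr_category=cvr))
        hi = derive_outcomes(make_individual(
            fasting_glucose=glucose + bump, bmi=bmi + bump, sbp=sbp + bump,
            dbp=dbp + bump, ldl=ldl + bump, cvr_category=cvr))
        assert np.all(hi.y >= lo.y)


class TestAggregation:
    def test_counts_and_means(self):
        inds = [
            make_individual("A", 1, sampling_weight=2.0, fasting_glucose=130.0),
            make_individual("B", 1, sampling_weight=4.0, fasting_glucose=100.0),
            make_individual("C", 1, sampling_weight=6.0, fasting_glucose=200.0),
        ]
        aggs = aggregate_to_province(inds, graph_size=3)
        a = aggs[0]
        assert a.n_sampled == 3
        assert a.case_counts[0] == 2 and a.n_observed[0] == 3
        assert a.crude_prevalence[0] == pytest.approx(2 / 3)
        assert a.mean_weight == pytest.approx(4.0)

    def test_unsampled_nodes_present(self):
        aggs = aggregate_to_province([make_individual(province_id=2)], graph_size=3)
        assert [a.sampled_flag for a in aggs] == [0, 1, 0]
        assert aggs[0].n_sampled == 0 and aggs[0].mean_weight is None

    def test_totals_conserved(self, rng):
        inds = [
            make_individual(
                f"P{i}", int(rng.integers(1, 6)),
                fasting_glucose=float(rng.uniform(80, 200)),
                bmi=None if rng.random() < 0.3 else float(rng.uniform(18, 40)),
            )
            for i in range(120)
        ]
        outcomes = [derive_outcomes(ind) for ind in inds]
        aggs = aggregate_to_province(inds, 5, outcomes)
        assert sum(a.n_sampled for a in aggs) == 120
        for k in range(4):
            observed_pos = sum(
                int(ov.y[k]) for ov in outcomes if ov.observed_mask[k]
            )
            assert sum(a.case_counts[k] for a in aggs) == observed_pos
        for a in aggs:
            crude = a.crude_prevalence
            ok = np.isfinite(crude)
            assert np.all((crude[ok] >= 0) & (crude[ok] <= 1))

    def test_out_of_range_province_errors(self):
        with pytest.raises(ValidationError, match="outside graph range"):
            aggregate_to_province([make_individual(province_id=9)], graph_size=3)


class TestDescriptives:
    def test_overall_mean_age(self):
        inds = [make_individual("A", age=40.0), make_individual("B", age=50.0)]
        table = descriptive_statistics(inds)
        assert table.set_index("variable").loc["age", "overall"] == pytest.approx(45.0)

    def test_identical_rates_give_p_one(self):
        # equal group sizes, identical outcome pattern by sex
        inds = []
        for s in (0, 1):
            inds += [make_individual(f"{s}a", sex=s, fasting_glucose=200.0, age=40),
                     make_individual(f"{s}b", sex=s, fasting_glucose=90.0, age=40)]
        table = descriptive_statistics(inds).set_index("variable")
        assert table.loc["diabetes", "p_value"] == pytest.approx(1.0)

    def test_two_proportion_test_power(self, rng):
        """Monte-Carlo power check: a 0.10 rate gap at n=2000/group is
        detected at alpha=0.05 in >90% of replicates (normal-approximation
        power at these sizes is ~1)."""
        n = 2000
        rejections = 0
        reps = 200
        for _ in range(reps):
            c1 = rng.binomial(n, 0.30)
            c2 = rng.binomial(n, 0.40)
            if two_proportion_pvalue(c1, n, c2, n) < 0.05:
                rejections += 1
        assert rejections / reps > 0.9

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            descriptive_statistics([])


class TestIO:
    def test_missing_field_masks_outcome(self, tmp_path):
        p = tmp_path / "survey.csv"
        p.write_text(
            "person_id,province_id,age,sex,sampling_weight,bmi\n"
            "A,1,40,0,1.5,31.0\nB,1,55,1,2.0,\nC,2,60,0,1.0,24.0\n"
        )
        inds = read_survey_table(p)
        assert len(inds) == 3
        masks = [derive_outcomes(i).observed_mask[1] for i in inds]
        assert masks == [True, False, True]

    def test_survey_round_trip(self, tmp_path, rng):
        inds = [
            make_individual(f"P{i}", int(rng.integers(1, 4)),
                            age=float(rng.uniform(20, 80)),
                            sampling_weight=float(rng.uniform(0.5, 5)),
                            ldl=None if i % 3 == 0 else 120.0)
            for i in range(10)
        ]
        path = tmp_path / "s.csv"
        write_survey_table(inds, path)
        back = read_survey_table(path)
        for a, b in zip(inds, back):
            assert a == b

    def test_province_round_trip(self, tmp_path):
        inds = [make_individual("A", 1), make_individual("B", 3, bmi=33.0)]
        aggs = aggregate_to_province(inds, 4)
        path = tmp_path / "prov.csv"
        write_province_table(aggs, path)
        back = read_province_table(path)
        for a, b in zip(aggs, back):
            assert a.province_id == b.province_id
            assert a.n_sampled == b.n_sampled
            assert np.array_equal(a.case_counts, b.case_counts)
            assert np.array_equal(a.n_observed, b.n_observed)
            assert (a.mean_age is None) == (b.mean_age is None)
            if a.mean_age is not None:
                assert a.mean_age == pytest.approx(b.mean_age)

    def test_zero_province_id_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("person_id,province_id,age,sex,sampling_weight\nA,0,40,0,1.0\n")
        with pytest.raises(ValidationError):
            read_survey_table(p)

    def test_unknown_column_warns_missing_required_errors(self, tmp_path):
        p = tmp_path / "extra.csv"
        p.write_text("person_id,province_id,age,sex,sampling_weight,shoe_size\n"
                     "A,1,40,0,1.0,42\n")
        with pytest.warns(UserWarning, match="shoe_size"):
            read_survey_table(p)
        q = tmp_path / "short.csv"
        q.write_text("person_id,age\nA,40\n")
        with pytest.raises(ValidationError, match="required"):
            read_survey_table(q)

    def test_column_mapping_and_tabs(self, tmp_path):
        p = tmp_path / "mapped.tsv"
        p.write_text("id\tprov\tage\tsex\tw\nA\t2\t44\t1\t1.25\n")
        inds = read_survey_table(
            p, column_map={"person_id": "id", "province_id": "prov",
                           "sampling_weight": "w"})
        assert inds[0].province_id == 2
        assert inds[0].sampling_weight == pytest.approx(1.25)

    def test_underage_warns_but_parses(self):
        with pytest.warns(UserWarning, match="target population"):
            make_individual(age=12.0)
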