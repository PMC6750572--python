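import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smicvd.cohort import (
    ETHNICITY_PRIORITY,
    CohortFlow,
    apply_exclusions,
    ascertain_exposure,
    ascertain_psychosis,
    ascertain_smi,
    is_psychosis_code,
    prioritized_ethnicity,
)
from smicvd.errors import DataError, LinkageError

from conftest import make_person, person_frame


def contacts_frame(rows):
    return pd.DataFrame(rows, columns=["person_id", "contact_date", "setting",
                                       "diagnosis_code"])


class TestExclusions:
    @pytest.mark.parametrize(
        "age,expected_eligible",
        [(29.9, False), (30.0, True), (74.0, True), (75.0, False), (74.5, False)],
    )
    def test_age_boundaries_inclusive_30_to_74(self, age, expected_eligible):
        persons = person_frame([make_person(age_at_index=age)])
        eligible, flow = apply_exclusions(persons)
        assert (len(eligible) == 1) is expected_eligible

    def test_eight_record_toy_matches_per_record_rule_evaluation(self):
        rows = [
            make_person(person_id="A"),                                    # eligible
            make_person(person_id="B", age_at_index=75.0),                 # age
            make_person(person_id="C", prior_cvd=True),                    # cvd
            make_person(person_id="D", prior_renal_failure=True),          # renal
            make_person(person_id="E", smoker_status=None),                # smoking
            make_person(person_id="F", tchdl=None),                        # chol
            make_person(person_id="G", age_at_index=20.0, prior_cvd=True), # age first
            make_person(person_id="H"),                                    # eligible
        ]
        persons = person_frame(rows)
        eligible, flow = apply_exclusions(persons)

        # brute-force per-record rule evaluation
        def first_failure(r):
            if not (30 <= r["age_at_index"] <= 74):
                return "age"
            if r["prior_cvd"] or r["prior_renal_failure"]:
                return "cvd_renal"
            if r["smoker_status"] is None:
                return "smoking"
            if r["tchdl"] is None:
                return "chol"
            return None

        verdicts = [first_failure(r) for r in rows]
        assert flow.assessed_total == 8
        assert flow.in_age_range == sum(v != "age" for v in verdicts)
        assert flow.excluded_prior_cvd_or_renal == verdicts.count("cvd_renal")
        assert flow.excluded_missing_smoking == verdicts.count("smoking")
        assert flow.excluded_missing_cholesterol == verdicts.count("chol")
        assert sorted(eligible["person_id"]) == ["A", "H"]

    def test_idempotent_on_own_output(self):
        persons = person_frame(
            [make_person(person_id=f"P{i}", age_at_index=40 + i) for i in range(5)]
            + [make_person(person_id="X", prior_cvd=True)]
        )
        eligible, _ = apply_exclusions(persons)
        again, flow2 = apply_exclusions(eligible)
        pd.testing.assert_frame_equal(again.reset_index(drop=True),
                                      eligible.reset_index(drop=True))
        assert flow2.excluded_prior_cvd_or_renal == 0
        assert flow2.final_eligible == flow2.in_age_range == len(eligible)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=20, max_value=85),
                st.booleans(), st.booleans(), st.booleans(), st.booleans(),
            ),
            min_size=0, max_size=40,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_flow_conservation_on_random_fixtures(self, spec_rows):
        rows = [
            make_person(
                person_id=f"P{i}",
                age_at_index=age,
                prior_cvd=cvd,
                prior_renal_failure=renal,
                smoker_status=None if miss_smoke else "never",
                tchdl=None if miss_chol else 4.0,
            )
            for i, (age, cvd, renal, miss_smoke, miss_chol) in enumerate(spec_rows)
        ]
        if not rows:
            return
        _, flow = apply_exclusions(person_frame(rows))
        assert (
            flow.final_eligible
            + flow.excluded_prior_cvd_or_renal
            + flow.excluded_missing_smoking
            + flow.excluded_missing_cholesterol
            == flow.in_age_range
        )

    def test_null_age_is_a_data_error(self):
        with pytest.raises(DataError, match="age_at_index"):
            apply_exclusions(person_frame([make_person(age_at_index=None)]))

    def test_flow_counts_must_telescope(self):
        with pytest.raises(DataError):
            CohortFlow(10, 10, 1, 1, 1, 9)


class TestSmiAscertainment:
    def persons(self):
        return person_frame([make_person(person_id="P1", index_date="2012-06-15")])

    def flags(self, contact_rows):
        return ascertain_smi(self.persons(), contacts_frame(contact_rows))

    def test_contact_one_day_before_index_qualifies(self):
        f = self.flags([("P1", "2012-06-14", "community_face_to_face", None)])
        assert f.loc["P1", "smi"]

    def test_contact_on_index_date_never_qualifies(self):
        # half-open window: "prior to" excludes the assessment day itself
        f = self.flags([("P1", "2012-06-15", "inpatient", None)])
        assert not f.loc["P1", "smi"]

    def test_contact_exactly_five_years_before_qualifies(self):
        f = self.flags([("P1", "2007-06-15", "inpatient", None)])
        assert f.loc["P1", "smi"]

    def test_contact_five_years_plus_one_day_before_does_not(self):
        f = self.flags([("P1", "2007-06-14", "inpatient", None)])
        assert not f.loc["P1", "smi"]

    def test_setting_other_never_qualifies(self):
        f = self.flags([("P1", "2012-06-14", "other", None)])
        assert not f.loc["P1", "smi"]

    def test_unknown_person_id_raises_linkage_error(self):
        with pytest.raises(LinkageError, match="ZZZ"):
            self.flags([("ZZZ", "2012-06-14", "inpatient", None)])

    def test_twenty_contact_toy_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        persons = person_frame(
            [make_person(person_id=f"P{i}", index_date="2012-06-15") for i in range(6)]
        )
        dates = pd.Timestamp("2012-06-15") + pd.to_timedelta(
            rng.integers(-2600, 200, 20), unit="D"
        )
        settings_ = rng.choice(["inpatient", "community_face_to_face", "other"], 20)
        ids = rng.choice([f"P{i}" for i in range(6)], 20)
        contacts = contacts_frame(
            list(zip(ids, dates.strftime("%Y-%m-%d"), settings_, [None] * 20))
        )
        flags = ascertain_smi(persons, contacts)

        index = pd.Timestamp("2012-06-15")
        lower = index - pd.DateOffset(years=5)
        for pid in persons["person_id"]:  # independent exhaustive window scan
            expected = any(
                (row.person_id == pid)
                and (row.setting in ("inpatient", "community_face_to_face"))
                and (lower <= pd.Timestamp(row.contact_date) < index)
                for row in contacts.itertuples()
            )
            assert flags.loc[pid, "smi"] == expected


class TestPsychosis:
    def base_flags(self, smi=True):
        persons = person_frame([make_person(person_id="P1", index_date="2012-06-15")])
        contacts = (
            [("P1", "2012-06-14", "inpatient", None)] if smi else []
        )
        return persons, contacts

    def test_post_index_code_counts(self):
        persons, base = self.base_flags()
        contacts = contacts_frame(base + [("P1", "2014-01-01", "other", "F25")])
        flags = ascertain_exposure(persons, contacts)
        assert flags.loc["P1", "psychosis"]
        assert not flags.loc["P1", "smi_non_psychosis"]

    def test_all_null_codes_default_to_non_psychosis(self):
        persons, base = self.base_flags()
        flags = ascertain_exposure(persons, contacts_frame(base))
        assert flags.loc["P1", "smi"] and not flags.loc["P1", "psychosis"]
        assert flags.loc["P1", "smi_non_psychosis"]

    def test_psychosis_requires_smi(self):
        # F-coded contact but no qualifying window contact: not SMI, not psychosis
        persons = person_frame([make_person(person_id="P1", index_date="2012-06-15")])
        contacts = contacts_frame([("P1", "2014-01-01", "other", "F20.0")])
        flags = ascertain_exposure(persons, contacts)
        assert not flags.loc["P1", "smi"] and not flags.loc["P1", "psychosis"]

    @pytest.mark.parametrize("family", range(19, 34))
    def test_code_family_range_f20_to_f31_inclusive(self, family):
        # enumerate F19..F33 against the range predicate
        assert is_psychosis_code(f"F{family}.1") == (20 <= family <= 31)

    def test_malformed_codes_treated_as_missing(self):
        persons, base = self.base_flags()
        contacts = contacts_frame(base + [("P1", "2011-01-01", "inpatient", "garbage")])
        flags = ascertain_exposure(persons, contacts)  # must not raise
        assert not flags.loc["P1", "psychosis"]


class TestPrioritizedEthnicity:
    def test_maori_beats_pacific(self):
        assert prioritized_ethnicity(["pacific", "maori"]) == "maori"

    def test_single_record(self):
        assert prioritized_ethnicity(["european"]) == "european_other"

    def test_all_two_element_permutations_match_priority_max(self):
        rank = {c: i for i, c in enumerate(ETHNICITY_PRIORITY)}
        for pair in itertools.permutations(ETHNICITY_PRIORITY, 2):
            expected = min(pair, key=lambda c: rank[c])  # enumeration oracle
            assert prioritized_ethnicity(list(pair)) == expected

    def test_order_independence(self):
        for combo in itertools.permutations(["indian", "pacific", "chinese_asian"]):
            assert prioritized_ethnicity(list(combo)) == "pacific"

    def test_empty_list_is_a_data_error(self):
        with pytest.raises(DataError):
            prioritized_ethnicity([])

    def test_pipe_joined_string_accepted(self):
        assert prioritized_ethnicity("european_other|maori") == "maori"
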