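import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialsql.criteria_pipeline import (
    RULES_BACKEND,
    BackendContract,
    extract_elements,
    filter_queryable,
    percent_reduction,
    preprocess_trial,
    segment,
    simplify,
    token_count,
)
from trialsql.errors import InputError, SchemaValidationError


def reference_token_split(text):
    """One-line reference splitter: isolate punctuation, split on whitespace."""
    return re.sub(r"([^\w\s])", r" \1 ", text).split()


class TestTokenCount:
    @pytest.mark.parametrize("text, n", [("", 0), ("Age ≥ 18", 3), ("a, b", 3)])
    def test_examples(self, text, n):
        assert token_count(text) == n

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=st.characters(codec="ascii", exclude_categories=["Cc"]), max_size=60))
    def test_matches_reference_splitter(self, text):
        assert token_count(text) == len(reference_token_split(text))


class TestSegment:
    def test_numbered_items_in_order(self):
        texts = [c.segmented_text for c in segment("1. Age ≥ 18\n2. Pregnancy")]
        assert texts == ["Age ≥ 18", "Pregnancy"]

    def test_inline_subitems_inherit_parent_prefix(self):
        texts = [c.segmented_text for c in segment("Diabetes with: a) HbA1c > 7%; b) on metformin")]
        assert len(texts) == 2
        assert all(t.startswith("Diabetes with:") for t in texts)

    def test_lettered_lines_inherit_parent_prefix(self):
        block = "Diabetes with:\na) retinopathy\nb) nephropathy"
        texts = [c.segmented_text for c in segment(block)]
        assert texts == ["Diabetes with: retinopathy", "Diabetes with: nephropathy"]

    def test_single_sentence_is_identity(self):
        crits = segment("Unstructured sentence about prior stroke")
        assert [c.segmented_text for c in crits] == ["Unstructured sentence about prior stroke"]

    def test_connectors_kept_verbatim(self):
        texts = [c.segmented_text for c in segment("- stroke OR transient ischemic attack")]
        assert texts == ["stroke OR transient ischemic attack"]

    def test_empty_block_rejected(self):
        with pytest.raises(InputError):
            segment("   ")

    def test_indices_and_token_counts_set(self):
        crits = segment("1. A\n2. B\n3. C", trial_id="NCT1")
        assert [c.index for c in crits] == [0, 1, 2]
        assert all("segmentation" in c.token_counts for c in crits)


class TestFilterQueryable:
    @pytest.mark.parametrize(
        "text, reason",
        [
            ("Provided written informed consent", "consent"),
            ("Willingness to comply with study visits", "willingness"),
            ("Any condition that in the opinion of the investigator precludes participation",
             "investigator_judgment"),
            ("Agreement to use adequate contraception", "contraception"),
            ("Currently enrolled in another clinical trial", "co_enrollment"),
        ],
    )
    def test_non_queryable_reason_codes(self, text, reason):
        crit = filter_queryable(segment(text))[0]
        assert not crit.queryable and crit.non_queryable_reason == reason

    def test_clinical_criterion_is_queryable(self):
        crit = filter_queryable(segment("Type 1 diabetes"))[0]
        assert crit.queryable and crit.non_queryable_reason is None

    def test_fixture_of_ten_retains_seven(self):
        block = "\n".join(
            [
                "1. Type 2 diabetes",
                "2. Written informed consent provided",
                "3. Age 18 years or older",
                "4. Hemoglobin < 10 g/dL",
                "5. Willingness to comply with all study procedures",
                "6. History of myocardial infarction",
                "7. Agrees to use contraception during the study",
                "8. eGFR < 30",
                "9. Pregnancy",
                "10. Active cancer treatment",
            ]
        )
        crits = filter_queryable(segment(block))
        assert len(crits) == 10  # ordering and count preserved
        assert sum(c.queryable for c in crits) == 7


class TestSimplify:
    def test_temporal_phrase_normalized_and_tokens_decrease(self):
        crit = filter_queryable(segment("history of MI within the past six months"))[0]
        simplify(crit)
        assert "≤ 6 months" in crit.simplified_text
        assert crit.token_counts["simplification"] < crit.token_counts["filtering"]

    def test_age_parenthetical_example(self):
        crit = filter_queryable(segment("age 18 years or older (adults)"))[0]
        simplify(crit)
        assert crit.simplified_text == "age ≥ 18 years"

    def test_idempotent_on_minimal_text(self):
        crit = filter_queryable(segment("Type 1 diabetes"))[0]
        simplify(crit)
        assert crit.simplified_text == "Type 1 diabetes"
        again = filter_queryable(segment(crit.simplified_text))[0]
        simplify(again)
        assert again.simplified_text == crit.simplified_text

    def test_non_queryable_rejected(self):
        crit = filter_queryable(segment("Provided written informed consent"))[0]
        with pytest.raises(InputError):
            simplify(crit)

    @pytest.mark.parametrize(
        "text",
        [
            "stroke within the last 3 months",
            "at least 2 weeks ago received chemotherapy",
            "hemoglobin greater than or equal to 10 g/dL",
            "patients must have biopsy-confirmed carcinoma",
            "creatinine less than 2 mg/dL (per local lab)",
        ],
    )
    def test_tokens_never_increase(self, text):
        crit = filter_queryable(segment(text))[0]
        simplify(crit)
        assert crit.token_counts["simplification"] <= crit.token_counts["filtering"]


class TestExtractElements:
    def _extract(self, text):
        crit = filter_queryable(segment(text))[0]
        simplify(crit)
        return extract_elements(crit)

    def test_value_constraint_parsed(self):
        rec = self._extract("hemoglobin < 10 g/dL")
        assert rec.value.comparator == "<" and rec.value.number == 10.0
        assert rec.value.unit == "g/dL"
        assert rec.clinical_terms == ["hemoglobin"]
        assert rec.negation is False

    def test_negation_cue_sets_flag_and_strips_term(self):
        rec = self._extract("no history of stroke")
        assert rec.negation is True and rec.clinical_terms == ["stroke"]

    def test_plain_criterion_has_empty_optional_slots(self):
        rec = self._extract("Type 1 diabetes")
        assert rec.clinical_terms == ["Type 1 diabetes"]
        assert rec.value is None and rec.temporal is None and rec.codes == []
        assert rec.negation is False

    def test_temporal_parsed_from_normalized_form(self):
        rec = self._extract("myocardial infarction within the past 6 months")
        assert rec.temporal.quantity == 6.0 and rec.temporal.unit == "month"

    def test_age_years_is_value_not_temporal(self):
        rec = self._extract("age 18 years or older")
        assert rec.value is not None and rec.temporal is None

    def test_attribute_words_collected(self):
        rec = self._extract("uncontrolled hypertension")
        assert "uncontrolled" in rec.attributes

    def test_invalid_backend_output_is_schema_error(self):
        bad = BackendContract(
            name="bad", transform=lambda task, payload: {"criteria": None}
            if task == "segment" else {"negation": "maybe"},
        )
        crit = filter_queryable(segment("Type 1 diabetes"))[0]
        simplify(crit)
        with pytest.raises(SchemaValidationError):
            extract_elements(crit, backend=bad)


class TestPreprocessTrial:
    TRIAL = {
        "trial_id": "NCT-SYNTH-1",
        "inclusion": "1. Age 18 years or older\n2. Type 2 diabetes\n3. Provided written informed consent",
        "exclusion": "1. Pregnancy\n2. Stroke within the past six months",
    }

    def test_stats_match_per_criterion_recomputation(self):
        criteria, stats = preprocess_trial(self.TRIAL)
        seg = [c.token_counts["segmentation"] for c in criteria]
        assert stats["segmentation"]["total_tokens"] == sum(seg)
        retained = [c for c in criteria if c.queryable]
        simp = [c.token_counts["simplification"] for c in retained]
        assert stats["simplification"]["total_tokens"] == sum(simp)
        expected = 100 * (1 - sum(simp) / sum(seg))
        assert stats["token_reduction_pct"] == pytest.approx(expected)

    def test_consent_filtered_and_order_preserved(self):
        criteria, stats = preprocess_trial(self.TRIAL)
        assert len(criteria) == 5
        assert stats["filtering"]["n_criteria"] == 4
        assert [c.polarity for c in criteria] == ["inclusion"] * 3 + ["exclusion"] * 2

    def test_monotone_token_counts(self):
        criteria, _ = preprocess_trial(self.TRIAL)
        for c in criteria:
            if c.queryable:
                assert (
                    c.token_counts["segmentation"]
                    >= c.token_counts["filtering"]
                    >= c.token_counts["simplification"]
                )

    def test_minimal_trial_has_zero_reduction(self):
        _, stats = preprocess_trial({"trial_id": "T", "inclusion": "Type 1 diabetes"})
        assert stats["token_reduction_pct"] == 0.0

    def test_empty_trial_rejected(self):
        with pytest.raises(InputError):
            preprocess_trial({"trial_id": "T"})

    def test_deterministic_with_rules_backend(self):
        a = preprocess_trial(self.TRIAL, backend=RULES_BACKEND)
        b = preprocess_trial(self.TRIAL, backend=RULES_BACKEND)
        assert [c.simplified_text for c in a[0]] == [c.simplified_text for c in b[0]]
        assert a[1] == b[1]


def test_percent_reduction_formula():
    assert percent_reduction(200, 100) == pytest.approx(50.0)
    with pytest.raises(InputError):
        percent_reduction(0, 10)
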