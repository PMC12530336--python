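import numpy as np
import pytest

from trialsql.audit import audit_batch, audit_query
from trialsql.criteria_pipeline import RULES_BACKEND, preprocess_trial
from trialsql.errors import FeasibilityError, InputError, ScriptedMissError
from trialsql.metrics import cohort_concordance
from trialsql.synth import (
    SynthVocabSpec,
    generate_cohort_pair,
    generate_mini_cdm,
    generate_valid_queries,
    generate_vocabulary,
    inject_errors,
    mock_backend,
    record_script,
)


class TestGenerateVocabulary:
    def test_sizes_and_reproducibility(self):
        spec = SynthVocabSpec(universe_size=1000, loaded_fraction=0.1, seed=42)
        uni1, load1 = generate_vocabulary(spec)
        uni2, load2 = generate_vocabulary(spec)
        assert len(uni1) == 1000 and len(load1) == 100
        assert uni1.concepts == uni2.concepts
        assert uni1.ancestor_pairs == uni2.ancestor_pairs
        assert load1.ids == load2.ids

    def test_full_fraction_loads_everything(self):
        uni, loaded = generate_vocabulary(SynthVocabSpec(universe_size=200, loaded_fraction=1.0, seed=1))
        assert loaded.ids == uni.ids

    def test_loaded_is_subset_of_universe(self, universe, loaded):
        assert loaded.ids <= universe.ids
        assert len(loaded) < len(universe)

    def test_zero_fraction_rejected(self):
        with pytest.raises(InputError):
            SynthVocabSpec(loaded_fraction=0.0)

    def test_hierarchy_is_domain_homogeneous(self, universe):
        for a, d in list(universe.ancestor_pairs)[:200]:
            assert universe.domain_of(a) == universe.domain_of(d)


class TestGenerateMiniCdm:
    def test_draw_log_is_execution_oracle(self, loaded, catalog):
        cid = sorted(c for c in loaded.ids if loaded.domain_of(c) == "Condition")[0]
        cdm = generate_mini_cdm(loaded, n_persons=20, event_rates={cid: 0.5}, seed=13)
        got = cdm.execute(
            f"SELECT person_id FROM condition_occurrence WHERE condition_concept_id = {cid}"
        )
        assert got == cdm.draw_log[cid]

    def test_rate_zero_and_one(self, loaded):
        cid = sorted(loaded.ids)[0]
        empty = generate_mini_cdm(loaded, n_persons=15, event_rates={cid: 0.0}, seed=1)
        full = generate_mini_cdm(loaded, n_persons=15, event_rates={cid: 1.0}, seed=1)
        assert empty.draw_log[cid] == set()
        assert full.draw_log[cid] == set(range(1, 16))

    def test_referential_integrity(self, loaded, mini_cdm, catalog):
        persons = set(mini_cdm.tables["person"]["person_id"].astype(int))
        for domain, rule in catalog.domain_rules.items():
            if rule.event_table == "person":
                continue
            df = mini_cdm.tables[rule.event_table]
            if df.empty:
                continue
            assert set(df["person_id"].dropna().astype(int)) <= persons
            for cid in df[rule.concept_column].dropna().astype(int):
                assert cid in loaded

    def test_csv_round_trip(self, mini_cdm, tmp_path):
        mini_cdm.write_csv(tmp_path)
        assert (tmp_path / "person.csv").exists()
        assert (tmp_path / "condition_occurrence.csv").exists()


class TestInjectErrors:
    def test_single_site_full_a_probability(self, universe, loaded, catalog):
        [q] = generate_valid_queries(loaded, 1, seed=2, catalog=catalog, max_concepts=1)
        injected, manifest = inject_errors([q], {"A": 1.0}, universe, loaded, seed=2, catalog=catalog)
        assert [s.category for s in manifest.sites] == ["A"]
        audit = audit_query(injected[0], loaded, catalog)
        assert audit.categories == ["A"]

    def test_zero_profile_is_identity(self, universe, loaded, catalog):
        queries = generate_valid_queries(loaded, 5, seed=3, catalog=catalog)
        injected, manifest = inject_errors(queries, {}, universe, loaded, seed=3, catalog=catalog)
        assert injected == queries and manifest.sites == []

    def test_valid_queries_audit_clean(self, loaded, catalog):
        queries = generate_valid_queries(loaded, 25, seed=4, catalog=catalog)
        audits, _ = audit_batch(queries, loaded, catalog)
        assert all(a.parse_ok and not a.instances for a in audits)

    def test_category_a_ids_come_from_outside_loaded(self, universe, loaded, catalog):
        queries = generate_valid_queries(loaded, 20, seed=6, catalog=catalog)
        _, manifest = inject_errors(queries, {"A": 0.8}, universe, loaded, seed=6, catalog=catalog)
        for site in manifest.sites:
            cid = int(site.injected)
            assert cid in universe and cid not in loaded

    def test_round_trip_recovery_over_seeds(self, universe, loaded, catalog):
        profile = {"A": 0.2, "B": 0.2, "C": 0.15, "D": 0.15, "E": 0.25}
        for seed in range(5):
            queries = generate_valid_queries(loaded, 30, seed=seed, catalog=catalog)
            injected, manifest = inject_errors(
                queries, profile, universe, loaded, seed=seed, catalog=catalog
            )
            audits, _ = audit_batch(injected, loaded, catalog)
            for i, a in enumerate(audits):
                assert a.categories == manifest.categories_for(i)

    def test_excess_probability_mass_rejected(self, universe, loaded, catalog):
        queries = generate_valid_queries(loaded, 2, seed=1, catalog=catalog)
        with pytest.raises(Exception):
            inject_errors(queries, {"A": 0.8, "B": 0.8}, universe, loaded, seed=1, catalog=catalog)


class TestGenerateCohortPair:
    def test_target_one_identical_sets(self):
        a, b = generate_cohort_pair(20, 20, 1.0, seed=1)
        assert a == b and len(a) == 20

    def test_target_zero_disjoint(self):
        a, b = generate_cohort_pair(15, 25, 0.0, seed=1)
        assert a.isdisjoint(b) and (len(a), len(b)) == (15, 25)

    def test_subset_pattern_three_in_hundred(self):
        a, b = generate_cohort_pair(3, 100, 0.03, seed=2)
        m = cohort_concordance(a, b)
        assert m.overlap == 1.0 and m.jaccard == pytest.approx(0.03)

    def test_requested_jaccard_within_tolerance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_a, n_b = int(rng.integers(20, 120)), int(rng.integers(20, 120))
            target = float(rng.uniform(0.05, 0.9))
            try:
                a, b = generate_cohort_pair(n_a, n_b, target, seed=int(rng.integers(1000)))
            except FeasibilityError as err:
                # coarse integer grid: the nearest achievable value is reported
                assert abs(err.nearest - target) > 0.01
                continue
            realized = cohort_concordance(a, b).jaccard
            assert abs(realized - target) <= 0.01
            assert (len(a), len(b)) == (n_a, n_b)

    def test_infeasible_target_reports_nearest(self):
        with pytest.raises(FeasibilityError) as err:
            generate_cohort_pair(1, 100, 0.5, seed=0)
        assert err.value.nearest == pytest.approx(0.01)

    def test_reproducible_under_seed(self):
        assert generate_cohort_pair(30, 40, 0.4, seed=9) == generate_cohort_pair(30, 40, 0.4, seed=9)


class TestMockBackend:
    TRIAL = {"trial_id": "T", "inclusion": "1. Type 2 diabetes\n2. Age 18 years or older"}

    def test_scripted_response_verbatim(self):
        from trialsql.synth import script_entry

        key, out = script_entry("segment", {"block": "x"}, {"criteria": ["x"]})
        backend = mock_backend({key: out})
        assert backend.transform("segment", {"block": "x"}) == {"criteria": ["x"]}

    def test_unscripted_input_raises(self):
        backend = mock_backend({})
        with pytest.raises(ScriptedMissError):
            backend.transform("segment", {"block": "unseen"})

    def test_mock_mirrors_rules_backend_on_pipeline(self):
        criteria, stats = preprocess_trial(self.TRIAL, backend=RULES_BACKEND)
        calls = [("segment", {"block": self.TRIAL["inclusion"]})]
        for c in criteria:
            calls.append(("filter", {"text": c.segmented_text, "rules": None}))
            if c.queryable:
                calls.append(("simplify", {"text": c.segmented_text}))
        script = record_script(RULES_BACKEND, calls)
        mocked = mock_backend(script)
        criteria2, stats2 = preprocess_trial(self.TRIAL, backend=mocked)
        assert [c.simplified_text for c in criteria2] == [c.simplified_text for c in criteria]
        assert stats2 == stats
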