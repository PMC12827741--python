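"""Similarity scoring, two-threshold classification, candidate matching."""

import math

import numpy as np
import pytest

import pseudolink as pl
from pseudolink.errors import LinkageError
from pseudolink.linkage import Comparator, Decision, FieldComparatorConfig, LinkageConfig
from pseudolink.model import Identity


class TestCompareField:
    def test_exact_equality(self):
        assert pl.compare_field("19800201", "19800201", Comparator.EXACT) == 1.0
        assert pl.compare_field("1980", "1981", Comparator.DATE_COMPONENT) == 0.0

    def test_bigram_dice_hand_computed(self):
        # _A AN NN NA A_  vs  _A AN NA A_  ->  2*4 / (5+4) = 8/9
        assert pl.compare_field("ANNA", "ANA", Comparator.NGRAM_DICE) == pytest.approx(8 / 9)

    def test_missing_on_either_side(self):
        assert pl.compare_field("MEIER", None, Comparator.NGRAM_DICE) is None
        assert pl.compare_field(None, "MEIER", Comparator.EXACT) is None

    def test_symmetry(self):
        a, b = "SCHNEIDER", "SCHNEIDR"
        assert pl.compare_field(a, b, Comparator.NGRAM_DICE) == pl.compare_field(
            b, a, Comparator.NGRAM_DICE
        )


def _config(fields):
    """fields: list of (name, e, f)."""
    comps = tuple(
        FieldComparatorConfig(name, Comparator.EXACT, error_rate=e, frequency=f)
        for name, e, f in fields
    )
    return LinkageConfig(comps)


class TestEpilinkScore:
    def test_equal_weights_average(self):
        config = _config([("a", 0.01, 0.01), ("b", 0.01, 0.01)])
        # identical field "a", differing field "b": s = (w*1 + w*0)/2w = 0.5
        score = pl.epilink_score({"a": "X", "b": "Y"}, {"a": "X", "b": "Z"}, config)
        assert score == pytest.approx(0.5)

    def test_three_field_hand_computation(self):
        """Hand-recomputed weighted average with w_i = log2((1-e)/f)."""
        config = _config([("a", 0.01, 0.001), ("b", 0.01, 0.01), ("c", 0.01, 0.1)])
        w = [math.log2(0.99 / f) for f in (0.001, 0.01, 0.1)]
        expected = (w[0] * 1 + w[1] * 1 + w[2] * 0) / sum(w)
        score = pl.epilink_score(
            {"a": "X", "b": "Y", "c": "P"}, {"a": "X", "b": "Y", "c": "Q"}, config
        )
        assert score == pytest.approx(expected)

    def test_bounds(self):
        config = _config([("a", 0.01, 0.01), ("b", 0.01, 0.01)])
        same = {"a": "X", "b": "Y"}
        assert pl.epilink_score(same, dict(same), config) == 1.0
        assert pl.epilink_score(same, {"a": "P", "b": "Q"}, config) == 0.0

    def test_missing_fields_excluded_from_denominator(self):
        config = _config([("a", 0.01, 0.001), ("b", 0.01, 0.01)])
        assert pl.epilink_score({"a": "X", "b": None}, {"a": "X", "b": "Y"}, config) == 1.0

    def test_no_comparable_fields_raises(self):
        config = _config([("a", 0.01, 0.01)])
        with pytest.raises(LinkageError):
            pl.epilink_score({"a": None}, {"a": "X"}, config)

    def test_symmetry_bounds_monotonicity_randomized(self, linkage_config):
        """Property sweep: symmetric, in [0,1], and monotone when one field
        similarity is forced upward (values replaced by an exact copy)."""
        rng = np.random.default_rng(5)
        records, _ = pl.generate_cohort(60, 0, seed=5)
        rows = [pl.normalize_record(r) for r in records.to_dict("records")]
        for _ in range(400):
            a, b = (rows[int(i)] for i in rng.integers(len(rows), size=2))
            s_ab = pl.epilink_score(a, b, linkage_config)
            assert 0.0 <= s_ab <= 1.0
            assert s_ab == pytest.approx(pl.epilink_score(b, a, linkage_config))
            # force one differing field to agree: score must not decrease
            diff = [k for k in a if a[k] and b[k] and a[k] != b[k]]
            if diff:
                improved = dict(b)
                improved[diff[0]] = a[diff[0]]
                assert pl.epilink_score(a, improved, linkage_config) >= s_ab


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.97, Decision.MATCH), (0.95, Decision.MATCH), (0.85, Decision.TENTATIVE),
         (0.80, Decision.TENTATIVE), (0.50, Decision.NON_MATCH)],
    )
    def test_threshold_zones(self, linkage_config, score, expected):
        decision, rejected = pl.classify(score, linkage_config)
        assert decision is expected and not rejected

    def test_auto_reject_reports_non_match_with_flag(self):
        config = pl.default_linkage_config(auto_reject_tentative=True)
        decision, rejected = pl.classify(0.85, config)
        assert decision is Decision.NON_MATCH and rejected


class TestMatchCandidate:
    def test_exact_copy_matches_at_one(self, store, linkage_config, anna, boris):
        pl.ingest_identity(store, anna, linkage_config)
        pl.ingest_identity(store, boris, linkage_config)
        result = pl.match_candidate(Identity.from_raw(anna), store, linkage_config)
        assert result.decision is Decision.MATCH
        assert result.score == 1.0
        assert result.best_patient.main_identity.field_values["last_name"] == "MEIER"

    def test_empty_store_non_match(self, store, linkage_config, anna):
        result = pl.match_candidate(Identity.from_raw(anna), store, linkage_config)
        assert result.decision is Decision.NON_MATCH and result.best_patient is None

    def test_alias_identities_searched(self, store, linkage_config, anna, anna_married):
        out = pl.ingest_identity(store, anna, linkage_config)
        store.add_identity(out.patient, Identity.from_raw(anna_married), as_main=False)
        result = pl.match_candidate(Identity.from_raw(anna_married), store, linkage_config)
        assert result.decision is Decision.MATCH and result.best_patient is out.patient

    def test_agrees_with_naive_all_pairs_oracle(self, linkage_config):
        """Blocking disabled: decision and best score must equal an
        independently coded exhaustive scorer on a 200-record instance."""
        records, _ = pl.generate_cohort(170, 30, seed=23)
        rows = [pl.normalize_record(r) for r in records.to_dict("records")]
        weights = {c.field_name: math.log2((1 - c.error_rate) / c.frequency)
                   for c in linkage_config.comparators}

        def oracle_score(a, b):
            num = den = 0.0
            for name, w in weights.items():
                if a.get(name) is None or b.get(name) is None:
                    continue
                if name in ("first_name", "last_name", "city"):
                    ga = [f"_{a[name]}_"[i:i+2] for i in range(len(a[name]) + 1)]
                    gb = [f"_{b[name]}_"[i:i+2] for i in range(len(b[name]) + 1)]
                    from collections import Counter
                    ca, cb = Counter(ga), Counter(gb)
                    s = 2 * sum(min(v, cb[g]) for g, v in ca.items()) / (len(ga) + len(gb))
                else:
                    s = 1.0 if a[name] == b[name] else 0.0
                num += w * s
                den += w
            return num / den if den else 0.0

        store = pl.PatientStore()
        stored_rows = []
        for row in rows:
            result = pl.match_candidate(Identity.from_raw(row), store, linkage_config)
            if stored_rows:
                best = max(oracle_score(row, prev) for prev in stored_rows)
                assert result.score == pytest.approx(best, abs=1e-12)
                expected = ("MATCH" if best >= 0.95 else
                            "TENTATIVE" if best >= 0.80 else "NON_MATCH")
                assert result.decision.value == expected
            else:
                assert result.decision is Decision.NON_MATCH
            store.new_patient(Identity.from_raw(row))
            stored_rows.append(row)


class TestIngestAndConflicts:
    def test_tentative_creates_pair_then_merge_clears(self, store, linkage_config, anna):
        pl.ingest_identity(store, anna, linkage_config)
        variant = dict(anna, birth_month=8)  # one component off -> tentative zone
        out = pl.ingest_identity(store, variant, linkage_config)
        assert out.decision is Decision.TENTATIVE and out.created
        pairs = pl.list_tentative_pairs(store)
        assert len(pairs) == 1
        pl.resolve_conflict(store, (pairs[0][0], pairs[0][1]), pl.ConflictDecision.MERGE)
        assert pl.list_tentative_pairs(store) == []
        assert len(store.active_patients()) == 1

    def test_split_prevents_reproposal(self, store, linkage_config, anna):
        pl.ingest_identity(store, anna, linkage_config)
        variant = dict(anna, birth_month=8)
        pl.ingest_identity(store, variant, linkage_config)
        (a, b, _score) = pl.list_tentative_pairs(store)[0]
        pl.resolve_conflict(store, (a, b), pl.ConflictDecision.SPLIT)
        assert pl.list_tentative_pairs(store) == []
        # re-linking b's identity matches b itself; the split pair stays closed
        out = pl.ingest_identity(store, variant, linkage_config)
        assert out.decision is Decision.MATCH and out.patient is b
        assert pl.list_tentative_pairs(store) == []

    def test_resolve_twice_errors(self, store, linkage_config, anna):
        pl.ingest_identity(store, anna, linkage_config)
        pl.ingest_identity(store, dict(anna, birth_month=8), linkage_config)
        (a, b, _score) = pl.list_tentative_pairs(store)[0]
        pl.resolve_conflict(store, (a, b), pl.ConflictDecision.MERGE)
        with pytest.raises(LinkageError):
            pl.resolve_conflict(store, (a, b), pl.ConflictDecision.SPLIT)

    def test_auto_reject_stores_nothing(self, anna):
        config = pl.default_linkage_config(auto_reject_tentative=True)
        store = pl.PatientStore()
        pl.ingest_identity(store, anna, config)
        out = pl.ingest_identity(store, dict(anna, birth_month=8), config)
        assert out.rejected_tentative and out.patient is None
        assert len(store.active_patients()) == 1

    def test_match_after_merge_finds_survivor_via_alias(self, store, linkage_config,
                                                        anna, anna_married):
        a = pl.ingest_identity(store, anna, linkage_config).patient
        b = pl.ingest_identity(store, anna_married, linkage_config).patient
        store.record_tentative(a, b, 0.9)
        store.merge_patients(a, b)
        out = pl.ingest_identity(store, anna_married, linkage_config)
        assert out.decision is Decision.MATCH and out.patient is a
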