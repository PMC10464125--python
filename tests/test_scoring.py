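"""Score formulas, classification, end-to-end scoring vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabolink.model import CountQuad, AssociationLabel, Thresholds
from metabolink.scoring import (
    association_strength,
    classify,
    confidence,
    score_all,
    summarize_by_disease,
    tally_counts,
)
from metabolink.propagate import propagate_directions
from metabolink.taxonomy import TaxonNode, TaxonomyIndex

from _oracle import oracle_score, random_instance
from conftest import dm, make_taxonomy, pl


@st.composite
def count_quads(draw):
    M = draw(st.integers(0, 50))
    N = draw(st.integers(0, 50))
    m = draw(st.integers(0, M))
    n = draw(st.integers(0, N))
    return CountQuad(m, n, M, N)


class TestFormulas:
    @pytest.mark.parametrize(
        "quad,expected",
        [
            (CountQuad(0, 5, 7, 8), -0.625),
            (CountQuad(0, 4, 7, 8), -0.5),
            (CountQuad(2, 1, 4, 2), 0.0),
            (CountQuad(1, 0, 1, 0), 1.0),   # all microbes in one direction
            (CountQuad(0, 1, 0, 1), -1.0),
        ],
    )
    def test_association_strength(self, quad, expected):
        assert association_strength(quad) == expected

    @pytest.mark.parametrize(
        "quad,expected",
        [
            (CountQuad(0, 5, 7, 8), 3.125),
            (CountQuad(0, 4, 7, 8), 2.0),
            (CountQuad(2, 1, 4, 2), 0.0),
        ],
    )
    def test_confidence(self, quad, expected):
        assert confidence(quad) == expected

    @given(count_quads())
    @settings(max_examples=300, derandomize=True)
    def test_range_invariants(self, q):
        s_as = association_strength(q)
        s_ac = confidence(q, s_as)
        assert -1.0 <= s_as <= 1.0
        assert 0.0 <= s_ac <= q.m + q.n

    @given(count_quads())
    @settings(max_examples=300, derandomize=True)
    def test_direction_symmetry(self, q):
        mirrored = CountQuad(q.n, q.m, q.N, q.M)
        assert association_strength(mirrored) == pytest.approx(
            -association_strength(q), abs=1e-15
        )
        assert confidence(mirrored) == pytest.approx(confidence(q), abs=1e-15)

    def test_exclusive_extremes(self):
        assert association_strength(CountQuad(7, 0, 7, 8)) == 1.0
        assert association_strength(CountQuad(0, 8, 7, 8)) == -1.0


class TestClassify:
    def test_meaningful_drug_like(self):
        s = classify("D003924", 5893, CountQuad(0, 5, 7, 8))
        assert s.meaningful
        assert s.label is AssociationLabel.DRUG_LIKE

    @pytest.mark.parametrize(
        "quad,thresholds,meaningful",
        [
            # |S_as| exactly at the cut-off fails (strict comparison)
            (CountQuad(1, 0, 20, 0), Thresholds(0.05, 0.01), False),
            # S_ac exactly at the cut-off fails
            (CountQuad(0, 2, 5, 10), Thresholds(0.05, 0.4), False),
            (CountQuad(0, 5, 7, 8), Thresholds(), True),
            (CountQuad(0, 2, 7, 8), Thresholds(), False),  # s_ac = 0.5 <= 1
        ],
    )
    def test_strict_thresholds(self, quad, thresholds, meaningful):
        assert classify("D1", 1, quad, thresholds).meaningful is meaningful

    def test_neutral_label_on_zero_score(self):
        s = classify("D1", 1, CountQuad(2, 1, 4, 2))
        assert s.label is AssociationLabel.NEUTRAL
        assert not s.meaningful


class TestTallyCounts:
    def test_hand_built_panel(self, small_taxonomy):
        tax = make_taxonomy({10: list(range(101, 108)), 20: list(range(201, 209))})
        universe = set(range(101, 108)) | set(range(201, 209))
        panel = propagate_directions(
            [dm("D003924", 10, "increase"), dm("D003924", 20, "decrease")],
            tax,
            universe,
        )
        # metabolite 5893 produced by 5 decreased strains and nothing else
        links = [pl(s, 5893) for s in range(201, 206)]
        counts = tally_counts(panel, links)
        assert counts[("D003924", 5893)] == CountQuad(0, 5, 7, 8)

    def test_non_producing_pair_suppressed(self):
        tax = make_taxonomy({10: [101], 20: [201]})
        panel = propagate_directions([dm("D1", 10, "increase")], tax, {101, 201})
        counts = tally_counts(panel, [pl(201, 7)])  # 201 not in any panel
        assert counts == {}

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(7)
        dm_rows, mm_rows, parent, rank = random_instance(rng)
        from _oracle import oracle_harmonize

        clean = oracle_harmonize(dm_rows)
        tax = TaxonomyIndex([TaxonNode(t, parent[t], rank[t], str(t)) for t in parent])
        universe = {t for t, _ in mm_rows}
        panel = propagate_directions([dm(*r) for r in clean], tax, universe)
        counts = tally_counts(panel, [pl(*r) for r in mm_rows])
        expected = oracle_score(dm_rows, mm_rows, parent, rank)
        assert set(counts) == set(expected)
        for key, quad in counts.items():
            m, n, M, N, _, _ = expected[key]
            assert (quad.m, quad.n, quad.M, quad.N) == (m, n, M, N)


class TestScoreAll:
    def test_planted_metabolite_ranks_first(self):
        tax = make_taxonomy({10: [101, 102], 20: [201, 202, 203]})
        assocs = [dm("D1", 10, "increase"), dm("D1", 20, "decrease")]
        links = [pl(s, 99) for s in (201, 202, 203)]  # exclusive, full coverage
        links += [pl(101, 7), pl(201, 7)]  # background
        scored = score_all(assocs, links, tax)
        first = [s for s in scored if s.disease_id == "D1"][0]
        assert first.metabolite_id == 99
        assert first.s_as == -1.0
        assert first.s_ac == 3.0

    def test_empty_production_table(self, small_taxonomy):
        assert score_all([dm("D1", 853, "increase")], [], small_taxonomy) == []

    def test_deterministic(self, small_taxonomy):
        assocs = [dm("D1", 853, "increase"), dm("D1", 820, "decrease")]
        links = [pl(8531, 7), pl(8201, 7), pl(8202, 9)]
        a = score_all(assocs, links, small_taxonomy)
        b = score_all(assocs, links, small_taxonomy)
        assert a == b

    def test_rank_order_within_disease(self, small_taxonomy):
        assocs = [dm("D1", 853, "increase"), dm("D1", 820, "decrease")]
        links = [pl(8201, 1), pl(8202, 1), pl(8203, 1), pl(8201, 2), pl(8531, 3)]
        scored = score_all(assocs, links, small_taxonomy)
        values = [s.s_as for s in scored]
        assert values == sorted(values)

    def test_equals_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            dm_rows, mm_rows, parent, rank = random_instance(rng)
            tax = TaxonomyIndex(
                [TaxonNode(t, parent[t], rank[t], str(t)) for t in parent]
            )
            scored = score_all([dm(*r) for r in dm_rows], [pl(*r) for r in mm_rows], tax)
            expected = oracle_score(dm_rows, mm_rows, parent, rank)
            got = {(s.disease_id, s.metabolite_id): s for s in scored}
            assert set(got) == set(expected)
            for key, (m, n, M, N, s_as, s_ac) in expected.items():
                s = got[key]
                assert (s.counts.m, s.counts.n, s.counts.M, s.counts.N) == (m, n, M, N)
                assert abs(s.s_as - s_as) < 1e-12
                assert abs(s.s_ac - s_ac) < 1e-12

    def test_direction_swap_negates_scores(self, small_taxonomy):
        assocs = [dm("D1", 853, "increase"), dm("D1", 820, "decrease")]
        flipped = [
            dm("D1", 853, "decrease"),
            dm("D1", 820, "increase"),
        ]
        links = [pl(8531, 7), pl(8201, 7), pl(8202, 9), pl(8532, 9)]
        a = {(s.disease_id, s.metabolite_id): s for s in score_all(assocs, links, small_taxonomy)}
        b = {(s.disease_id, s.metabolite_id): s for s in score_all(flipped, links, small_taxonomy)}
        assert set(a) == set(b)
        for key in a:
            assert a[key].s_as == pytest.approx(-b[key].s_as, abs=1e-15)
            assert a[key].s_ac == pytest.approx(b[key].s_ac, abs=1e-15)


class TestSummarize:
    def test_mean_and_order(self, small_taxonomy):
        assocs = [
            dm("D1", 853, "increase"),
            dm("D2", 853, "decrease"),
        ]
        links = [pl(8531, 7), pl(8532, 9)]
        scored = score_all(assocs, links, small_taxonomy)
        summaries = summarize_by_disease(scored)
        assert [s.disease_id for s in summaries] == ["D1", "D2"]
        # D1: both metabolites produced by 1 of 2 increased strains -> +0.5
        assert summaries[0].mean_s_as == 0.5
        assert summaries[1].mean_s_as == -0.5

    def test_balanced_pairs_average_to_zero(self):
        from metabolink.model import ScoredAssociation

        mk = lambda d, c, v: ScoredAssociation(
            d, c, CountQuad(1, 0, 2, 0) if v > 0 else CountQuad(0, 1, 0, 2),
            v, abs(v), True,
            AssociationLabel.MARKER_LIKE if v > 0 else AssociationLabel.DRUG_LIKE,
        )
        summaries = summarize_by_disease([mk("D1", 1, 0.5), mk("D1", 2, -0.5)])
        assert summaries[0].mean_s_as == 0.0
        assert summaries[0].n_metabolites == 2

    def test_matches_independent_mean(self, small_taxonomy):
        assocs = [dm("D1", 853, "increase"), dm("D1", 820, "decrease")]
        links = [pl(8531, 7), pl(8201, 7), pl(8202, 9)]
        scored = score_all(assocs, links, small_taxonomy)
        summaries = summarize_by_disease(scored)
        by_disease = {}
        for s in scored:
            by_disease.setdefault(s.disease_id, []).append(s.s_as)
        for summary in summaries:
            vals = by_disease[summary.disease_id]
            assert summary.mean_s_as == pytest.approx(sum(vals) / len(vals))
            assert summary.n_metabolites == len(vals)
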