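from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coibarcode import (
    BarcodeError,
    SimulationConfig,
    barcoding_gap,
    distance_matrix,
    interspecific_fold_ratio,
    k2p_distance,
    simulate,
    summarize_by_rank,
)
from coibarcode.divergence import (
    NoComparableSitesError,
    RankDivergenceSummary,
    p_distance,
)

from _oracles import k2p_by_hand
from conftest import make_dataset, matrix_from_percent


def _random_pair(rng: random.Random, length: int, n_subs: int):
    bases = "ACGT"
    a = [rng.choice(bases) for _ in range(length)]
    b = list(a)
    for site in rng.sample(range(length), n_subs):
        b[site] = rng.choice([x for x in bases if x != b[site]])
    return "".join(a), "".join(b)


class TestK2PDistance:
    def test_identity(self):
        cmp = k2p_distance("ACGT" * 160, "ACGT" * 160)
        assert cmp.P == cmp.Q == 0.0
        assert cmp.d == 0.0 and cmp.defined

    def test_closed_form_on_known_counts(self):
        # 100 comparable sites: 10 transitions (A<->G), 5 transversions
        # (A<->C); expected d = -1/2 ln(0.75 * sqrt(0.90))
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        cmp = k2p_distance(a, b)
        assert cmp.P == pytest.approx(0.10)
        assert cmp.Q == pytest.approx(0.05)
        expected = -0.5 * math.log((1 - 2 * 0.10 - 0.05)
                                   * math.sqrt(1 - 2 * 0.05))
        assert cmp.d == pytest.approx(expected, abs=1e-12)
        assert cmp.d == pytest.approx(0.17018116514, abs=1e-10)

    def test_saturation_is_undefined_not_error(self):
        # P = 0.5, Q = 0: log argument hits zero
        cmp = k2p_distance("A" * 100, "G" * 50 + "A" * 50)
        assert not cmp.defined and cmp.d is None

    def test_no_comparable_sites_is_distinct_error(self):
        with pytest.raises(NoComparableSitesError):
            k2p_distance("NNNN", "ACGT")

    def test_pairwise_deletion_matches_hand_oracle(self):
        rng = random.Random(42)
        for _ in range(30):
            a, b = _random_pair(rng, 200, rng.randrange(0, 60))
            # punch ambiguity/gap holes
            a = "N" + a[1:150] + "-" + a[151:]
            P, Q, d_hand = k2p_by_hand(a, b)
            cmp = k2p_distance(a, b)
            assert (cmp.P, cmp.Q) == (pytest.approx(P), pytest.approx(Q))
            if d_hand is None:
                assert not cmp.defined
            else:
                assert cmp.d == pytest.approx(d_hand, abs=1e-12)

    @given(st.lists(
        st.tuples(st.sampled_from("ACGTN-"), st.sampled_from("ACGTN-")),
        min_size=4, max_size=120))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_property_matches_hand_oracle_on_arbitrary_pairs(self, pairs):
        a = "".join(x for x, _ in pairs)
        b = "".join(y for _, y in pairs)
        try:
            cmp = k2p_distance(a, b)
        except NoComparableSitesError:
            assert all(x not in "ACGT" or y not in "ACGT" for x, y in pairs)
            return
        P, Q, d_hand = k2p_by_hand(a, b)
        assert (cmp.P, cmp.Q) == (pytest.approx(P), pytest.approx(Q))
        if d_hand is None:
            assert not cmp.defined
        else:
            assert cmp.d == pytest.approx(d_hand, abs=1e-12)

    def test_k2p_at_least_p_distance(self):
        # the multiple-hit correction can only stretch distances
        rng = random.Random(7)
        for _ in range(50):
            a, b = _random_pair(rng, 300, rng.randrange(0, 120))
            cmp = k2p_distance(a, b)
            if cmp.defined:
                assert cmp.d >= p_distance(a, b) - 1e-12


class TestDistanceMatrix:
    def test_identical_sequences_all_zero(self):
        ds = make_dataset({k: "ACGTACGT" for k in "abc"},
                          {k: ("S1", "G1", "F1", "O1") for k in "abc"})
        m = distance_matrix(ds)
        assert np.allclose(m.d, 0.0)

    def test_matches_per_pair_recomputation(self, small_sim, small_matrix):
        recs = small_sim.dataset.records
        for i in range(0, len(recs), 5):
            for j in range(i + 1, len(recs), 7):
                cmp = k2p_distance(recs[i].sequence, recs[j].sequence)
                assert small_matrix.d[i, j] == pytest.approx(cmp.d, abs=1e-12)
                assert small_matrix.n_comparable[i, j] == cmp.n_comparable

    def test_permutation_consistency(self, small_sim, small_matrix):
        ds = small_sim.dataset
        perm_ds = make_dataset(
            {r.id: r.sequence for r in reversed(ds.records)},
            ds.taxonomy())
        m2 = distance_matrix(perm_ds)
        for a in range(0, len(ds), 4):
            for b in range(a + 1, len(ds), 4):
                i2 = m2.ids.index(ds.ids[a])
                j2 = m2.ids.index(ds.ids[b])
                assert m2.d[i2, j2] == small_matrix.d[a, b]


class TestRankSummaries:
    def test_hand_built_two_tier_matrix(self):
        ids = ["s1a", "s1b", "s2a", "s2b"]
        tax = {"s1a": ("S1", "G", "F", "O"), "s1b": ("S1", "G", "F", "O"),
               "s2a": ("S2", "G", "F", "O"), "s2b": ("S2", "G", "F", "O")}
        pct = {("s1a", "s1b"): 0.2, ("s2a", "s2b"): 0.2,
               ("s1a", "s2a"): 6.0, ("s1a", "s2b"): 6.0,
               ("s1b", "s2a"): 6.0, ("s1b", "s2b"): 6.0}
        summaries = summarize_by_rank(matrix_from_percent(ids, pct), tax)
        by = {s.level: s for s in summaries}
        assert by["within_species"].mean == pytest.approx(0.2)
        assert by["within_species"].n_pairs == 2
        assert by["within_genus"].mean == pytest.approx(6.0)
        assert by["within_genus"].n_pairs == 4
        assert "within_family" not in by  # single genus: stratum omitted

    def test_singleton_species_stratum_omitted(self):
        ids = ["x", "y"]
        tax = {"x": ("S1", "G1", "F", "O"), "y": ("S2", "G2", "F", "O")}
        summaries = summarize_by_rank(
            matrix_from_percent(ids, {("x", "y"): 10.0}), tax)
        assert {s.level for s in summaries} == {"within_family"}

    def test_strata_partition_defined_same_order_pairs(self, small_sim,
                                                       small_matrix):
        tax = small_sim.dataset.taxonomy()
        summaries = summarize_by_rank(small_matrix, tax)
        n = len(small_matrix.ids)
        same_order = sum(
            1 for i in range(n) for j in range(i + 1, n)
            if small_matrix.defined[i, j]
            and tax[small_matrix.ids[i]][3] == tax[small_matrix.ids[j]][3])
        assert sum(s.n_pairs for s in summaries) == same_order

    def test_recovers_simulated_tier_means(self, small_sim, small_matrix):
        summaries = summarize_by_rank(small_matrix,
                                      small_sim.dataset.taxonomy())
        targets = {"within_species": 0.21, "within_genus": 6.5,
                   "within_family": 23.7, "within_order": 25.6}
        for s in summaries:
            assert s.mean == pytest.approx(targets[s.level], rel=0.25)


class TestFoldRatio:
    def test_table_values_give_31_fold(self):
        summaries = [
            RankDivergenceSummary("within_species", 85, 240, 0.21, 0, 1.83, 0.01),
            RankDivergenceSummary("within_genus", 68, 500, 6.50, 0, 21.7, 0.02),
        ]
        ratio = interspecific_fold_ratio(summaries)
        assert round(ratio) == 31

    def test_equal_means_give_one(self):
        summaries = [
            RankDivergenceSummary("within_species", 2, 2, 5.0, 0, 9.0, 0.1),
            RankDivergenceSummary("within_genus", 2, 2, 5.0, 0, 9.0, 0.1),
        ]
        assert interspecific_fold_ratio(summaries) == pytest.approx(1.0)

    def test_zero_intraspecific_mean_is_undefined(self):
        summaries = [
            RankDivergenceSummary("within_species", 2, 2, 0.0, 0, 0.0, 0.0),
            RankDivergenceSummary("within_genus", 2, 2, 5.0, 0, 9.0, 0.1),
        ]
        assert interspecific_fold_ratio(summaries) is None


class TestBarcodingGap:
    IDS = ["s1a", "s1b", "s2a", "lone"]
    TAX = {"s1a": ("S1", "G", "F", "O"), "s1b": ("S1", "G", "F", "O"),
           "s2a": ("S2", "G", "F", "O"), "lone": ("S3", "G", "F", "O")}

    def _matrix(self):
        return matrix_from_percent(self.IDS, {
            ("s1a", "s1b"): 0.4,
            ("s1a", "s2a"): 5.0, ("s1b", "s2a"): 5.5,
            ("s1a", "lone"): 8.0, ("s1b", "lone"): 8.5,
            ("s2a", "lone"): 9.0})

    def test_gap_is_nn_minus_max_intra(self):
        records = {g.species: g for g in barcoding_gap(self._matrix(), self.TAX)}
        g = records["S1"]
        assert g.max_intraspecific == pytest.approx(0.4)
        assert g.min_to_nearest_heterospecific == pytest.approx(5.0)
        assert g.nearest_neighbor == "S2"
        assert g.gap == pytest.approx(4.6)

    def test_singleton_gets_nn_but_no_gap(self):
        records = {g.species: g for g in barcoding_gap(self._matrix(), self.TAX)}
        lone = records["S3"]
        assert lone.gap is None and lone.max_intraspecific is None
        assert lone.min_to_nearest_heterospecific == pytest.approx(8.0)

    def test_cross_species_identical_sequences_overlap(self):
        ids = ["s1a", "s1b", "s2a"]
        tax = {"s1a": ("S1", "G", "F", "O"), "s1b": ("S1", "G", "F", "O"),
               "s2a": ("S2", "G", "F", "O")}
        m = matrix_from_percent(ids, {("s1a", "s1b"): 0.5,
                                      ("s1a", "s2a"): 0.0,
                                      ("s1b", "s2a"): 0.5})
        g = {r.species: r for r in barcoding_gap(m, tax)}["S1"]
        assert g.gap is not None and g.gap <= 0
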