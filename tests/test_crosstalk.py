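"""Syn/Hetero grouping, pairwise distances, degree, co-occurrence."""

from itertools import combinations

import numpy as np
import pytest

from ptmdyn.crosstalk import (
    classify_protein_group,
    cooccurrence_matrix,
    interaction_degree,
    pairwise_distances,
    summarize_protein,
    ProteinCrosstalkSummary,
)
from ptmdyn.io_tables import InteractionEdge
from ptmdyn.temporal import classify_rule_based
from .conftest import make_profile


def _cls(m05, m2, position=1, ptm_type="phospho", accession="P1"):
    return classify_rule_based(
        make_profile(m05, m2, accession=accession, position=position, ptm_type=ptm_type)
    )


class TestClassifyProteinGroup:
    @pytest.mark.parametrize(
        "speeds,expected",
        [
            ([], "unregulated"),
            ([("fast")], "single"),
            (["fast", "fast"], "syn"),
            (["slow", "slow", "slow"], "syn"),
            (["fast", "slow"], "hetero"),
            (["fast", "fast", "slow"], "hetero"),
        ],
    )
    def test_grouping_by_speed_axis(self, speeds, expected):
        profile_of = {"fast": (1.5, 0.0), "slow": (0.0, 1.5)}
        cls = [
            _cls(*profile_of[s], position=i + 1) for i, s in enumerate(speeds)
        ]
        cls.append(_cls(0.1, 0.1, position=99))  # unregulated site never counts
        assert classify_protein_group(cls) == expected

    def test_direction_and_persistence_ignored(self):
        # fast-up + fast-down is still synchronous: only speed matters
        cls = [_cls(1.5, 1.5, position=1), _cls(-1.5, 0.0, position=2)]
        assert classify_protein_group(cls) == "syn"


class TestPairwiseDistances:
    def test_all_pairs_enumeration(self):
        sites = [(10, "fast"), (20, "fast"), (40, "fast")]
        distances = pairwise_distances(sites, "all_regulated")
        assert sorted(distances) == [10, 20, 30]
        assert np.mean(distances) == 20

    def test_hetero_protein_pair_sets(self):
        # fast at 10, slow at 50, slow at 60
        sites = [(10, "fast"), (50, "slow"), (60, "slow")]
        assert sorted(pairwise_distances(sites, "hetero_pairs")) == [40, 50]
        assert pairwise_distances(sites, "syn_pairs") == [10]

    def test_single_site_yields_empty(self):
        assert pairwise_distances([(10, "fast")], "all_regulated") == []

    def test_order_invariance_and_positivity(self):
        rng = np.random.default_rng(0)
        sites = [(int(p), s) for p, s in zip(rng.integers(1, 500, 8),
                                             rng.choice(["fast", "slow"], 8))]
        d1 = sorted(pairwise_distances(sites, "all_regulated"))
        d2 = sorted(pairwise_distances(sites[::-1], "all_regulated"))
        assert d1 == d2
        assert all(d >= 0 for d in d1)

    def test_unknown_pair_set_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([], "nope")


class TestInteractionDegree:
    def test_star_graph(self):
        edges = [InteractionEdge("HUB", leaf, 0.9) for leaf in "ABCD"]
        degrees = interaction_degree(["HUB", "A", "ZZZ"], edges)
        assert degrees == {"HUB": 4, "A": 1, "ZZZ": 0}

    def test_duplicate_edge_counted_once(self):
        edges = [InteractionEdge("A", "B", 0.9), InteractionEdge("A", "B", 0.95)]
        assert interaction_degree(["A"], edges)["A"] == 1


class TestSummarizeProtein:
    def test_syn_protein_distance_and_flags(self):
        cls = [
            _cls(1.5, 0.0, position=10, ptm_type="acetyl"),
            _cls(1.5, 0.0, position=20, ptm_type="phospho"),
            _cls(0.1, 0.1, position=300),
        ]
        s = summarize_protein("P1", cls, [10, 20, 300], degree=2)
        assert s.group == "syn"
        assert s.multi_type is True
        assert s.n_sites_total == 3 and s.n_sites_regulated == 2
        assert s.mean_distance_all == 10
        assert s.fast_types == {"acetyl", "phospho"}

    def test_unregulated_protein_uses_quantified_pairs(self):
        cls = [_cls(0.1, 0.1, position=10), _cls(0.2, 0.0, position=40)]
        s = summarize_protein("P1", cls, [10, 40])
        assert s.group == "unregulated"
        assert s.mean_distance_all == 30

    def test_hetero_protein_split_distances(self):
        cls = [
            _cls(1.5, 0.0, position=10),
            _cls(0.0, 1.5, position=50),
            _cls(0.0, 1.5, position=60),
        ]
        s = summarize_protein("P1", cls, [10, 50, 60])
        assert s.group == "hetero"
        assert s.mean_distance_hetero == 45  # (40 + 50) / 2
        assert s.mean_distance_syn == 10


class TestCooccurrence:
    def test_single_fast_acetyl_slow_phospho_protein(self):
        s = ProteinCrosstalkSummary(
            accession="P1",
            group="hetero",
            fast_types={"acetyl"},
            slow_types={"phospho"},
        )
        mat = cooccurrence_matrix([s])
        assert mat.loc["acetyl", "phospho"] == 1
        assert mat.values.sum() == 1

    def test_empty_input_is_zero_matrix(self):
        assert cooccurrence_matrix([]).values.sum() == 0

    def test_wcp_pseudo_type_uses_protein_speed(self):
        s = ProteinCrosstalkSummary(
            accession="P1", group="single", fast_types={"ubiquityl"}, slow_types=set()
        )
        mat = cooccurrence_matrix([s], wcp_speed={"P1": "slow"})
        assert mat.loc["ubiquityl", "wcp"] == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(4)
        types = ["acetyl", "phospho", "ubiquityl"]
        summaries = []
        for i in range(10):
            summaries.append(
                ProteinCrosstalkSummary(
                    accession=f"P{i}",
                    group="hetero",
                    fast_types=set(rng.choice(types, rng.integers(0, 3), replace=False)),
                    slow_types=set(rng.choice(types, rng.integers(0, 3), replace=False)),
                )
            )
        mat = cooccurrence_matrix(summaries)
        for x in types:
            for y in types:
                expected = sum(
                    1 for s in summaries if x in s.fast_types and y in s.slow_types
                )
                assert mat.loc[x, y] == expected

    def test_group_sizes_partition_protein_universe(self):
        rng = np.random.default_rng(5)
        summaries = []
        for i in range(30):
            n_fast, n_slow = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            cls = [_cls(1.5, 0.0, position=10 * j + 1) for j in range(n_fast)]
            cls += [_cls(0.0, 1.5, position=100 * j + 5) for j in range(n_slow)]
            cls += [_cls(0.0, 0.0, position=900)]
            summaries.append(summarize_protein(f"P{i}", cls, [900]))
        groups = [s.group for s in summaries]
        assert len(groups) == 30
        assert set(groups) <= {"unregulated", "single", "syn", "hetero"}
        single = [s for s in summaries if s.group == "single"]
        assert all(s.n_sites_regulated == 1 for s in single)
        multi = [s for s in summaries if s.group in ("syn", "hetero")]
        assert all(s.n_sites_regulated >= 2 for s in multi)
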