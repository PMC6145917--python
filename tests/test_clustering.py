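"""Greedy clustering, chaining, the threshold ladder, and OTU tables."""

import numpy as np
import pytest

from phylocore import (
    DEFAULT_GRID,
    build_otu_table,
    chain_cluster,
    greedy_cluster,
    ladder_cluster,
    pairwise_identity,
)
from conftest import make_dataset, mutate, random_seq
from _oracles import greedy_cluster_oracle


class TestGreedyCluster:
    def test_identical_sequences_one_otu(self, rng):
        seq = random_seq(rng, 120)
        res = greedy_cluster([("a", seq, 1), ("b", seq, 1), ("c", seq, 1)], 0.97)
        assert len(res.otus) == 1
        assert set(res.otus[0].member_ids) == {"a", "b", "c"}

    def test_threshold_splits_at_constructed_identity(self, rng):
        seq = random_seq(rng, 100)
        var = mutate(rng, seq, 5)  # identity exactly 0.95
        assert pairwise_identity(seq, var) == pytest.approx(0.95)
        items = [("a", seq, 2), ("b", var, 1)]
        assert len(greedy_cluster(items, 0.97).otus) == 2
        assert len(greedy_cluster(items, 0.90).otus) == 1

    def test_empty_input(self):
        res = greedy_cluster([], 0.97)
        assert res.otus == [] and res.origin_map == {}

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            greedy_cluster([("a", "ACGT" * 30, 1), ("a", "ACGT" * 30, 1)], 0.9)

    def test_processing_order_weight_then_id(self, rng):
        seq = random_seq(rng, 100)
        # heaviest item becomes the centroid regardless of listing order
        res = greedy_cluster(
            [("z", mutate(rng, seq, 1), 1), ("m", seq, 5)], 0.97
        )
        assert res.otus[0].representative_id == "m"
        # tie on weight: ascending id founds the OTU
        res2 = greedy_cluster([("b", seq, 1), ("a", seq, 1)], 0.97)
        assert res2.otus[0].representative_id == "a"

    def test_otu_ids_and_membership_guarantee(self, rng):
        seqs = [random_seq(rng, 150) for _ in range(8)]
        items = [(f"s{i}", s, 1) for i, s in enumerate(seqs)]
        res = greedy_cluster(items, 0.9)
        for k, otu in enumerate(res.otus):
            assert otu.otu_id == f"T90_{k + 1}"
            assert otu.representative_id in otu.member_ids
            for m in otu.member_ids:
                seq = seqs[int(m[1:])]
                if m != otu.representative_id:
                    assert pairwise_identity(seq, otu.representative_seq) >= 0.9

    def test_deterministic(self, rng):
        items = [(f"s{i}", random_seq(rng, 90), int(rng.integers(1, 5))) for i in range(15)]
        a = greedy_cluster(items, 0.85)
        b = greedy_cluster(items, 0.85)
        assert a.origin_map == b.origin_map
        assert [o.otu_id for o in a.otus] == [o.otu_id for o in b.otus]

    def test_matches_quadratic_reference(self, rng):
        """Structured instance: ancestors + mutants; oracle shares only the
        identity callable and the stated ordering/tie rules."""
        ancestors = [random_seq(rng, 120) for _ in range(4)]
        items = []
        for i in range(30):
            anc = ancestors[int(rng.integers(4))]
            items.append((f"q{i:02d}", mutate(rng, anc, int(rng.integers(0, 8))), int(rng.integers(1, 6))))
        res = greedy_cluster(items, 0.95)
        assign, reps = greedy_cluster_oracle(items, 0.95, pairwise_identity)
        assert [o.representative_id for o in res.otus] == [r[0] for r in reps]
        got = {sid: int(res.origin_map[sid].rsplit("_", 1)[1]) - 1 for sid in assign}
        assert got == assign


class TestChainAndLadder:
    def test_single_otu_chains_to_single_otu(self):
        ds = make_dataset({"S1": ["ACGT" * 30] * 3})
        ladder = ladder_cluster(ds, [0.97, 0.96])
        assert len(ladder[0.96].otus) == 1
        assert set(ladder[0.96].origin_map) == set(ladder[0.97].origin_map)

    def test_chain_requires_lower_threshold(self, rng):
        ds = make_dataset({"S1": [random_seq(rng, 100)]})
        prev = ladder_cluster(ds, [0.97])[0.97]
        with pytest.raises(ValueError):
            chain_cluster(prev, 0.97)

    def test_merge_conserves_membership(self, rng):
        anc = random_seq(rng, 100)
        varA, varB = anc, mutate(rng, anc, 4)  # 0.96 identity
        ds = make_dataset({"S1": [varA] * 3 + [varB] * 2})
        ladder = ladder_cluster(ds, [0.97, 0.95])
        assert len(ladder[0.97].otus) == 2
        assert len(ladder[0.95].otus) == 1
        assert len(ladder[0.95].origin_map) == 5

    def test_three_step_chain_composes_maps(self, rng):
        ancs = [random_seq(rng, 150) for _ in range(3)]
        seqs = [mutate(rng, ancs[i % 3], int(rng.integers(0, 10))) for i in range(30)]
        ds = make_dataset({"S1": seqs[:15], "S2": seqs[15:]})
        ladder = ladder_cluster(ds, [0.97, 0.96, 0.95])
        # explicit composition of the per-step maps
        l97, l96, l95 = ladder[0.97], ladder[0.96], ladder[0.95]
        rep96 = {o.otu_id: o.representative_id for o in l96.otus}
        # map each read through 0.97 -> 0.96 -> 0.95 via representatives
        rep97 = {o.otu_id: o.representative_id for o in l97.otus}
        for rec in ds:
            o97 = l97.origin_map[rec.seq_id]
            o96 = l96.origin_map[rep97[o97]]
            o95 = l95.origin_map[rep96[o96]]
            assert l95.origin_map[rec.seq_id] == o95

    def test_default_grid_has_23_levels(self):
        assert len(DEFAULT_GRID) == 23
        assert DEFAULT_GRID[0] == 0.97 and DEFAULT_GRID[-1] == 0.75

    def test_single_sequence_dataset_one_otu_everywhere(self):
        ds = make_dataset({"S1": ["ACGTAGCTAGCTAGGCTA" * 6]})
        ladder = ladder_cluster(ds, DEFAULT_GRID)
        assert all(len(res.otus) == 1 for res in ladder.values())

    def test_otu_count_monotone_and_totals_conserved(self, rng):
        ancs = [random_seq(rng, 120) for _ in range(5)]
        seqs = [mutate(rng, ancs[i % 5], int(rng.integers(0, 15))) for i in range(40)]
        ds = make_dataset({"S1": seqs[:20], "S2": seqs[20:]})
        ladder = ladder_cluster(ds, DEFAULT_GRID)
        counts = [len(ladder[t].otus) for t in DEFAULT_GRID]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for t in DEFAULT_GRID:
            assert build_otu_table(ladder[t], ds).total == len(ds)

    def test_non_descending_grid_rejected(self, rng):
        ds = make_dataset({"S1": [random_seq(rng, 100)]})
        with pytest.raises(ValueError):
            ladder_cluster(ds, [0.95, 0.97])


class TestBuildTable:
    def test_single_cell(self):
        ds = make_dataset({"S1": ["ACGT" * 30] * 5})
        res = ladder_cluster(ds, [0.97])[0.97]
        table = build_otu_table(res, ds)
        assert table.counts.tolist() == [[5]]

    def test_shared_otu_spans_samples(self):
        ds = make_dataset({"S1": ["ACGT" * 30] * 2, "S2": ["ACGT" * 30] * 3})
        table = build_otu_table(ladder_cluster(ds, [0.97])[0.97], ds)
        assert table.counts.shape == (2, 1)
        assert (table.counts > 0).sum() == 2
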