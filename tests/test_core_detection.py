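"""Masking, per-level core detection, and the full dynamic-core walk."""

import numpy as np
import pytest

from phylocore import (
    build_otu_table,
    detect_core_at_level,
    ladder_cluster,
    mask_table,
    run_dynamic_core,
)
from phylocore.core_detection import recount_core_prevalence
from phylocore.seq_io import OTUTable
from conftest import make_dataset, mutate, random_seq
from _oracles import recount_presence


class TestMaskTable:
    def _setup(self, rng):
        anc1, anc2 = random_seq(rng, 100), random_seq(rng, 100)
        ds = make_dataset(
            {"S1": [anc1, anc1, anc2], "S2": [anc1, anc2, anc2]}
        )
        res = ladder_cluster(ds, [0.97])[0.97]
        return ds, res, build_otu_table(res, ds)

    def test_no_claims_is_identity(self, rng):
        ds, res, table = self._setup(rng)
        assert mask_table(table, res, set(), ds) == table

    def test_full_otu_claim_zeroes_its_column(self, rng):
        ds, res, table = self._setup(rng)
        members = res.members_by_otu()
        target = table.otu_ids[0]
        masked = mask_table(table, res, set(members[target]), ds)
        j = masked.otu_ids.index(target)
        assert (masked.counts[:, j] == 0).all()
        other = [k for k in range(len(table.otu_ids)) if k != j]
        assert np.array_equal(masked.counts[:, other], table.counts[:, other])

    def test_partial_claim_drops_exact_counts(self, rng):
        ds, res, table = self._setup(rng)
        members = res.members_by_otu()
        target = table.otu_ids[0]
        claim = set(members[target][:2])  # spread over the samples
        masked = mask_table(table, res, claim, ds)
        # brute-force recount over raw records
        for j, otu in enumerate(table.otu_ids):
            for i, s in enumerate(table.sample_ids):
                expect = sum(
                    1
                    for rec in ds
                    if rec.sample_id == s
                    and rec.seq_id not in claim
                    and res.origin_map[rec.seq_id] == otu
                )
                assert masked.counts[i, j] == expect


class TestDetectCore:
    def _table(self, counts):
        arr = np.array(counts)
        return OTUTable(
            tuple(f"S{i}" for i in range(arr.shape[0])),
            tuple(f"o{j}" for j in range(arr.shape[1])),
            arr,
            0.97,
        )

    def test_prevalence_one_requires_all_samples(self):
        t = self._table([[1, 1], [2, 0], [3, 1]])
        assert detect_core_at_level(t, 1.0) == ["o0"]

    def test_fractional_prevalence_uses_ceil(self):
        t = self._table([[1, 1], [2, 0], [3, 1]])  # o1 in 2/3 samples
        assert detect_core_at_level(t, 0.6) == ["o0", "o1"]  # ceil(1.8)=2

    def test_all_zero_column_never_core(self):
        t = self._table([[1, 0], [2, 0]])
        assert detect_core_at_level(t, 0.1) == ["o0"]

    def test_prevalence_monotone(self):
        rng = np.random.default_rng(5)
        t = self._table(rng.integers(0, 3, size=(6, 20)))
        prev_sets = [set(detect_core_at_level(t, p)) for p in (1.0, 0.8, 0.5, 0.2)]
        for hi, lo in zip(prev_sets, prev_sets[1:]):
            assert hi <= lo  # lowering prevalence never removes a core


class TestRunDynamicCore:
    def test_requires_two_samples(self):
        ds = make_dataset({"S1": ["ACGT" * 30]})
        with pytest.raises(ValueError):
            run_dynamic_core(ds)

    def test_exact_shared_sequence_is_core_at_097(self, rng):
        shared = random_seq(rng, 120)
        privates = {s: random_seq(rng, 120) for s in ("S1", "S2", "S3")}
        ds = make_dataset({s: [shared, privates[s]] for s in privates})
        core = run_dynamic_core(ds)
        assert len(core.cores) == 1
        c = core.cores[0]
        assert c.detection_threshold == 0.97
        assert all(v == 1 for v in c.per_sample_counts.values())

    def test_disjoint_private_sequences_no_core(self, rng):
        ds = make_dataset(
            {f"S{i}": [random_seq(rng, 150) for _ in range(3)] for i in range(3)}
        )
        core = run_dynamic_core(ds)
        assert core.cores == []

    def test_two_planted_lineages_detected_disjointly(self, rng):
        """A tight universal lineage surfaces at 0.97; a broad one whose
        0.97 variants are subject-private surfaces deeper, disjointly."""
        ancA, ancB = random_seq(rng, 200), random_seq(rng, 200)
        spec = {}
        for i, s in enumerate(("S1", "S2", "S3")):
            tight = mutate(rng, ancA, 2)  # within 1% of ancestor A
            broad = mutate(rng, ancB, 10)  # private ~5% variant of B
            spec[s] = [ancA, tight, broad, broad]
        ds = make_dataset(spec)
        core = run_dynamic_core(ds)
        levels = sorted({c.detection_threshold for c in core.cores}, reverse=True)
        assert levels[0] == 0.97
        assert len(levels) >= 2 and levels[1] < 0.97
        ids = [set(c.masked_member_ids) for c in core.cores]
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert not (a & b)

    def test_masked_membership_disjoint_and_recount_sound(self, rng):
        ancs = [random_seq(rng, 150) for _ in range(4)]
        spec = {
            f"S{i}": [mutate(rng, ancs[j % 4], int(rng.integers(0, 12))) for j in range(10)]
            for i in range(4)
        }
        ds = make_dataset(spec)
        core = run_dynamic_core(ds)
        claimed = []
        for c in core.cores:
            claimed.extend(c.masked_member_ids)
        assert len(claimed) == len(set(claimed))  # pairwise disjoint
        assert len(claimed) <= len(ds)
        presence = recount_presence(
            {c.otu_id: set(c.masked_member_ids) for c in core.cores}, ds.records
        )
        for c in core.cores:
            assert presence[c.otu_id] == set(ds.samples)

    def test_recluster_mode_agrees_on_clean_structure(self, rng):
        shared = random_seq(rng, 120)
        ds = make_dataset(
            {s: [shared, random_seq(rng, 120)] for s in ("S1", "S2", "S3")}
        )
        a = run_dynamic_core(ds)
        b = run_dynamic_core(ds, recluster_after_mask=True)
        assert len(a.cores) == len(b.cores) == 1
        assert set(a.cores[0].masked_member_ids) == set(b.cores[0].masked_member_ids)

    def test_json_round_trip(self, rng, tmp_path):
        shared = random_seq(rng, 120)
        ds = make_dataset({s: [shared] for s in ("S1", "S2")})
        core = run_dynamic_core(ds)
        p = tmp_path / "core.json"
        core.to_json(p)
        from phylocore import PhylogeneticCore

        back = PhylogeneticCore.from_json(p)
        assert [c.otu_id for c in back.cores] == [c.otu_id for c in core.cores]
        assert back.cores[0].per_sample_counts == core.cores[0].per_sample_counts
        assert back.sample_depths == core.sample_depths


def test_independent_recount_helper_matches_oracle(rng):
    shared = random_seq(rng, 120)
    ds = make_dataset({s: [shared, random_seq(rng, 120)] for s in ("S1", "S2")})
    core = run_dynamic_core(ds)
    ours = recount_core_prevalence(core, ds)
    oracle = recount_presence(
        {c.otu_id: set(c.masked_member_ids) for c in core.cores}, ds.records
    )
    assert ours == {k: len(v) for k, v in oracle.items()}
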