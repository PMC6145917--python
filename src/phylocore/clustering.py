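"""Greedy centroid OTU clustering and the multi-step (chained) ladder.

De novo clustering at a fixed identity threshold: items are processed in
order of decreasing weight (ties: ascending id); each item is compared to
all existing centroids and joins the best one with identity >= threshold
(identity ties: earliest-created centroid), otherwise it founds a new OTU.
The ladder chains levels: the representatives of level t feed clustering at
the next lower threshold, weighted by their OTUs' original-sequence counts,
and membership maps are composed back to original reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._align import pairwise_identity
from .seq_io import Dataset, OTUTable

#: The study's threshold ladder: all 0.01 steps from 0.97 down to 0.75,
#: both endpoints included (23 levels).
DEFAULT_GRID: tuple[float, ...] = tuple(round(x / 100, 2) for x in range(97, 74, -1))


@dataclass(frozen=True)
class OTU:
    otu_id: str
    threshold: float
    representative_id: str
    representative_seq: str
    member_ids: tuple[str, ...]  # ids of this level's input items, creation order


@dataclass
class ClusteringResult:
    """OTUs at one threshold plus the membership map.

    ``origin_map`` maps every clustered id to its OTU id.  For ladder levels
    it is composed down to *original* read ids even though the level's direct
    input items are dereplicated uniques or previous-level representatives.
    """

    threshold: float
    otus: list[OTU]
    origin_map: dict[str, str]

    def otu_by_id(self, otu_id: str) -> OTU:
        for o in self.otus:
            if o.otu_id == otu_id:
                return o
        raise KeyError(otu_id)

    def members_by_otu(self) -> dict[str, list[str]]:
        """Invert origin_map: OTU id -> ids of original sequences, input order."""
        out: dict[str, list[str]] = {o.otu_id: [] for o in self.otus}
        for seq_id, otu_id in self.origin_map.items():
            out[otu_id].append(seq_id)
        return out


def _otu_id(threshold: float, k: int) -> str:
    return f"T{int(round(threshold * 100))}_{k}"


def greedy_cluster(
    items: Sequence[tuple[str, str, int]], threshold: float
) -> ClusteringResult:
    """Cluster ``(id, sequence, weight)`` items at ``threshold``.

    Deterministic: abundance-sorted processing, best-hit assignment with
    earliest-centroid tie-break, OTU ids ``T<threshold*100>_<k>`` in creation
    order.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    ids = [it[0] for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate item ids")
    order = sorted(items, key=lambda it: (-it[2], it[0]))

    cent_ids: list[str] = []
    cent_seqs: list[str] = []
    members: list[list[str]] = []
    origin_map: dict[str, str] = {}

    for item_id, seq, weight in order:
        if weight < 1:
            raise ValueError(f"weight of {item_id!r} must be >= 1")
        best_k = -1
        best_ident = -1.0
        for k in range(len(cent_ids)):
            ident = pairwise_identity(seq, cent_seqs[k])
            if ident > best_ident:  # strict > keeps the earliest centroid on ties
                best_ident = ident
                best_k = k
        if best_k >= 0 and best_ident >= threshold:
            members[best_k].append(item_id)
        else:
            cent_ids.append(item_id)
            cent_seqs.append(seq)
            members.append([item_id])
            best_k = len(cent_ids) - 1
        origin_map[item_id] = best_k  # resolved to string ids below

    otus = [
        OTU(_otu_id(threshold, k + 1), threshold, cent_ids[k], cent_seqs[k], tuple(members[k]))
        for k in range(len(cent_ids))
    ]
    origin = {item_id: otus[k].otu_id for item_id, k in origin_map.items()}
    return ClusteringResult(threshold, otus, origin)


def dereplicate(records: Iterable) -> list[tuple[str, str, int, list[str]]]:
    """Collapse exact duplicate sequences.

    Returns ``(unique_id, sequence, weight, original_ids)`` per distinct
    sequence; ``unique_id`` is the lexicographically smallest member id.
    """
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.residues, []).append(rec.seq_id)
    out = []
    for seq, idlist in groups.items():
        uid = min(idlist)
        out.append((uid, seq, len(idlist), idlist))
    out.sort(key=lambda t: t[0])
    return out


def chain_cluster(prev: ClusteringResult, threshold: float) -> ClusteringResult:
    """Cluster the previous level's representatives at a lower threshold.

    Representatives are weighted by their OTUs' total original-sequence
    counts; the returned origin_map is the composition original read ->
    previous OTU -> new OTU.
    """
    if threshold >= prev.threshold:
        raise ValueError(
            f"chained threshold {threshold} must be below previous {prev.threshold}"
        )
    weights: dict[str, int] = {o.otu_id: 0 for o in prev.otus}
    for otu_id in prev.origin_map.values():
        weights[otu_id] += 1
    items = [
        (o.representative_id, o.representative_seq, max(weights[o.otu_id], 1))
        for o in prev.otus
    ]
    sub = greedy_cluster(items, threshold)
    rep_of_prev = {o.otu_id: o.representative_id for o in prev.otus}
    origin = {
        seq_id: sub.origin_map[rep_of_prev[prev_otu]]
        for seq_id, prev_otu in prev.origin_map.items()
    }
    return ClusteringResult(threshold, sub.otus, origin)


def ladder_cluster(
    dataset: Dataset, thresholds: Sequence[float] = DEFAULT_GRID
) -> dict[float, ClusteringResult]:
    """Multi-step OTU picking over a strictly descending threshold grid.

    The first level clusters dereplicated unique sequences (weight =
    duplicate count); every later level chains from the previous one.  All
    returned origin_maps cover the original read ids.
    """
    thresholds = [round(float(t), 6) for t in thresholds]
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0,1)")
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly descending")
    if not thresholds:
        raise ValueError("empty threshold grid")

    uniques = dereplicate(dataset.records)
    items = [(uid, seq, w) for uid, seq, w, _ in uniques]
    first = greedy_cluster(items, thresholds[0])
    # expand the membership map from unique ids to all original read ids
    full_map: dict[str, str] = {}
    for uid, _seq, _w, idlist in uniques:
        otu = first.origin_map[uid]
        for seq_id in idlist:
            full_map[seq_id] = otu
    levels: dict[float, ClusteringResult] = {
        thresholds[0]: ClusteringResult(thresholds[0], first.otus, full_map)
    }
    prev = levels[thresholds[0]]
    for t in thresholds[1:]:
        prev = chain_cluster(prev, t)
        levels[t] = prev
    return levels


def build_otu_table(result: ClusteringResult, dataset: Dataset) -> OTUTable:
    """Subjects x OTUs counts from a clustering's origin_map."""
    otu_index = {o.otu_id: j for j, o in enumerate(result.otus)}
    sample_index = {s: i for i, s in enumerate(dataset.samples)}
    counts = np.zeros((len(sample_index), len(otu_index)), dtype=np.int64)
    for rec in dataset.records:
        if rec.seq_id not in result.origin_map:
            raise ValueError(f"record {rec.seq_id!r} missing from origin_map")
        counts[sample_index[rec.sample_id], otu_index[result.origin_map[rec.seq_id]]] += 1
    return OTUTable(
        dataset.samples, tuple(o.otu_id for o in result.otus), counts, result.threshold
    )
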