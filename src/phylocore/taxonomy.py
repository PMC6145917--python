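"""Consensus taxonomy per core OTU from per-sequence classifier output.

The classifier itself runs externally (e.g. a naive-Bayes 16S classifier
against SILVA); this module consumes its per-sequence assignments in the
mothur ``.taxonomy`` dialect — ``seq_id TAB Taxon(conf);Taxon(conf);...`` —
and reduces them to one consensus lineage per core OTU.  Before the
consensus walk each lineage is truncated at the first rank whose confidence
falls below ``min_confidence`` (default 0.80, the usual bootstrap cutoff).
Walking root to leaf, a taxon is kept while it is held by at least
``cutoff`` of all inputs (default 0.51); the walk stops at the first rank
without such a majority.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .clustering import dereplicate, greedy_cluster
from .core_detection import CoreOTU
from .seq_io import Dataset

_TAXON_RE = re.compile(r"^(.*?)(?:\((\d+(?:\.\d+)?)\))?$")


@dataclass(frozen=True)
class RankAssignment:
    taxon: str
    confidence: float  # in [0,1]


Lineage = tuple[RankAssignment, ...]


@dataclass
class ConsensusTaxonomy:
    core_otu_id: str | None
    lineage: tuple[str, ...]
    support: float  # fraction of inputs agreeing at the deepest reported rank
    n_inputs: int


def parse_lineage(text: str) -> Lineage:
    """Parse ``Taxon(conf);Taxon(conf);...``; confidence defaults to 1.0.

    Confidences above 1 are interpreted as percentages.
    """
    out = []
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        m = _TAXON_RE.match(part)
        name = m.group(1).strip()
        conf = float(m.group(2)) if m.group(2) is not None else 1.0
        if conf > 1:
            conf /= 100.0
        if not 0 <= conf <= 1:
            raise ValueError(f"confidence out of range in {part!r}")
        out.append(RankAssignment(name, conf))
    return tuple(out)


def read_taxonomy(path) -> dict[str, Lineage]:
    """Read a mothur-style ``.taxonomy`` TSV: seq_id TAB lineage."""
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0]] = parse_lineage(parts[1])
    return out


def truncate_lineage(lineage: Lineage, min_confidence: float) -> Lineage:
    """Cut the lineage at the first rank with confidence < min_confidence."""
    kept = []
    for ra in lineage:
        if ra.confidence < min_confidence:
            break
        kept.append(ra)
    return tuple(kept)


def consensus(
    assignments: Sequence[Lineage],
    cutoff: float = 0.51,
    min_confidence: float = 0.80,
    core_otu_id: str | None = None,
) -> ConsensusTaxonomy:
    """Majority-walk consensus over per-sequence lineages.

    The agreement fraction at every rank is computed against *all* inputs,
    so a short (early-truncated) lineage counts against deeper consensus.
    A tie at a rank (possible only when cutoff <= 0.5) stops the walk.
    """
    if not assignments:
        raise ValueError("consensus requires at least one assignment")
    n = len(assignments)
    lineages = [truncate_lineage(lin, min_confidence) for lin in assignments]

    names: list[str] = []
    support = 1.0  # vacuous agreement at the root when nothing is classifiable
    depth = 0
    while True:
        counts: dict[str, int] = {}
        for lin in lineages:
            if len(lin) > depth and tuple(r.taxon for r in lin[:depth]) == tuple(names):
                counts[lin[depth].taxon] = counts.get(lin[depth].taxon, 0) + 1
        if not counts:
            break
        best = max(counts.values())
        winners = [t for t, c in counts.items() if c == best]
        if len(winners) != 1 or best / n < cutoff:
            break
        names.append(winners[0])
        support = best / n
        depth += 1
    return ConsensusTaxonomy(core_otu_id, tuple(names), support, n)


def subcluster_core(
    core_otu: CoreOTU, dataset: Dataset, threshold: float = 0.97
) -> list[tuple[str, str]]:
    """Re-cluster a core OTU's masked members at 0.97; return representatives.

    This recovers the "species-level" variants inside a deep core unit; the
    representatives are what gets classified (and matched against reference
    genomes).
    """
    records = [dataset.get(m) for m in core_otu.masked_member_ids]
    uniques = dereplicate(records)
    res = greedy_cluster([(u, s, w) for u, s, w, _ in uniques], threshold)
    return [(o.representative_id, o.representative_seq) for o in res.otus]


def consensus_for_core(
    core_otu: CoreOTU,
    dataset: Dataset,
    assignments: Mapping[str, Lineage],
    cutoff: float = 0.51,
    min_confidence: float = 0.80,
    subcluster_threshold: float = 0.97,
) -> ConsensusTaxonomy:
    """Consensus over the classifier calls of a core's 0.97 representatives."""
    reps = subcluster_core(core_otu, dataset, subcluster_threshold)
    lineages = []
    for rep_id, _seq in reps:
        if rep_id not in assignments:
            raise KeyError(f"no taxonomy assignment for representative {rep_id!r}")
        lineages.append(assignments[rep_id])
    return consensus(lineages, cutoff, min_confidence, core_otu_id=core_otu.otu_id)


def write_consensus_tsv(rows: Sequence[ConsensusTaxonomy], path) -> None:
    with open(path, "w") as fh:
        fh.write("core_otu_id\tconsensus_lineage\tsupport\tn_inputs\n")
        for r in rows:
            fh.write(
                f"{r.core_otu_id}\t{';'.join(r.lineage)}\t{r.support:.4f}\t{r.n_inputs}\n"
            )
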