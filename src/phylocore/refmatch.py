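"""Coverage of the core by a reference 16S collection.

For each core OTU, its masked members are re-clustered at 0.97 and every
resulting representative is aligned exhaustively against the reference set;
the best identity per representative is aggregated to mean ± sd per core.
Low values flag core lineages without closely related sequenced genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._align import pairwise_identity
from .core_detection import PhylogeneticCore
from .seq_io import Dataset
from .taxonomy import subcluster_core


@dataclass
class RefMatchRow:
    core_otu_id: str
    mean_best_identity: float
    sd_best_identity: float
    n_reps: int
    best_ref_ids: tuple[str, ...]


@dataclass
class RefMatchReport:
    per_core: list[RefMatchRow]


def best_identity(
    query: str,
    references: Sequence[tuple[str, str]],
    min_coverage: float = 1.0,
) -> tuple[str, float]:
    """Best semi-global identity of ``query`` to any reference.

    ``min_coverage`` drops references shorter than that fraction of the
    query length (a span filter: a fragmentary reference cannot cover the
    amplicon region).  Identity ties go to the lexicographically smallest
    reference id.
    """
    if not references:
        raise ValueError("empty reference set")
    refs = [(rid, rseq) for rid, rseq in references if len(rseq) >= min_coverage * len(query)]
    if not refs:
        raise ValueError("no reference passes the span (min_coverage) filter")
    best_id = None
    best_ident = -1.0
    for rid, rseq in refs:
        ident = pairwise_identity(query, rseq)
        if ident > best_ident or (ident == best_ident and rid < best_id):
            best_ident = ident
            best_id = rid
    return best_id, best_ident


def refmatch_report(
    core: PhylogeneticCore,
    dataset: Dataset,
    references: Sequence[tuple[str, str]],
    min_coverage: float = 1.0,
    subcluster_threshold: float = 0.97,
    ddof: int = 1,
) -> RefMatchReport:
    rows = []
    for c in core.cores:
        reps = subcluster_core(c, dataset, subcluster_threshold)
        hits = [best_identity(seq, references, min_coverage) for _rid, seq in reps]
        idents = np.array([h[1] for h in hits])
        sd = float(idents.std(ddof=ddof)) if idents.size > ddof else 0.0
        rows.append(
            RefMatchRow(
                c.otu_id,
                float(idents.mean()),
                sd,
                len(reps),
                tuple(h[0] for h in hits),
            )
        )
    return RefMatchReport(rows)


def write_refmatch_tsv(report: RefMatchReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("core_otu_id\tmean_best_identity\tsd_best_identity\tn_reps\tbest_ref_ids\n")
        for r in report.per_core:
            fh.write(
                f"{r.core_otu_id}\t{r.mean_best_identity:.4f}\t{r.sd_best_identity:.4f}"
                f"\t{r.n_reps}\t{','.join(r.best_ref_ids)}\n"
            )
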