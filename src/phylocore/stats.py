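"""Summary statistics for a detected phylogenetic core.

Pooled core frequency: per subject, the percentage of that subject's reads
claimed by any core OTU; reported as mean ± sd (sample sd, n−1 by default)
with the min/max range across subjects.  Per-core statistics: mean relative
abundance across subjects, coefficient of variation, and the abundance-rank
percentile of the core within the ECDF of all OTUs at its detection level.
Relative abundances are taken against the post-rarefaction sample depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .core_detection import PhylogeneticCore
from .seq_io import Dataset, OTUTable


class ECDF:
    """Right-continuous empirical cumulative distribution function."""

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError("ECDF needs at least one value")
        self._sorted = np.sort(arr)
        self._n = arr.size

    def __call__(self, x):
        return np.searchsorted(self._sorted, x, side="right") / self._n


def ecdf(values: Sequence[float]) -> ECDF:
    return ECDF(values)


@dataclass
class FrequencySummary:
    mean: float
    sd: float
    minimum: float
    maximum: float


@dataclass
class PerCoreStats:
    otu_id: str
    detection_threshold: float
    mean_relative_abundance: float
    cv: float
    abundance_percentile: float  # ECDF position among the level's OTUs, in %


@dataclass
class CoreSummary:
    frequency: FrequencySummary
    per_level_counts: dict[float, int]
    per_core: list[PerCoreStats]
    n_cores: int


def pooled_core_frequency(
    core: PhylogeneticCore, dataset: Dataset | None = None, ddof: int = 1
) -> FrequencySummary:
    """Percentage of each subject's reads that belong to any core OTU."""
    depths = dataset.depths() if dataset is not None else core.sample_depths
    freqs = []
    for s in core.sample_ids:
        depth = depths[s]
        if depth == 0:
            raise ValueError(f"sample {s!r} has zero depth")
        claimed = sum(c.per_sample_counts.get(s, 0) for c in core.cores)
        freqs.append(100.0 * claimed / depth)
    arr = np.asarray(freqs)
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return FrequencySummary(float(arr.mean()), sd, float(arr.min()), float(arr.max()))


def per_core_abundance_stats(
    core: PhylogeneticCore,
    masked_tables: Mapping[float, OTUTable] | None = None,
    ddof: int = 1,
) -> list[PerCoreStats]:
    """Mean relative abundance, CV, and within-level abundance percentile.

    ``masked_tables`` defaults to the per-level masked tables recorded by
    ``run_dynamic_core``; the ECDF at each level is taken over the mean
    relative abundances of that level's OTUs with nonzero masked totals.
    """
    tables = masked_tables if masked_tables is not None else core.masked_tables
    if not tables:
        raise ValueError("no per-level tables available")
    depths = np.array([core.sample_depths[s] for s in core.sample_ids], dtype=float)

    level_ecdf: dict[float, ECDF] = {}
    level_mean: dict[float, dict[str, float]] = {}
    for t, table in tables.items():
        rel = table.counts / depths[:, None]
        means = rel.mean(axis=0)
        keep = table.counts.sum(axis=0) > 0
        level_mean[t] = dict(zip(table.otu_ids, means))
        if keep.any():
            level_ecdf[t] = ECDF(means[keep])

    out = []
    for c in core.cores:
        s_counts = np.array(
            [c.per_sample_counts.get(s, 0) for s in core.sample_ids], dtype=float
        )
        rel = s_counts / depths
        mean = float(rel.mean())
        sd = float(rel.std(ddof=ddof)) if rel.size > ddof else 0.0
        cv = sd / mean if mean > 0 else float("nan")
        t = c.detection_threshold
        pct = float(level_ecdf[t](level_mean[t][c.otu_id]) * 100) if t in level_ecdf else float("nan")
        out.append(PerCoreStats(c.otu_id, t, mean, cv, pct))
    return out


def core_summary(
    core: PhylogeneticCore,
    dataset: Dataset | None = None,
    masked_tables: Mapping[float, OTUTable] | None = None,
    ddof: int = 1,
) -> CoreSummary:
    freq = pooled_core_frequency(core, dataset, ddof=ddof)
    tables = masked_tables if masked_tables is not None else core.masked_tables
    per_core = per_core_abundance_stats(core, tables, ddof=ddof) if tables else []
    return CoreSummary(freq, core.per_level_counts(), per_core, len(core.cores))


def format_summary_table(summary: CoreSummary) -> str:
    """Human-readable one-dataset analogue of the cohort summary table."""
    groups = ", ".join(
        f"{int(round(t * 100))}:{n}"
        for t, n in sorted(summary.per_level_counts.items(), reverse=True)
    )
    f = summary.frequency
    return (
        f"Frequency: {f.mean:.1f} +/- {f.sd:.1f}%\n"
        f"Range: {f.minimum:.1f}-{f.maximum:.1f}%\n"
        f"Core OTUs: {summary.n_cores}\n"
        f"Core groups per clustering threshold: {groups if groups else '(none)'}\n"
    )


def summary_to_json(summary: CoreSummary, path=None) -> str:
    doc = asdict(summary)
    doc["per_level_counts"] = {str(k): v for k, v in summary.per_level_counts.items()}
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
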