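"""End-to-end workflow: rarefy -> ladder -> core -> permutation -> summary.

All randomness flows from one master seed; each stage derives its own seed
by hashing ``"<master>:<stage name>"`` (BLAKE2, truncated below 2**31), so a
single integer reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .clustering import DEFAULT_GRID, build_otu_table, ladder_cluster
from .core_detection import run_dynamic_core
from .permutation import permutation_core_test
from .refmatch import refmatch_report, write_refmatch_tsv
from .seq_io import (
    read_fasta,
    read_fasta_with_samples,
    subsample_common_depth,
    write_fasta,
    write_otu_table,
    DEFAULT_MIN_LENGTH,
)
from .stats import core_summary, format_summary_table, summary_to_json
from .taxonomy import consensus_for_core, read_taxonomy, write_consensus_tsv

log = logging.getLogger("phylocore")


def stage_seed(master: int, stage: str) -> int:
    h = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


def parse_threshold_grid(text: str) -> tuple[float, ...]:
    """Parse ``hi:lo:step`` (e.g. ``0.97:0.75:0.01``) into a descending grid."""
    hi, lo, step = (float(x) for x in text.split(":"))
    if not (0 < lo <= hi < 1) or step <= 0:
        raise ValueError(f"bad threshold grid spec {text!r}")
    grid = []
    t = hi
    while t >= lo - 1e-9:
        grid.append(round(t, 6))
        t -= step
    return tuple(grid)


@dataclass
class RunConfig:
    input_fasta: str
    out_dir: str
    sample_map: str | None = None
    taxonomy_path: str | None = None
    references_fasta: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_GRID
    prevalence: float = 1.0
    seed: int = 1
    n_permutations: int = 100
    min_length: int = DEFAULT_MIN_LENGTH
    subsample: bool = True
    recluster_after_mask: bool = False

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["thresholds"] = list(self.thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "thresholds" in doc:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(**doc)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run the whole workflow; returns the output directory."""
    inputs = [config.input_fasta, config.sample_map, config.taxonomy_path,
              config.references_fasta]
    for p in inputs:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {str(p): _sha256(p) for p in inputs if p is not None}

    log.info("reading %s", config.input_fasta)
    dataset = read_fasta_with_samples(
        config.input_fasta, sample_map=config.sample_map, min_length=config.min_length
    )
    if config.subsample:
        dataset = subsample_common_depth(dataset, stage_seed(config.seed, "subsample"))
        log.info("rarefied to common depth %d", min(dataset.depths().values()))

    log.info("dynamic core detection over %d thresholds", len(config.thresholds))
    core = run_dynamic_core(
        dataset,
        thresholds=config.thresholds,
        prevalence=config.prevalence,
        recluster_after_mask=config.recluster_after_mask,
    )
    core.to_json(out / "core.json")
    write_fasta(
        ((c.otu_id, c.representative_seq) for c in core.cores),
        out / "core_representatives.fasta",
    )

    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)
    perm_results = {}
    for t in config.thresholds:
        table = core.masked_tables[t]
        write_otu_table(table, tables_dir / f"level_{int(round(t * 100)):03d}.tsv")
        res = permutation_core_test(
            table,
            n_permutations=config.n_permutations,
            prevalence=config.prevalence,
            seed=stage_seed(config.seed, f"permute:{t}"),
        )
        perm_results[f"{t:g}"] = {
            "observed_core_count": res.observed_core_count,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
        }
    with open(out / "permutation.json", "w") as fh:
        json.dump(perm_results, fh, indent=2, sort_keys=True)

    summary = core_summary(core, dataset)
    summary_to_json(summary, out / "summary.json")
    with open(out / "summary.txt", "w") as fh:
        fh.write(format_summary_table(summary))

    if config.taxonomy_path is not None:
        assignments = read_taxonomy(config.taxonomy_path)
        rows = [consensus_for_core(c, dataset, assignments) for c in core.cores]
        write_consensus_tsv(rows, out / "taxonomy.tsv")
    if config.references_fasta is not None:
        refs = read_fasta(config.references_fasta)
        write_refmatch_tsv(
            refmatch_report(core, dataset, refs), out / "refmatch.tsv"
        )

    config.to_yaml(out / "config.yaml")
    manifest = {
        "phylocore_version": __version__,
        "seed": config.seed,
        "input_checksums": checksums,
        "n_samples": len(dataset.samples),
        "n_records": len(dataset),
        "n_cores": len(core.cores),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
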