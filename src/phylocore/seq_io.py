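"""Sequence and OTU-table I/O with per-sample attribution.

Input universe: demultiplexed 16S amplicon reads in FASTA, where each read
belongs to exactly one subject (sample).  Attribution follows either the
QIIME convention (header ``sampleID_serial``; sample = text before the first
underscore) or an explicit two-column TSV map (``seq_id TAB sample_id``).

OTU tables are written as TSV (rows = OTUs, columns = samples, with a
``# threshold=`` comment line) or as a minimal BIOM v1 (JSON, sparse) dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import SeqIO

DEFAULT_MIN_LENGTH = 75

_VALID = set("ACGTN")


def _sanitize(residues: str) -> str:
    """Uppercase and collapse non-ACGT IUPAC codes to N."""
    s = residues.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class SequenceRecord:
    """One amplicon read attributed to one subject."""

    seq_id: str
    sample_id: str
    residues: str

    def __post_init__(self):
        if not self.seq_id or not self.sample_id:
            raise ValueError("seq_id and sample_id must be non-empty")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")


class Dataset:
    """Ordered collection of SequenceRecords plus the ordered sample set.

    Record order is the input order; ``samples`` is the first-appearance
    order of sample ids.  seq_ids are unique.
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: tuple[SequenceRecord, ...] = tuple(records)
        seen: dict[str, SequenceRecord] = {}
        samples: list[str] = []
        for rec in self.records:
            if rec.seq_id in seen:
                raise ValueError(f"duplicate seq_id {rec.seq_id!r}")
            seen[rec.seq_id] = rec
            if rec.sample_id not in samples:
                samples.append(rec.sample_id)
        self.samples: tuple[str, ...] = tuple(samples)
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self.records == other.records

    def get(self, seq_id: str) -> SequenceRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def depths(self) -> dict[str, int]:
        d = {s: 0 for s in self.samples}
        for rec in self.records:
            d[rec.sample_id] += 1
        return d

    def records_by_sample(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {s: [] for s in self.samples}
        for rec in self.records:
            out[rec.sample_id].append(rec)
        return out


@dataclass
class OTUTable:
    """Subjects x OTUs integer count matrix for one clustering threshold."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_otus), int64
    threshold: float

    def __post_init__(self):
        self.sample_ids = tuple(self.sample_ids)
        self.otu_ids = tuple(self.otu_ids)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match labels")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OTUTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and self.threshold == other.threshold
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def presence_counts(self) -> np.ndarray:
        """Number of samples in which each OTU has a nonzero count."""
        return (self.counts > 0).sum(axis=0)

    def copy(self) -> "OTUTable":
        return OTUTable(self.sample_ids, self.otu_ids, self.counts.copy(), self.threshold)


# ---------------------------------------------------------------------------
# FASTA reading with sample attribution


def _read_sample_map(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_fasta_with_samples(
    fasta_path,
    sample_map=None,
    header_style: str = "qiime_underscore",
    min_length: int = DEFAULT_MIN_LENGTH,
) -> Dataset:
    """Read a demultiplexed FASTA into a Dataset.

    ``header_style`` is ``qiime_underscore`` (sample id = header text before
    the first underscore) or ``map_file`` (requires ``sample_map``, a TSV of
    ``seq_id TAB sample_id``).  Passing ``sample_map`` implies ``map_file``.
    Reads shorter than ``min_length`` are dropped.  A read without a sample
    attribution is a hard error naming the read.
    """
    if sample_map is not None:
        header_style = "map_file"
    if header_style not in ("qiime_underscore", "map_file"):
        raise ValueError(f"unknown header_style {header_style!r}")
    if header_style == "map_file":
        if sample_map is None:
            raise ValueError("map_file style requires a sample_map path")
        mapping = _read_sample_map(sample_map)

    records: list[SequenceRecord] = []
    n_parsed = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_parsed += 1
        seq_id = rec.id
        residues = _sanitize(str(rec.seq))
        if len(residues) < min_length:
            continue
        if header_style == "qiime_underscore":
            if "_" not in seq_id:
                raise ValueError(
                    f"cannot attribute {seq_id!r} to a sample: "
                    "no underscore in QIIME-style header"
                )
            sample_id = seq_id.split("_", 1)[0]
        else:
            if seq_id not in mapping:
                raise ValueError(f"seq_id {seq_id!r} missing from sample map")
            sample_id = mapping[seq_id]
        records.append(SequenceRecord(seq_id, sample_id, residues))
    if n_parsed == 0:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return Dataset(records)


def read_fasta(path) -> list[tuple[str, str]]:
    """Plain FASTA reader returning (id, uppercase sequence) pairs."""
    out = [(rec.id, _sanitize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def write_dataset_fasta(dataset: Dataset, fasta_path, map_path=None) -> None:
    write_fasta(((r.seq_id, r.residues) for r in dataset.records), fasta_path)
    if map_path is not None:
        with open(map_path, "w") as fh:
            for r in dataset.records:
                fh.write(f"{r.seq_id}\t{r.sample_id}\n")


# ---------------------------------------------------------------------------
# Common-depth subsampling (classic rarefaction, without replacement)


def subsample_common_depth(dataset: Dataset, seed: int) -> Dataset:
    """Rarefy every sample to the minimum per-sample depth.

    Records are drawn uniformly without replacement per sample; the surviving
    records keep their input order and are returned verbatim.  Deterministic
    given ``seed``.
    """
    depths = dataset.depths()
    if not depths:
        raise ValueError("empty dataset")
    for sample, d in depths.items():
        if d < 1:
            raise ValueError(f"sample {sample!r} has no sequences")
    target = min(depths.values())
    rng = np.random.default_rng(seed)
    indices_by_sample: dict[str, list[int]] = {s: [] for s in dataset.samples}
    for i, rec in enumerate(dataset.records):
        indices_by_sample[rec.sample_id].append(i)
    keep: set[int] = set()
    for sample in dataset.samples:
        idx = indices_by_sample[sample]
        chosen = rng.choice(len(idx), size=target, replace=False)
        keep.update(idx[j] for j in chosen)
    return Dataset(rec for i, rec in enumerate(dataset.records) if i in keep)


# ---------------------------------------------------------------------------
# OTU table I/O


def write_otu_table(table: OTUTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# threshold={table.threshold}\n")
            fh.write("#OTU_ID\t" + "\t".join(table.sample_ids) + "\n")
            for j, otu in enumerate(table.otu_ids):
                row = "\t".join(str(int(v)) for v in table.counts[:, j])
                fh.write(f"{otu}\t{row}\n")
    elif format == "biom_json":
        data = []
        for j in range(len(table.otu_ids)):
            for i in range(len(table.sample_ids)):
                v = int(table.counts[i, j])
                if v:
                    data.append([j, i, v])
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "phylocore",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(table.otu_ids), len(table.sample_ids)],
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
            "phylocore": {"threshold": table.threshold},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
    else:
        raise ValueError(f"unknown OTU table format {format!r}")


def read_otu_table(path, format: str = "tsv") -> OTUTable:
    if format == "tsv":
        return _read_otu_table_tsv(path)
    if format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = tuple(r["id"] for r in doc["rows"])
        sample_ids = tuple(c["id"] for c in doc["columns"])
        counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
        for j, i, v in doc["data"]:
            counts[i, j] = v
        threshold = float(doc.get("phylocore", {}).get("threshold", 0.0))
        return OTUTable(sample_ids, otu_ids, counts, threshold)
    raise ValueError(f"unknown OTU table format {format!r}")


def _read_otu_table_tsv(path) -> OTUTable:
    threshold = None
    sample_ids = None
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# threshold="):
                threshold = float(line.split("=", 1)[1])
                continue
            if line.startswith("#OTU_ID"):
                sample_ids = tuple(line.split("\t")[1:])
                continue
            if sample_ids is None:
                raise ValueError(f"{path}:{lineno}: data before #OTU_ID header")
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, got {len(parts)}"
                )
            otu_ids.append(parts[0])
            try:
                rows.append([int(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count ({exc})") from None
    if sample_ids is None:
        raise ValueError(f"{path}: missing #OTU_ID header line")
    if threshold is None:
        raise ValueError(f"{path}: missing '# threshold=' comment line")
    counts = (
        np.array(rows, dtype=np.int64).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int64)
    )
    return OTUTable(sample_ids, tuple(otu_ids), counts, threshold)
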