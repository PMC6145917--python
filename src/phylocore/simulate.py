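"""Synthetic multi-subject amplicon communities with planted ground truth.

The generator emulates the community structure the core-detection method
assumes: a pan-microbiome of discrete lineages, some *universal* (present in
every subject — the planted core) and some *sporadic* (present per subject
with an occupancy probability), with log-normal between-subject abundance
jitter and a fixed per-subject sequencing depth.

Each lineage is a random ancestor 16S fragment plus ``n_variants`` derived
variants obtained by i.i.d. substitutions (no indels by default, keeping
pairwise identities analytically predictable).  Lineage layout depends on
the intra-lineage divergence ``d``:

* shallow (``d`` <= 0.03): a dominant variant identical to the ancestor is
  shared by all carrying subjects and the remaining variants sit within
  ``d`` of it, so the whole lineage falls in a single 0.97 cluster — a
  species-like unit;
* deep (``d`` > 0.03): only mutated variants (per-variant rates drawn in
  [d/2, d]) are emitted and every subject carries its own small random
  subset of them, so no single 0.97 variant cluster is universal and the
  lineage can only surface as a core at a lower (deeper) threshold.

Universal lineages are guaranteed at least one read per subject (a
"universal" lineage that was never sequenced in some subject would make the
ground truth ill-defined at the simulated depth); ``force_universal=False``
disables this to study depth-driven core loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._align import pairwise_identity
from .core_detection import PhylogeneticCore
from .seq_io import Dataset, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: intra-lineage divergence at or below which one 0.97 cluster spans the lineage
SHALLOW_CUTOFF = 0.03


@dataclass
class LineageSpec:
    """Blueprint for one planted lineage.

    ``intra_divergence`` is the maximum per-variant substitution rate from
    the ancestor.  ``variants_per_subject=None`` resolves automatically:
    shallow lineages expose all variants to every carrying subject, deep
    lineages give each subject a private random subset of 2 variants.
    """

    lineage_id: str
    intra_divergence: float
    universal: bool
    n_variants: int = 8
    ancestor_length: int = 250
    occupancy: float = 0.5
    base_abundance: float = 1.0
    abundance_dispersion: float = 1.0
    variants_per_subject: int | None = None
    dominant_weight: float = 0.5  # read share of the ancestor variant (shallow only)

    def __post_init__(self):
        if not 0 <= self.intra_divergence <= 0.2:
            raise ValueError("intra_divergence must be in [0, 0.2]")
        if not self.universal and not 0 < self.occupancy < 1:
            raise ValueError("occupancy must be in (0,1) for sporadic lineages")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")

    @property
    def shallow(self) -> bool:
        return self.intra_divergence <= SHALLOW_CUTOFF

    def resolved_variants_per_subject(self) -> int | None:
        if self.variants_per_subject is not None:
            return min(self.variants_per_subject, self.n_variants)
        if self.shallow:
            return None  # all variants
        return min(2, self.n_variants)


@dataclass
class SimulationTruth:
    """Complete provenance of a simulated dataset."""

    seed: int
    universal_lineages: tuple[str, ...]
    record_lineage: dict[str, str]  # every emitted read -> lineage
    record_variant: dict[str, int]
    lineage_variants: dict[str, tuple[str, ...]]
    subject_lineage_counts: dict[str, dict[str, int]]

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "seed": self.seed,
                "universal_lineages": list(self.universal_lineages),
                "record_lineage": self.record_lineage,
                "record_variant": self.record_variant,
                "lineage_variants": {k: list(v) for k, v in self.lineage_variants.items()},
                "subject_lineage_counts": self.subject_lineage_counts,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with probability ``rate``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_lineages(
    specs: Sequence[LineageSpec],
    min_inter_divergence: float = 0.25,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 200,
) -> dict[str, tuple[str, ...]]:
    """Draw ancestors and variant sets for every lineage.

    Ancestors are redrawn until every pair has identity <= 1 −
    ``min_inter_divergence`` (separability).  Variant 0 of a shallow lineage
    is the ancestor itself; all other variants carry i.i.d. substitutions at
    a per-variant rate bounded by the lineage's intra divergence.
    """
    max_intra = max((s.intra_divergence for s in specs), default=0.0)
    if specs and min_inter_divergence <= 2 * max_intra:
        import warnings

        warnings.warn(
            "min_inter_divergence does not exceed twice the maximum intra-lineage "
            "divergence; lineages may not be separable",
            stacklevel=2,
        )
    ids = [s.lineage_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lineage_id")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ancestors: list[str] = []
    for spec in specs:
        for attempt in range(max_attempts):
            cand = _random_seq(rng, spec.ancestor_length)
            if all(
                pairwise_identity(cand, a) <= 1 - min_inter_divergence
                for a in ancestors
            ):
                ancestors.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw a separable ancestor for {spec.lineage_id!r} "
                f"in {max_attempts} attempts"
            )

    out: dict[str, tuple[str, ...]] = {}
    for spec, anc in zip(specs, ancestors):
        variants: list[str] = []
        if spec.shallow:
            variants.append(anc)  # dominant exact-ancestor variant
            for _ in range(spec.n_variants - 1):
                rate = rng.uniform(0.0, spec.intra_divergence)
                variants.append(_mutate(rng, anc, rate))
        else:
            for _ in range(spec.n_variants):
                rate = rng.uniform(spec.intra_divergence / 2, spec.intra_divergence)
                variants.append(_mutate(rng, anc, rate))
        out[spec.lineage_id] = tuple(variants)
    return out


def simulate_dataset(
    specs: Sequence[LineageSpec],
    n_subjects: int = 10,
    depth_per_subject: int = 500,
    seed: int = 0,
    min_inter_divergence: float = 0.25,
    force_universal: bool = True,
) -> tuple[Dataset, SimulationTruth]:
    """Simulate a multi-subject amplicon dataset with known ground truth."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if depth_per_subject < 1:
        raise ValueError("depth must be >= 1")
    if not specs:
        raise ValueError("no lineage specs")
    if all(s.base_abundance <= 0 for s in specs):
        raise ValueError("degenerate spec: all base abundances are zero")

    rng = np.random.default_rng(seed)
    variants = simulate_lineages(specs, min_inter_divergence, rng)

    width = len(str(n_subjects))
    subjects = [f"S{i + 1:0{width}d}" for i in range(n_subjects)]
    records: list[SequenceRecord] = []
    record_lineage: dict[str, str] = {}
    record_variant: dict[str, int] = {}
    subject_counts: dict[str, dict[str, int]] = {}

    for subject in subjects:
        # lineage inclusion: universal always, sporadic per occupancy draw
        for _ in range(100):
            included = [
                s
                for s in specs
                if s.universal or rng.random() < s.occupancy
            ]
            if included:
                break
        else:
            raise RuntimeError("no lineage included after repeated occupancy draws")

        weights = np.array(
            [s.base_abundance * rng.lognormal(0.0, s.abundance_dispersion) for s in included]
        )
        counts = rng.multinomial(depth_per_subject, weights / weights.sum())
        if force_universal:
            for k, s in enumerate(included):
                if s.universal and counts[k] == 0:
                    donor = int(np.argmax(counts))
                    counts[donor] -= 1
                    counts[k] += 1

        per_lineage: dict[str, int] = {}
        serial = 0
        for k, spec in enumerate(included):
            c = int(counts[k])
            if c == 0:
                continue
            vset = variants[spec.lineage_id]
            kper = spec.resolved_variants_per_subject()
            if spec.shallow:
                pool = np.arange(len(vset))
                # dominant ancestor variant takes dominant_weight of the reads
                probs = np.full(len(pool), 0.0)
                probs[0] = spec.dominant_weight
                if len(pool) > 1:
                    probs[1:] = (1 - spec.dominant_weight) / (len(pool) - 1)
                else:
                    probs[0] = 1.0
            else:
                pool = rng.choice(len(vset), size=kper, replace=False)
                pool.sort()
                probs = np.full(len(pool), 1 / len(pool))
            vcounts = rng.multinomial(c, probs)
            for vi, vc in zip(pool, vcounts):
                for _ in range(int(vc)):
                    seq_id = f"{subject}_{serial}"
                    serial += 1
                    records.append(
                        SequenceRecord(seq_id, subject, vset[int(vi)])
                    )
                    record_lineage[seq_id] = spec.lineage_id
                    record_variant[seq_id] = int(vi)
            per_lineage[spec.lineage_id] = c
        subject_counts[subject] = per_lineage

    truth = SimulationTruth(
        seed=seed,
        universal_lineages=tuple(s.lineage_id for s in specs if s.universal),
        record_lineage=record_lineage,
        record_variant=record_variant,
        lineage_variants=variants,
        subject_lineage_counts=subject_counts,
    )
    return Dataset(records), truth


def default_community(
    seed: int = 0,
    n_universal: int = 5,
    n_sporadic: int = 15,
    occupancy: float = 0.5,
) -> list[LineageSpec]:
    """The study-condition community: planted universal lineages of mixed
    phylogenetic depth plus a sporadic background.

    Intra-lineage divergences are sampled from {0, 0.02, 0.06, 0.10};
    universal lineages get a higher baseline abundance, as core lineages in
    real gut pan-microbiomes rank among the most abundant.
    """
    rng = np.random.default_rng(seed)
    depths = np.array([0.0, 0.02, 0.06, 0.10])
    specs: list[LineageSpec] = []
    for i in range(n_universal):
        d = float(rng.choice(depths))
        specs.append(
            LineageSpec(
                lineage_id=f"core{i + 1:02d}",
                intra_divergence=d,
                universal=True,
                n_variants=6 if d <= SHALLOW_CUTOFF else 8,
                base_abundance=2.0,
            )
        )
    for i in range(n_sporadic):
        d = float(rng.choice(depths))
        specs.append(
            LineageSpec(
                lineage_id=f"spor{i + 1:02d}",
                intra_divergence=d,
                universal=False,
                occupancy=occupancy,
                n_variants=6 if d <= SHALLOW_CUTOFF else 8,
                base_abundance=1.0,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Ground-truth scoring


@dataclass
class RecoveryReport:
    recovered_lineages: tuple[str, ...]  # majority lineage of each core OTU, deduplicated
    true_universal: tuple[str, ...]
    precision: float
    recall: float
    lineage_best_level: dict[str, float]  # lineage -> highest detection threshold

    @property
    def exact(self) -> bool:
        return set(self.recovered_lineages) == set(self.true_universal)


def evaluate_recovery(core: PhylogeneticCore, truth: SimulationTruth) -> RecoveryReport:
    """Compare detected core OTUs against the planted universal lineages.

    Each core OTU is attributed to the majority lineage of its masked
    members; precision/recall are set-level against the planted universal
    lineage set.
    """
    recovered: list[str] = []
    best_level: dict[str, float] = {}
    for c in core.cores:
        votes: dict[str, int] = {}
        for m in c.masked_member_ids:
            lin = truth.record_lineage[m]
            votes[lin] = votes.get(lin, 0) + 1
        lineage = max(sorted(votes), key=lambda k: votes[k])
        if lineage not in recovered:
            recovered.append(lineage)
        best_level[lineage] = max(best_level.get(lineage, 0.0), c.detection_threshold)
    rec_set = set(recovered)
    uni_set = set(truth.universal_lineages)
    precision = len(rec_set & uni_set) / len(rec_set) if rec_set else 1.0
    recall = len(rec_set & uni_set) / len(uni_set) if uni_set else 1.0
    return RecoveryReport(
        tuple(recovered), truth.universal_lineages, precision, recall, best_level
    )
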