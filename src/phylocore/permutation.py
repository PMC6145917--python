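"""Permutation null for the number of core OTUs per clustering level.

The null preserves each sample's richness: within every sample (row), the
full multiset of abundance values — zeros included — is permuted uniformly
across OTU columns.  Row sums, per-row nonzero counts, and the exact value
multisets are all invariant.  The p-value is the add-one empirical rank of
the observed core count in the shuffled distribution:

    p = (1 + #{null >= observed}) / (1 + n_permutations)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq_io import OTUTable


@dataclass
class PermutationResult:
    threshold: float
    observed_core_count: int
    null_counts: tuple[int, ...]
    p_value: float
    n_permutations: int
    prevalence: float
    seed: int | None


def shuffle_within_samples(table: OTUTable, seed) -> OTUTable:
    """Permute each sample's abundance values across OTU columns.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shuffled = rng.permuted(table.counts, axis=1)
    return OTUTable(table.sample_ids, table.otu_ids, shuffled, table.threshold)


def _core_count(counts: np.ndarray, prevalence: float) -> int:
    n = counts.shape[0]
    need = math.ceil(prevalence * n)
    return int(((counts > 0).sum(axis=0) >= need).sum())


def permutation_core_test(
    table: OTUTable,
    n_permutations: int = 100,
    prevalence: float = 1.0,
    seed: int | None = None,
) -> PermutationResult:
    """Significance of the observed core-OTU count at one clustering level.

    Measures the probability of obtaining at least as many universal OTUs by
    chance given the sample richness structure of the community table.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0,1]")
    rng = np.random.default_rng(seed)
    observed = _core_count(table.counts, prevalence)
    null_counts = []
    for _ in range(n_permutations):
        shuffled = rng.permuted(table.counts, axis=1)
        null_counts.append(_core_count(shuffled, prevalence))
    k = sum(1 for c in null_counts if c >= observed)
    p = (1 + k) / (1 + n_permutations)
    return PermutationResult(
        table.threshold, observed, tuple(null_counts), p, n_permutations, prevalence, seed
    )
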