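import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phylocore.seq_io import Dataset, SequenceRecord


def make_dataset(spec: dict[str, list[str]]) -> Dataset:
    """Build a Dataset from {sample_id: [sequence, ...]}."""
    records = []
    for sample, seqs in spec.items():
        for i, seq in enumerate(seqs):
            records.append(SequenceRecord(f"{sample}_{i}", sample, seq))
    return Dataset(records)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
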