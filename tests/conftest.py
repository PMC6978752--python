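import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from seedtrace import TranscriptRecord, let7_query


@pytest.fixture(scope="session")
def let7():
    return let7_query()


@pytest.fixture()
def rng():
    return random.Random(20240917)


def make_record(sequence: str, cds_start=None, cds_end=None, **kw) -> TranscriptRecord:
    n = len(sequence)
    if cds_start is None:
        cds_start = 0
    if cds_end is None:
        cds_end = n
    defaults = dict(transcript_id="tx", species="mouse", gene_symbol="Gene")
    defaults.update(kw)
    return TranscriptRecord(
        sequence=sequence, cds_start=cds_start, cds_end=cds_end, **defaults
    )


def random_dna(rng: random.Random, length: int, gc: float = 0.5) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=length))


def seeded_dna(rng: random.Random, length: int, seed_str: str, n_fragments: int,
               gc: float = 0.5) -> str:
    """Random background with seed fragments sprinkled in, to exercise the
    scanner on sequences that actually contain hits."""
    seq = list(random_dna(rng, length, gc))
    for _ in range(n_fragments):
        offset = rng.randint(0, len(seed_str) - 6)
        frag_len = rng.randint(6, len(seed_str) - offset)
        if length >= frag_len:
            pos = rng.randint(0, length - frag_len)
            seq[pos : pos + frag_len] = seed_str[offset : offset + frag_len]
    return "".join(seq)
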