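"""Shared fixtures and generators for the test-suite."""

from __future__ import annotations

import numpy as np
import pytest

from acoqs.fastq_io import FastqRecord


def random_records(rng: np.random.Generator,
                   n_reads: int,
                   max_len: int = 40,
                   qmax: int = 93,
                   allow_empty: bool = True,
                   n_prob: float = 0.05) -> list[FastqRecord]:
    """Adversarial random FASTQ records: ragged, N bases, extreme qualities."""
    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    records = []
    for i in range(n_reads):
        lo = 0 if allow_empty else 1
        ln = int(rng.integers(lo, max_len + 1))
        weights = np.array([1 - n_prob] * 4 + [4 * n_prob]) / (4 - 4 * n_prob + 4 * n_prob)
        weights = weights / weights.sum()
        bases = alphabet[rng.choice(5, size=ln, p=weights)].tobytes().decode()
        # mix smooth and extreme quality values
        if rng.random() < 0.2:
            quals = rng.choice([0, 1, qmax - 1, qmax], size=ln)
        else:
            quals = np.clip(rng.normal(35, 8, size=ln).round(), 0, qmax)
        records.append(FastqRecord(f"r{i}", bases, quals.astype(np.uint8)))
    return records


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
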