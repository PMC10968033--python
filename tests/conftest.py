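from __future__ import annotations

import numpy as np
import pytest

from hydroscreen.peptide_io import CANONICAL_AA, PeptideRecord, PeptideTable

AA_LETTERS = sorted(CANONICAL_AA)


def random_peptide_table(
    rng: np.random.Generator,
    n_records: int,
    samples: tuple[str, ...] = ("A",),
    min_len: int = 3,
    max_len: int = 30,
    zero_intensity_frac: float = 0.1,
) -> PeptideTable:
    """Random table with unique sequences and positive (mostly) intensities."""
    records = []
    seen = set()
    while len(records) < n_records:
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(AA_LETTERS, size=length))
        if seq in seen:
            continue
        seen.add(seq)
        intensity = {}
        for s in samples:
            if rng.random() < zero_intensity_frac:
                intensity[s] = 0.0
            else:
                intensity[s] = float(rng.lognormal(10, 1))
        records.append(PeptideRecord(sequence=seq, intensity=intensity))
    return PeptideTable(records=tuple(records), samples=samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table() -> PeptideTable:
    records = (
        PeptideRecord(sequence="GGG", intensity={"A": 2.0}),
        PeptideRecord(sequence="DKEH", intensity={"A": 2.0}),
    )
    return PeptideTable(records=records, samples=("A",))
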