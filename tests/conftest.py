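"""Shared fixtures: small random count-matrix instances with sequences."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oligogeo.sequences import RESIDUES


def random_instance(rng, max_oligos=6, max_sites=4, max_count=12, seq_length=12):
    """A random oligotype x site count matrix with unique sequences.

    Every oligotype has at least one copy and every site at least one
    sequence, with total N kept small enough for brute-force expansion.
    """
    k = int(rng.integers(2, max_oligos + 1))
    s = int(rng.integers(2, max_sites + 1))
    seqs = set()
    while len(seqs) < k:
        seqs.add("".join(rng.choice(list("ACGT"), size=seq_length)))
    seqs = sorted(seqs)
    while True:
        counts = rng.integers(0, max_count + 1, size=(k, s))
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
            break
    mat = pd.DataFrame(
        counts, index=[f"OT{i}" for i in range(k)], columns=[f"S{j}" for j in range(s)]
    )
    return mat, seqs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
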