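"""Shared fixtures and independently coded oracles.

The oracles here deliberately avoid the package's own code paths: a plain
Gotoh dynamic program for alignment scores, loop-based composition counting,
and a Hamming-based greedy clusterer for equal-length substitution families.
"""

from __future__ import annotations

import numpy as np
import pytest

from trpcensus.catalog import STANDARD_AA, ProteinRecord

LETTERS = list(STANDARD_AA)


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(LETTERS, size=length))


def gotoh_score(a: str, b: str, match=1, mismatch=-1, open_=-2, extend=-1) -> float:
    """Independent affine-gap global alignment score (first gap residue costs
    ``open_``, each further residue ``extend``)."""
    neg = float("-inf")
    la, lb = len(a), len(b)
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # gap in b (moving along a)
    iy = np.full((la + 1, lb + 1), neg)  # gap in a
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        ix[i, 0] = open_ + (i - 1) * extend
    for j in range(1, lb + 1):
        iy[0, j] = open_ + (j - 1) * extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            m[i, j] = max(m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1]) + s
            ix[i, j] = max(m[i - 1, j] + open_, ix[i - 1, j] + extend,
                           iy[i - 1, j] + open_)
            iy[i, j] = max(m[i, j - 1] + open_, iy[i, j - 1] + extend,
                           ix[i, j - 1] + open_)
    return max(m[la, lb], ix[la, lb], iy[la, lb])


def hamming_identity(a: str, b: str) -> float:
    """Identity for equal-length substitution-only pairs (no alignment)."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def greedy_cluster_oracle(records: list[ProteinRecord], c: float) -> list[list[str]]:
    """Independently coded greedy scheme over Hamming identity.

    Valid only for equal-length substitution families, where the optimal
    global alignment is gapless and alignment identity equals Hamming
    identity.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for i, rep in enumerate(reps):
            if len(rep.sequence) == len(rec.sequence) and hamming_identity(
                rep.sequence, rec.sequence
            ) >= c:
                members[i].append(rec.accession)
                break
        else:
            reps.append(rec)
            members.append([rec.accession])
    return members
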