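"""Greedy sequence-identity clustering standing in for CD-HIT at c = 0.7.

Identity between two sequences is defined as the number of identical aligned
columns in one optimal global alignment (match +1, mismatch -1, gap open -2,
gap extend -1) divided by the length of the shorter sequence — CD-HIT's
global-identity convention.  Clustering is the usual greedy incremental scheme:
sequences are visited longest-first and each either joins the first existing
representative it matches at >= c identity or founds a new cluster.  CD-HIT's
short-word prefilter and banded alignment are deliberately not reproduced;
here clustering only needs to deduplicate, not to scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from trpcensus.catalog import ProteinRecord

__all__ = ["IdentityCluster", "pairwise_identity", "cluster_at_threshold", "write_clusters"]


@lru_cache(maxsize=500_000)
def _lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length, bit-parallel (one big int per row)."""
    if len(a) > len(b):
        a, b = b, a
    masks: dict[str, int] = {}
    for i, ch in enumerate(a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    full = (1 << len(a)) - 1
    v = full
    for ch in b:
        m = masks.get(ch, 0)
        u = v & m
        v = ((v + u) | (v & ~m)) & full
    # LCS = number of zero bits that appeared among the len(a) positions
    return len(a) - bin(v).count("1")


@dataclass(frozen=True)
class IdentityCluster:
    """One cluster from the greedy scheme.

    The representative is the longest member (ties broken lexicographically by
    accession) and is always included in ``members``.
    """

    representative: str
    members: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned columns over the shorter sequence length.

    Symmetric; returns a value in [0, 1].  Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    return _identity_cached(*sorted((a, b)))


@lru_cache(maxsize=500_000)
def _identity_cached(a: str, b: str) -> float:
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def cluster_at_threshold(
    records: Sequence[ProteinRecord], c: float = 0.7
) -> list[IdentityCluster]:
    """Greedy incremental clustering of records at identity threshold ``c``.

    Records are sorted by length descending (ties by accession); each sequence
    joins the first representative with identity >= c, else founds a new
    cluster.  The representatives form the nonredundant set.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if not 0 < c <= 1:
        raise ValueError("c must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for i, rep in enumerate(reps):
            # matched columns of any alignment form a common subsequence, so
            # LCS / shorter length soundly upper-bounds identity: prune cheaply
            shorter = min(len(rep.sequence), len(rec.sequence))
            if _lcs_length(*sorted((rep.sequence, rec.sequence))) < c * shorter:
                continue
            if pairwise_identity(rep.sequence, rec.sequence) >= c:
                members[i].append(rec.accession)
                break
        else:
            reps.append(rec)
            members.append([rec.accession])
    return [
        IdentityCluster(rep.accession, tuple(mem), c) for rep, mem in zip(reps, members)
    ]


def representatives(
    records: Sequence[ProteinRecord], c: float = 0.7
) -> list[ProteinRecord]:
    """Convenience: the nonredundant record subset at threshold ``c``."""
    by_acc = {r.accession: r for r in records}
    return [by_acc[cl.representative] for cl in cluster_at_threshold(records, c)]


def write_clusters(
    clusters: Iterable[IdentityCluster],
    records: Sequence[ProteinRecord],
    path: str | Path,
) -> None:
    """Write a cluster table as TSV (representative, member, identity)."""
    by_acc = {r.accession: r for r in records}
    with open(path, "w") as handle:
        handle.write("representative\tmember\tidentity\n")
        for cl in clusters:
            for member in cl.members:
                ident = (
                    1.0
                    if member == cl.representative
                    else pairwise_identity(
                        by_acc[cl.representative].sequence, by_acc[member].sequence
                    )
                )
                handle.write(f"{cl.representative}\t{member}\t{ident:.4f}\n")
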