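"""MSA column information content, logo heights and conserved-position ranking.

Information content of a column is ``log2(20) − H`` with ``H`` the Shannon
entropy of the observed non-gap residue frequencies (gaps carry no probability
mass).  Logo letter heights are ``IC × p̂``.  Columns with fewer than a minimum
number of non-gap residues (default 10) are masked before any analysis, and
the top-k ranking maps columns back to ungapped residue numbers of a chosen
reference sequence, reproducing the "top ten conserved positions" readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from trpcensus.catalog import STANDARD_AA

__all__ = [
    "Alignment",
    "ICRanking",
    "MAX_IC_BITS",
    "read_and_filter_msa",
    "column_ic",
    "rank_positions",
    "logo_heights",
]

GAP = "-"
#: maximum information content for a 20-letter alphabet, log2(20) bits
MAX_IC_BITS = math.log2(20)


@dataclass(frozen=True)
class Alignment:
    """An aligned sequence set with a kept/removed column mask."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    column_mask: np.ndarray  # bool, True = kept

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one sequence")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")
        mask = np.asarray(self.column_mask, dtype=bool)
        if mask.shape != (width,):
            raise ValueError("column mask length mismatch")
        object.__setattr__(self, "column_mask", mask)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        return "".join(row[index] for row in self.rows)

    def kept_columns(self) -> list[int]:
        return [i for i in range(self.width) if self.column_mask[i]]


@dataclass(frozen=True)
class ICRanking:
    """Conserved positions ranked by information content (descending).

    Each entry is ``(column index, reference residue number or None,
    consensus residue, IC bits)``.  Ties in IC break by ascending column
    index, so output is byte-stable.
    """

    reference_id: str
    entries: tuple[tuple[int, int | None, str, float], ...]

    def __post_init__(self) -> None:
        ics = [e[3] for e in self.entries]
        if any(ic < -1e-12 or ic > MAX_IC_BITS + 1e-12 for ic in ics):
            raise ValueError("IC outside [0, log2 20]")
        for (ca, _, _, ia), (cb, _, _, ib) in zip(self.entries, self.entries[1:]):
            if ib > ia + 1e-12 or (abs(ia - ib) <= 1e-12 and cb < ca):
                raise ValueError("entries not sorted by IC desc, column asc")


def read_and_filter_msa(path: str | Path, min_seqs: int = 10) -> Alignment:
    """Read an aligned FASTA and mask columns with fewer than ``min_seqs``
    non-gap characters."""
    msa = AlignIO.read(str(path), "fasta")
    ids = tuple(rec.id for rec in msa)
    rows = tuple(str(rec.seq).upper() for rec in msa)
    aln = Alignment(ids, rows, np.ones(len(rows[0]), dtype=bool))
    counts = np.array(
        [sum(1 for row in rows if row[i] != GAP) for i in range(aln.width)]
    )
    return Alignment(ids, rows, counts >= min_seqs)


def column_ic(column: str, background: Sequence[float] | None = None) -> float:
    """Information content of one column in bits: ``log2(20) − H``.

    ``H`` is the Shannon entropy of the non-gap observed frequencies.  With a
    non-uniform ``background`` (length-20 distribution over the standard
    letters) the relative-entropy form ``Σ p̂ log2(p̂/q)`` is used instead; the
    default uniform background reduces to ``log2(20) − H``.
    """
    residues = [c for c in column.upper() if c != GAP]
    if not residues:
        raise ValueError("empty column")
    letters, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    if background is None:
        h = float(-(p * np.log2(p)).sum())
        return MAX_IC_BITS - h
    q = np.asarray(background, dtype=float)
    if q.shape != (20,) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a distribution over 20 letters")
    qmap = dict(zip(STANDARD_AA, q))
    return float(sum(pi * math.log2(pi / qmap[a]) for pi, a in zip(p, letters)))


def _consensus(column: str) -> str:
    residues = [c for c in column.upper() if c != GAP]
    letters, counts = np.unique(residues, return_counts=True)
    return letters[np.lexsort((letters, -counts))][0]


def _reference_positions(aln: Alignment, reference_id: str) -> dict[int, int | None]:
    """Column index -> ungapped 1-based residue number in the reference row."""
    try:
        row = aln.rows[aln.ids.index(reference_id)]
    except ValueError as exc:
        raise KeyError(f"reference {reference_id!r} not in alignment") from exc
    positions: dict[int, int | None] = {}
    pos = 0
    for i, c in enumerate(row):
        if c != GAP:
            pos += 1
            positions[i] = pos
        else:
            positions[i] = None
    return positions


def rank_positions(aln: Alignment, reference_id: str, k: int = 10) -> ICRanking:
    """Top-``k`` kept columns by IC, mapped to reference residue numbers."""
    positions = _reference_positions(aln, reference_id)
    scored = []
    for col in aln.kept_columns():
        column = aln.column(col)
        scored.append((col, positions[col], _consensus(column), column_ic(column)))
    scored.sort(key=lambda e: (-e[3], e[0]))
    return ICRanking(reference_id, tuple(scored[:k]))


def logo_heights(aln: Alignment) -> pd.DataFrame:
    """Per-column letter heights: ``height(a, col) = IC(col) × p̂_a(col)``.

    Returns a DataFrame indexed by kept column, one column per standard
    letter; row sums equal the column IC.
    """
    records = {}
    for col in aln.kept_columns():
        column = aln.column(col)
        residues = [c for c in column.upper() if c != GAP]
        letters, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        ic = column_ic(column)
        heights = dict.fromkeys(STANDARD_AA, 0.0)
        for letter, pi in zip(letters, p):
            heights[letter] = ic * float(pi)
        records[col] = heights
    return pd.DataFrame.from_dict(records, orient="index", columns=list(STANDARD_AA))
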