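"""Amino-acid composition statistics: the numbers behind the abundance table.

Two conventions are provided, because both appear in proteome censuses:

* per-protein percentages, summarised unweighted across proteins (mean ± sample
  SD) — short and long proteins count equally; this is the default comparator;
* a pooled (length-weighted) composition over the concatenated dataset, the
  convention of EMBOSS Pepstats.

Ambiguity letters (X, B, Z, U, O) are excluded from both numerator and
denominator so that the 20-letter percentages are not diluted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trpcensus.catalog import STANDARD_AA, Category, ProteinRecord

__all__ = [
    "CompositionVector",
    "CategorySummary",
    "composition_of",
    "summarize_category",
    "pooled_composition",
    "write_table",
]


@dataclass(frozen=True)
class CompositionVector:
    """Percent composition of one protein (or one pooled dataset).

    ``percent`` maps each of the 20 standard letters to the percentage of
    counted residues; percentages sum to 100 whenever ``counted_length > 0``.
    """

    percent: Mapping[str, float]
    counted_length: int

    def __post_init__(self) -> None:
        extra = set(self.percent) - set(STANDARD_AA)
        if extra:
            raise ValueError(f"non-standard keys {sorted(extra)}")
        if any(v < 0 for v in self.percent.values()):
            raise ValueError("negative percentage")

    def __getitem__(self, letter: str) -> float:
        return self.percent.get(letter, 0.0)


@dataclass(frozen=True)
class CategorySummary:
    """Per-category mean ± sample SD of per-protein percentages."""

    label: Category | str
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n_proteins: int

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("negative SD")


def composition_of(sequence: str) -> CompositionVector:
    """Percent composition of one sequence over the 20 standard letters."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    counted = sum(counts[a] for a in STANDARD_AA)
    if counted == 0:
        raise ValueError("no countable residues")
    percent = {a: 100.0 * counts[a] / counted for a in STANDARD_AA}
    return CompositionVector(percent, counted)


def summarize_category(
    vectors: Sequence[CompositionVector], label: Category | str
) -> CategorySummary:
    """Unweighted mean and sample SD (n-1) of per-protein percentages."""
    if not vectors:
        raise ValueError("empty vector list")
    mat = np.array([[v[a] for a in STANDARD_AA] for v in vectors])
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1) if len(vectors) > 1 else np.zeros(len(STANDARD_AA))
    return CategorySummary(
        label,
        dict(zip(STANDARD_AA, means.tolist())),
        dict(zip(STANDARD_AA, sds.tolist())),
        len(vectors),
    )


def pooled_composition(records: Sequence[ProteinRecord]) -> CompositionVector:
    """Length-weighted composition over the concatenation of all sequences."""
    if not records:
        raise ValueError("no records")
    return composition_of("".join(r.sequence for r in records))


def write_table(
    summaries: Iterable[CategorySummary], path: str | Path
) -> pd.DataFrame:
    """Write an abundance table (rows = amino acids, columns = categories,
    cells ``mean ± SD``, final row n) as TSV; returns the DataFrame."""
    summaries = list(summaries)
    data = {}
    for s in summaries:
        col = [f"{s.mean[a]:.2f} ± {s.sd[a]:.2f}" for a in STANDARD_AA]
        col.append(str(s.n_proteins))
        data[str(s.label)] = col
    df = pd.DataFrame(data, index=list(STANDARD_AA) + ["n"])
    df.to_csv(path, sep="\t", index_label="amino_acid")
    return df
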