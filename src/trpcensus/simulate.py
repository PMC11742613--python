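"""Seeded generators for every input class the pipelines consume.

Each generator is deterministic under a fixed seed and returns machine-readable
ground truth alongside its output, so every pipeline stage can be scored
without re-deriving the truth:

* :func:`gen_proteome` — annotated sequence sets with controlled per-category
  amino-acid frequencies and TMD counts (defaults are the published abundance
  means for the soluble / 6-10 TMD / CerS / TLC-other strata);
* :func:`gen_redundant_copies` — substitution-only mutants with exact
  pairwise identity by construction, fixtures for the c = 0.7 rule;
* :func:`gen_helical_bundle` — ideal α-helical bundles (1.5 Å rise, 100° twist,
  2.3 Å radius) with a known membrane frame and planted Trp depths;
* :func:`gen_msa` — alignments with planted conserved columns;
* :func:`gen_depth_cohort` — paired Trp-depth samples with a tunable
  lumenal-interface / cytoplasmic-leaflet asymmetry bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trpcensus.catalog import STANDARD_AA, ProteinRecord
from trpcensus.conservation import Alignment
from trpcensus.depth import MembraneFrame, StructureModel

__all__ = [
    "CategorySpec",
    "BundleSpec",
    "MsaSpec",
    "CohortSpec",
    "DEFAULT_CATEGORY_PERCENTS",
    "gen_proteome",
    "gen_redundant_copies",
    "gen_helical_bundle",
    "gen_msa",
    "gen_depth_cohort",
    "helix_coords",
]

# Published per-category mean composition (percent per amino acid) used as the
# generator's default target frequencies, keyed by census stratum.
DEFAULT_CATEGORY_PERCENTS: Mapping[str, Mapping[str, float]] = {
    "SOLUBLE": {
        "A": 8.03, "C": 1.59, "D": 5.55, "E": 6.97, "F": 3.67, "G": 6.84,
        "H": 2.28, "I": 5.87, "K": 6.44, "L": 9.29, "M": 2.37, "N": 4.22,
        "P": 4.68, "Q": 3.88, "R": 5.74, "S": 6.72, "T": 5.22, "V": 6.71,
        "W": 1.00, "Y": 2.92,
    },
    "TM_6_10": {
        "A": 8.36, "C": 1.48, "D": 3.12, "E": 3.53, "F": 6.43, "G": 7.08,
        "H": 1.92, "I": 7.87, "K": 3.95, "L": 12.9, "M": 2.96, "N": 3.47,
        "P": 4.20, "Q": 2.86, "R": 4.10, "S": 7.16, "T": 5.50, "V": 7.67,
        "W": 1.89, "Y": 3.54,
    },
    "CERS": {
        "A": 6.11, "C": 1.68, "D": 4.51, "E": 4.31, "F": 7.45, "G": 4.57,
        "H": 2.71, "I": 6.98, "K": 5.22, "L": 11.5, "M": 2.73, "N": 3.15,
        "P": 3.92, "Q": 2.76, "R": 5.07, "S": 6.75, "T": 5.01, "V": 6.75,
        "W": 3.35, "Y": 5.51,
    },
    "TLC_OTHER": {
        "A": 7.40, "C": 1.98, "D": 3.06, "E": 3.11, "F": 7.05, "G": 5.55,
        "H": 2.88, "I": 6.69, "K": 4.24, "L": 12.6, "M": 3.12, "N": 3.41,
        "P": 3.80, "Q": 2.61, "R": 4.46, "S": 7.34, "T": 5.26, "V": 8.14,
        "W": 2.61, "Y": 4.74,
    },
}

_HYDROPHOBIC = "LIVFA"
_POLAR = "STNQKEDRGP"


def _freq_array(freqs: Mapping[str, float]) -> np.ndarray:
    v = np.array([freqs.get(a, 0.0) for a in STANDARD_AA], dtype=float)
    if (v < 0).any():
        raise ValueError("negative frequency")
    total = v.sum()
    if total <= 0:
        raise ValueError("frequency vector sums to zero")
    return v / total


# ---------------------------------------------------------------------------
# proteome generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySpec:
    """One synthetic census stratum.

    ``aa_freqs`` may be percents or probabilities; it is normalised to sum
    to 1.  ``tmd_count_range`` bounds the number of TRANSMEM segments drawn
    per record (inclusive); segment length is fixed at 21 residues.
    """

    label: str
    n: int
    length_range: tuple[int, int] = (200, 400)
    aa_freqs: Mapping[str, float] | None = None
    tmd_count_range: tuple[int, int] = (0, 0)
    subcellular_location: str = ""
    tmd_length: int = 21

    def frequencies(self) -> np.ndarray:
        raw = self.aa_freqs or DEFAULT_CATEGORY_PERCENTS.get(self.label)
        if raw is None:
            raise ValueError(f"no frequency vector for category {self.label!r}")
        return _freq_array(raw)


def _place_segments(
    rng: np.random.Generator, length: int, count: int, seg_len: int
) -> tuple[tuple[int, int], ...]:
    """Non-overlapping fixed-length segments placed uniformly at random."""
    if count == 0:
        return ()
    if count * seg_len > length:
        raise ValueError("sequence too short for requested TMD count")
    # sample start offsets via the stars-and-bars gap construction
    slack = length - count * seg_len
    cuts = np.sort(rng.integers(0, slack + 1, size=count))
    segments = []
    for i, cut in enumerate(cuts):
        start = int(cut) + i * seg_len + 1  # 1-based
        segments.append((start, start + seg_len - 1))
    return tuple(segments)


def gen_proteome(
    categories: Sequence[CategorySpec], seed: int
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate an annotated synthetic proteome.

    Sequences are drawn i.i.d. per position from each category's frequency
    vector; TMD segments are placed non-overlapping at random.  Returns the
    records plus a truth table (accession, category, length, n_tmd and the
    planted percent frequency of every letter).
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    records: list[ProteinRecord] = []
    truth_rows = []
    for spec in categories:
        freqs = spec.frequencies()
        lo, hi = spec.length_range
        for i in range(spec.n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=freqs))
            n_tmd = int(rng.integers(spec.tmd_count_range[0], spec.tmd_count_range[1] + 1))
            segments = _place_segments(rng, length, n_tmd, spec.tmd_length)
            locations = (
                frozenset([spec.subcellular_location])
                if spec.subcellular_location
                else frozenset()
            )
            acc = f"{spec.label}{i:05d}"
            records.append(
                ProteinRecord(acc, seq, segments, locations, source_dataset=spec.label)
            )
            row = {"accession": acc, "category": spec.label, "length": length,
                   "n_tmd": n_tmd}
            row.update({f"freq_{a}": 100.0 * f for a, f in zip(STANDARD_AA, freqs)})
            truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# redundant-copy generator
# ---------------------------------------------------------------------------


def gen_redundant_copies(
    seed_sequence: str,
    n_copies: int,
    target_identity: float,
    seed: int,
    accession_base: str = "FAM0",
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Substitution-only mutants at an exact identity to the seed sequence.

    Each copy differs from the seed by exactly ``round((1-t) * L)`` point
    substitutions at distinct random positions; no indels, so the optimal
    global alignment is gapless and the identity is exact by construction.
    The seed record (accession ``accession_base``) is returned first and
    sorts before its copies, so greedy clustering founds the family on it.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    length = len(seed_sequence)
    n_sub = round((1.0 - target_identity) * length)
    if n_sub > length:
        raise ValueError("requested identity implies more substitutions than positions")
    rng = np.random.default_rng(seed)
    records = [ProteinRecord(accession_base, seed_sequence)]
    rows = [{"accession": accession_base, "identity_to_seed": 1.0, "n_substitutions": 0}]
    for i in range(n_copies):
        positions = rng.choice(length, size=n_sub, replace=False)
        seq = list(seed_sequence)
        for pos in positions:
            alternatives = [a for a in STANDARD_AA if a != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
        acc = f"{accession_base}_c{i:03d}"
        records.append(ProteinRecord(acc, "".join(seq)))
        rows.append(
            {"accession": acc,
             "identity_to_seed": (length - n_sub) / length,
             "n_substitutions": n_sub}
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helical-bundle generator
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å


def helix_coords(
    n_residues: int,
    start: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    direction: int = 1,
    phase_deg: float = 0.0,
) -> np.ndarray:
    """Calpha coordinates of an ideal α-helix along ±z starting at ``start``."""
    m = np.arange(n_residues)
    angle = np.radians(phase_deg + m * HELIX_TWIST_DEG)
    start = np.asarray(start, dtype=float)
    return np.column_stack(
        [
            start[0] + HELIX_RADIUS * np.cos(angle),
            start[1] + HELIX_RADIUS * np.sin(angle),
            start[2] + direction * m * HELIX_RISE,
        ]
    )


def _rotation_matrix(euler_deg: Sequence[float]) -> np.ndarray:
    ax, ay, az = np.radians(euler_deg)
    rx = np.array([[1, 0, 0], [0, math.cos(ax), -math.sin(ax)], [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)], [0, 1, 0], [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0], [math.sin(az), math.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class BundleSpec:
    """A synthetic membrane-embedded helical bundle.

    The bundle is built in a canonical frame whose membrane normal is +z and
    bilayer centre is z = 0; ``tilt_deg`` tilts the helix axes relative to
    that normal (fixture validity bound 60°); ``rotation_deg``/``translation``
    then move the whole object rigidly, carrying the true frame along.
    ``trp_depths`` plants Trp at the residues whose true z is closest to each
    requested depth.  ``hox_side`` (±1) optionally adds a compact extramembrane
    domain on the given side, for topology-filter fixtures.
    """

    accession: str = "BNDL0001"
    n_helices: int = 7
    residues_per_helix: int = 30
    tilt_deg: float = 0.0
    center_offset: float = 0.0
    trp_depths: tuple[float, ...] = ()
    nterm_side: int = -1  # lumenal N-terminus, the CerS topology
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cterm_tail: int = 8
    hox_side: int | None = None
    core_half_width: float = 15.0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 10:
            raise ValueError("need >= 1 helix with >= 10 residues each")
        if abs(self.tilt_deg) > 60:
            raise ValueError("tilt beyond 60° breaks the fixture's validity")
        if self.nterm_side not in (-1, 1):
            raise ValueError("nterm_side must be ±1")


@dataclass(frozen=True)
class BundleTruth:
    """Ground truth attached to a generated bundle."""

    frame: MembraneFrame
    true_z: np.ndarray  # per residue, canonical-frame depth
    trp_residue_numbers: tuple[int, ...]
    hox_residue_range: tuple[int, int] | None
    nterm_residue_range: tuple[int, int]
    cterm_residue_range: tuple[int, int]


def gen_helical_bundle(
    spec: BundleSpec, seed: int
) -> tuple[StructureModel, BundleTruth]:
    """Generate an ideal helical bundle with known membrane frame and depths.

    Membrane-core residues (|z| <= core half-width) get hydrophobic types and
    flank residues polar ones, so hydrophobicity-based slab placement can be
    scored against the exact truth.
    """
    rng = np.random.default_rng(seed)
    m = spec.residues_per_helix
    span = (m - 1) * HELIX_RISE
    half = span / 2.0
    coords_list = []
    side = spec.nterm_side
    grid = math.ceil(math.sqrt(spec.n_helices))
    for j in range(spec.n_helices):
        cx, cy = 10.0 * (j % grid), 10.0 * (j // grid)
        start_z = -half if side < 0 else half
        coords_list.append(
            helix_coords(m, (cx, cy, start_z), direction=-side,
                         phase_deg=float(rng.uniform(0, 360)))
        )
        side = -side
    coords = np.vstack(coords_list)
    # after the loop `side` has flipped past the last helix: its end side
    cterm_side = side

    # C-terminal extramembrane tail continuing past the last helix end
    tail_start_z = (half if cterm_side > 0 else -half) + 2.0 * (1 if cterm_side > 0 else -1)
    tail = np.column_stack(
        [
            np.full(spec.cterm_tail, coords_list[-1][-1, 0]),
            np.full(spec.cterm_tail, coords_list[-1][-1, 1]),
            tail_start_z + cterm_side * 1.5 * np.arange(spec.cterm_tail),
        ]
    )
    coords = np.vstack([coords, tail])

    if spec.tilt_deg:
        coords = coords @ _rotation_matrix((spec.tilt_deg, 0.0, 0.0)).T

    hox_range = None
    if spec.hox_side is not None:
        # compact 20-residue extramembrane domain well outside the bilayer
        center = np.array([5.0, 5.0, spec.hox_side * 28.0])
        hox = center + rng.normal(scale=3.0, size=(20, 3))
        first_hox = len(coords) + 1
        coords = np.vstack([coords, hox])
        hox_range = (first_hox, first_hox + 19)

    n_total = len(coords)
    true_z = coords[:, 2].copy()

    types = np.array(
        [
            _HYDROPHOBIC[rng.integers(len(_HYDROPHOBIC))]
            if abs(z) <= spec.core_half_width
            else _POLAR[rng.integers(len(_POLAR))]
            for z in true_z
        ]
    )
    trp_numbers = []
    for depth_target in spec.trp_depths:
        order = np.argsort(np.abs(true_z - depth_target))
        for idx in order:
            if types[idx] != "W":
                types[idx] = "W"
                trp_numbers.append(int(idx) + 1)
                break

    # carry the canonical frame through centre offset and rigid motion
    coords = coords + np.array([0.0, 0.0, spec.center_offset])
    rot = _rotation_matrix(spec.rotation_deg)
    t = np.asarray(spec.translation, dtype=float)
    coords = coords @ rot.T + t
    normal = rot @ np.array([0.0, 0.0, 1.0])
    d0 = spec.center_offset + float(t @ normal)

    model = StructureModel(
        spec.accession, tuple(range(1, n_total + 1)), "".join(types), coords
    )
    frame = MembraneFrame(normal, d0, oriented=True)
    helix_res = spec.n_helices * m
    truth = BundleTruth(
        frame=frame,
        true_z=true_z,
        trp_residue_numbers=tuple(sorted(trp_numbers)),
        hox_residue_range=hox_range,
        nterm_residue_range=(1, min(10, n_total)),
        cterm_residue_range=(helix_res + 1, helix_res + spec.cterm_tail),
    )
    return model, truth


# ---------------------------------------------------------------------------
# MSA generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MsaSpec:
    """A synthetic alignment with planted conserved columns.

    ``conserved_columns`` maps 0-based column index to the planted residue;
    at each conserved column every row emits that residue with probability
    ``conservation_level`` and a uniform residue otherwise.  ``gap_rate`` may
    be a single float or a per-column mapping.
    """

    n_rows: int = 50
    n_cols: int = 40
    conserved_columns: Mapping[int, str] = field(default_factory=dict)
    conservation_level: float = 1.0
    gap_rate: float | Mapping[int, float] = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.conservation_level <= 1:
            raise ValueError("conservation level must be in (0, 1]")
        if any(not 0 <= c < self.n_cols for c in self.conserved_columns):
            raise ValueError("conserved column outside alignment")


def gen_msa(spec: MsaSpec, seed: int) -> tuple[Alignment, pd.DataFrame]:
    """Generate an alignment with planted conserved columns and gaps."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    cols = []
    for c in range(spec.n_cols):
        if c in spec.conserved_columns:
            base = np.where(
                rng.random(spec.n_rows) < spec.conservation_level,
                spec.conserved_columns[c],
                rng.choice(letters, size=spec.n_rows),
            )
        else:
            base = rng.choice(letters, size=spec.n_rows)
        rate = (
            spec.gap_rate.get(c, 0.0)
            if isinstance(spec.gap_rate, Mapping)
            else spec.gap_rate
        )
        if rate:
            base = np.where(rng.random(spec.n_rows) < rate, "-", base)
        cols.append(base)
    matrix = np.column_stack(cols)
    ids = tuple(f"seq{i:04d}" for i in range(spec.n_rows))
    rows = tuple("".join(r) for r in matrix)
    aln = Alignment(ids, rows, np.ones(spec.n_cols, dtype=bool))
    truth = pd.DataFrame(
        [{"column": c, "residue": r} for c, r in sorted(spec.conserved_columns.items())]
    )
    return aln, truth


def write_msa(aln: Alignment, path) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as handle:
        for name, row in zip(aln.ids, aln.rows):
            handle.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# depth-cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Paired Trp-depth samples with a tunable asymmetry bias.

    The baseline cohort mixes symmetric interface peaks at ±18 Å with a broad
    uniform component over the 40 Å window.  The biased (Hox-like) cohort
    redraws a ``bias`` fraction of its observations from two asymmetric
    components — a lumenal-interface peak at −20 Å (weight ``lumenal_weight``)
    and a cytoplasmic-leaflet peak at +7.5 Å — the enrichment pattern of
    Hox-containing CerS, whose Trp distribution is biased towards the lumenal
    side of the ER membrane.  ``bias = 0`` makes the cohorts identically
    distributed.
    """

    n_per_cohort: int = 500
    bias: float = 0.5
    lumenal_weight: float = 0.7
    interface_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_per_cohort < 1:
            raise ValueError("n_per_cohort must be >= 1")
        if not 0 <= self.bias <= 1:
            raise ValueError("bias must be in [0, 1]")
        if not 0 <= self.lumenal_weight <= 1:
            raise ValueError("lumenal_weight must be in [0, 1]")


def _baseline_depths(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[0.3, 0.3, 0.4])
    out = np.empty(n)
    out[comp == 0] = rng.normal(-18.0, sd, size=(comp == 0).sum())
    out[comp == 1] = rng.normal(+18.0, sd, size=(comp == 1).sum())
    out[comp == 2] = rng.uniform(-35.0, 35.0, size=(comp == 2).sum())
    return out


def gen_depth_cohort(
    spec: CohortSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate (hox_like, baseline) Trp-depth samples plus a truth dict."""
    rng = np.random.default_rng(seed)
    n = spec.n_per_cohort
    baseline = _baseline_depths(rng, n, spec.interface_sd)
    hox = _baseline_depths(rng, n, spec.interface_sd)
    biased = rng.random(n) < spec.bias
    n_biased = int(biased.sum())
    lumenal = rng.random(n_biased) < spec.lumenal_weight
    extra = np.where(
        lumenal,
        rng.normal(-20.0, 2.0, size=n_biased),
        rng.normal(+7.5, 1.5, size=n_biased),
    )
    hox[biased] = extra
    truth = {"bias": spec.bias, "n_per_cohort": n, "n_biased_draws": n_biased}
    return hox, baseline, truth
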