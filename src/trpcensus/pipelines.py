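"""End-to-end pipelines: census, depth profiling and conservation ranking.

Each pipeline reads its inputs from a :class:`PipelineConfig`, writes TSV/JSON
outputs plus a manifest under the configured run directory, and is
deterministic: re-running with the same config reproduces the outputs
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from trpcensus import __version__
from trpcensus.catalog import Category, assign_categories, parse_records
from trpcensus.composition import composition_of, summarize_category, write_table
from trpcensus.conservation import logo_heights, rank_positions, read_and_filter_msa
from trpcensus.depth import (
    classify_region,
    compare_trp_depths,
    hox_orientation_filter,
    orient_frame,
    parse_structure,
    place_membrane,
    residue_depths,
)
from trpcensus.redundancy import representatives
from trpcensus.stats import anova_oneway, tukey_hsd

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_census", "run_depth", "run_conserve"]

#: Trp-abundance comparison strata for the ANOVA + Tukey step
CENSUS_TEST_CATEGORIES = (Category.TM_6_10, Category.CERS, Category.TLC_OTHER)


@dataclass
class PipelineConfig:
    """Flat key-value configuration shared by the three pipelines.

    Keys carry explicit units (``half_thickness_angstrom``) so unit errors are
    visible in the config file itself.  The file format is ``key = value``
    per line, ``#`` comments allowed; round-trips losslessly.
    """

    out_dir: str = "run"
    seed: int = 0
    # census
    input_path: str = ""
    input_table: str = ""
    dialect: str = "fasta_plus_table"
    cers_list: str = ""
    tlc_list: str = ""
    identity_threshold_c: float = 0.7
    # depth
    models_dir: str = ""
    cohorts_table: str = ""
    half_thickness_angstrom: float = 18.0
    depth_window_angstrom: float = 40.0
    # conservation
    msa_fasta: str = ""
    reference_id: str = ""
    top_k: int = 10
    min_seqs_per_column: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold_c <= 1:
            raise ValueError("identity_threshold_c outside (0, 1]")
        if self.half_thickness_angstrom <= 0 or self.depth_window_angstrom <= 0:
            raise ValueError("thickness/window must be positive")
        if self.min_seqs_per_column < 1 or self.top_k < 0:
            raise ValueError("min_seqs_per_column >= 1 and top_k >= 0 required")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name in values:
                caster = type(getattr(cls, f.name, f.default))
                kwargs[f.name] = caster(values.pop(f.name))
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def _write_manifest(out: Path, pipeline: str, config: PipelineConfig,
                    counts: Mapping[str, int]) -> None:
    manifest = {
        "pipeline": pipeline,
        "version": __version__,
        "config": {f.name: getattr(config, f.name) for f in fields(config)},
        "counts": dict(counts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _read_accession_list(path: str) -> frozenset[str]:
    if not path:
        return frozenset()
    return frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )


def run_census(config: PipelineConfig) -> dict:
    """Parse, categorise, deduplicate, and summarise composition per stratum.

    Stages: parse records → assign categories → per-category redundancy
    filtering at ``c`` → per-protein composition → category mean ± SD table →
    one-way ANOVA with post hoc Tukey HSD on Trp percent across the 6-10 TMD,
    CerS and TLC-other strata (when all three are populated).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = parse_records(
        config.input_path, config.dialect, table_path=config.input_table or None
    )
    logger.info("census: parsed %d records", len(records))
    cers = _read_accession_list(config.cers_list)
    tlc = _read_accession_list(config.tlc_list)
    assignments = {r.accession: assign_categories(r, cers, tlc) for r in records}

    summaries = []
    trp_samples: dict[Category, np.ndarray] = {}
    counts = {"records_in": len(records)}
    for category in Category:
        members = [r for r in records if category in assignments[r.accession].labels]
        if not members:
            logger.info("census: category %s empty, omitted", category)
            continue
        nonredundant = representatives(members, config.identity_threshold_c)
        vectors = [composition_of(r.sequence) for r in nonredundant]
        summaries.append(summarize_category(vectors, category))
        counts[f"n_{category.value}"] = len(nonredundant)
        if category in CENSUS_TEST_CATEGORIES:
            if category is Category.TM_6_10:
                # the published comparison group is 6-10 TMD proteins OTHER
                # than the CerS clade and TLC family: keep strata disjoint
                excluded = {Category.CERS, Category.TLC_OTHER}
                sample = [
                    v
                    for v, r in zip(vectors, nonredundant)
                    if not (assignments[r.accession].labels & excluded)
                ]
            else:
                sample = vectors
            trp_samples[category] = np.array([v["W"] for v in sample])
        logger.info(
            "census: %s %d records -> %d nonredundant", category, len(members),
            len(nonredundant),
        )
    table = write_table(summaries, out / "composition_table.tsv")

    stats_report: dict = {"comparison": "Trp percent", "groups": {}}
    usable = [c for c in CENSUS_TEST_CATEGORIES if trp_samples.get(c) is not None
              and len(trp_samples[c]) >= 2]
    if len(usable) >= 2:
        groups = [trp_samples[c] for c in usable]
        anova = anova_oneway(groups)
        stats_report["groups"] = {c.value: len(trp_samples[c]) for c in usable}
        stats_report["group_means"] = {
            c.value: float(trp_samples[c].mean()) for c in usable
        }
        stats_report["anova"] = {"F": anova.statistic, "p": anova.p_value}
        stats_report["tukey"] = [
            {
                "pair": [usable[r.pair[0]].value, usable[r.pair[1]].value],
                "q": r.statistic,
                "p": r.p_value,
                "mean_diff": r.extra["mean_diff"],
            }
            for r in tukey_hsd(groups)
        ]
    else:
        stats_report["skipped"] = "fewer than two populated comparison strata"
        logger.info("census: group tests skipped (%s)", stats_report["skipped"])
    (out / "group_tests.json").write_text(
        json.dumps(stats_report, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(out, "census", config, counts)
    return {"table": table, "stats": stats_report, "counts": counts}


def run_depth(config: PipelineConfig) -> dict:
    """Depth-profile structure models and compare Trp depths between cohorts.

    The cohorts table (TSV) must carry columns ``accession``, ``cohort`` and
    optionally ``hox_start``/``hox_end``, ``nterm_start``/``nterm_end`` and
    ``cyto_start``/``cyto_end``.  Models with a Hox range whose N-terminus
    lands on the Hox side are rejected and logged.  The cytoplasmic reference
    defaults to the last 10 modelled residues.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models_dir = Path(config.models_dir)
    cohort_df = pd.read_csv(config.cohorts_table, sep="\t")
    if not models_dir.is_dir():
        raise FileNotFoundError(models_dir)

    profiles: dict[str, list] = {}
    depth_rows = []
    rejected = []
    counts = {"models_in": len(cohort_df)}
    for row in cohort_df.itertuples(index=False):
        path = models_dir / f"{row.accession}.pdb"
        model = parse_structure(path, accession=row.accession)
        frame = place_membrane(model)
        if _has_range(row, "cyto"):
            cyto = range(int(row.cyto_start), int(row.cyto_end) + 1)
        else:
            cyto = model.residue_numbers[-10:]
        frame = orient_frame(frame, model, cyto)
        if _has_range(row, "hox") and _has_range(row, "nterm"):
            verdict = hox_orientation_filter(
                model,
                frame,
                (int(row.hox_start), int(row.hox_end)),
                (int(row.nterm_start), int(row.nterm_end)),
            )
            if verdict == "reject":
                logger.info("depth: rejected %s (N-terminus on the Hox side)",
                            row.accession)
                rejected.append(row.accession)
                continue
        profile = residue_depths(model, frame, config.depth_window_angstrom)
        profiles.setdefault(row.cohort, []).append(profile)
        for num, res, z, inc in zip(
            profile.residue_numbers, profile.residue_types, profile.z, profile.included
        ):
            if inc:
                depth_rows.append(
                    {
                        "accession": row.accession,
                        "cohort": row.cohort,
                        "residue_number": num,
                        "residue_type": res,
                        "z_angstrom": round(float(z), 3),
                        "region": classify_region(z, config.half_thickness_angstrom),
                    }
                )
    counts["models_rejected"] = len(rejected)
    counts["models_profiled"] = sum(len(v) for v in profiles.values())
    if not profiles:
        raise ValueError("no structures survived filtering")

    depth_table = pd.DataFrame(depth_rows)
    depth_table.to_csv(out / "residue_depths.tsv", sep="\t", index=False)
    trp_table = depth_table[depth_table.residue_type == "W"][
        ["cohort", "accession", "z_angstrom"]
    ]
    trp_table.to_csv(out / "trp_depths.tsv", sep="\t", index=False)

    report: dict = {"rejected": sorted(rejected),
                    "cohorts": {c: len(v) for c, v in profiles.items()}}
    cohort_names = sorted(profiles)
    if len(cohort_names) == 2:
        result = compare_trp_depths(profiles[cohort_names[0]], profiles[cohort_names[1]])
        report["mann_whitney"] = {
            "cohort_a": cohort_names[0],
            "cohort_b": cohort_names[1],
            "U": result.statistic,
            "p": result.p_value,
            **{k: v for k, v in result.extra.items()},
        }
    (out / "cohort_comparison.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(out, "depth", config, counts)
    return {"report": report, "counts": counts, "profiles": profiles}


def _has_range(row, prefix: str) -> bool:
    start, end = f"{prefix}_start", f"{prefix}_end"
    return (
        hasattr(row, start)
        and hasattr(row, end)
        and pd.notna(getattr(row, start))
        and pd.notna(getattr(row, end))
    )


def run_conserve(config: PipelineConfig) -> dict:
    """Filter the MSA, compute IC and logo heights, rank conserved positions."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = read_and_filter_msa(config.msa_fasta, config.min_seqs_per_column)
    ranking = rank_positions(aln, config.reference_id, config.top_k)
    heights = logo_heights(aln)

    heights.to_csv(out / "logo_heights.tsv", sep="\t", index_label="column")
    with open(out / "ic_ranking.tsv", "w") as handle:
        handle.write("rank\tcolumn\treference_position\tconsensus\tic_bits\n")
        for rank, (col, pos, consensus, ic) in enumerate(ranking.entries, start=1):
            pos_str = "" if pos is None else str(pos)
            handle.write(f"{rank}\t{col}\t{pos_str}\t{consensus}\t{ic:.4f}\n")
    counts = {
        "n_sequences": len(aln.ids),
        "n_columns": aln.width,
        "n_columns_kept": int(aln.column_mask.sum()),
        "n_ranked": len(ranking.entries),
    }
    _write_manifest(out, "conserve", config, counts)
    return {"ranking": ranking, "heights": heights, "counts": counts}
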