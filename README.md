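# trpcensus

Tryptophan is one of the rarest amino acids, yet it is over-represented in
membrane proteins, where its indole ring favours the lipid–water interface and
helps anchor transmembrane (TM) helices in the bilayer. Ceramide synthases
(CerS) — seven-TMD enzymes of the endoplasmic reticulum that *N*-acylate
sphingoid bases — push this further: their Trp content is markedly higher than
in other proteins with a similar number of TMDs, several of their most
conserved residues are Trp, and in the Hox-domain-containing CerS the Trp
residues are distributed asymmetrically across the membrane, biased towards
the ER-lumenal side.

`trpcensus` is a tested pipeline for quantifying exactly these observations,
for computational biologists working with annotated proteomes, structure
models and multiple sequence alignments:

* **Sequence catalog** — parse UniProt-style records (reduced flat file, or
  FASTA plus a `Transmembrane` annotation table), count TRANSMEM segments and
  stratify proteins into census categories (soluble; 1, 2–5, 6–10, ≥11 TMDs;
  ER-located; CerS clade; other TLC-domain proteins).
* **Redundancy filter** — greedy sequence-identity clustering in the style of
  CD-HIT at threshold *c* = 0.7. Identity of a pair is the number of identical
  columns in one optimal global alignment (match +1, mismatch −1, gap open −2,
  gap extend −1) divided by the shorter sequence length.
* **Composition census** — per-protein percent composition over the 20
  standard residues (ambiguity letters excluded), summarised per category as
  mean ± sample SD, plus the pooled length-weighted alternative.
* **Inference statistics** — Mann-Whitney *U* (exact enumeration for small
  samples, tie- and continuity-corrected normal approximation otherwise),
  one-way ANOVA (*F* = MSB/MSW), and Tukey's HSD with studentized-range
  p-values computed by numerical quadrature. All implemented from the
  formulas and cross-checked against independent references in the tests.
* **Membrane depth** — place a planar membrane slab on a Cα trace by
  maximising windowed hydrophobicity (a deterministic surrogate for
  transfer-energy minimisers such as PPM), sign it so the cytoplasmic side is
  positive, and report the signed depth *z* of every Cα from the bilayer
  centre, with a ±18 Å bilayer boundary and a 40 Å analysis window. Includes
  the topology filter that rejects models whose N-terminus folds onto the
  Hox-domain side.
* **Conservation** — alignment column information content
  IC = log₂20 − *H* (gaps carry no probability mass), sequence-logo letter
  heights IC·p̂, and top-*k* conserved-position ranking mapped to a reference
  sequence's residue numbering.
* **Synthetic data** — seeded generators for every input class (annotated
  proteomes with controlled composition, substitution families with exact
  identity, ideal α-helical bundles with a known membrane frame and planted
  Trp depths, alignments with planted conserved columns, paired depth
  cohorts), each returning machine-readable ground truth.

## Worked example

A miniature census over three synthetic strata whose planted Trp
frequencies are the published per-category means (CerS-like 3.35 %,
6–10 TMD-like 1.89 %, TLC-like 2.61 %):

```python
from trpcensus.simulate import CategorySpec, gen_proteome
from trpcensus.composition import composition_of, summarize_category
from trpcensus.stats import anova_oneway, tukey_hsd

specs = [
    CategorySpec("CERS", 60, length_range=(300, 300), tmd_count_range=(7, 7)),
    CategorySpec("TM_6_10", 60, length_range=(300, 300), tmd_count_range=(6, 10)),
    CategorySpec("TLC_OTHER", 60, length_range=(300, 300), tmd_count_range=(6, 8)),
]
records, truth = gen_proteome(specs, seed=7)
samples = {}
for label in ("TM_6_10", "CERS", "TLC_OTHER"):
    vecs = [composition_of(r.sequence) for r in records if r.source_dataset == label]
    s = summarize_category(vecs, label)
    samples[label] = [v["W"] for v in vecs]
    print(f"{label:10s} Trp {s.mean['W']:.2f} +/- {s.sd['W']:.2f} %  (n={s.n_proteins})")
anova = anova_oneway(list(samples.values()))
print(f"one-way ANOVA: F = {anova.statistic:.1f}, p = {anova.p_value:.2e}")
for r in tukey_hsd(list(samples.values())):
    pair = [list(samples)[i] for i in r.pair]
    print(f"Tukey {pair[0]} vs {pair[1]}: q = {r.statistic:.2f}, p = {r.p_value:.4g}")
```

prints

```
TM_6_10    Trp 1.93 +/- 0.94 %  (n=60)
CERS       Trp 3.48 +/- 1.04 %  (n=60)
TLC_OTHER  Trp 2.53 +/- 0.97 %  (n=60)
one-way ANOVA: F = 37.8, p = 2.17e-14
Tukey TM_6_10 vs CERS: q = 12.18, p = 0
Tukey TM_6_10 vs TLC_OTHER: q = 4.67, p = 0.003294
Tukey CERS vs TLC_OTHER: q = 7.51, p = 9.692e-07
```

The recovered means sit within sampling error of the planted values, and all
three pairwise Trp-abundance differences are flagged by the Tukey HSD test —
the CerS-like stratum is the clear outlier, as in real proteomes.

The same computations are available from the shell via the `trpcensus` CLI
(`catalog`, `dedupe`, `census`, `depth`, `conserve`, `stats`, `simulate`);
each pipeline writes TSV/JSON outputs and a manifest under a run directory.

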