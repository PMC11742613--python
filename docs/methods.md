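# Methods

This note documents the models, conventions and numerical choices behind
`trpcensus`, and what the synthetic-data generators do and do not emulate.

## Sequence catalog and census categories

Protein records carry a sequence over the 20 standard letters plus the
ambiguity letters X, B, Z, U, O, a list of TRANSMEM segments, and free-text
subcellular locations. Feature coordinates are **1-based inclusive** (the
UniProt convention); segments are stored sorted and must not overlap.

Two input dialects are supported. The reduced flat-file parser interprets
only the `ID`/`AC`/`FT TRANSMEM`/`CC -!- SUBCELLULAR LOCATION`/`SQ` line
types — everything the census needs — and either skips malformed entries
with a logged line number or raises in strict mode. The FASTA + TSV dialect
pairs a FASTA file with an annotation table whose `Transmembrane` column
uses the UniProt download style (`TRANSMEM 11..31; TRANSMEM 45..65`); it is
also the round-trippable output format.

Categories: 0 TMDs → SOLUBLE; otherwise TM_ANY plus exactly one count bin
(1 / 2–5 / 6–10 / ≥11 — seven-TMD proteins such as CerS land in 6–10).
ER membership is a case-insensitive substring match against a configurable
term list (default: "endoplasmic reticulum"); substring matching is
deliberate, because curated location strings are heterogeneous and often
composite. CerS/TLC membership comes from explicit accession lists, with
CerS taking precedence.

## Redundancy filtering

Pairwise identity is defined as the number of identical aligned columns in
one optimal global alignment under a fixed scoring (match +1, mismatch −1,
gap open −2, gap extend −1), divided by the length of the shorter sequence —
the global-identity convention of CD-HIT, whose deduplication role this
module reproduces at *c* = 0.7. CD-HIT's short-word prefilter and banded
alignment are not reproduced; exact equivalence with CD-HIT output is not
promised, only the clustering contract.

Clustering is greedy incremental: sequences sorted by length descending
(ties broken by accession so output is byte-stable); each sequence joins the
first existing representative at identity ≥ *c*, else founds a cluster.
Representatives therefore satisfy the pairwise property that each is below
threshold against all earlier representatives.

Because identical columns of **any** global alignment form a common
subsequence, identity ≤ LCS/min-length. The clusterer uses this as an exact
prune: a cheap bit-parallel LCS is computed first and the full alignment is
run only when the bound reaches the threshold. For unrelated sequence pairs
the bound almost always rejects, which is what makes deduplicating
thousand-record catalogs fast; the prune never changes the result.

## Composition census

Per-protein composition counts the 20 standard letters only; ambiguity
letters are excluded from numerator **and** denominator, so percentages are
never diluted by X-runs. Category cells are the unweighted mean ± sample SD
(n−1) of per-protein percentages — short and long proteins count equally.
The pooled, length-weighted composition over the concatenated dataset (the
Pepstats convention) is provided as the alternative; the per-protein
summary is the default comparator. A sequence with zero countable residues
is an error, not a zero vector.

## Group statistics

All three tests are implemented from the formulas; scipy supplies only
distributions and rank utilities, and the test suite cross-checks every
routine against an independent reference and against simulation oracles.

* **Mann-Whitney U.** U is computed from midranks. For pooled sample sizes
  ≤ 12 the p-value is exact, by enumeration of all C(n₁+n₂, n₁) rank
  assignments (two-sided p = twice the smaller tail, capped at 1). Above
  that, a normal approximation with the tie-corrected variance and a 0.5
  continuity correction is used. Two-sided alternatives are the default
  throughout the pipelines.
* **One-way ANOVA.** F = MSB/MSW on (k−1, N−k) df. MSW = 0 with equal means
  yields F = 0, p = 1; MSW = 0 with unequal means is an error rather than an
  infinite statistic.
* **Tukey HSD.** q = |mean difference| / sqrt(MSW/ñ), with ñ the harmonic
  mean of the two group sizes (the Tukey-Kramer adjustment). P-values come
  from the studentized-range CDF evaluated by numerical quadrature: the
  k-normal range CDF is integrated by 160-node Gauss-Legendre quadrature
  and then against the chi distribution of the pooled-SD scale factor by
  adaptive quadrature with absolute tolerance 1e-6. This keeps the test
  independent of any single library's implementation; agreement with an
  independent implementation and with a 50,000-replicate Monte-Carlo null
  is asserted in the tests.

## Membrane placement and depth profiling

A structure model is its Cα trace (altlocs resolve to the first occurrence;
residues without a standard one-letter code are skipped with a warning).
The membrane is a planar slab: a unit normal, a centre offset d₀ along it,
and a half-thickness of 18 Å, the reported bilayer boundary.

Placement maximises S(n, d₀) = Σᵢ h(resᵢ)·1[|zᵢ − d₀| ≤ w], with h the
mean-centred Kyte-Doolittle hydropathy and w = 15 Å the core half-width —
a deterministic, dependency-free surrogate for transfer-energy minimisers,
validated by parameter recovery on generated bundles rather than by
matching any particular program's output. The search covers 500 hemisphere
normals on a deterministic Fibonacci spiral; for each direction the optimal
d₀ is found **exactly** by a sweep over the 2N interval endpoints of the
per-residue membership windows (taking the midpoint of the best plateau),
which is both faster and more accurate than a fixed-step offset scan on a
piecewise-constant objective. The best grid directions are then refined by
tangent-plane tilts with shrinking angular steps (4° → 0.25°), each
candidate again paired with its exact offset. On generated bundles with
helix tilts up to 30° this recovers the normal within 5°, the centre within
2 Å, and ≥ 95 % of residue depths within 2 Å.

The frame is unsigned until `orient_frame` flips it, if needed, so that a
reference residue set of known cytoplasmic topology (for CerS, the
C-terminal segment) has positive mean depth; a zero reference mean is an
error. Depth is zᵢ = Cαᵢ·n − d₀, cytoplasmic positive. Residues with
|z| > 40 Å are masked from analysis; the window is measured from the
bilayer **centre**, matching the plotted depth axis (the alternative
reading, 40 Å from the boundaries, would extend to |z| ≤ 58 Å and is not
used). z = 0 belongs to the cytoplasmic half by the declared ≥ tie rule.
The topology filter rejects a model when the mean depths of its N-terminal
segment and of its Hox-like domain share a sign — the predicted fold has
put the N-terminus on the wrong side of the bundle. Hox-domain residue
ranges are supplied via the cohort configuration table, as they are not
derivable from coordinates.

Cohort comparison pools all Trp depths per cohort and applies the two-sided
Mann-Whitney U test, reporting counts and medians alongside.

## Conservation

Column information content is IC = log₂20 − H over the observed non-gap
frequencies, in bits (0 to log₂20 ≈ 4.3219). Gaps carry no probability
mass, consistent with the occupancy filter that masks columns with fewer
than 10 non-gap residues before analysis. No small-sample correction is
applied by default, and HMM-weighted (posterior-probability) IC as computed
by logo web servers is not reproduced: top-k rankings of highly conserved
columns are insensitive to the difference, and rank agreement — not
bit-for-bit equality — is the contract. Logo letter heights are IC·p̂ and
sum to the column IC. Rankings sort by IC descending with ties broken by
ascending column index; positions are reported in the reference sequence's
ungapped numbering, null where the reference is gapped.

## Synthetic-data generators

All generators are deterministic under a fixed seed (byte-identical files)
and attach ground truth sufficient to score the downstream stage.

* **Proteomes.** Sequences are drawn i.i.d. per position from a per-category
  frequency vector; the defaults are the published per-category composition
  means, so the CerS-like stratum plants 3.35 % Trp, the 6–10 TMD stratum
  1.89 %, the TLC stratum 2.61 %, and the soluble stratum 1.00 %. TMD
  segments (21 residues) are placed non-overlapping, uniformly at random.
  What is **not** emulated: length–composition correlation, domain
  structure, and homology between records.
* **Substitution families.** Copies differ from their seed by exactly
  round((1−t)·L) point substitutions at distinct positions — no indels — so
  the optimal alignment is gapless and identity is exact by construction,
  decoupling clustering tests from the aligner.
* **Helical bundles.** Ideal α-helix geometry (rise 1.5 Å/residue,
  100°/residue twist, radius 2.3 Å), an odd number of antiparallel helices
  (default 7, the CerS architecture) spanning a membrane centred at z = 0,
  lumenal N-terminus and a cytoplasmic C-terminal tail. Residues inside the
  15 Å core are drawn from hydrophobic types, flanks from polar ones; Trp is
  planted at requested true depths; an optional compact extramembrane domain
  on a chosen side provides topology-filter fixtures. Bundles can be tilted
  (validity bound 60°), rigidly rotated and translated, with the true frame
  carried along. Loops between helices and side-chain atoms are not
  modelled.
* **Alignments.** Planted conserved columns emit a fixed residue with a set
  probability, other columns are uniform, and gaps are injected at a global
  or per-column rate. Rows are independent — no phylogenetic covariance.
* **Depth cohorts.** The baseline cohort mixes symmetric interface peaks at
  ±18 Å (SD 4 Å, weight 0.3 each) with a uniform component over ±35 Å. The
  Hox-like cohort redraws a fraction `bias` of its observations from two
  asymmetric components: a lumenal-interface peak at −20 Å and a
  cytoplasmic-leaflet peak at +7.5 Å. The defaults (bias 0.5, lumenal
  weight 0.7) encode a pronounced net lumenal shift — the hallmark of the
  Hox-CerS Trp distribution — strong enough that a 500-per-cohort
  comparison is decisively significant, while bias 0 yields identically
  distributed cohorts for null calibration.

Because the generators plant exactly the features the pipeline measures,
passing tests demonstrate correctness of the computation, calibration of
the statistics, and parameter recovery under idealised geometry; they do
not demonstrate robustness to real-structure artefacts (loops, broken
helices, non-planar membranes) or to biased real-world annotation.

## Pipeline conventions and problem sizes

Pipelines are configured by a flat `key = value` file with units in key
names (`half_thickness_angstrom`), write TSV/JSON plus a manifest, and are
byte-reproducible for a fixed config. In the census group tests, the
6–10 TMD comparison stratum excludes CerS-clade and TLC members so the
three compared groups are disjoint, mirroring the "other TLC-domain
proteins (excluding the CerS clade)" comparison design; the category
summary table itself keeps the plain bin semantics (bins partition TM_ANY).
The ALL column is deduplicated over its own pooled record set, with
redundancy filtering otherwise performed per category.

The bundled verification runs use desk-scale problem sizes chosen to give
stable statistics with comfortable margins: 150 proteins per census stratum
at length 300 (planted-mean recovery within 3 standard errors), 50 bundles
for frame recovery, 100 replicates of 500-per-cohort depth comparisons for
null calibration, and 2,000 replicates for the Mann-Whitney rejection-rate
check.

## Known limitations

* The naive clustering path is quadratic in catalog size; it deduplicates
  desk-scale catalogs quickly thanks to the LCS prune but is not meant for
  full proteome databases.
* The membrane surrogate assumes a single planar slab and one membrane pass
  region; curvature, re-entrant helices and lipid-specific interactions are
  out of scope.
* Exact Mann-Whitney enumeration is limited to pooled sizes ≤ 12 by
  combinatorics; beyond that the corrected normal approximation is used
  (agreement within 0.02 at the boundary is asserted in tests).
* Alignment construction itself (e.g. ClustalW) is upstream input, not
  computed here.
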