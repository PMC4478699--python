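# Methods

This note documents the models and procedures `amdcomp` implements, the
assumptions they rest on, the defaults and why, and what the synthetic
data can and cannot tell you about real paired DNA/cDNA libraries.

## Data model

The unit of observation is one annotated protein-coding read: sample
(community), layer (DNA or cDNA), genus, optional species, optional COG
id, COG functional category (one letter) and KEGG pathway. The package
consumes annotations as given — taxonomic and functional assignment
(BLAST/LCA pipelines, COG/KEGG lookups) happens upstream and is out of
scope, as are rRNA screening and quality control.

Counting reads at an annotation level yields a features × communities
integer matrix per layer. Reads lacking the level's annotation are
excluded from both the numerator and the denominator of every percentage.
This is a real choice, not a technicality: including unannotated reads in
the denominator would deflate every abundance by the (layer- and
community-specific) annotation rate. Exclusion makes abundances
comparable across communities with different annotation rates, at the
price of conditioning on "annotated at this level".

## Relative abundance

`abundance(f, c) = 100 · a / b` with `a` the reads assigned to feature
`f` in community `c` and `b` the total assigned reads there. Columns sum
to 100 within 1e−9 by construction. No rarefaction and no compositional
transform is applied; all downstream statistics work on counts (tests) or
percentages (profiles, clustering). The presentation filter "feature ≥ t%
in at least one community" is inclusive at the threshold and can pool the
remainder into an `other` row so columns still sum to 100.

For per-organism analyses the matrix is restricted to one taxon's reads
and `b` becomes the taxon's own per-community total, so the question is
"what share of this organism's transcription is gene g here", independent
of how abundant the organism is.

## Fisher screen and indicator features

For each feature and each unordered pair of communities a 2×2 table of
(feature reads, all other reads) × (community i, community j) is tested
with the two-tailed Fisher exact test. The two-tailed p is the sum of
hypergeometric point probabilities not exceeding the observed one; "not
exceeding" is judged at relative tolerance 1e−7, the conventional guard
against floating-point ties. Tables with a grand total ≤ 1024 are
evaluated in exact integer arithmetic (the tie rule applied to integer
weights), larger ones through log-gamma; the test-suite pins both paths to
an exhaustive enumeration oracle and to an independent implementation.
Degenerate tables (a zero margin) get p = 1 and are excluded from the
multiple-testing family, as are features absent everywhere, so the BH `m`
counts real hypotheses.

Benjamini–Hochberg correction is applied over all features × pairs of one
screen jointly (the conservative reading when the correction scope is not
otherwise specified); per-pair correction is available as a config flag.
Alongside each test a 99% conditional maximum-likelihood confidence
interval for the odds ratio can be attached; significance is always the
adjusted p < α (default α = 0.05), never the CI.

A feature is an **indicator** of community c (direction higher/lower) iff
all k−1 pairwise comparisons of c against the other communities are
significant after correction *and* c's proportion is on the same side in
every one. Directions are derived from proportions a/b, never raw counts,
because column totals differ. At most one higher and one lower call can
exist per feature. "Significantly different across communities" for the
summary screen means significant in ≥ 1 pair; this is one of several
defensible aggregations and is used consistently.

No omnibus k-sample test, continuity-corrected χ² fallback, or
overdispersed GLM is provided: the analysis is deliberately the composition
of exact pairwise tests.

## Activity ranking and discordance

A taxon's activity in a community is its cDNA-layer relative abundance
among protein-coding reads; "most active" is simply the top of that
ranking (ties broken lexicographically so output is reproducible). The
activity ratio cDNA%/DNA% quantifies discordance between layers:

* `abundant-inactive`: DNA ≥ 5% and ratio < 0.1 (defaults) — the
  dominant-but-silent pattern;
* `active-rare`: cDNA ≥ 5% and ratio > 10;
* `dna-absent-active`: transcripts with no DNA signal (ratio undefined,
  handled explicitly).

Both thresholds are user-facing settings, defaulting to order-of-magnitude
discordance for community-dominant taxa; there is no formal test attached,
matching the descriptive use of the pattern in the field.

## Clustering and ordination

Correlation distance d = 1 − Pearson r between profile vectors (range
[0, 2]; zero-variance profiles are a named error). UPGMA merges the
closest pair, inter-cluster distance being the unweighted mean of all
cross-cluster leaf-pair distances; exact ties merge the pair whose sorted
leaf-label tuple is smallest, so dendrograms are identical across runs and
platforms. Heights are monotone (UPGMA is reducible); output is a
scipy-layout merge table plus newick with ultrametric branch lengths
(each node at half its merge height). Pearson rather than Spearman, as in
the common R defaults; configurable at the distance step by supplying a
precomputed matrix.

PCA centres variables and takes the SVD; variance proportions sum to 1
over all returned components, and each component's sign is fixed so its
largest-magnitude loading is positive. Abundance profiles are not
standardized by default (all variables are percentages on one scale);
geochemistry tables are, because mg/l concentrations span four orders of
magnitude and pH/temperature are different units entirely.

## Geochemistry validation

The site table uses the standard column abbreviations (pH, Temperature,
DO, DOC, T-Fe, Fe2+, Fe3+, SO42-, Al, Pb, Zn, Cu, Cd, Cr, Mn), all
concentrations in mg/l. "ND" parses as missing and is never imputed as
zero. The iron mass balance |T-Fe − (Fe²⁺ + Fe³⁺)| ≤ tolerance is a
warning, not an error, with default tolerance 15 mg/l to absorb
rounding in published tables; the bundled four-site AMD table contains one
row that is internally inconsistent by 10 mg/l, which the strict
(tolerance 0) check flags and the default absorbs.

## Dereplication

"Replicate sequences sharing 100% nucleotide similarity and length" is
implemented as exact string equality after uppercasing — equal length is
implied by equal strings, ambiguity codes are not wildcards (N ≠ A), and
no reverse-complement matching is attempted. The first read in file order
represents each duplicate set. The operation is idempotent and
kept + removed always partitions the input. Clustering below 100%
identity is out of scope.

## Synthetic data generator

The generator emulates the study design the pipeline targets, not
sequences: four communities (default labels DBS, FK, YFS, YFP), features
that are (genus, COG) pairs, one multinomial draw per community × layer.

* **Baseline composition** — a single probability vector over features.
  `SimulationConfig.realistic()` draws genus weights lognormal(σ = 1) and
  within-genus COG weights lognormal(σ = 0.8), giving the skewed
  rank-abundance structure of real annotation profiles; the plain
  constructor defaults to uniform, which is the right null for calibration
  experiments.
* **Activity multipliers** — one positive number per genus; the cDNA
  expectation is the DNA proportion times the genus multiplier,
  renormalized. `realistic()` makes the most DNA-abundant genus nearly
  silent (multiplier 0.01), reproducing the dominant-but-inactive pattern
  as an explicit parameter.
* **Planted indicators** — (feature, community, fold ≥ 1, direction,
  layer): the community's expected proportion is multiplied by fold
  (higher) or 1/fold (lower) and the vector renormalized; the exact
  post-renormalization proportions are recorded as truth. A plant that
  would push a proportion above 1 before renormalization is rejected.
* **Depths** — defaults 50 000 DNA and 20 000 cDNA reads per community:
  desk-scale stand-ins for the hundreds of thousands of protein-coding
  reads per library that full runs produce, chosen so the whole test-suite
  and calibration Monte Carlo run in seconds to minutes on one CPU.
* **Determinism** — one seed fixes everything; null replicates use
  seed + replicate-index so each replicate is individually reproducible.

Sampling is multinomial only. With a single library per community there
is no information to estimate biological overdispersion, so none is
modelled; a negative-binomial layer would be the natural extension. The
generator emits the same TSV read-table dialect the ingestion stage
consumes (plus a truth JSON sidecar), and a dummy-FASTA writer with
planted exact duplicates supports dereplication tests. No error models,
read sequences, or rRNA contamination are simulated — so passing tests
demonstrate the statistics and bookkeeping on data satisfying the
sampling assumptions, not robustness to annotation error, contamination,
or overdispersion in real libraries.

## Calibration results the suite recomputes

The acceptance tests and `scripts/acceptance.py` recompute, from scratch,
at fixed design points: the iron-balance worked examples; exact-test and
BH oracle equivalence; the null false-indicator-call rate over 200
replicates (4 communities × 500 uniform features at depth 20 000), which
must stay below α + 2 Monte-Carlo standard errors; recovery sensitivity
≥ 0.8 for fold-4 higher indicators planted on 0.5%-abundance features at
depth 50 000 (a repository acceptance setting, not a field claim);
guaranteed abundant-inactive flagging at multiplier 0.01; and the
first-merge behaviour of two communities simulated from identical truth.

## Known limitations

* Multinomial sampling understates real between-library variance; the
  Fisher test inherits the same assumption, so p-values on real data are
  anti-conservative to an unknown degree (single-library designs cannot
  quantify it).
* The indicator definition requires unanimity across k−1 tests, making it
  conservative and increasingly strict as k grows.
* Per-taxon screens trust upstream taxonomic assignment; misassigned reads
  move mass between taxa in ways the package cannot detect.
* UPGMA with four items is description, not inference: no bootstrap or
  support values are attached.
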