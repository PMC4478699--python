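# amdcomp

Comparative metagenome/metatranscriptome profiling of microbial
communities, built around the analysis style used for acid-mine-drainage
(AMD) ecosystems: a handful of extremely acidic, metal-rich sites, each
sampled for both community DNA (who is there) and community mRNA as cDNA
(who is doing something), with every protein-coding read annotated by
taxon and by function (COG, COG category, KEGG pathway).

The package is for microbial ecologists who have per-read annotation
tables from paired DNA/cDNA libraries and want to answer, with explicit
statistics:

* which taxa and functions dominate each community, in each layer;
* which taxa are transcriptionally active — and which dominate the DNA
  layer yet contribute almost no transcripts;
* which functional categories are *indicators* of a community, i.e.
  expressed at a significantly higher (or lower) level there than in every
  other community;
* how communities group by their overall expression profiles.

## The statistics

**Relative abundance.** For a feature (taxon, gene, COG, …) in one
community and one layer,

    abundance = 100 * a / b

where `a` is the number of reads assigned to the feature and `b` the total
number of reads assigned to any feature at that annotation level. Reads
without an annotation at the level are excluded from both `a` and `b`.

**Differential expression.** For every feature and every pair of
communities *(i, j)* a 2×2 table `[[a_i, b_i − a_i], [a_j, b_j − a_j]]` is
tested with the two-tailed Fisher exact test (exact enumeration; ties in
point probability at relative 1e−7). P-values are Benjamini–Hochberg
adjusted over the whole feature × pair family (per-pair correction is a
config switch), with a 99% conditional-MLE confidence interval on the odds
ratio available per test. A feature whose proportion in community *c* is
significantly higher (lower) than in **all** k−1 other communities, with
concordant directions, is a higher (lower) **indicator** of *c*. The same
machinery restricted to one taxon's reads — denominators being the taxon's
own per-community totals — gives per-organism differential genes.

**Clustering/ordination.** Profiles are compared by correlation distance
(1 − Pearson r), clustered with unweighted average linkage (UPGMA, with a
deterministic label-based tie-break), and ordinated by PCA (covariance by
default; standardized for geochemistry, where variables carry different
units).

**Supporting ingestion.** Annotated read tables (TSV, one row per read)
are validated strictly; FASTA read sets are dereplicated by removing
replicate sequences with 100% nucleotide identity and length (exact string
equality, first occurrence kept); a site geochemistry table is validated,
including an iron mass-balance check T-Fe ≈ Fe²⁺ + Fe³⁺ that warns — never
errors — on internally inconsistent rows.

Because real paired libraries are bulky and annotation-pipeline dependent,
the package ships a first-class synthetic generator
(`amdcomp.simulate`): communities composed of (genus, COG) features, a
per-genus activity multiplier linking DNA to cDNA expectations, multinomial
sampling at configurable depth, and planted indicator features of known
fold-change — so every downstream stage is testable against exact truth.

## Worked example

The `analysis/` scripts run the full story on synthetic data; computation
lives in `src/amdcomp/` and the scripts only narrate. In order:

```
python analysis/01_simulate_communities.py
python analysis/02_validate_geochemistry.py
python analysis/03_profile_abundance_activity.py
python analysis/04_indicator_screen.py
python analysis/05_null_calibration.py
python analysis/06_cluster_ordination.py
```

Sample output (abridged):

```
== 02
iron mass balance exact for 3/4 sites;
  YFS: off by -10 mg/l (warned, absorbed by the default 15 mg/l rounding tolerance)
== 03
top-3 transcriptionally active genera per community (cDNA share):
  FK: Acidithiobacillus (35.5%), Ferroplasma (17.2%), ARMAN (15.3%)
abundant-but-inactive: Acidimicrobium averages 28.9% of DNA but only
  0.35% of transcripts (4/4 communities flagged)
== 04
8 of 120 COGs differ significantly in transcript share across the four
communities (BH-adjusted p < 0.05)
indicator COGs per community (higher / lower):
  FK: 2 higher, 0 lower
  YFP: 1 higher, 0 lower
planted indicators recovered: 3/4
== 05
null false indicator-call rate: 0.0000 +/- 0.0000 (alpha = 0.05, 200 replicates)
planted fold-4 indicators recovered: 20/20 (sensitivity 1.00)
```

Reading this: the bundled geochemistry table passes the iron mass balance
exactly at three sites and is 10 mg/l off at the fourth (flagged, not
fatal). The generator deliberately made one genus DNA-dominant but almost
silent; the activity stage finds and flags it in all four communities. Of
the four planted indicator COGs, three are recovered — the fourth, a
fold-5 depletion of one genus's slice of a shared COG, misses narrowly in
one of its three pairwise tests (adjusted p = 0.11), which is exactly the
dilution behaviour one should expect when effects are planted at the
(genus, COG) level but screened at the COG level. Under the null the
indicator definition (all three pairwise tests significant and concordant)
makes false calls rare; against fold-4 effects at 0.5% abundance and
50 000-read depth it recovers everything.

The same stages are available as a CLI (`amdcomp simulate | ingest |
dereplicate | geochem | abundance | screen | indicators | activity |
cluster | all`); `amdcomp all --out run/ --seed 1` writes every stage
artifact plus a machine-readable `summary.json`.

## Layout

```
src/amdcomp/      simulate, ingest, abundance, differential, activity,
                  multivariate, pipeline, cli
analysis/         numbered narrative drivers (01–06)
tests/            pytest suite, including oracle-equivalence and
                  Monte-Carlo acceptance checks
docs/methods.md   models, assumptions, parameter defaults, limitations
```
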