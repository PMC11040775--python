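# Methods

## The study → model → test data model

Every omic analysis fits one or more statistical models to measurements and
then tests hypotheses on the fitted parameters. `omicrate` archives results
under exactly that hierarchy. A **Study** carries open metadata, an optional
report link, linkout URL patterns, a plot-hook registry, annotation
databases and an optional cross-model feature-ID mapping table; a **Model**
groups **Tests** (each a per-feature results table) with an optional assay
matrix, feature metadata and per-database enrichment results. The minimal
valid study is one results table under one model and test; everything else
is incremental, and re-adding a component under the same key replaces it
(mirroring reinstall semantics rather than merging).

Feature identifiers are opaque strings — no assumptions about Ensembl,
UniProt or any annotation scheme. The mapping table allows many-to-many
rows (a protein maps to several phosphosites); lookups return all matches.

Column semantics are declared, not hard-coded: each column carries a role
(`feature_id`, `effect_size`, `statistic`, `p_value`, `adjusted_p_value`,
`other`) plus a tooltip and display name. When the analyst supplies no
roles, they are inferred case-insensitively from conventional names
(`p_value`/`pval`/`p`, `padj`/`fdr`/`adj_p_val`, `logFC`/`effect`,
`t`/`stat`/`z`); explicit roles always win. Downstream analytics locate
p-value and statistic columns through roles only.

Two validation regimes coexist deliberately. Mutating calls
(`add_results`, `add_enrichments`, ...) raise eagerly on malformed input —
duplicate feature ids, p-values outside [0, 1], enrichment tests that are
not a subset of the model's differential tests, terms absent from their
database, linkout patterns without exactly one slot. `validate_study` is
total: it never raises, re-checks every invariant (including states a
hostile or hand-edited container could reach) and returns a coded report;
an empty error list is the installability criterion, warnings (assay/result
feature overlap below 1, heterogeneous schemas for a test name reused
across models, all-missing mapping rows) never block.

## Containers, registry, archives

A container is a plain directory: `manifest.json` (schema version, study
fields, model/test counts, per-file SHA-256 inventory, version history),
TSV component files, JSON for annotations/metadata/linkouts. The format is
deliberately language-neutral and diff-able rather than tied to any
package ecosystem. Tabular encoding is TSV with `NA` for missing and
shortest-round-trip float formatting; readers use correctly-rounded float
parsing, so `load(install(study))` reproduces every stored value exactly
(the round-trip property tests assert component-wise equality, not
approximate equality). Installation stages into a temp directory inside the
registry root and renames, so a failed install leaves the registry in its
prior state; reinstalling records the prior version in `history` without
migration logic. Export zips the container; import extracts, verifies every
checksum and refuses tampered archives. Loaders accept any `1.x` schema and
reject other majors. Per-test results tables load lazily — checksum
verification reads bytes, but parsing happens on first access.

## Accessor semantics

Query filters AND together; OR across conditions is expressed as multiple
queries or through set analysis. Comparisons never match missing values.
Sorting is stable with feature-id ascending as the tie-break, which makes
pagination a partition of the sorted result. Serialization supports TSV,
CSV, records-oriented JSON (`null` for missing) and Arrow/feather;
`parse_table` inverts each. Spreadsheet formats are out of scope — CSV
substitutes. Linkout resolution substitutes the percent-encoded cell value
into the pattern's single `{slot}`.

## Set analysis

A set definition is an AND of threshold clauses over one test's numeric
columns, with a per-clause `absolute` flag (so `|logFC| ≥ 1` needs no
precomputed magnitude column) and an optional complement. Missing values
fail clauses; consequently **negation includes features whose value is
missing**, because the complement is taken against the universe, not
against "features with a value". The universe defaults to the union of
feature ids across the model's tests (the most permissive choice;
intersection is available) — complements need an explicit reference set,
and the union is the only one derivable from the archived data alone.

The UpSet summary computes **exclusive** intersections by default: each
element of the union contributes to exactly one membership pattern, so
region sizes always partition the union (asserted as a property test and
against exhaustive `2^T − 1` enumeration). Inclusive "at least these sets"
counts are available by flag. Regions rank by size descending with ties
broken by degree ascending then pattern lexicographic; `top_n` defaults
to 10. The same machinery applies verbatim to the enrichment term-test
table with terms as elements.

## Enrichment analytics

**Barcode.** Features of a term, restricted to those actually present in
the selected test's results (untested members are counted and reported,
never imputed), ranked descending by the absolute value of the
role=`statistic` column (|t| in the fixtures); ties break by feature id so
ranks are a deterministic 1..n permutation invariant under monotone
transforms of the statistic. The box summary uses linear-interpolation
quartiles.

**Term network.** Nodes are terms whose adjusted p (nominal optional)
passes `node_cutoff` (default 0.05) in at least one test; each node carries
one wedge per stored test and its size is `|term ∩ tested universe|` —
never the raw database term size, since untested members say nothing about
this model. Edges join pairs whose similarity on those tested sets reaches
`edge_cutoff`; defaults (Jaccard, 0.25; combined k = 0.5 with 0.375
offered) follow common enrichment-map practice since the coefficients
themselves carry no canonical cutoff. Clusters are connected components;
raising the edge cutoff can only refine the partition, so cluster counts
are monotone in the cutoff (tested against a union-find oracle).

**Tiled layout.** Clusters sort by node count or edge count (descending) or
minimum adjusted p (ascending), with deterministic tie-breaks (secondary
statistic, then smallest member term id); nodes within a cluster sort by
(min adjusted p, term id). Tiles fill a near-square grid column-major, so
the ranking reads top-to-bottom then left-to-right. The "trend" statistic a
dashboard might sort by is not canonically defined; the sort key is exposed
instead.

**Hexbin.** The standard two-offset-lattice construction: centres at
`(i·dx, j·dy)` and `(i+½)·dx, (j+½)·dy` with `dx = x-span/gridsize` and
`ny ≈ gridsize/√3` rows; a point joins the nearest centre under the
anisotropic metric `(Δx/dx)² + 3(Δy/dy)²`, whose Voronoi cells are
hexagons. Tie-breaks are pinned down so the vectorized path agrees exactly
with an exhaustive nearest-centre scan: between lattices the first lattice
wins, within a lattice the smaller index wins. Non-finite points are
dropped and counted; counts plus drops always equal the input size. The
reported extent pads the data bounding box by half a cell.

## The synthetic-study generator

The generator emulates the structure of a classic three-population RNA-seq
comparison: groups Basal, LP and ML measured in triplicate, one model
(`Differential_Expression`) with the three pairwise tests `BasalvsLP`,
`BasalvsML`, `LPvsML`. Defaults, chosen once as a realistic small design on
a log2-like abundance scale: baseline per feature ~ N(8, 2); within-group
noise sd 1; 10 % of features truly differential, implemented as one
randomly chosen group's mean shifted by an effect ~ N(0, 4); 20 annotation
terms of 5–20 features with 3 planted enriched terms per test, 80 % of a
planted term drawn from that test's true differentials. Truth is recorded
from the realized group means, so a drawn effect of exactly zero would not
be counted as signal.

Results are honest statistics, not labels: per-feature two-sample t-tests
(equal variance) on the generated matrix give the statistic and nominal p,
Benjamini–Hochberg gives the adjusted p (the field-default FDR procedure),
and the group-mean difference is the effect size. Enrichment p-values are
one-sided hypergeometric tests of each term's overlap with the test's true
differential set, BH-adjusted within test. Under a pure-null configuration
(`frac_differential = 0`) the t-test p-values are exactly uniform, which
the Kolmogorov–Smirnov calibration check exploits.

The two-model variant adds a per-feature batch shift ~ N(0, 2) to half the
replicates and archives the same data twice: once ignoring batch and once
after centring within batch — the with/without-covariate pattern that
motivates multiple models of one dataset. A Gaussian/t-test generator was
chosen over a negative-binomial count pipeline deliberately: the container
stores arbitrary analyst results, so the simplest generator with exactly
known null behaviour is the right test instrument; count-based generation
is an extension point.

What the generator does **not** emulate: count overdispersion and
library-size normalization, correlated genes, empirical-Bayes variance
moderation, and realistic annotation overlap structure. Passing tests
therefore demonstrate the container/analytics contracts and the
statistical calibration of the generator itself, not performance on real
RNA-seq data. With triplicates, unit noise and N(0, 4) effects, BH power at
α = 0.05 is genuinely modest (mean sensitivity around 0.05–0.1 in the
acceptance report) — an expected property of small designs, not a defect.

## Problem sizes and determinism

Tests and the acceptance script use deliberately scaled fixtures: 20–60
features for the 50-study round-trip sweep, 5 000 features for the
set-algebra oracle sweep (200 random threshold configurations) and the
null-calibration KS check, 2 000 points at gridsize 25 for the exhaustive
hexbin oracle, 1 000 random set pairs for the similarity dominance check.
All randomness flows through a single `numpy.random.default_rng` seeded
from the test fixture or the script's `--seed`; a fixed seed reproduces
byte-identical containers (asserted via manifest checksums).

## Known limitations

- The accessor API is in-process; there is no HTTP layer.
- Plot hooks are stored and dispatched but never rendered; no graphics
  export of any kind.
- Set analysis does not span models; cross-model filtering would require
  mapping-table semantics in the set algebra.
- Within a single set definition clauses only AND; OR is expressed as the
  union of definitions.
- Study versioning on reinstall overwrites and records history; there is no
  migration or diffing of container schema minors.
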