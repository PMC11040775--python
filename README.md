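# omicrate

Archival container and analytics engine for omic study results.

High-throughput biology experiments end in tables: per-feature hypothesis
tests (differential expression, abundance, phosphorylation, ...) and
per-term enrichment tests over feature sets. `omicrate` archives those
tables under a universal **study → model → test** hierarchy — a study holds
one or more statistical models of the data (the same counts modelled with
and without a batch covariate, or one model per omic layer), and each model
holds one or more hypothesis tests — and computes, server-side, the
analytics an exploration dashboard needs:

- **Container & registry** — studies serialize to plain-directory containers
  with a JSON manifest and per-file SHA-256 checksums, install atomically
  into a local registry, export as a single zip, and load lazily (large
  tables parse on first access). The minimal payload is one per-test results
  table: a feature-id column plus at least one numeric column.
- **Accessors** — filtered/sorted/paginated slices of any stored table,
  serialized to TSV, CSV, records-JSON or Arrow/feather; linkout URL
  resolution with percent-encoding.
- **Set analysis** — per-test feature sets from AND-ed threshold clauses
  (e.g. `padj ≤ 0.05 ∧ |logFC| ≥ 1`), combined by intersection / union /
  complement, summarized as UpSet-style exclusive intersection regions.
- **Enrichment analytics** — barcode rankings of a term's features by |t|;
  an EnrichmentMap-style term network with Jaccard
  (J = |A∩B|/|A∪B|), overlap (O = |A∩B|/min(|A|,|B|)) and combined
  (C = k·O + (1−k)·J) edges; connected-component clusters with a
  deterministic tiled layout; hexagonal binning for large scatter plots.
- **Fixtures** — a seeded generator of complete synthetic studies (Gaussian
  abundances, genuine two-sample t-tests with Benjamini–Hochberg adjustment,
  hypergeometric enrichment p-values) with planted ground truth, so every
  layer is testable without external data.

## Worked example

```python
import omicrate as oc
from omicrate.sets import Clause, SetDefinition

study, truth = oc.generate_study(oc.FixtureSpec(seed=7, n_features=500))
reg = oc.Registry("registry")
oc.install_study(study, reg)
oc.list_studies(reg)
# [{"name": "synthetic-rnaseq", "version": "0.1.0",
#   "n_models": 1, "n_tests": 3, "description": "synthetic three-population
#   differential expression study"}]

table, total = oc.get_results(study, oc.TableQuery(
    model="Differential_Expression", test="BasalvsLP",
    filters=[oc.Filter("adj_p_value", "<=", 0.05)], sort=("adj_p_value", "asc")))
total                              # 7 significant features
table.head(3)
# feature_id      logFC           t      p_value  adj_p_value
#  gene00355  -8.921921 -139.769589 1.571637e-08     0.000008
#  gene00169   9.511524   13.297215 1.848880e-04     0.023806
#  gene00383 -10.047419  -13.303672 1.845359e-04     0.023806

m = study.model("Differential_Expression")
sig_lp = SetDefinition("BasalvsLP", [Clause("adj_p_value", "<=", 0.05)])
not_ml = SetDefinition("LPvsML", [Clause("adj_p_value", "<=", 0.05)], negate=True)
len(oc.combine_sets(m, [sig_lp, not_ml]))   # 5 features significant between
                                            # Basal and LP but not LP vs ML

per_test = {t: oc.evaluate_set(m, SetDefinition(t, [Clause("adj_p_value", "<=", 0.05)]))
            for t in m.test_names}
ups = oc.upset_summary(per_test, top_n=3)
ups.set_sizes   # {'BasalvsLP': 7, 'BasalvsML': 5, 'LPvsML': 6}
ups.regions     # [(('BasalvsLP',), 3), (('BasalvsML', 'LPvsML'), 3),
                #  (('BasalvsLP', 'BasalvsML'), 2)]  — exclusive regions,
                # summing with the rest to the 11-feature union

bc = oc.barcode_data(study, "Differential_Expression", "synthetic_pathways",
                     "term_0005", "BasalvsLP")
bc.entries.head(3)
# feature_id  statistic  rank
#  gene00383  13.303672     1
#  gene00222  10.518616     2
#  gene00152   7.429309     3
bc.box  # {'min': 0.001, 'q1': 0.448, 'median': 1.125, 'q3': 3.395, 'max': 13.304}
```

The significant features and their statistics are the output of real
two-sample t-tests on the seeded synthetic assay; the UpSet regions are
exclusive intersections (each feature counted in exactly one membership
pattern); the barcode ranks features of an enriched term by |t| within the
selected test.

A command line mirrors the library for shell use:

```sh
omicrate fixture --seed 7 --features 500 -o registry/
omicrate list -r registry/
omicrate query synthetic-rnaseq Differential_Expression BasalvsLP \
    -r registry/ --filter adj_p_value:<=:0.05 --format tsv
omicrate upset synthetic-rnaseq Differential_Expression -r registry/ --top 5
omicrate network synthetic-rnaseq Differential_Expression synthetic_pathways \
    -r registry/
```

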