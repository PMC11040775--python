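"""Seeded synthetic studies with planted ground truth.

Emulates the structure of the classic three-population mouse mammary RNA-seq
demo — one model, three pairwise tests among three groups (Basal, LP, ML)
measured in triplicate — and its two-model variant where the same assay is
modelled with and without a batch covariate.  No external data is required:
abundances are drawn from a Gaussian model on a log2-like scale, per-test
results come from genuine two-sample t-tests on the generated matrix with
Benjamini–Hochberg adjustment, and per-term enrichment p-values come from a
one-sided hypergeometric test of term overlap with the true differential
set.  The planted truth (which features/terms are genuinely differential or
enriched) is returned alongside the study so every downstream module can be
checked against a known answer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidTableError
from .model import (
    AnnotationDatabase,
    Assay,
    ColumnMeta,
    EnrichmentResults,
    Study,
)

__all__ = ["FixtureSpec", "PlantedTruth", "generate_study", "truth_recovery_report"]

DEFAULT_GROUPS = ("Basal", "LP", "ML")


@dataclass
class FixtureSpec:
    """Conditions of a generated study; one fixed seed ⇒ one identical study.

    Scale is log2-like abundance: baseline per feature ~ N(8, 2), within-group
    noise sd 1; a differential feature has one group's mean shifted by an
    effect drawn from N(effect_mean, effect_sd).
    """

    seed: int = 0
    n_features: int = 100
    groups: tuple = DEFAULT_GROUPS
    replicates: int = 3
    n_models: int = 1                      # 2 adds the batch-covariate variant
    frac_differential: float = 0.1
    effect_mean: float = 0.0
    effect_sd: float = 4.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    batch_sd: float = 2.0                  # per-feature batch shift (n_models == 2)
    n_terms: int = 20
    term_size_range: tuple = (5, 20)
    n_enriched_terms: int = 3              # planted per test
    enriched_purity: float = 0.8           # fraction of a planted term drawn from truth
    database_name: str = "synthetic_pathways"
    study_name: str = "synthetic-rnaseq"

    def validate(self) -> None:
        if self.n_features < 1 or self.replicates < 2 or len(self.groups) < 2:
            raise InvalidTableError("need >=1 feature, >=2 replicates, >=2 groups")
        if self.n_models not in (1, 2):
            raise InvalidTableError("n_models must be 1 or 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise InvalidTableError("frac_differential must be in [0, 1]")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_features):
            raise InvalidTableError("term_size_range must satisfy 1 <= lo <= hi <= n_features")


@dataclass
class PlantedTruth:
    """Which features/terms are genuinely differential/enriched, per test."""

    study_name: str
    differential: dict = field(default_factory=dict)      # test -> frozenset(feature ids)
    enriched: dict = field(default_factory=dict)          # (database, test) -> frozenset(term ids)

    def to_dict(self) -> dict:
        return {
            "study_name": self.study_name,
            "differential": {t: sorted(s) for t, s in self.differential.items()},
            "enriched": {f"{db}::{t}": sorted(s) for (db, t), s in self.enriched.items()},
        }


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _pairwise_results(matrix: pd.DataFrame, group_cols: dict[str, list[str]]
                      ) -> dict[str, pd.DataFrame]:
    """Two-sample t-tests for every group pair; columns follow field convention."""
    out = {}
    for g1, g2 in itertools.combinations(group_cols, 2):
        a = matrix[group_cols[g1]].to_numpy()
        b = matrix[group_cols[g2]].to_numpy()
        t, p = stats.ttest_ind(a, b, axis=1)
        out[f"{g1}vs{g2}"] = pd.DataFrame({
            "feature_id": matrix.index.astype(str),
            "logFC": a.mean(axis=1) - b.mean(axis=1),
            "t": t,
            "p_value": p,
            "adj_p_value": _bh(p),
        }).reset_index(drop=True)
    return out


_COLUMN_META = {
    "feature_id": ColumnMeta(role="feature_id", tooltip="opaque feature identifier"),
    "logFC": ColumnMeta(role="effect_size", tooltip="difference of group means (log2 scale)"),
    "t": ColumnMeta(role="statistic", tooltip="two-sample t-statistic"),
    "p_value": ColumnMeta(role="p_value", tooltip="nominal p-value"),
    "adj_p_value": ColumnMeta(role="adjusted_p_value", tooltip="Benjamini-Hochberg adjusted"),
}


def generate_study(spec: Optional[FixtureSpec] = None, **overrides
                   ) -> tuple[Study, PlantedTruth]:
    """Build a complete synthetic study plus its planted truth.

    The generated study always validates cleanly and carries every optional
    component (assay, feature metadata, annotation database, enrichment
    results, linkout, report, metadata) so round-trip and accessor machinery
    is exercised end to end.
    """
    spec = replace(spec or FixtureSpec(), **overrides) if overrides else (spec or FixtureSpec())
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = tuple(spec.groups)
    n, G, R = spec.n_features, len(groups), spec.replicates

    width = max(5, len(str(n)))
    features = [f"gene{i:0{width}d}" for i in range(n)]
    samples = [f"{g}_rep{r + 1}" for g in groups for r in range(R)]
    group_cols = {g: [f"{g}_rep{r + 1}" for r in range(R)] for g in groups}

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    group_means = np.tile(baseline[:, None], (1, G))
    is_diff = rng.random(n) < spec.frac_differential
    shifted_group = rng.integers(0, G, size=n)
    effects = rng.normal(spec.effect_mean, spec.effect_sd, size=n)
    group_means[is_diff, shifted_group[is_diff]] += effects[is_diff]

    noise = rng.normal(0.0, spec.noise_sd, size=(n, G * R))
    data = np.repeat(group_means, R, axis=1) + noise

    # optional batch structure: replicate r is batch r % 2, shift per feature
    batch = np.array([r % 2 for _ in groups for r in range(R)])
    if spec.n_models == 2:
        batch_shift = rng.normal(0.0, spec.batch_sd, size=n)
        data = data + np.outer(batch_shift, batch)

    matrix = pd.DataFrame(data, index=features, columns=samples)
    sample_meta = pd.DataFrame({
        "group": [g for g in groups for _ in range(R)],
        "replicate": [r + 1 for _ in groups for r in range(R)],
        "batch": [f"batch{b + 1}" for b in batch],
    }, index=samples)

    # planted truth per pairwise test: group means genuinely differ
    truth = PlantedTruth(study_name=spec.study_name)
    gi = {g: i for i, g in enumerate(groups)}
    for g1, g2 in itertools.combinations(groups, 2):
        diff = group_means[:, gi[g1]] != group_means[:, gi[g2]]
        truth.differential[f"{g1}vs{g2}"] = frozenset(np.array(features)[diff])

    # annotation database with planted enriched terms per test
    test_names = list(truth.differential)
    term_ids = [f"term_{i:04d}" for i in range(spec.n_terms)]
    lo, hi = spec.term_size_range
    planted_plan: list[Optional[str]] = [None] * spec.n_terms
    slot = 0
    for tname in test_names:
        for _ in range(spec.n_enriched_terms):
            if slot < spec.n_terms:
                planted_plan[slot] = tname
                slot += 1
    terms: dict[str, dict] = {}
    feature_arr = np.array(features)
    for term_id, planted_for in zip(term_ids, planted_plan):
        size = int(rng.integers(lo, hi + 1))
        if planted_for is not None and truth.differential[planted_for]:
            pool = sorted(truth.differential[planted_for])
            n_true = min(len(pool), max(1, round(spec.enriched_purity * size)))
            chosen = list(rng.choice(pool, size=n_true, replace=False))
            rest_pool = [f for f in features if f not in set(chosen)]
            n_rest = min(size - n_true, len(rest_pool))
            if n_rest > 0:
                chosen += list(rng.choice(rest_pool, size=n_rest, replace=False))
        else:
            chosen = list(rng.choice(feature_arr, size=size, replace=False))
        terms[term_id] = {"description": f"synthetic pathway {term_id}",
                          "features": sorted(chosen)}
    database = AnnotationDatabase(spec.database_name, terms)
    for tname in test_names:
        # a term is genuinely enriched only if its test has planted signal
        planted = {tid for tid, tgt in zip(term_ids, planted_plan)
                   if tgt == tname and truth.differential[tname]}
        truth.enriched[(spec.database_name, tname)] = frozenset(planted)

    # enrichment p-values: one-sided hypergeometric overlap with the truth set
    def enrichment_table(test: str) -> pd.DataFrame:
        K = len(truth.differential[test])
        rows = []
        for tid in term_ids:
            term_set = database.feature_set(tid)
            k = len(term_set & truth.differential[test])
            p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, n, K, len(term_set)))
            rows.append((tid, test, min(p, 1.0)))
        df = pd.DataFrame(rows, columns=["term_id", "test", "nominal"])
        df["adjusted"] = _bh(df["nominal"].to_numpy())
        return df

    # assemble one or two models of the same data
    study = Study(spec.study_name,
                  description="synthetic three-population differential expression study",
                  maintainer="omicrate fixtures",
                  metadata={"seed": spec.seed, "n_features": n, "groups": list(groups),
                            "replicates": R,
                            "analysis details": "two-sample t-tests per group pair; "
                                                "BH adjustment; hypergeometric enrichment"})

    def add_model(name: str, mat: pd.DataFrame, description: str) -> None:
        results = _pairwise_results(mat, group_cols)
        for tname, table in results.items():
            study.add_results(name, tname, table, column_meta=_COLUMN_META,
                              description=f"pairwise comparison {tname}")
        study.add_assays(name, Assay(matrix, sample_meta))
        study.add_features(name, pd.DataFrame({
            "feature_id": features,
            "symbol": [f"SYM{i}" for i in range(n)],
            "planted_effect": np.where(is_diff, effects, np.nan),
        }))
        study.model(name).description = description
        enr = pd.concat([enrichment_table(t) for t in test_names], ignore_index=True)
        study.add_enrichments(name, database, EnrichmentResults(spec.database_name, enr))

    add_model("Differential_Expression", matrix,
              "per-group-pair t-tests on the raw abundance matrix")
    if spec.n_models == 2:
        # second model of the same data: centre within batch before testing
        centred = matrix.copy()
        for b in np.unique(batch):
            cols = [s for s, bb in zip(samples, batch) if bb == b]
            centred[cols] = centred[cols].sub(centred[cols].mean(axis=1), axis=0)
        centred = centred.add(matrix.mean(axis=1), axis=0)
        add_model("Differential_Expression_Batch", centred,
                  "per-group-pair t-tests after removing the batch covariate")
        study.add_mapping(pd.DataFrame({
            "Differential_Expression": features,
            "Differential_Expression_Batch": features,
        }))

    study.add_linkout("feature_id", "https://example.org/feature/{id}", label="gene page")
    study.set_report("https://example.org/reports/" + spec.study_name)
    return study, truth


def truth_recovery_report(study: Study, truth: PlantedTruth, alpha: float = 0.05,
                          model: str = "Differential_Expression") -> dict:
    """Per-test sensitivity and observed false discovery proportion at ``alpha``.

    Calls are adjusted-p <= alpha; sensitivity = TP / planted, FDR = FP / calls.
    """
    if study.name != truth.study_name:
        raise InvalidTableError("study / truth mismatch")
    m = study.model(model)
    out = {}
    for tname, test in m.tests.items():
        df = test.results.df
        called = set(df.loc[df["adj_p_value"] <= alpha, "feature_id"])
        planted = set(truth.differential.get(tname, ()))
        tp = len(called & planted)
        out[tname] = {
            "n_called": len(called),
            "n_planted": len(planted),
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "observed_fdr": (len(called) - tp) / len(called) if called else 0.0,
        }
    return out
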