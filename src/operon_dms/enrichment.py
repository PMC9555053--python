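"""Enrichment scores, fitness, and phenotype classes from count tables.

The survival score of a mutant is its post/pre-selection normalized read
fraction; the enrichment score ES is that survival normalized to WT's, so
WT has ES = 1 by construction. ES converts to a per-generation fitness proxy
w = ES^(1/generations). Phenotype classes bin the replicate-averaged ES:
inactive (ES <= 0.1), marginally active (0.1 < ES < 0.7), active
(0.7 <= ES <= 1.5), hyperactive (ES > 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CountTable, WT_ROW_ID

DEFAULT_MIN_UNSELECTED_READS = 20
DEFAULT_GENERATIONS = 37

PHENOTYPES = ("inactive", "marginal", "active", "hyperactive")


@dataclass
class GrowthParams:
    """Plate-growth parameters used to convert ES to per-generation fitness."""

    total_time_h: float = 14.0
    lag_time_h: float = 1.4
    doubling_time_min: float = 20.2

    def __post_init__(self):
        if not self.total_time_h > self.lag_time_h >= 0:
            raise ValueError("need total_time > lag_time >= 0")
        if self.doubling_time_min <= 0:
            raise ValueError("doubling_time must be positive")


def survival_score(
    mut_pre: float, mut_post: float, total_pre: float, total_post: float
) -> float | None:
    """(mut_post/total_post) / (mut_pre/total_pre); None when mut_pre == 0."""
    if total_pre <= 0 or total_post <= 0:
        raise ValueError("condition totals must be positive")
    if mut_pre == 0:
        return None
    return (mut_post / total_post) / (mut_pre / total_pre)


def es_seq(
    mut_pre: float,
    mut_post: float,
    wt_pre: float,
    wt_post: float,
    min_unselected_reads: int = DEFAULT_MIN_UNSELECTED_READS,
) -> float | None:
    """Enrichment score: mutant survival over WT survival.

    Condition totals cancel in the ratio, so only mutant and WT counts enter.
    Returns None (missing) when the mutant's unselected count is below the
    read cutoff; returns 0.0 when the mutant vanishes after selection.
    """
    if wt_pre <= 0 or wt_post <= 0:
        raise ValueError("WT must have nonzero counts in both conditions")
    if mut_pre < min_unselected_reads:
        return None
    return (mut_post / wt_post) / (mut_pre / wt_pre)


def average_es(es_per_replicate: list[float | None]) -> float | None:
    """Arithmetic mean over non-missing replicate values; None if all missing."""
    vals = [v for v in es_per_replicate if v is not None and not np.isnan(v)]
    if not vals:
        return None
    return float(np.mean(vals))


def generations(params: GrowthParams) -> int:
    """Number of generations on plates: floor((total - lag) / doubling)."""
    eff_min = (params.total_time_h - params.lag_time_h) * 60.0
    if eff_min < 0:
        raise ValueError("effective growth time is negative")
    return int(math.floor(eff_min / params.doubling_time_min))


def fitness(es: float, n_generations: int = DEFAULT_GENERATIONS) -> float:
    """Per-generation fitness proxy w = ES^(1/generations); w(0) = 0."""
    if es < 0:
        raise ValueError("enrichment score must be nonnegative")
    if n_generations < 1:
        raise ValueError("need at least one generation")
    if es == 0:
        return 0.0
    return es ** (1.0 / n_generations)


def classify_phenotype(es_mean: float | None) -> str | None:
    """Phenotype bin of a replicate-averaged ES; None for missing scores."""
    if es_mean is None or (isinstance(es_mean, float) and np.isnan(es_mean)):
        return None
    if es_mean < 0:
        raise ValueError("enrichment score must be nonnegative")
    if es_mean <= 0.1:
        return "inactive"
    if es_mean < 0.7:
        return "marginal"
    if es_mean <= 1.5:
        return "active"
    return "hyperactive"


def score_table(
    table: CountTable,
    min_unselected_reads: int = DEFAULT_MIN_UNSELECTED_READS,
    n_generations: int = DEFAULT_GENERATIONS,
) -> pd.DataFrame:
    """Per-variant enrichment records for every variant in a count table.

    Columns: position, wt_codon, mut_codon, kind, es_rep<r> per replicate,
    es_mean, fitness_w, phenotype, n_replicates_used. ES columns are NaN when
    the replicate fails the unselected-read cutoff.
    """
    reps = table.replicates
    counts = table.counts
    out = table.variants.copy()
    es_cols = []
    for rep in reps:
        pre = counts[("unselected", rep)]
        post = counts[("selected", rep)]
        wt_pre = pre.loc[WT_ROW_ID]
        wt_post = post.loc[WT_ROW_ID]
        if wt_pre <= 0 or wt_post <= 0:
            raise ValueError(f"replicate {rep}: WT has zero reads; cannot normalize")
        es = (post / wt_post) / (pre / wt_pre)
        es[pre < min_unselected_reads] = np.nan
        col = f"es_rep{rep}"
        out[col] = es.reindex(out.index)
        es_cols.append(col)
    es_block = out[es_cols]
    out["es_mean"] = es_block.mean(axis=1)  # skips NaN; all-NaN -> NaN
    out["n_replicates_used"] = es_block.notna().sum(axis=1)
    out["fitness_w"] = [
        fitness(v, n_generations) if not np.isnan(v) else np.nan
        for v in out["es_mean"]
    ]
    out["phenotype"] = [classify_phenotype(v) for v in out["es_mean"]]
    return out


def position_class_fractions(records: pd.DataFrame, min_mutants: int = 10) -> pd.DataFrame:
    """Per-position fractions of scored mutants in each phenotype class.

    Positions with n_mutants <= ``min_mutants`` are flagged ``excluded`` (the
    "more than 10 mutants" plotting rule). Fractions are over scored (non-
    missing) mutants only and sum to 1 where any exist.
    """
    scored = records[records["phenotype"].notna()]
    rows = []
    for pos, grp in scored.groupby("position"):
        n = len(grp)
        fracs = {p: float((grp["phenotype"] == p).mean()) for p in PHENOTYPES}
        rows.append({"position": int(pos), "n_mutants": n, **fracs, "excluded": n <= min_mutants})
    return pd.DataFrame(rows).set_index("position")


def avg_pairwise_codon_delta(records_at_position: pd.DataFrame) -> float | None:
    """Mean |ES_a - ES_b| over codon pairs encoding the same mutant amino acid.

    Pairs are pooled over mutant amino acids at the position and the sum of
    absolute differences is divided by the total pair count. Only scored
    nonsynonymous variants enter. None when no eligible pair exists.
    """
    from .core import translate_codon

    grp = records_at_position
    grp = grp[(grp["kind"] == "nonsynonymous") & grp["es_mean"].notna()]
    total = 0.0
    n_pairs = 0
    for _aa, sub in grp.groupby([translate_codon(c) for c in grp["mut_codon"]]):
        vals = sub["es_mean"].to_numpy()
        for a, b in combinations(vals, 2):
            total += abs(a - b)
            n_pairs += 1
    if n_pairs == 0:
        return None
    return total / n_pairs


def position_summary(records: pd.DataFrame, min_mutants: int = 10) -> pd.DataFrame:
    """Class fractions plus the average pairwise codon ES difference per position."""
    fractions = position_class_fractions(records, min_mutants)
    deltas = {
        int(pos): avg_pairwise_codon_delta(grp)
        for pos, grp in records.groupby("position")
    }
    fractions["avg_pairwise_codon_delta"] = [
        deltas.get(pos, None) for pos in fractions.index
    ]
    return fractions
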