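"""Feature-phenotype association tests and box-plot summaries.

Variants are split into inactive (ES <= 0.1) and active (ES > 0.1) classes
and each sequence feature is compared across classes with a two-sided
Mann-Whitney rank-sum test: exact when both samples are small and tie-free,
otherwise the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

ACTIVITY_THRESHOLD = 0.1
EXACT_MAX_N = 12

DEFAULT_FEATURES = ("rcu", "rel_trna", "rel_gc", "n_base_changes", "rel_stall", "rel_cai")


@dataclass
class MWResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_tie_corrected"
    n_x: int
    n_y: int


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y, method: str = "auto") -> MWResult:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` uses exact enumeration when n_x + n_y <= 12 and there
    are no ties, else the normal approximation with tie and continuity
    corrections. ``'exact'`` and ``'asymptotic'`` force a method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        use_exact = x.size + y.size <= EXACT_MAX_N and not _has_ties(x, y)
    elif method == "exact":
        use_exact = True
    elif method == "asymptotic":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return MWResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "normal_tie_corrected",
        n_x=int(x.size),
        n_y=int(y.size),
    )


def split_by_activity(
    scores: pd.Series, threshold: float = ACTIVITY_THRESHOLD
) -> tuple[pd.Index, pd.Index]:
    """(active ids, inactive ids) from a variant_id -> es_mean series.

    Inactive: es <= threshold; active: es > threshold; missing scores are
    excluded from both groups.
    """
    s = scores.dropna()
    inactive = s.index[s <= threshold]
    active = s.index[s > threshold]
    return active, inactive


@dataclass
class BoxStats:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def box_stats(values) -> BoxStats:
    """Box-plot summary: quartiles by linear interpolation, 1.5*IQR whiskers."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo = max(v.min(), q1 - 1.5 * iqr)
    hi = min(v.max(), q3 + 1.5 * iqr)
    outliers = v[(v < lo) | (v > hi)]
    return BoxStats(float(med), float(q1), float(q3), float(iqr), float(lo), float(hi), outliers)


def feature_association_report(
    records: pd.DataFrame,
    features: pd.DataFrame,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    threshold: float = ACTIVITY_THRESHOLD,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney comparison of active vs inactive variants.

    ``records`` needs an ``es_mean`` column indexed by variant_id; ``features``
    holds the feature columns with the same index. Variants missing a feature
    are excluded for that feature only. A Bonferroni-adjusted p column is
    emitted for transparency; the ``significant`` flag uses the raw p-value,
    matching the per-feature reporting convention.
    """
    active_ids, inactive_ids = split_by_activity(records["es_mean"], threshold)
    rows = []
    for feat in feature_names:
        if feat not in features.columns:
            rows.append({"feature": feat, "missing": True})
            continue
        col = features[feat]
        a = col.reindex(active_ids).dropna().to_numpy(dtype=float)
        i = col.reindex(inactive_ids).dropna().to_numpy(dtype=float)
        if a.size == 0 or i.size == 0:
            rows.append({"feature": feat, "missing": True})
            continue
        res = mann_whitney_u(a, i)
        rows.append(
            {
                "feature": feat,
                "missing": False,
                "n_active": res.n_x,
                "n_inactive": res.n_y,
                "median_active": float(np.median(a)),
                "median_inactive": float(np.median(i)),
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
                "significant": res.p_value < alpha,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    if "p_value" in out.columns:
        m = out["p_value"].notna().sum()
        out["p_bonferroni"] = np.minimum(out["p_value"] * m, 1.0)
    return out


def box_stats_table(
    records: pd.DataFrame,
    features: pd.DataFrame,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    threshold: float = ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Box-plot statistics per feature and activity class."""
    active_ids, inactive_ids = split_by_activity(records["es_mean"], threshold)
    rows = []
    for feat in feature_names:
        if feat not in features.columns:
            continue
        for label, ids in (("active", active_ids), ("inactive", inactive_ids)):
            vals = features[feat].reindex(ids).dropna()
            if vals.empty:
                continue
            b = box_stats(vals)
            rows.append(
                {
                    "feature": feat,
                    "class": label,
                    "n": len(vals),
                    "median": b.median,
                    "q1": b.q1,
                    "q3": b.q3,
                    "iqr": b.iqr,
                    "whisker_low": b.whisker_low,
                    "whisker_high": b.whisker_high,
                    "n_outliers": len(b.outliers),
                }
            )
    return pd.DataFrame(rows)
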