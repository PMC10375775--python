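"""Statistical screening of candidate quality indices.

Three layers, applied per index: (1) factor-wise significance -- one-way
ANOVA across production areas and growth years, a two-sample t test between
harvest seasons, each at alpha = 0.05 by default; (2) redundancy pruning of
retained indices whose pairwise Pearson |r| exceeds a threshold, keeping a
designated primary (diameter over weight, the traditionally preferred trait);
(3) for chemical composition indices, a PLS-DA variable-importance (VIP)
filter at the conventional VIP >= 1.0 cut.  No multiple-testing correction is
applied by default, matching per-factor P < 0.05 practice; a
Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreeningRules",
    "one_way_anova",
    "two_sample_t",
    "pearson_correlation",
    "plsda_vip",
    "screen_indices",
]


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Accepts two or more groups of observations.  Unlike a bare F ratio, an
    all-identical input (zero between- and within-group variance everywhere)
    is reported as F = 0, p = 1 rather than 0/0.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    n_total = sum(g.size for g in arrs)
    k = len(arrs)
    if n_total - k <= 0:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(arrs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssb == 0.0:
        return 0.0, 1.0
    if ssw == 0.0:
        return float("inf"), 0.0
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    f = msb / msw
    p = float(stats.f.sf(f, k - 1, n_total - k))
    return float(f), p


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t test (pooled variance by default; Welch via
    ``equal_var=False``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate samples: zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def plsda_vip(X, y, n_components: int = 2) -> np.ndarray:
    """Variable importance in projection from a PLS-DA fit.

    X is autoscaled, y dummy-coded {0,1} and centred by the PLS fit; the
    NIPALS solution comes from scikit-learn.  For predictor j,

        VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a )

    with SSY_a the y-variance explained by component a; sum_j VIP_j^2 = p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"PLS-DA expects exactly 2 classes, got {classes.size}")
    sd = X.std(axis=0, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        raise ValueError(f"constant predictor column(s): {const.tolist()}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    n_components = min(n_components, rank)
    y01 = (y == classes[1]).astype(float)

    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y01)
    t = pls.x_scores_          # n x a
    w = pls.x_weights_         # p x a
    q = pls.y_loadings_        # 1 x a
    p_feat = X.shape[1]
    ssy = np.sum(t**2, axis=0) * q.ravel() ** 2  # y-variance per component
    if ssy.sum() == 0:
        raise ValueError("PLS explained no y-variance; VIP undefined")
    w2 = (w / np.linalg.norm(w, axis=0)) ** 2
    vip = np.sqrt(p_feat * (w2 @ ssy) / ssy.sum())
    return vip


@dataclass
class ScreeningRules:
    """Retention rules for candidate indices.

    An index is retained iff it is significant (p < ``alpha``) for every
    factor in ``required_factors``; among retained indices correlated above
    ``r_redundant`` the listed primary wins (e.g. diameter over weight);
    indices named in ``chemical_indices`` must additionally reach
    ``vip_threshold`` in a PLS-DA against ``vip_label``.
    """

    alpha: float = 0.05
    required_factors: tuple[str, ...] = ("area", "years", "season")
    r_redundant: float = 0.8
    redundancy_primary: dict[str, str] = field(
        default_factory=lambda: {"weight": "diameter"}
    )
    chemical_indices: tuple[str, ...] = ()
    vip_threshold: float = 1.0
    vip_label: str = "area"
    vip_components: int = 2
    bh_correct: bool = False
    equal_var: bool = True

    _KNOWN = {
        "alpha", "required_factors", "r_redundant", "redundancy_primary",
        "chemical_indices", "vip_threshold", "vip_label", "vip_components",
        "bh_correct", "equal_var",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningRules":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown screening rule key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("required_factors", "chemical_indices"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


_FACTOR_COLUMNS = {"area": "region", "years": "growth_years", "season": "season"}


def _factor_pvalue(values: np.ndarray, labels: pd.Series, rules: ScreeningRules) -> float:
    groups = [values[(labels == lv).to_numpy()] for lv in labels.unique()]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        return float("nan")
    if len(groups) == 2:
        try:
            _, p = two_sample_t(groups[0], groups[1], equal_var=rules.equal_var)
        except ValueError:
            return 1.0
        return p
    _, p = one_way_anova(*groups)
    return p


def screen_indices(
    features: pd.DataFrame,
    factors: pd.DataFrame,
    rules: ScreeningRules | dict | None = None,
    index_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Screen candidate indices against the provenance factors.

    Parameters
    ----------
    features
        One row per batch with a ``batch_id`` column and one numeric column
        per candidate index.
    factors
        One row per batch with ``batch_id`` and the factor columns
        ``region``, ``growth_years``, ``season``.
    rules
        :class:`ScreeningRules` or a plain dict of rule overrides.
    index_columns
        Candidate columns to screen; defaults to every numeric non-factor
        column of ``features``.

    Returns a report with per-index factor p-values, redundancy partner and
    Pearson r, VIP (for chemical indices), the retained flag and a reason
    string.
    """
    if rules is None:
        rules = ScreeningRules()
    elif isinstance(rules, dict):
        rules = ScreeningRules.from_dict(rules)
    for f in rules.required_factors:
        if f not in _FACTOR_COLUMNS:
            raise ValueError(f"unknown factor '{f}'; expected {sorted(_FACTOR_COLUMNS)}")

    merged = features.merge(factors, on="batch_id", how="inner", suffixes=("", "_factor"))
    if index_columns is None:
        drop = {"batch_id", "true_grade"} | set(_FACTOR_COLUMNS.values())
        index_columns = [
            c for c in features.columns
            if c not in drop and pd.api.types.is_numeric_dtype(features[c])
        ]

    report = pd.DataFrame(index=index_columns)
    for factor in ("area", "years", "season"):
        col = _FACTOR_COLUMNS[factor]
        labels = merged[col]
        report[f"p_{factor}"] = [
            _factor_pvalue(merged[idx].to_numpy(dtype=float), labels, rules)
            for idx in index_columns
        ]
    pcols = [f"p_{f}" for f in rules.required_factors]
    if rules.bh_correct:
        for col in pcols:
            report[col] = multipletests(report[col].to_numpy(), method="fdr_bh")[1]

    selected = pd.Series(True, index=report.index)
    reason = pd.Series("significant for all required factors", index=report.index, dtype=object)
    for idx in report.index:
        failed = [f for f in rules.required_factors if not report.loc[idx, f"p_{f}"] < rules.alpha]
        if failed:
            selected[idx] = False
            reason[idx] = "; ".join(f"p_{f} >= alpha" for f in failed)

    # redundancy pruning among retained indices
    report["pearson_partner"] = ""
    report["pearson_r"] = np.nan
    for secondary, primary in rules.redundancy_primary.items():
        if secondary not in report.index or primary not in report.index:
            continue
        try:
            r, _ = pearson_correlation(merged[secondary], merged[primary])
        except ValueError:
            continue
        report.loc[secondary, ["pearson_partner", "pearson_r"]] = primary, r
        report.loc[primary, ["pearson_partner", "pearson_r"]] = secondary, r
        if selected[secondary] and selected[primary] and abs(r) > rules.r_redundant:
            selected[secondary] = False
            reason[secondary] = f"redundant with {primary} (|r|={abs(r):.2f} > {rules.r_redundant})"

    # VIP filter on chemical indices
    report["vip"] = np.nan
    chem = [c for c in rules.chemical_indices if c in report.index]
    if chem:
        label_col = _FACTOR_COLUMNS[rules.vip_label]
        y = merged[label_col]
        if rules.vip_label == "area":
            y = merged["region"].astype(str).str.startswith("nongenuine")
        vips = plsda_vip(merged[chem].to_numpy(dtype=float), y.to_numpy(), rules.vip_components)
        for c, v in zip(chem, vips):
            report.loc[c, "vip"] = v
            if selected[c] and v < rules.vip_threshold:
                selected[c] = False
                reason[c] = f"VIP {v:.2f} < {rules.vip_threshold}"

    report["selected"] = selected
    report["reason"] = reason
    report.index.name = "index"
    return report.reset_index()
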