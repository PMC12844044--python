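"""Univariate statistics, effect sizes, FDR control and feature selection.

Discriminant metabolites are the conjunction of multivariate and univariate
evidence: VIP > 1.0 from the OPLS-DA model AND Benjamini-Hochberg q < 0.05
from a two-sided per-feature test between arms. The default test is the
Mann-Whitney U (exact for small tie-free samples, otherwise the normal
approximation with tie correction); Welch's t is available by flag. Fold
changes are differences of group means on the log2 scale (the data reach
this module already log-transformed) and Cohen's d uses the pooled
(n-1)-weighted SD, both computed on the log matrix rather than the Pareto
one, which would distort effect sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import MetabolomicsDataset
from .multivariate import opls_fit
from .preprocess import pareto_scale

LOG2 = np.log(2.0)


class StatsError(ValueError):
    pass


def univariate_test(group_a, group_b, method: str = "mann_whitney") -> float:
    """Two-sided p-value for a difference between two independent groups.

    ``mann_whitney`` (default) delegates to scipy with automatic
    exact/asymptotic switching (tie-corrected normal approximation for
    larger samples); ``welch`` is the unequal-variance t test. Two identical
    constant groups return p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("identical constant groups; p set to 1", stacklevel=2)
        return 1.0
    if method == "mann_whitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="auto").pvalue)
    if method == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise StatsError(f"unknown test method {method!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j, capped
    at 1, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise StatsError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cohen_d(group_a, group_b) -> float:
    """Standardized mean difference (meanA - meanB) / pooled SD with
    (n-1)-weighted pooling; NaN with a warning when the pooled SD is 0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        warnings.warn("pooled SD is zero; Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def volcano_table(
    ds_log: MetabolomicsDataset,
    phase: str,
    vip: pd.Series | None = None,
    test: str = "mann_whitney",
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    opls_seed: int = 0,
    cv_folds: int = 7,
) -> pd.DataFrame:
    """Per-feature discriminant table for the polyphenol-vs-placebo contrast
    within one phase.

    ``ds_log`` must be the log-scale (pre-Pareto) dataset. When ``vip`` is
    not supplied, the phase subset is Pareto-scaled and a one-predictive-
    component OPLS-DA fit to obtain it. Columns: vip, p_value, q_value,
    log2_fc (polyphenol minus placebo), cohen_d, selected; sorted by q then
    descending |log2_fc|. ``selected`` is exactly
    ``(vip > vip_threshold) & (q_value < alpha)``.
    """
    if phase not in set(ds_log.samples["phase"]):
        raise StatsError(f"phase {phase!r} absent from dataset")
    sub = ds_log.subset(phase=phase)
    arm = sub.samples["arm"]
    poly = sub.abundance[arm == "polyphenol"]
    plac = sub.abundance[arm == "placebo"]

    if vip is None:
        scaled = pareto_scale(sub)
        model = opls_fit(scaled.abundance, arm.to_numpy(), n_ortho="auto",
                         cv_folds=cv_folds, seed=opls_seed)
        vip = model.vip
    vip = vip.reindex(sub.abundance.columns)

    # log-scale means differ by a factor ln2 from log2 means
    scale_to_log2 = 1.0 / LOG2
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for feat in sub.abundance.columns:
            a = poly[feat].to_numpy()
            b = plac[feat].to_numpy()
            records.append({
                "feature_id": feat,
                "vip": float(vip[feat]),
                "p_value": univariate_test(a, b, method=test),
                "log2_fc": (a.mean() - b.mean()) * scale_to_log2,
                "cohen_d": cohen_d(a, b),
            })
    table = pd.DataFrame(records).set_index("feature_id")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["selected"] = (table["vip"] > vip_threshold) & (table["q_value"] < alpha)
    table = table.sort_values(
        ["q_value", "log2_fc"],
        key=lambda s: s if s.name == "q_value" else -s.abs(),
    )
    return table[["vip", "p_value", "q_value", "log2_fc", "cohen_d", "selected"]]
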