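"""Preprocessing: missingness filter, RF imputation, log transform, Pareto scaling.

Fixed pipeline order: ``filter_missing -> impute_rf -> log_transform ->
pareto_scale``; each step records itself in dataset provenance and the
scaling step refuses to run twice. The imputer is a missForest-style
iterative scheme built on random-forest regression; observed cells are
never altered. Cohen's d and the targeted ratio indices consume the
intermediate matrices (raw imputed and log-scale respectively), so
:func:`preprocess` returns all four stages.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io import DatasetError, MetabolomicsDataset


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class PreprocessConfig:
    """Knobs for the four preprocessing stages.

    ``max_missing_fraction`` — features missing in strictly more than this
    fraction of samples are dropped (default 0.30).
    ``rf_trees``/``rf_max_iter``/``rf_tol`` — forest size, iteration cap and
    relative-change stopping tolerance of the iterative imputer.
    ``log_base`` — ``None`` for natural log.
    Zeros are log-transformed after adding half the minimum positive
    observed value of that feature (applied to exact zeros only).
    """

    max_missing_fraction: float = 0.30
    rf_trees: int = 100
    rf_max_iter: int = 10
    rf_tol: float = 1e-3
    log_base: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction < 1.0:
            raise PreprocessError("max_missing_fraction must lie in [0, 1)")
        if self.rf_trees < 1:
            raise PreprocessError("rf_trees must be >= 1")


def filter_missing(ds: MetabolomicsDataset,
                   max_missing_fraction: float = 0.30) -> MetabolomicsDataset:
    """Drop features missing in strictly more than the threshold fraction
    of samples (pooled across all samples)."""
    frac = ds.missing_fraction()
    keep = frac.index[frac <= max_missing_fraction]
    n_removed = ds.n_features - len(keep)
    if len(keep) == 0:
        raise PreprocessError("missingness filter removed every feature")
    return ds.with_abundance(
        ds.abundance[keep].copy(),
        f"filter_missing(threshold={max_missing_fraction}, removed={n_removed})",
    )


def impute_rf(ds: MetabolomicsDataset,
              config: PreprocessConfig | None = None) -> MetabolomicsDataset:
    """missForest-style iterative random-forest imputation.

    Missing cells start at per-feature medians; features are then visited in
    ascending-missingness order, each regressed on all others over its
    observed rows and its missing rows predicted; sweeps repeat until the
    relative change of the imputed cells drops below ``rf_tol`` or
    ``rf_max_iter`` sweeps have run. Deterministic under a fixed seed;
    observed cells are returned bit-identical.
    """
    config = config or PreprocessConfig()
    X = ds.abundance.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    n_obs = (~mask).sum(axis=0)
    low = np.flatnonzero(n_obs < 2)
    if low.size:
        bad = ds.abundance.columns[low].tolist()
        raise PreprocessError(
            f"features with < 2 observed values (filter first): {bad}")
    if not mask.any():
        return ds.with_abundance(ds.abundance.copy(), "impute_rf(no_missing)")

    medians = np.nanmedian(X, axis=0)
    for j in range(X.shape[1]):
        X[mask[:, j], j] = medians[j]

    order = np.argsort(mask.sum(axis=0), kind="stable")
    order = [j for j in order if mask[:, j].any()]
    # fixed per-feature forest seeds: successive sweeps then differ only
    # through the updated imputations, so the iteration actually converges
    seeds = {j: (config.seed * 7_993 + 31 * j + 1) % (2**31 - 1) for j in order}
    n_iter = 0
    prev_change = math.inf
    while n_iter < config.rf_max_iter:
        previous = X[mask].copy()
        for j in order:
            obs = ~mask[:, j]
            others = np.delete(X, j, axis=1)
            forest = RandomForestRegressor(
                n_estimators=config.rf_trees,
                random_state=seeds[j],
                n_jobs=1,
            )
            forest.fit(others[obs], X[obs, j])
            X[mask[:, j], j] = forest.predict(others[mask[:, j]])
        n_iter += 1
        denom = math.sqrt(float(np.sum(X[mask] ** 2)))
        change = math.sqrt(float(np.sum((X[mask] - previous) ** 2)))
        if denom == 0 or change / denom < config.rf_tol or change >= prev_change:
            break
        prev_change = change

    imputed = pd.DataFrame(X, index=ds.abundance.index, columns=ds.abundance.columns)
    # guarantee observed cells untouched
    imputed = imputed.where(pd.DataFrame(mask, index=imputed.index,
                                         columns=imputed.columns), ds.abundance)
    return ds.with_abundance(
        imputed, f"impute_rf(trees={config.rf_trees}, iters={n_iter}, seed={config.seed})")


def log_transform(ds: MetabolomicsDataset,
                  config: PreprocessConfig | None = None) -> MetabolomicsDataset:
    """Log the complete raw-scale matrix; exact zeros get half the feature's
    minimum positive value as a pseudo-count before logging."""
    config = config or PreprocessConfig()
    if ds.is_logged:
        raise PreprocessError("dataset is already log-transformed (provenance)")
    X = ds.abundance.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PreprocessError("log_transform requires a complete matrix; impute first")
    if (X < 0).any():
        raise PreprocessError("negative abundances cannot be log-transformed")
    out = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        zeros = col == 0
        if zeros.any():
            positive = col[col > 0]
            if positive.size == 0:
                raise PreprocessError(
                    f"feature {ds.abundance.columns[j]!r} is entirely zero")
            out[zeros, j] = positive.min() / 2.0
    out = np.log(out)
    base = config.log_base
    if base is not None:
        out = out / math.log(base)
    logged = pd.DataFrame(out, index=ds.abundance.index, columns=ds.abundance.columns)
    return ds.with_abundance(logged, f"log_transform(base={'e' if base is None else base})")


def pareto_scale(ds: MetabolomicsDataset) -> MetabolomicsDataset:
    """Center each feature and divide by the square root of its sample SD
    (ddof = 1). Constant features are centered, left at zero, and warned
    about. Refuses to scale twice (provenance check)."""
    if ds.is_pareto_scaled:
        raise PreprocessError("dataset is already Pareto-scaled (provenance)")
    X = ds.abundance.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = X - mean
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant features left at zero after centering: "
            f"{ds.abundance.columns[constant].tolist()}",
            stacklevel=2,
        )
    nz = ~constant
    out[:, nz] = out[:, nz] / np.sqrt(sd[nz])
    scaled = pd.DataFrame(out, index=ds.abundance.index, columns=ds.abundance.columns)
    return ds.with_abundance(scaled, "pareto_scale()")


@dataclasses.dataclass
class PreprocessResult:
    """All four pipeline stages, oldest to newest.

    ``filtered`` (raw, post-filter), ``imputed`` (raw, complete), ``logged``
    (log scale — effect sizes and fold changes are computed here), and
    ``scaled`` (Pareto — multivariate models consume this).
    """

    filtered: MetabolomicsDataset
    imputed: MetabolomicsDataset
    logged: MetabolomicsDataset
    scaled: MetabolomicsDataset


def preprocess(ds: MetabolomicsDataset,
               config: PreprocessConfig | None = None) -> PreprocessResult:
    """Run the fixed pipeline filter -> impute -> log -> pareto."""
    config = config or PreprocessConfig()
    filtered = filter_missing(ds, config.max_missing_fraction)
    imputed = impute_rf(filtered, config)
    logged = log_transform(imputed, config)
    scaled = pareto_scale(logged)
    return PreprocessResult(filtered, imputed, logged, scaled)
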