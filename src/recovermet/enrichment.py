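"""Metabolite-set over-representation analysis (ORA).

Given a selection of discriminant features and a pathway annotation
(pathway name -> feature set; the annotation universe is the union of all
annotated features), each pathway gets an upper-tail hypergeometric
p-value::

    p = P(hits >= k | N, K, n) = sum_{x >= k} C(K, x) C(N-K, n-x) / C(N, n)

with N the universe size, K the pathway size, n the (annotated) selection
size and k the number of selected features in the pathway, followed by
Benjamini-Hochberg adjustment across pathways. "Impact" is reported as
k / K — the fraction of the pathway hit — a deliberately simple surrogate
for topology-weighted pathway impact scores (no pathway graph is used).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .discriminant import bh_adjust


class EnrichmentError(ValueError):
    pass


@dataclasses.dataclass
class PathwayAnnotation:
    """Pathway -> feature-ID sets; features may belong to several pathways."""

    sets: dict[str, frozenset]

    def __post_init__(self) -> None:
        if not self.sets:
            raise EnrichmentError("empty pathway annotation")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise EnrichmentError(f"empty pathway sets: {empty}")

    @property
    def universe(self) -> frozenset:
        out: frozenset = frozenset()
        for members in self.sets.values():
            out |= members
        return out

    @staticmethod
    def from_feature_table(features: pd.DataFrame,
                           pathway_column: str = "pathway") -> "PathwayAnnotation":
        """Annotation from a feature-metadata table (one pathway per feature)."""
        grouped = features.groupby(pathway_column).groups
        return PathwayAnnotation({str(k): frozenset(v) for k, v in grouped.items()})

    @staticmethod
    def from_csv(path) -> "PathwayAnnotation":
        """Two-column CSV: feature_id, pathway."""
        table = pd.read_csv(path)
        sets: dict[str, set] = {}
        for _, row in table.iterrows():
            sets.setdefault(str(row.iloc[1]), set()).add(str(row.iloc[0]))
        return PathwayAnnotation({k: frozenset(v) for k, v in sets.items()})


def ora(selected: Iterable, annotation: PathwayAnnotation | Mapping) -> pd.DataFrame:
    """Over-representation table, one row per pathway, sorted by p.

    Selected features outside the annotation universe are dropped with a
    warning (they cannot inform any pathway). Columns: k (hits), K
    (pathway size), n (annotated selection size), N (universe size),
    p_value, q_value (BH across pathways), impact (k/K).
    """
    if not isinstance(annotation, PathwayAnnotation):
        annotation = PathwayAnnotation(dict(annotation))
    universe = annotation.universe
    selected = set(selected)
    outside = selected - universe
    if outside:
        warnings.warn(
            f"{len(outside)} selected features outside annotation universe "
            f"dropped: {sorted(outside)[:5]}...", stacklevel=2)
    inside = selected & universe
    N = len(universe)
    n = len(inside)
    rows = []
    for pathway, members in sorted(annotation.sets.items()):
        K = len(members)
        k = len(inside & members)
        # upper tail: P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": pathway, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0), "impact": k / K})
    table = pd.DataFrame(rows).set_index("pathway")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values("p_value")[
        ["k", "K", "n", "N", "p_value", "q_value", "impact"]]
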