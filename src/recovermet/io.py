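"""Core dataset container and plain-text I/O.

The whole pipeline passes a single object around: a :class:`MetabolomicsDataset`
holding a sample x feature abundance matrix together with sample metadata
(subject, study arm, sampling phase, dataset ID) and feature metadata
(display name, pathway label). Missing cells are explicit ``NaN`` — never
zero, since zero is a legal observed intensity.

On disk a dataset is three delimited text files: the abundance matrix
(sample IDs in the first column, feature IDs in the header) plus one
metadata table per axis. Correlation networks are exported as GraphML.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

PHASES = ("Pre", "Post", "Rec")
ARMS = ("placebo", "polyphenol")
PATHWAYS = (
    "purine",
    "redox",
    "lipid_peroxidation",
    "polyphenol_derived",
    "amino_acid",
    "glycolysis",
    "xenobiotic",
    "other",
)

SAMPLE_COLUMNS = ("subject_id", "dataset_id", "arm", "phase")
FEATURE_COLUMNS = ("display_name", "pathway")


class DatasetError(ValueError):
    """Structural problem with a dataset or its on-disk representation."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise DatasetError(f"duplicate {what}: {dupes}")


@dataclasses.dataclass
class MetabolomicsDataset:
    """Abundance matrix plus aligned sample and feature metadata.

    Parameters
    ----------
    abundance
        Samples in rows, features in columns; ``NaN`` marks a missing cell.
        Values are raw non-negative intensities until a log transform is
        recorded in ``provenance``.
    samples
        Indexed by sample ID with columns ``subject_id``, ``dataset_id``,
        ``arm`` (placebo/polyphenol) and ``phase`` (Pre/Post/Rec).
    features
        Indexed by feature ID with columns ``display_name`` and ``pathway``.
    provenance
        Ordered log of transforms applied, e.g. ``log_transform(base=e)``.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    provenance: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        _check_unique(self.samples.index, "sample IDs")
        _check_unique(self.features.index, "feature IDs")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise DatasetError(f"sample metadata lacks columns {missing_cols}")
        missing_cols = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing_cols:
            raise DatasetError(f"feature metadata lacks columns {missing_cols}")

        extra_rows = self.abundance.index.difference(self.samples.index)
        if len(extra_rows):
            raise DatasetError(
                f"samples in matrix but not in metadata: {extra_rows.tolist()}"
            )
        extra_meta = self.samples.index.difference(self.abundance.index)
        if len(extra_meta):
            raise DatasetError(
                f"samples in metadata but not in matrix: {extra_meta.tolist()}"
            )
        extra_cols = self.abundance.columns.difference(self.features.index)
        if len(extra_cols):
            raise DatasetError(
                f"features in matrix but not in metadata: {extra_cols.tolist()}"
            )
        extra_fmeta = self.features.index.difference(self.abundance.columns)
        if len(extra_fmeta):
            raise DatasetError(
                f"features in metadata but not in matrix: {extra_fmeta.tolist()}"
            )

        bad_phase = set(self.samples["phase"]) - set(PHASES)
        if bad_phase:
            raise DatasetError(f"unknown phase labels: {sorted(bad_phase)}")
        bad_arm = set(self.samples["arm"]) - set(ARMS)
        if bad_arm:
            raise DatasetError(f"unknown arm labels: {sorted(bad_arm)}")

        values = self.abundance.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if not np.isfinite(observed).all():
            raise DatasetError("abundance contains non-finite observed values")
        if not self.is_logged and observed.size and observed.min() < 0:
            raise DatasetError("raw-scale abundance contains negative values")

        # keep axes aligned in a canonical order
        self.samples = self.samples.loc[self.abundance.index]
        self.features = self.features.loc[self.abundance.columns]

    # -- provenance helpers -------------------------------------------------

    @property
    def is_logged(self) -> bool:
        return any(step.startswith("log_transform") for step in self.provenance)

    @property
    def is_pareto_scaled(self) -> bool:
        return any(step.startswith("pareto_scale") for step in self.provenance)

    def with_abundance(self, abundance: pd.DataFrame, note: str) -> "MetabolomicsDataset":
        """New dataset with replaced values and one more provenance entry."""
        return MetabolomicsDataset(
            abundance=abundance,
            samples=self.samples.loc[abundance.index].copy(),
            features=self.features.loc[abundance.columns].copy(),
            provenance=[*self.provenance, note],
        )

    # -- convenience --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing cells across all samples."""
        return self.abundance.isna().mean(axis=0)

    def subset(self, phase: str | None = None, arm: str | None = None) -> "MetabolomicsDataset":
        """Restrict to one phase and/or arm (metadata-validated labels)."""
        mask = pd.Series(True, index=self.samples.index)
        if phase is not None:
            if phase not in PHASES:
                raise DatasetError(f"unknown phase {phase!r}")
            mask &= self.samples["phase"] == phase
        if arm is not None:
            if arm not in ARMS:
                raise DatasetError(f"unknown arm {arm!r}")
            mask &= self.samples["arm"] == arm
        keep = mask[mask].index
        return MetabolomicsDataset(
            abundance=self.abundance.loc[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            features=self.features.copy(),
            provenance=[*self.provenance, f"subset(phase={phase}, arm={arm})"],
        )


# ---------------------------------------------------------------------------
# tabular I/O


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_dataset(
    abundance_path: str | os.PathLike,
    sample_meta_path: str | os.PathLike,
    feature_meta_path: str | os.PathLike,
    na_sentinel: str = "NA",
    provenance_path: str | os.PathLike | None = None,
) -> MetabolomicsDataset:
    """Read the three-file layout; empty cells and ``na_sentinel`` are missing.

    ``provenance_path`` (a plain-text transform log written by
    :func:`write_dataset`) restores the provenance of already-transformed
    matrices; without it a log-scale matrix would fail raw-scale validation.
    """
    kw = dict(na_values=[na_sentinel, ""], keep_default_na=False)
    abundance = pd.read_csv(abundance_path, sep=_sep_for(abundance_path), index_col=0, **kw)
    abundance = abundance.astype(float)
    samples = pd.read_csv(sample_meta_path, sep=_sep_for(sample_meta_path), index_col=0, dtype=str)
    features = pd.read_csv(feature_meta_path, sep=_sep_for(feature_meta_path), index_col=0, dtype=str)
    abundance.index = abundance.index.astype(str)
    abundance.columns = abundance.columns.astype(str)
    samples.index = samples.index.astype(str)
    features.index = features.index.astype(str)
    provenance: list[str] = []
    if provenance_path is not None and os.path.exists(provenance_path):
        provenance = [l for l in open(provenance_path).read().splitlines() if l]
    return MetabolomicsDataset(abundance=abundance, samples=samples,
                               features=features, provenance=provenance)


def write_dataset(ds: MetabolomicsDataset, out_dir: str | os.PathLike, prefix: str = "dataset") -> dict[str, str]:
    """Write abundance/sample/feature CSVs; missing cells serialize as ``NA``.

    Returns the three paths written, keyed ``abundance``/``samples``/``features``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "abundance": os.path.join(out_dir, f"{prefix}_abundance.csv"),
        "samples": os.path.join(out_dir, f"{prefix}_samples.csv"),
        "features": os.path.join(out_dir, f"{prefix}_features.csv"),
        "provenance": os.path.join(out_dir, f"{prefix}_provenance.txt"),
    }
    ds.abundance.to_csv(paths["abundance"], na_rep="NA", float_format="%.17g")
    ds.samples.to_csv(paths["samples"])
    ds.features.to_csv(paths["features"])
    with open(paths["provenance"], "w") as fh:
        fh.write("\n".join(ds.provenance) + "\n" if ds.provenance else "")
    return paths


# ---------------------------------------------------------------------------
# GraphML export (replaces interactive network visualization)


def write_network_graphml(network, path: str | os.PathLike) -> None:
    """Serialize a correlation network with node pathway/betweenness and
    edge r/p attributes; round-trips through :func:`read_network_graphml`."""
    g = nx.Graph()
    for node in network.nodes:
        g.add_node(
            node,
            pathway_label=str(network.pathways.get(node, "other")),
            betweenness=float(network.betweenness[node]),
        )
    for i, j, r, p in network.edges:
        g.add_edge(i, j, spearman_r=float(r), p_value=float(p))
    nx.write_graphml(g, path)


def read_network_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# flat key-value text (config / ground-truth serialization)


def write_key_value(mapping: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key in sorted(mapping):
            fh.write(f"{key}\t{mapping[key]!r}\n")


def read_key_value(path: str | os.PathLike) -> dict:
    import ast

    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = ast.literal_eval(value)
    return out
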