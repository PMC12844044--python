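"""Targeted purine/redox panel extraction and ratio indices.

The targeted branch consumes the post-imputation, *raw-scale* matrix: the
uric-acid/hypoxanthine ratio (UA/HX, a surrogate for terminal purine
oxidation by xanthine oxidase) and the glutathione redox ratio (GSH/GSSG)
are meaningless on log- or Pareto-scale values. Ratios are computed per
sample; a zero or missing denominator (or numerator) makes the ratio
undefined — flagged, never silently dropped. Feature matching goes through
an editable alias table so that e.g. "urate" and "uric acid" both resolve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .discriminant import univariate_test
from .io import ARMS, PHASES, MetabolomicsDataset


class TargetedError(ValueError):
    pass


#: canonical slot -> accepted names (case/space/underscore-insensitive);
#: entries ending in '*' are prefix matches (for lipid species like
#: PC-OOH(16:0/18:2)).
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "hx": ("hypoxanthine", "hx"),
    "ua": ("uric_acid", "uric acid", "urate", "ua"),
    "inosine": ("inosine",),
    "xanthine": ("xanthine",),
    "adenosine": ("adenosine",),
    "gsh": ("gsh", "glutathione", "reduced glutathione"),
    "gssg": ("gssg", "glutathione disulfide", "oxidized glutathione"),
    "pc_ooh": ("pc-ooh*", "pcooh*"),
}


def _canon(name: str) -> str:
    return name.lower().replace("_", " ").strip()


def resolve_panel(ds: MetabolomicsDataset,
                  aliases: dict[str, tuple[str, ...]] | None = None) -> dict[str, str]:
    """Map each canonical targeted slot to a feature ID in the dataset."""
    aliases = aliases or DEFAULT_ALIASES
    lookup: dict[str, str] = {}
    canon_ids = {_canon(fid): fid for fid in ds.features.index}
    canon_names = {_canon(dn): fid for fid, dn in ds.features["display_name"].items()}
    missing = []
    for slot, options in aliases.items():
        found = None
        for opt in options:
            if opt.endswith("*"):
                prefix = _canon(opt[:-1])
                for cname, fid in {**canon_ids, **canon_names}.items():
                    if cname.startswith(prefix):
                        found = fid
                        break
            else:
                copt = _canon(opt)
                found = canon_ids.get(copt) or canon_names.get(copt)
            if found:
                break
        if found is None:
            missing.append(slot)
        else:
            lookup[slot] = found
    if missing:
        raise TargetedError(f"targeted metabolites absent from dataset: {missing}")
    return lookup


def compute_indices(ds: MetabolomicsDataset,
                    aliases: dict[str, tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Per-sample targeted panel with UA/HX and GSH/GSSG ratios.

    Returns one row per sample: the eight raw-scale abundances, the two
    ratios, defined-ness flags, and the sample's arm/phase/subject labels.
    """
    if ds.is_logged:
        raise TargetedError("targeted indices require the raw-scale (pre-log) matrix")
    panel = resolve_panel(ds, aliases)
    out = pd.DataFrame(index=ds.abundance.index)
    for slot, fid in panel.items():
        out[slot] = ds.abundance[fid]

    def ratio(num: pd.Series, den: pd.Series) -> tuple[pd.Series, pd.Series]:
        defined = num.notna() & den.notna() & (den != 0)
        values = pd.Series(np.nan, index=num.index)
        values[defined] = num[defined] / den[defined]
        return values, defined

    out["ua_hx_ratio"], out["ua_hx_defined"] = ratio(out["ua"], out["hx"])
    out["gsh_gssg_ratio"], out["gsh_gssg_defined"] = ratio(out["gsh"], out["gssg"])
    out["arm"] = ds.samples["arm"]
    out["phase"] = ds.samples["phase"]
    out["subject"] = ds.samples["subject_id"]
    return out


def phase_summaries(indices: pd.DataFrame,
                    value: str = "ua_hx_ratio") -> pd.DataFrame:
    """Per (arm, phase) summary of one index over its defined values:
    median, IQR, mean, SD, n, plus the per-phase placebo-vs-polyphenol
    Mann-Whitney p. Empty cells are omitted with a warning."""
    flag = f"{value.removesuffix('_ratio')}_defined" if value.endswith("_ratio") else None
    rows = []
    for phase in PHASES:
        per_arm: dict[str, np.ndarray] = {}
        for arm in ARMS:
            mask = (indices["arm"] == arm) & (indices["phase"] == phase)
            vals = indices.loc[mask, value]
            if flag is not None:
                vals = vals[indices.loc[mask, flag]]
            vals = vals.dropna().to_numpy()
            if vals.size == 0:
                warnings.warn(f"empty cell ({arm}, {phase}) omitted", stacklevel=2)
                continue
            per_arm[arm] = vals
            q1, q3 = (np.percentile(vals, [25, 75]) if vals.size > 1
                      else (vals[0], vals[0]))
            rows.append({
                "arm": arm, "phase": phase, "n": vals.size,
                "median": float(np.median(vals)), "iqr": float(q3 - q1),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            })
        p = np.nan
        if len(per_arm) == 2 and all(len(v) >= 2 for v in per_arm.values()):
            p = univariate_test(per_arm["placebo"], per_arm["polyphenol"])
        for row in rows:
            if row["phase"] == phase:
                row["mw_p_placebo_vs_polyphenol"] = p
    return pd.DataFrame(rows)


def pairwise_targeted_correlation(ds: MetabolomicsDataset, pair: tuple[str, str],
                                  phase: str, arm: str,
                                  aliases: dict[str, tuple[str, ...]] | None = None,
                                  ) -> tuple[float, float]:
    """Spearman r and two-sided p between two targeted metabolites within
    one phase/arm cell (complete pairs only; needs >= 4)."""
    from .network import spearman_pair

    panel = resolve_panel(ds, aliases)
    sub = ds.subset(phase=phase, arm=arm)
    ids = []
    for name in pair:
        ids.append(panel[name] if name in panel else name)
    x = sub.abundance[ids[0]]
    y = sub.abundance[ids[1]]
    keep = x.notna() & y.notna()
    if keep.sum() < 4:
        raise TargetedError(
            f"need >= 4 complete pairs for {pair} in ({arm}, {phase}); "
            f"have {int(keep.sum())}")
    return spearman_pair(x[keep].to_numpy(), y[keep].to_numpy())
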