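"""End-to-end dataset-stratified analysis and multi-study concordance.

Each study is analyzed independently — raw intensity matrices are never
pooled across studies — through the fixed stage order preprocess ->
multivariate -> discriminant -> targeted -> network -> enrichment; evidence
is then synthesized as a concordance table counting how many datasets agree
in direction on three key statistics: the recovery-phase UA/HX arm
contrast, the mean purine-lipid-peroxidation correlation difference, and
the summed betweenness change of the targeted panel. A pooled-demographics
helper aggregates study-level participant tables.

Every threshold used is serialized into a plain-text run manifest so a run
is auditable and byte-reproducible under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import os
import warnings

import numpy as np
import pandas as pd

from . import io as rio
from .discriminant import volcano_table
from .enrichment import PathwayAnnotation, ora
from .multivariate import opls_fit, opls_permutation_test, pca_fit
from .network import build_network, differential_network, pvalue_ecdf, spearman_matrix
from .preprocess import PreprocessConfig, preprocess
from .synthetic import SyntheticConfig, generate_multistudy
from .targeted import compute_indices, phase_summaries, resolve_panel


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    phase: str = "Rec"
    vip_threshold: float = 1.0
    q_threshold: float = 0.05
    r_threshold: float = 0.6
    strong_r_threshold: float = 0.7
    p_threshold: float = 0.05
    n_perm: int = 200
    cv_folds: int = 7
    full_panel_networks: bool = False
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("vip_threshold", "r_threshold", "strong_r_threshold"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be non-negative")
        for name in ("q_threshold", "p_threshold"):
            if not 0 < getattr(self, name) <= 1:
                raise PipelineError(f"{name} must lie in (0, 1]")

    def manifest_lines(self) -> list[str]:
        return [
            f"phase={self.phase}",
            f"vip_threshold={self.vip_threshold}",
            f"q_threshold={self.q_threshold}",
            f"r_threshold={self.r_threshold}",
            f"strong_r_threshold={self.strong_r_threshold}",
            f"p_threshold={self.p_threshold}",
            f"n_perm={self.n_perm}",
            f"cv_folds={self.cv_folds}",
            f"max_missing_fraction={self.preprocess.max_missing_fraction}",
            f"rf_trees={self.preprocess.rf_trees}",
            f"seed={self.seed}",
            f"n_datasets={self.synthetic.n_datasets}",
            f"n_per_arm={self.synthetic.n_per_arm}",
            f"decoupling_factor={self.synthetic.decoupling_factor}",
        ]


STAGES = ("preprocess", "multivariate", "discriminant", "targeted", "network",
          "enrichment")


@dataclasses.dataclass
class DatasetResult:
    dataset_id: str
    preprocessed: object
    pca: object
    opls: object
    discriminant: pd.DataFrame
    targeted_indices: pd.DataFrame
    targeted_summary: pd.DataFrame
    networks: dict
    differential: object
    ecdf: dict
    enrichment: pd.DataFrame
    truth: object = None
    stages_completed: tuple = STAGES


@dataclasses.dataclass
class RunResult:
    config: RunConfig
    datasets: list[DatasetResult]
    concordance: pd.DataFrame
    manifest: str


def analyze_dataset(ds, config: RunConfig, truth=None) -> DatasetResult:
    """Run all six stages on one dataset."""
    dataset_id = ds.samples["dataset_id"].iloc[0]
    stage = "preprocess"
    try:
        pp = preprocess(ds, config.preprocess)

        stage = "multivariate"
        scaled_phase = pp.scaled.subset(phase=config.phase)
        pca = pca_fit(pp.scaled, n_components=min(5, pp.scaled.n_samples - 1,
                                                  pp.scaled.n_features))
        arms = scaled_phase.samples["arm"].to_numpy()
        model = opls_fit(scaled_phase.abundance, arms, n_ortho="auto",
                         cv_folds=config.cv_folds, seed=config.seed)
        if config.n_perm:
            opls_permutation_test(scaled_phase.abundance, arms,
                                  n_perm=config.n_perm, seed=config.seed,
                                  cv_folds=config.cv_folds, model=model)

        stage = "discriminant"
        disc = volcano_table(pp.logged, config.phase, vip=model.vip,
                             vip_threshold=config.vip_threshold,
                             alpha=config.q_threshold, opls_seed=config.seed,
                             cv_folds=config.cv_folds)

        stage = "targeted"
        indices = compute_indices(pp.imputed)
        summary = phase_summaries(indices)

        stage = "network"
        panel = resolve_panel(pp.imputed)
        selected = set(disc.index[disc["selected"]])
        node_set = sorted(selected | set(panel.values()))
        if config.full_panel_networks:
            node_set = list(pp.logged.abundance.columns)
        pathway_map = pp.logged.features["pathway"].to_dict()
        networks, ecdfs = {}, {}
        for arm in rio.ARMS:
            sub = pp.logged.subset(phase=config.phase, arm=arm)
            r, p = spearman_matrix(sub.abundance[node_set])
            networks[arm] = build_network(
                r, p, r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
                pathways={k: pathway_map.get(k, "other") for k in node_set})
            # per-feature within-arm Rec-vs-Pre p-values for the ECDF summary
            from .discriminant import univariate_test

            rec = pp.logged.subset(phase=config.phase, arm=arm).abundance
            pre = pp.logged.subset(phase="Pre", arm=arm).abundance
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals = [univariate_test(rec[f], pre[f]) for f in rec.columns]
            ecdfs[arm] = pvalue_ecdf(pvals)
        diff = differential_network(networks["placebo"], networks["polyphenol"],
                                    pathways=pd.Series(pathway_map).reindex(node_set),
                                    strong_threshold=config.strong_r_threshold)

        stage = "enrichment"
        annotation = PathwayAnnotation.from_feature_table(pp.logged.features)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enrich = ora(selected, annotation)
    except Exception as exc:  # annotate with dataset/stage context
        raise PipelineError(f"dataset {dataset_id!r}, stage {stage!r}: {exc}") from exc

    return DatasetResult(
        dataset_id=dataset_id, preprocessed=pp, pca=pca, opls=model,
        discriminant=disc, targeted_indices=indices, targeted_summary=summary,
        networks=networks, differential=diff, ecdf=ecdfs, enrichment=enrich,
        truth=truth,
    )


# --- concordance statistics -------------------------------------------------


def _ua_hx_contrast_sign(result: DatasetResult, phase: str) -> int:
    idx = result.targeted_indices
    cell = idx[(idx["phase"] == phase) & idx["ua_hx_defined"]]
    med = cell.groupby("arm")["ua_hx_ratio"].median()
    return int(np.sign(med.get("polyphenol", np.nan) - med.get("placebo", np.nan)))


def _purine_lipid_delta_sign(result: DatasetResult) -> int:
    table = result.differential.pathway_pair_mean_delta
    mask = (
        ((table["pathway_a"] == "purine") & (table["pathway_b"] == "lipid_peroxidation"))
        | ((table["pathway_a"] == "lipid_peroxidation") & (table["pathway_b"] == "purine"))
    )
    if not mask.any():
        return 0
    return int(np.sign(table.loc[mask, "mean_delta_r"].mean()))


def _targeted_centrality_sign(result: DatasetResult) -> int:
    panel_nodes = [n for n in resolve_panel(result.preprocessed.imputed).values()
                   if n in result.differential.delta_betweenness.index]
    if not panel_nodes:
        return 0
    return int(np.sign(result.differential.delta_betweenness[panel_nodes].sum()))


def concordance_table(results: list[DatasetResult], phase: str) -> pd.DataFrame:
    """Per key statistic: sign in each dataset and how many datasets agree
    with the majority direction."""
    stats = {
        "ua_hx_rec_contrast": [_ua_hx_contrast_sign(r, phase) for r in results],
        "purine_lipid_delta_r": [_purine_lipid_delta_sign(r) for r in results],
        "targeted_delta_betweenness": [_targeted_centrality_sign(r) for r in results],
    }
    rows = []
    for name, signs in stats.items():
        signs_arr = np.asarray(signs)
        nonzero = signs_arr[signs_arr != 0]
        majority = int(np.sign(nonzero.sum())) if nonzero.size else 0
        agree = int(np.sum(signs_arr == majority)) if majority else 0
        rows.append({
            "statistic": name,
            "n_datasets": len(signs),
            "majority_direction": majority,
            "n_agreeing": agree,
            "signs": ",".join(str(s) for s in signs),
        })
    return pd.DataFrame(rows).set_index("statistic")


def run_all(config: RunConfig) -> RunResult:
    """Generate (or load) the studies, analyze each, and synthesize.

    Writes, when ``config.out_dir`` is set: per-dataset discriminant,
    targeted, enrichment and delta tables as CSV, per-arm GraphML networks,
    the concordance table, and a plain-text manifest.
    """
    config.validate()
    studies = generate_multistudy(config.synthetic)
    results = [analyze_dataset(ds, config, truth=truth) for ds, truth in studies]
    concordance = concordance_table(results, config.phase)

    lines = ["recovermet run manifest", "", "[config]"]
    lines += config.manifest_lines()
    lines += ["", "[datasets]"]
    for res in results:
        lines.append(
            f"{res.dataset_id}: stages={','.join(res.stages_completed)} "
            f"n_samples={res.preprocessed.scaled.n_samples} "
            f"n_features={res.preprocessed.scaled.n_features} "
            f"q2={res.opls.q2:.6f} r2y={res.opls.r2y:.6f} "
            f"perm_p={res.opls.permutation.p_value if res.opls.permutation else 'NA'} "
            f"n_selected={int(res.discriminant['selected'].sum())}"
        )
    lines += ["", "[concordance]"]
    for stat, row in concordance.iterrows():
        lines.append(f"{stat}: {row['n_agreeing']}/{row['n_datasets']} "
                     f"direction={row['majority_direction']} signs={row['signs']}")
    manifest = "\n".join(lines) + "\n"

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for res in results:
            d = os.path.join(config.out_dir, res.dataset_id)
            os.makedirs(d, exist_ok=True)
            res.discriminant.to_csv(os.path.join(d, "discriminant.csv"))
            res.targeted_indices.to_csv(os.path.join(d, "targeted_indices.csv"))
            res.targeted_summary.to_csv(os.path.join(d, "targeted_summary.csv"), index=False)
            res.enrichment.to_csv(os.path.join(d, "enrichment.csv"))
            res.differential.delta_r.to_csv(os.path.join(d, "delta_r.csv"))
            res.differential.delta_betweenness.to_csv(
                os.path.join(d, "delta_betweenness.csv"), header=["delta_betweenness"])
            res.differential.pathway_pair_mean_delta.to_csv(
                os.path.join(d, "pathway_pair_delta.csv"), index=False)
            for arm, net in res.networks.items():
                rio.write_network_graphml(net, os.path.join(d, f"network_{arm}.graphml"))
            if res.truth is not None:
                res.truth.to_file(os.path.join(d, "truth.txt"))
        concordance.to_csv(os.path.join(config.out_dir, "concordance.csv"))
        with open(os.path.join(config.out_dir, "manifest.txt"), "w") as fh:
            fh.write(manifest)

    return RunResult(config=config, datasets=results, concordance=concordance,
                     manifest=manifest)


# ---------------------------------------------------------------------------
# pooled demographics (worked example over the published study table)

#: Study-level participant characteristics of the four analyzed datasets.
#: Crossover rows allocate unique participants evenly between arms (each
#: participant serves in both conditions), which is what makes the per-arm
#: pooled totals sum to half the cohort each. BMI NaN = not reported.
DEFAULT_STUDY_TABLE = pd.DataFrame(
    [
        {"study": "Study 1", "design": "parallel", "n_total": 14, "n_poly": 7,
         "n_placebo": 7, "mean_age": 21.5, "sex_m": 14, "sex_f": 0, "mean_bmi": 22.4},
        {"study": "Study 2", "design": "crossover", "n_total": 16, "n_poly": 8,
         "n_placebo": 8, "mean_age": 26.8, "sex_m": 16, "sex_f": 0, "mean_bmi": 23.9},
        {"study": "Study 3", "design": "parallel", "n_total": 12, "n_poly": 6,
         "n_placebo": 6, "mean_age": 23.1, "sex_m": 8, "sex_f": 4, "mean_bmi": 22.8},
        {"study": "Study 4", "design": "crossover", "n_total": 16, "n_poly": 8,
         "n_placebo": 8, "mean_age": 25.4, "sex_m": 12, "sex_f": 4, "mean_bmi": np.nan},
    ]
).set_index("study")


def pooled_demographics(table: pd.DataFrame | None = None) -> dict:
    """Pool study-level demographics by summation.

    ``pct_male`` is 100 * total males / total participants rounded to one
    decimal; ``weighted_mean_bmi`` is the n-weighted mean over studies
    reporting BMI, rounded to one decimal.
    """
    if table is None:
        table = DEFAULT_STUDY_TABLE
    counts = table[["n_total", "n_poly", "n_placebo", "sex_m", "sex_f"]]
    if (counts.to_numpy() < 0).any():
        raise PipelineError("negative participant counts")
    bad = table.index[table["sex_m"] + table["sex_f"] != table["n_total"]]
    if len(bad):
        raise PipelineError(f"sex split does not sum to n_total for: {bad.tolist()}")
    n_total = int(table["n_total"].sum())
    sex_m = int(table["sex_m"].sum())
    sex_f = int(table["sex_f"].sum())
    with_bmi = table.dropna(subset=["mean_bmi"])
    weighted_bmi = float("nan")
    if len(with_bmi):
        weighted_bmi = round(
            float((with_bmi["n_total"] * with_bmi["mean_bmi"]).sum()
                  / with_bmi["n_total"].sum()), 1)
    return {
        "n_total": n_total,
        "n_poly": int(table["n_poly"].sum()),
        "n_placebo": int(table["n_placebo"].sum()),
        "sex_m": sex_m,
        "sex_f": sex_f,
        "pct_male": round(100.0 * sex_m / n_total, 1),
        "weighted_mean_bmi": weighted_bmi,
    }
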