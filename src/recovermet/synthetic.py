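"""Synthetic two-arm, three-phase longitudinal metabolomics generator.

The generator emulates the statistical structure of a placebo-controlled
polyphenol supplementation trial sampled before exercise (Pre), immediately
after (Post) and during recovery (Rec):

* overlapping baselines between arms at Pre,
* a global Post displacement shared by both arms,
* partial reversion toward baseline at Rec in the polyphenol arm only,
  with purine catabolites staying elevated under placebo,
* a suppressed uric-acid/hypoxanthine ratio under supplementation,
* arm-dependent coupling between purine metabolites and lipid-peroxidation
  markers, driven by a single latent recovery-stress factor whose loadings
  are attenuated by a decoupling factor delta in the supplemented arm.

Model, on the natural-log scale, for subject i, feature j, phase t::

    x_ijt = mu_j + effect_j(arm, t) + u_ij + lam_j(arm) * s_i * [t == Rec] + eps

with ``u_ij ~ N(0, subject_sd^2)`` a subject-by-feature baseline held
constant across phases (independent across features, so it creates
within-subject longitudinal correlation without coupling features to each
other), ``s_i ~ N(0, 1)`` the latent recovery-stress score, ``lam_j(arm)``
equal to the configured loading in the placebo arm and ``delta * lam_j`` in
the polyphenol arm, and ``eps ~ N(0, residual_sd^2)``. Abundances are
exported on the raw (exponentiated) scale; missingness is applied afterwards
as MCAR dropout plus left-censoring below a per-feature quantile,
mimicking LC-MS detection limits.

The Rec-phase correlation induced between two coupled features a, b within
an arm has the closed form ``lam_a lam_b / sqrt((lam_a^2 + s2)(lam_b^2 + s2))``
with ``s2 = subject_sd^2 + residual_sd^2``; :class:`SyntheticTruth` records
it, along with every realized effect, for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ARMS, PATHWAYS, PHASES, MetabolomicsDataset, read_key_value, write_key_value

REQUIRED_TARGETED = (
    "adenosine",
    "inosine",
    "hypoxanthine",
    "xanthine",
    "uric_acid",
    "GSH",
    "GSSG",
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass(frozen=True)
class Metabolite:
    name: str
    pathway: str

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ConfigurationError(f"unknown pathway {self.pathway!r} for {self.name}")


@dataclasses.dataclass(frozen=True)
class PhaseEffect:
    """Log-scale mean shifts relative to Pre, by phase and arm."""

    post_placebo: float = 0.0
    post_polyphenol: float = 0.0
    rec_placebo: float = 0.0
    rec_polyphenol: float = 0.0

    def shift(self, arm: str, phase: str) -> float:
        if phase == "Pre":
            return 0.0
        return getattr(self, f"{phase.lower()}_{arm}")


# --- default study conditions ----------------------------------------------
# Panel and effect sizes encode the qualitative contrasts of a recovery-phase
# polyphenol trial: a shared catabolic Post excursion, sustained purine and
# lipid-peroxidation elevation under placebo at Rec with reversion under
# supplementation, circulating polyphenol-derived phenolics only in the
# supplemented arm, and a latent stress factor coupling purines to
# lipid-peroxidation markers that the intervention attenuates.

DEFAULT_PANEL: tuple[Metabolite, ...] = (
    Metabolite("adenosine", "purine"),
    Metabolite("inosine", "purine"),
    Metabolite("hypoxanthine", "purine"),
    Metabolite("xanthine", "purine"),
    Metabolite("uric_acid", "purine"),
    Metabolite("GSH", "redox"),
    Metabolite("GSSG", "redox"),
    Metabolite("PC-OOH(16:0/18:2)", "lipid_peroxidation"),
    Metabolite("PE-OOH(18:0/20:4)", "lipid_peroxidation"),
    Metabolite("MDA", "lipid_peroxidation"),
    Metabolite("4-HNE", "lipid_peroxidation"),
    Metabolite("hippuric_acid", "polyphenol_derived"),
    Metabolite("4-hydroxyhippuric_acid", "polyphenol_derived"),
    Metabolite("epicatechin_sulfate", "polyphenol_derived"),
    Metabolite("urolithin_A", "polyphenol_derived"),
    Metabolite("alanine", "amino_acid"),
    Metabolite("glutamine", "amino_acid"),
    Metabolite("leucine", "amino_acid"),
    Metabolite("tryptophan", "amino_acid"),
    Metabolite("lactate", "glycolysis"),
    Metabolite("pyruvate", "glycolysis"),
    Metabolite("glucose_6_phosphate", "glycolysis"),
    Metabolite("caffeine", "xenobiotic"),
    Metabolite("paraxanthine", "xenobiotic"),
    Metabolite("creatinine", "other"),
    Metabolite("carnitine", "other"),
)

DEFAULT_BASELINES: dict[str, float] = {
    "adenosine": 7.5, "inosine": 8.0, "hypoxanthine": 9.0, "xanthine": 8.5,
    "uric_acid": 11.0, "GSH": 10.0, "GSSG": 8.0, "PC-OOH(16:0/18:2)": 7.0,
    "PE-OOH(18:0/20:4)": 6.5, "MDA": 7.5, "4-HNE": 6.0, "hippuric_acid": 9.0,
    "4-hydroxyhippuric_acid": 7.0, "epicatechin_sulfate": 6.0,
    "urolithin_A": 5.5, "alanine": 11.5, "glutamine": 12.0, "leucine": 11.0,
    "tryptophan": 10.5, "lactate": 12.5, "pyruvate": 10.0,
    "glucose_6_phosphate": 8.0, "caffeine": 9.0, "paraxanthine": 8.5,
    "creatinine": 11.0, "carnitine": 10.5,
}

DEFAULT_PHASE_EFFECTS: dict[str, PhaseEffect] = {
    # purine cascade: shared Post surge; placebo stays elevated at Rec,
    # supplementation reverts; UA/HX log-ratio ends +0.4 (placebo) vs -0.4
    # (polyphenol) relative to Pre.
    "adenosine": PhaseEffect(0.5, 0.5, 0.3, 0.1),
    "inosine": PhaseEffect(1.0, 1.0, 0.6, 0.2),
    "hypoxanthine": PhaseEffect(1.2, 1.2, 0.6, 0.25),
    "xanthine": PhaseEffect(0.9, 0.9, 0.7, 0.2),
    "uric_acid": PhaseEffect(0.4, 0.4, 1.0, -0.15),
    # redox: GSH depleted / GSSG accumulated post-exercise; placebo recovery lags
    "GSH": PhaseEffect(-0.4, -0.4, -0.3, 0.1),
    "GSSG": PhaseEffect(0.5, 0.5, 0.4, 0.0),
    # lipid peroxidation: sustained under placebo only
    "PC-OOH(16:0/18:2)": PhaseEffect(0.6, 0.6, 0.5, 0.1),
    "PE-OOH(18:0/20:4)": PhaseEffect(0.6, 0.6, 0.5, 0.1),
    "MDA": PhaseEffect(0.5, 0.5, 0.4, 0.1),
    "4-HNE": PhaseEffect(0.5, 0.5, 0.4, 0.1),
    # circulating phenolic metabolites appear only under supplementation
    "hippuric_acid": PhaseEffect(0.0, 1.2, 0.0, 1.5),
    "4-hydroxyhippuric_acid": PhaseEffect(0.0, 1.2, 0.0, 1.5),
    "epicatechin_sulfate": PhaseEffect(0.0, 1.5, 0.0, 1.2),
    "urolithin_A": PhaseEffect(0.0, 1.0, 0.0, 1.3),
    # energy/amino-acid shifts shared between arms
    "alanine": PhaseEffect(0.3, 0.3, 0.1, 0.0),
    "glutamine": PhaseEffect(-0.2, -0.2, -0.1, 0.0),
    "leucine": PhaseEffect(-0.3, -0.3, -0.1, 0.0),
    "tryptophan": PhaseEffect(-0.2, -0.2, 0.0, 0.0),
    "lactate": PhaseEffect(1.5, 1.5, 0.3, 0.1),
    "pyruvate": PhaseEffect(0.8, 0.8, 0.2, 0.1),
    "glucose_6_phosphate": PhaseEffect(0.4, 0.4, 0.1, 0.0),
}

DEFAULT_COUPLING: dict[str, float] = {
    # latent recovery-stress loadings; purines and lipid peroxidation load
    # together, glutathione loads with opposite signs
    "inosine": 0.6, "hypoxanthine": 0.8, "xanthine": 0.7, "uric_acid": 0.8,
    "PC-OOH(16:0/18:2)": 0.8, "PE-OOH(18:0/20:4)": 0.7, "MDA": 0.7,
    "4-HNE": 0.6, "GSH": -0.5, "GSSG": 0.5,
}


@dataclasses.dataclass
class SyntheticConfig:
    """Full specification of the data-generating conditions.

    Defaults reproduce the study conditions the pipeline is validated
    against: 30 subjects per arm, 4 independent studies, decoupling factor
    0.2, log-scale subject and residual SDs of 0.3 and 0.4, and ~8% total
    missingness (3% MCAR + left-censoring below each feature's 5% quantile).
    """

    n_per_arm: int = 30
    n_datasets: int = 4
    panel: tuple[Metabolite, ...] = DEFAULT_PANEL
    baselines: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    phase_effects: Mapping[str, PhaseEffect] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PHASE_EFFECTS))
    coupling_loading: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COUPLING))
    decoupling_factor: float = 0.2
    subject_sd: float = 0.3
    residual_sd: float = 0.4
    dataset_baseline_sd: float = 0.5
    missing_mcar_rate: float = 0.03
    censor_quantile: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.decoupling_factor <= 1.0:
            raise ConfigurationError("decoupling_factor must lie in [0, 1]")
        if not 0.0 <= self.missing_mcar_rate < 1.0:
            raise ConfigurationError("missing_mcar_rate must lie in [0, 1)")
        if not 0.0 <= self.censor_quantile < 1.0:
            raise ConfigurationError("censor_quantile must lie in [0, 1)")
        if self.n_per_arm < 3:
            raise ConfigurationError("n_per_arm must be >= 3")
        if self.n_datasets < 1:
            raise ConfigurationError("n_datasets must be >= 1")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        names = {m.name for m in self.panel}
        missing = [m for m in REQUIRED_TARGETED if m not in names]
        if not any(n.startswith("PC-OOH") for n in names):
            missing.append("PC-OOH*")
        if missing:
            raise ConfigurationError(
                f"panel lacks required targeted metabolites: {missing}")

    # -- canned study conditions -------------------------------------------

    @staticmethod
    def null(seed: int = 0, **overrides) -> "SyntheticConfig":
        """Zero-effect configuration: no phase/arm effects, identical
        coupling in both arms (delta = 1) and no missingness — both arms
        are exchangeable at every phase. Used for type-I calibration."""
        cfg = dict(
            phase_effects={},
            decoupling_factor=1.0,
            missing_mcar_rate=0.0,
            censor_quantile=0.0,
            seed=seed,
        )
        cfg.update(overrides)
        return SyntheticConfig(**cfg)

    @staticmethod
    def planted(effect_log2: float = 1.0, metabolite: str = "alanine",
                seed: int = 0, **overrides) -> "SyntheticConfig":
        """Null conditions plus a single planted Rec-phase arm effect of
        ``effect_log2`` log2 units on one (uncoupled) metabolite."""
        shift = effect_log2 * math.log(2.0)
        cfg = SyntheticConfig.null(seed=seed, **overrides)
        cfg.phase_effects = {metabolite: PhaseEffect(0.0, 0.0, 0.0, shift)}
        return cfg


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth realized by one generated dataset.

    ``rec_correlation`` maps ``(feature_a, feature_b, arm)`` to the
    closed-form Rec-phase Pearson correlation induced by the latent stress
    factor; ``effects`` maps ``(feature, arm, phase)`` to the true total
    log-scale mean shift; ``ua_hx_ratio`` maps ``(arm, phase)`` to the
    geometric-mean uric-acid/hypoxanthine ratio.
    """

    seed: int
    dataset_id: str
    rec_correlation: dict[tuple[str, str, str], float]
    effects: dict[tuple[str, str, str], float]
    ua_hx_ratio: dict[tuple[str, str], float]

    def to_file(self, path) -> None:
        flat: dict[str, float | int | str] = {
            "seed": self.seed, "dataset_id": self.dataset_id}
        for (a, b, arm), r in self.rec_correlation.items():
            flat[f"rec_correlation|{a}|{b}|{arm}"] = r
        for (f, arm, phase), v in self.effects.items():
            flat[f"effect|{f}|{arm}|{phase}"] = v
        for (arm, phase), v in self.ua_hx_ratio.items():
            flat[f"ua_hx_ratio|{arm}|{phase}"] = v
        write_key_value(flat, path)

    @staticmethod
    def from_file(path) -> "SyntheticTruth":
        flat = read_key_value(path)
        truth = SyntheticTruth(flat["seed"], flat["dataset_id"], {}, {}, {})
        for key, value in flat.items():
            parts = key.split("|")
            if parts[0] == "rec_correlation":
                truth.rec_correlation[(parts[1], parts[2], parts[3])] = value
            elif parts[0] == "effect":
                truth.effects[(parts[1], parts[2], parts[3])] = value
            elif parts[0] == "ua_hx_ratio":
                truth.ua_hx_ratio[(parts[1], parts[2])] = value
        return truth


def expected_rec_correlation(lam_a: float, lam_b: float, sigma2: float) -> float:
    """Closed-form Rec-phase correlation between two stress-coupled features."""
    return lam_a * lam_b / math.sqrt((lam_a**2 + sigma2) * (lam_b**2 + sigma2))


def _effective_loading(config: SyntheticConfig, name: str, arm: str) -> float:
    lam = config.coupling_loading.get(name, 0.0)
    if arm == "polyphenol":
        lam *= config.decoupling_factor
    return lam


def _build_truth(config: SyntheticConfig, seed: int, dataset_id: str,
                 baseline: Mapping[str, float]) -> SyntheticTruth:
    sigma2 = config.subject_sd**2 + config.residual_sd**2
    names = [m.name for m in config.panel]
    rec_corr: dict[tuple[str, str, str], float] = {}
    coupled = [n for n in names if config.coupling_loading.get(n, 0.0) != 0.0]
    for arm in ARMS:
        for ia, a in enumerate(coupled):
            for b in coupled[ia + 1:]:
                rec_corr[(a, b, arm)] = expected_rec_correlation(
                    _effective_loading(config, a, arm),
                    _effective_loading(config, b, arm),
                    sigma2,
                )
    effects = {
        (name, arm, phase): config.phase_effects.get(name, PhaseEffect()).shift(arm, phase)
        for name in names for arm in ARMS for phase in PHASES
    }
    ua_hx = {}
    for arm in ARMS:
        for phase in PHASES:
            log_ratio = (
                baseline["uric_acid"] + effects[("uric_acid", arm, phase)]
                - baseline["hypoxanthine"] - effects[("hypoxanthine", arm, phase)]
            )
            ua_hx[(arm, phase)] = math.exp(log_ratio)
    return SyntheticTruth(seed, dataset_id, rec_corr, effects, ua_hx)


def generate_dataset(
    config: SyntheticConfig,
    dataset_id: str = "study1",
    seed: int | None = None,
    baseline_offset: Mapping[str, float] | None = None,
) -> tuple[MetabolomicsDataset, SyntheticTruth]:
    """Simulate one study: ``2 * n_per_arm`` subjects, one sample per
    subject and phase, raw-scale abundances with missingness applied.

    ``baseline_offset`` shifts per-feature log baselines (platform
    heterogeneity between studies); :func:`generate_multistudy` supplies it.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    names = [m.name for m in config.panel]
    n_feat = len(names)
    baseline = {
        n: config.baselines.get(n, 8.0) + (baseline_offset or {}).get(n, 0.0)
        for n in names
    }

    sample_ids, subj_col, arm_col, phase_col = [], [], [], []
    rows = []
    for arm in ARMS:
        for i in range(config.n_per_arm):
            subject = f"{dataset_id}_{arm[:4]}_{i:03d}"
            u = rng.normal(0.0, config.subject_sd, size=n_feat)
            s = rng.normal()
            lam = np.array([_effective_loading(config, n, arm) for n in names])
            for phase in PHASES:
                shift = np.array([
                    config.phase_effects.get(n, PhaseEffect()).shift(arm, phase)
                    for n in names
                ])
                eps = rng.normal(0.0, config.residual_sd, size=n_feat)
                x = (
                    np.array([baseline[n] for n in names])
                    + shift + u + eps
                    + (lam * s if phase == "Rec" else 0.0)
                )
                rows.append(np.exp(x))
                sample_ids.append(f"{subject}_{phase}")
                subj_col.append(subject)
                arm_col.append(arm)
                phase_col.append(phase)

    abundance = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=names)

    # missingness: MCAR dropout, then left-censoring below the per-feature
    # censor quantile (strict, so quantile 0 censors nothing)
    if config.missing_mcar_rate > 0:
        mcar = rng.random(abundance.shape) < config.missing_mcar_rate
        abundance = abundance.mask(mcar)
    if config.censor_quantile > 0:
        limits = abundance.quantile(config.censor_quantile)
        abundance = abundance.mask(abundance.lt(limits, axis=1))

    samples = pd.DataFrame(
        {
            "subject_id": subj_col,
            "dataset_id": dataset_id,
            "arm": arm_col,
            "phase": phase_col,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "display_name": names,
            "pathway": [m.pathway for m in config.panel],
        },
        index=pd.Index(names, name="feature_id"),
    )
    ds = MetabolomicsDataset(
        abundance=abundance,
        samples=samples,
        features=features,
        provenance=[f"synthetic(dataset_id={dataset_id}, seed={seed})"],
    )
    truth = _build_truth(config, seed, dataset_id, baseline)
    return ds, truth


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-dataset seed below 2**31."""
    return (master_seed * 1_000_003 + 7_919 * index + 1) % (2**31)


def generate_multistudy(
    config: SyntheticConfig,
) -> list[tuple[MetabolomicsDataset, SyntheticTruth]]:
    """Independent studies with dataset-specific baseline offsets.

    Dataset 0 is the reference platform (zero offset, so ``n_datasets = 1``
    reduces exactly to :func:`generate_dataset` at the derived seed);
    later datasets get per-feature log-baseline offsets drawn
    ``N(0, dataset_baseline_sd^2)`` emulating platform heterogeneity.
    """
    out = []
    names = [m.name for m in config.panel]
    for d in range(config.n_datasets):
        seed_d = derive_seed(config.seed, d)
        if d == 0:
            offset = None
        else:
            off_rng = np.random.default_rng(derive_seed(config.seed, 10_000 + d))
            offset = dict(zip(names, off_rng.normal(0.0, config.dataset_baseline_sd, len(names))))
        out.append(
            generate_dataset(config, dataset_id=f"study{d + 1}", seed=seed_d,
                             baseline_offset=offset)
        )
    return out
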