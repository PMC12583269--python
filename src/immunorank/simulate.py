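"""Seeded synthetic-cohort generator.

Emulates a targeted immune-panel RNA study with no public data deposit: a
735-sample pan-cancer reference cohort plus a 514-sample study cohort across
~30 cancer types, with

* a latent per-sample immune-infiltration factor that induces positive
  correlation among checkpoint and co-stimulatory transcripts (CD40, CD28,
  GITR, PD-1/PD-L1/PD-L2, CTLA-4, LAG-3, ICOS, 4-1BB, CD27, OX40, CD40LG,
  CD4, CD8A),
* cancer-type-specific CD40 shifts (elevated in pancreatic, liver/bile-duct
  and ovarian tumors, depressed in colorectal and head-and-neck tumors),
* missing-at-random MSI/TMB driven by observed cancer type,
* a binary somatic-mutation matrix with a logistic link to the latent
  factor (negative for APC, mildly positive for CCND1),
* two proportional-hazards survival endpoints (OS from advanced disease;
  OS/PFS from immunotherapy start for the treated subset) with censoring.

Counts are Poisson with log2-mean = depth offset + gene baseline +
loading x latent factor + type shift + residual noise; each batch carries a
Poisson no-template control and the same background mean is added to every
sample so that background subtraction is meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as irio
from .normalize import RawPanelCounts, ReferenceModel, build_reference_model

__all__ = [
    "SimulationConfig",
    "StudyCohort",
    "generate_reference",
    "generate_study_cohort",
    "generate_gene_sets",
    "write_fixtures",
    "IMMUNE_GENES",
    "HK_GENES",
    "CONTROL_GENES",
    "MUTATION_GENES",
]

# 12 emphasized immune genes (HGNC symbols; PD-1=PDCD1, PD-L1=CD274,
# PD-L2=PDCD1LG2, 4-1BB=TNFRSF9, OX40=TNFRSF4, GITR=TNFRSF18).
IMMUNE_GENES = [
    "CD40", "PDCD1", "CD274", "PDCD1LG2", "CTLA4", "LAG3",
    "ICOS", "TNFRSF9", "CD27", "CD28", "TNFRSF4", "TNFRSF18",
]
T_CELL_GENES = ["CD4", "CD8A"]
LIGAND_GENE = "CD40LG"
HK_GENES = [
    "ABCF1", "G6PD", "GUSB", "HMBS", "POLR2A",
    "SDHA", "TBP", "TUBB", "ALAS1", "PPIA",
]
# Non-immune controls: tumor markers, antigens, proliferation genes.
CONTROL_GENES = [
    "MKI67", "EGFR", "ERBB2", "MYC", "CCND1", "CEACAM5",
    "MUC1", "KRT19", "TERT", "AURKA", "TOP2A", "VIM",
]

DEFAULT_GENES = IMMUNE_GENES + [LIGAND_GENE] + T_CELL_GENES + HK_GENES + CONTROL_GENES

# Study-cohort composition mirrors the most frequent tumor types of a
# real-world pan-cancer referral cohort (colorectal-dominant), padded with
# rare types so ~30 types appear overall.
_TYPE_COUNTS = {
    "colorectal": 140, "pancreatic": 55, "breast": 49, "ovarian": 43,
    "stomach": 25, "sarcoma": 24, "uterine": 24, "lung": 20,
    "liver_bile_duct": 19, "neuroendocrine": 15, "unknown_primary": 13,
    "head_neck": 12, "melanoma": 11, "prostate": 9, "kidney": 8,
    "bladder": 7, "esophageal": 7, "cervical": 6, "brain": 6,
    "thyroid": 5, "appendiceal": 5, "salivary": 4, "anal": 4,
    "small_bowel": 4, "adrenal": 3, "mesothelioma": 3, "thymic": 3,
    "vulvar": 3, "testicular": 2, "penile": 2, "other": 2,
}
DEFAULT_TYPE_WEIGHTS = {t: c / sum(_TYPE_COUNTS.values()) for t, c in _TYPE_COUNTS.items()}

# Per-gene loading on the latent immune factor; housekeeping and
# non-immune control genes load zero by construction.
DEFAULT_LOADINGS = {
    "CD40": 1.0, "PDCD1": 0.9, "CD274": 0.8, "PDCD1LG2": 0.8, "CTLA4": 0.8,
    "LAG3": 0.9, "ICOS": 0.8, "TNFRSF9": 0.9, "CD27": 0.9, "CD28": 0.9,
    "TNFRSF4": 0.8, "TNFRSF18": 0.6, "CD40LG": 0.5, "CD4": 0.9, "CD8A": 0.9,
}

# log2 shifts of individual genes in individual cancer types; defaults
# emulate the elevated-CD40 / depressed-CD40 histologies.
DEFAULT_TYPE_SHIFTS = {
    ("pancreatic", "CD40"): 0.9,
    ("liver_bile_duct", "CD40"): 0.9,
    ("ovarian", "CD40"): 0.85,
    ("neuroendocrine", "CD40"): 0.5,
    ("colorectal", "CD40"): -0.55,
    ("head_neck", "CD40"): -0.8,
    ("ovarian", "CD40LG"): -0.3,
}

# Baseline log2 abundance (arbitrary units): housekeeping genes dominate
# total signal, immune transcripts are mid-range, the ligand sits low so its
# cohort distribution peaks at the bottom of the scale.
_BASE_LOG2 = {}
_BASE_LOG2.update({g: 10.0 for g in HK_GENES})
_BASE_LOG2.update({g: 8.0 for g in CONTROL_GENES})
_BASE_LOG2.update({g: 6.3 for g in IMMUNE_GENES})
_BASE_LOG2.update({"CD40": 7.0, "TNFRSF18": 6.0, "CD4": 6.8, "CD8A": 6.5, "CD40LG": 3.2})

MUTATION_GENES = [
    "TP53", "KRAS", "APC", "CDKN2A", "SMAD4", "ARID1A", "PIK3CA", "CCND1",
    "PTEN", "BRAF", "EGFR", "ERBB2", "MYC", "BRCA1", "BRCA2", "ATM",
    "RB1", "NF1", "FBXW7", "CTNNB1", "STK11", "KEAP1", "NOTCH1", "FGFR1",
    "CDK4", "MDM2", "GNAS", "SOX9", "TERT", "ARID2",
]

# Baseline log-odds chosen so marginal alteration frequencies echo the
# pan-cancer landscape (TP53 ~50%, KRAS ~22%, APC ~18%, ...).
DEFAULT_MUTATION_LOGODDS = {
    "TP53": 0.0, "KRAS": -1.25, "APC": -1.5, "CDKN2A": -1.8, "SMAD4": -2.1,
    "ARID1A": -2.1, "PIK3CA": -1.7, "CCND1": -2.6, "PTEN": -2.3, "BRAF": -2.4,
    "EGFR": -2.6, "ERBB2": -2.9, "MYC": -2.7, "BRCA1": -3.0, "BRCA2": -2.8,
    "ATM": -2.7, "RB1": -2.8, "NF1": -2.9, "FBXW7": -2.9, "CTNNB1": -2.9,
    "STK11": -3.1, "KEAP1": -3.2, "NOTCH1": -3.0, "FGFR1": -3.2, "CDK4": -3.3,
    "MDM2": -3.3, "GNAS": -3.2, "SOX9": -3.3, "TERT": -2.6, "ARID2": -3.2,
}

# APC alterations mark WNT-driven, immune-excluded tumors (negative link to
# the immune factor); CCND1 trends the other way.
DEFAULT_MUTATION_SLOPES = {g: 0.0 for g in MUTATION_GENES}
DEFAULT_MUTATION_SLOPES.update({"APC": -1.0, "CCND1": 0.35, "CTNNB1": -0.5})


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the emulated
    study conditions (735 reference + 514 study samples, colorectal-dominant
    type mix, checkpoint co-expression through one latent factor)."""

    seed: int = 0
    n_reference: int = 735
    n_study: int = 514
    cancer_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    genes: list[str] = field(default_factory=lambda: list(DEFAULT_GENES))
    hk_genes: list[str] = field(default_factory=lambda: list(HK_GENES))
    immune_factor_sd: float = 0.8
    gene_loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    type_shifts: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_SHIFTS)
    )
    residual_sd: float = 0.75          # per sample-gene log2 noise (non-HK)
    residual_sd_hk: float = 0.15       # housekeeping genes are stable
    depth_range: tuple[float, float] = (200_000.0, 1_000_000.0)
    background_rate: float = 5.0       # mean NTC counts per gene
    n_batches: int = 8
    clinical_fraction: float = 489 / 514   # samples with curated clinical data
    ici_fraction: float = 217 / 489        # treated subset among curated
    missing_rate_msi: float = 34 / 514
    missing_rate_tmb: float = 64 / 514
    mutation_genes: list[str] = field(default_factory=lambda: list(MUTATION_GENES))
    mutation_base_logodds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_LOGODDS)
    )
    mutation_factor_slope: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_SLOPES)
    )
    hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: {"immune_factor": -0.2}
    )
    censor_rate: float = 0.35
    # Baseline exponential hazards (per month) roughly matching advanced
    # pan-cancer medians: OS-from-advanced ~42 mo, OS-from-ICI ~18 mo,
    # PFS-from-ICI ~5 mo.
    baseline_hazards: dict[str, float] = field(
        default_factory=lambda: {"os_advanced": 0.0165, "os_ici": 0.0385, "pfs_ici": 0.14}
    )

    def __post_init__(self) -> None:
        total = sum(self.cancer_type_weights.values())
        if not self.cancer_type_weights or abs(total - 1.0) > 1e-9:
            raise ValueError(f"cancer_type_weights must sum to 1 (got {total})")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        for g in self.hk_genes:
            if g not in self.genes:
                raise ValueError(f"housekeeping gene {g!r} missing from panel")
            if self.gene_loadings.get(g, 0.0) != 0.0:
                raise ValueError("housekeeping genes must have zero immune-factor loading")
        for rate in (self.missing_rate_msi, self.missing_rate_tmb, self.censor_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class StudyCohort:
    """Raw counts plus the clinical table and binary mutation matrix."""

    raw: RawPanelCounts
    clinical: pd.DataFrame
    mutations: pd.DataFrame  # samples x genes, 0/1
    immune_factor: pd.Series  # latent factor (for diagnostics/tests only)


def _substream(config: SimulationConfig, label: str) -> np.random.Generator:
    """Independent deterministic stream per stage, all tied to config.seed."""
    offsets = {"reference": 1, "study": 2, "clinical": 3, "mutation": 4,
               "survival": 5, "genesets": 6}
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(offsets[label],)))


def _draw_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    prefix: str,
) -> tuple[RawPanelCounts, np.ndarray, np.ndarray]:
    """Draw raw counts with NTCs; returns (raw, latent factor, cancer types)."""
    genes = config.genes
    g = len(genes)
    types = np.array(list(config.cancer_type_weights))
    probs = np.array([config.cancer_type_weights[t] for t in types])
    cancer_type = rng.choice(types, size=n, p=probs)
    z = rng.normal(0.0, config.immune_factor_sd, size=n)

    base = np.array([_BASE_LOG2.get(gg, 7.0) for gg in genes])
    load = np.array([config.gene_loadings.get(gg, 0.0) for gg in genes])
    res_sd = np.array(
        [config.residual_sd_hk if gg in config.hk_genes else config.residual_sd for gg in genes]
    )
    shift = np.zeros((n, g))
    for (t, gg), s in config.type_shifts.items():
        if gg in genes:
            shift[cancer_type == t, genes.index(gg)] += s

    log2_abund = (
        base[None, :]
        + load[None, :] * z[:, None]
        + shift
        + rng.normal(0.0, 1.0, size=(n, g)) * res_sd[None, :]
    )
    abund = np.exp2(log2_abund)
    props = abund / abund.sum(axis=1, keepdims=True)
    depth = rng.uniform(*config.depth_range, size=n)
    lam = props * depth[:, None] + config.background_rate
    counts = rng.poisson(lam)

    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    batches = [f"batch{(i % config.n_batches) + 1}" for i in range(n)]
    ntc_of = {
        f"batch{b + 1}": rng.poisson(config.background_rate, size=g)
        for b in range(config.n_batches)
    }
    raw = RawPanelCounts(
        sample_ids=sample_ids,
        gene_ids=list(genes),
        counts=counts,
        batch_of=dict(zip(sample_ids, batches)),
        ntc_of=ntc_of,
    )
    return raw, z, cancer_type


def generate_reference(config: SimulationConfig) -> tuple[RawPanelCounts, ReferenceModel]:
    """Reference cohort counts plus the locked ReferenceModel built from them."""
    if config.n_reference < 10:
        raise ValueError("n_reference must be >= 10")
    rng = _substream(config, "reference")
    raw, _, _ = _draw_counts(config, rng, config.n_reference, "REF")
    model = build_reference_model(raw, config.hk_genes)
    return raw, model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_study_cohort(config: SimulationConfig) -> StudyCohort:
    """Study cohort: counts, clinical covariates, mutations, survival."""
    rng = _substream(config, "study")
    raw, z, cancer_type = _draw_counts(config, rng, config.n_study, "PT")
    n = config.n_study
    sample_ids = raw.sample_ids

    crng = _substream(config, "clinical")
    age = np.clip(crng.normal(61.0, 11.0, size=n), 21.0, 92.0)
    sex = np.where(crng.random(n) < 0.60, "female", "male")
    msi_unstable = crng.random(n) < 0.03
    # TMB (mutations/Mb): lognormal, inflated for MSI-unstable tumors;
    # dichotomized at >= 10.
    tmb = np.exp(crng.normal(1.2, 0.9, size=n)) * np.where(msi_unstable, 6.0, 1.0)
    tmb_high = tmb >= 10.0
    pdl1_positive = crng.random(n) < _sigmoid(-0.9 + 0.8 * z)

    # MAR missingness: probability depends only on the observed cancer type
    # (alternating type-specific multipliers around the target rate).
    type_list = sorted(config.cancer_type_weights)
    type_mult = {t: (0.5 if i % 2 == 0 else 1.5) for i, t in enumerate(type_list)}
    mult = np.array([type_mult[t] for t in cancer_type])
    msi_missing = crng.random(n) < np.clip(config.missing_rate_msi * mult, 0, 1)
    tmb_missing = crng.random(n) < np.clip(config.missing_rate_tmb * mult, 0, 1)

    has_clinical = crng.random(n) < config.clinical_fraction
    ici_treated = has_clinical & (crng.random(n) < config.ici_fraction)

    # Mutations: per-gene logistic link to the latent immune factor.
    mrng = _substream(config, "mutation")
    mut = {}
    for g in config.mutation_genes:
        logit = config.mutation_base_logodds.get(g, -2.5) + config.mutation_factor_slope.get(g, 0.0) * z
        mut[g] = (mrng.random(n) < _sigmoid(logit)).astype(int)
    mutations = pd.DataFrame(mut, index=sample_ids)

    # Survival under proportional hazards with exponential baselines.
    srng = _substream(config, "survival")
    covars = {"immune_factor": z, "age": (age - 61.0) / 10.0, "tmb_high": tmb_high.astype(float)}
    linpred = np.zeros(n)
    for name, coef in config.hazard_coefficients.items():
        if name not in covars:
            raise ValueError(f"unknown hazard covariate {name!r}")
        linpred += coef * covars[name]
    risk = np.exp(linpred)

    def _draw_endpoint(base_hazard: float, extra_rate: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        t_event = srng.exponential(1.0, size=n) / (base_hazard * risk * np.exp(extra_rate))
        if config.censor_rate <= 0:
            return t_event, np.ones(n, dtype=int)
        lam_c = base_hazard * config.censor_rate / max(1.0 - config.censor_rate, 1e-9)
        t_cens = srng.exponential(1.0 / lam_c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event

    os_adv_t, os_adv_e = _draw_endpoint(config.baseline_hazards["os_advanced"])
    os_ici_t, os_ici_e = _draw_endpoint(config.baseline_hazards["os_ici"])
    prog_t = srng.exponential(1.0, size=n) / (config.baseline_hazards["pfs_ici"] * risk)
    pfs_t = np.minimum(prog_t, os_ici_t)
    pfs_e = np.where(prog_t <= os_ici_t, 1, os_ici_e)

    clinical = pd.DataFrame(
        {
            "sample": sample_ids,
            "cancer_type": cancer_type,
            "age_years": np.round(age, 1),
            "sex": sex,
            "msi": np.where(msi_missing, None, np.where(msi_unstable, "unstable", "stable")),
            "tmb_high": np.where(tmb_missing, None, np.where(tmb_high, "true", "false")),
            "pdl1_positive": np.where(pdl1_positive, "true", "false"),
            "has_clinical": has_clinical,
            "ici_treated": ici_treated,
            "os_advanced_months": np.round(os_adv_t, 3),
            "os_advanced_event": os_adv_e,
            "os_ici_months": np.where(ici_treated, np.round(os_ici_t, 3), np.nan),
            "os_ici_event": np.where(ici_treated, os_ici_e, np.nan),
            "pfs_ici_months": np.where(ici_treated, np.round(pfs_t, 3), np.nan),
            "pfs_ici_event": np.where(ici_treated, pfs_e, np.nan),
        }
    )
    clinical.loc[~clinical["has_clinical"], [
        "os_advanced_months", "os_advanced_event",
        "os_ici_months", "os_ici_event", "pfs_ici_months", "pfs_ici_event",
    ]] = np.nan
    return StudyCohort(
        raw=raw,
        clinical=clinical,
        mutations=mutations,
        immune_factor=pd.Series(z, index=sample_ids, name="immune_factor"),
    )


def generate_gene_sets(config: SimulationConfig, n_sets: int = 50) -> dict[str, list[str]]:
    """Hallmark-like gene-set collection over the mutation-gene universe.

    Every mutation gene is covered by at least one set, and a TGF-beta-like
    set deliberately contains the WNT/TGF axis genes (APC, SMAD4, CTNNB1) so
    pathway-level enrichment has signal to find.
    """
    rng = _substream(config, "genesets")
    genes = list(config.mutation_genes)
    sets: dict[str, list[str]] = {
        "HALLMARK_TGF_BETA_SIGNALING": ["APC", "SMAD4", "CTNNB1"],
    }
    for i in range(n_sets - 1):
        size = int(rng.integers(4, min(15, len(genes)) + 1))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        sets[f"HALLMARK_SET_{i + 1:02d}"] = members
    # guarantee coverage of every mutation gene
    covered = set().union(*sets.values())
    leftovers = [g for g in genes if g not in covered]
    if leftovers:
        sets["HALLMARK_SET_01"] = sorted(set(sets["HALLMARK_SET_01"]) | set(leftovers))
    return sets


def write_fixtures(
    reference_raw: RawPanelCounts,
    model: ReferenceModel,
    cohort: StudyCohort,
    gene_sets: dict[str, list[str]],
    directory,
) -> dict[str, Path]:
    """Write counts.tsv, clinical.csv, mutations.tsv, hallmark_like.gmt and
    reference_model.json; all files round-trip through :mod:`immunorank.io`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_counts": directory / "reference_counts.tsv",
        "counts": directory / "counts.tsv",
        "clinical": directory / "clinical.csv",
        "mutations": directory / "mutations.tsv",
        "gmt": directory / "hallmark_like.gmt",
        "reference_model": directory / "reference_model.json",
    }
    irio.write_counts(reference_raw, paths["reference_counts"])
    irio.write_counts(cohort.raw, paths["counts"])
    irio.write_clinical(cohort.clinical, paths["clinical"])
    irio.write_mutations(cohort.mutations, paths["mutations"])
    irio.write_gmt(gene_sets, paths["gmt"])
    model.to_json(paths["reference_model"])
    return paths
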