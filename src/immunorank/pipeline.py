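"""End-to-end orchestration: simulate -> normalize -> associate ->
contrast -> enrich -> survive, with file-based stage hand-offs, input
validation, and a consolidated machine-readable report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as irio
from .association import (
    agonist_candidate_profile,
    binarize_high,
    combined_signature,
    crosstab_signature,
    landscape_by_type,
    multivariable_logistic_mi,
    spearman,
    univariable_screen,
)
from .contrast import log_transform, moderated_t_contrast, volcano_table, zscore_rows
from .enrichment import (
    bonferroni_topk_comparison,
    gene_level_enrichment,
    pathway_collapse,
    pathway_level_enrichment,
)
from .normalize import CATEGORY_HIGH, build_reference_model, percentile_table
from .simulate import (
    CONTROL_GENES,
    IMMUNE_GENES,
    SimulationConfig,
    generate_gene_sets,
    generate_reference,
    generate_study_cohort,
    write_fixtures,
)
from .survival import build_survival_cohorts, cox_fit, km_estimate, logrank_test

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "build_cohort_table", "load_report"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str = "immunorank_run"
    seed: int = 0
    gene_of_interest: str = "CD40"
    ligand_gene: str = "CD40LG"
    screen_alpha: float = 0.05
    mi_imputations: int = 20
    mi_burn_in: int = 10
    landscape_min_samples: int = 11
    profile_min_samples: int = 20
    enrichment_min_altered: int = 3
    topk: int = 20
    survival_covariates: list[str] = field(default_factory=lambda: ["age_ge_61", "pdl1_pos"])
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.screen_alpha < 1:
            raise ValueError("screen_alpha must lie in (0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        def _clean(o):
            if isinstance(o, dict):
                return {str(k): _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o

        blob = json.dumps(_clean(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def build_cohort_table(clinical: pd.DataFrame, percentiles: pd.DataFrame) -> pd.DataFrame:
    """Merge the clinical table with per-gene ranks and categories."""
    ranks = irio.percentiles_wide(percentiles, "rank").add_prefix("rank_")
    cats = irio.percentiles_wide(percentiles, "category").add_prefix("category_")
    table = clinical.set_index("sample").join(ranks).join(cats).reset_index()
    return table.rename(columns={"index": "sample"})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def _km_summary(rec: pd.DataFrame, mask: np.ndarray) -> dict:
    est = km_estimate(rec.loc[mask, "time_months"], rec.loc[mask, "event"])
    return {
        "n": est.n,
        "n_events": est.n_events,
        "median": est.median,
        "median_ci": list(est.median_ci),
        "curve_times": est.times.tolist(),
        "curve_survival": est.survival.tolist(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    goi = config.gene_of_interest
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    }

    # --- simulate ------------------------------------------------------
    sim = config.simulation
    ref_raw, model = generate_reference(sim)
    cohort = generate_study_cohort(sim)
    gene_sets = generate_gene_sets(sim)
    paths = write_fixtures(ref_raw, model, cohort, gene_sets, out / "data")
    report["simulate"] = {
        "n_reference": ref_raw.n_samples,
        "n_study": cohort.raw.n_samples,
        "files": {k: str(v) for k, v in paths.items()},
    }

    # --- normalize -----------------------------------------------------
    percentiles, qc_failures = percentile_table(cohort.raw, model)
    irio.write_percentiles(percentiles, out / "percentiles.tsv")
    report["normalize"] = {
        "n_ranked": percentiles["sample"].nunique(),
        "qc_failures": [dataclasses.asdict(f) for f in qc_failures],
    }

    # --- associate -----------------------------------------------------
    table = build_cohort_table(cohort.clinical, percentiles)
    high = binarize_high(table, goi).astype(bool)
    landscape = landscape_by_type(table, goi, config.landscape_min_samples)
    landscape.to_csv(out / "landscape.tsv", sep="\t", index=False)
    profile = agonist_candidate_profile(
        table, goi, config.ligand_gene, config.profile_min_samples
    )
    uni_results, selected = univariable_screen(
        table, goi, IMMUNE_GENES, alpha=config.screen_alpha
    )

    design = pd.DataFrame(index=table.index)
    for name in selected:
        if name.startswith("cancer_type:"):
            design[name] = (table["cancer_type"] == name.split(":", 1)[1]).astype(float)
        elif name.startswith("rna:"):
            design[name] = binarize_high(table, name.split(":", 1)[1]).astype(float)
        elif name == "age":
            design[name] = (table["age_years"] >= 61).astype(float)
        elif name == "sex":
            design[name] = (table["sex"] == "male").astype(float)
        elif name == "msi":
            design[name] = (table["msi"] == "unstable").where(table["msi"].notna()).astype(float)
        elif name == "tmb":
            design[name] = (
                (table["tmb_high"].astype(str) == "true").where(table["tmb_high"].notna()).astype(float)
            )
        elif name == "pdl1_ihc":
            design[name] = (table["pdl1_positive"].astype(str) == "true").astype(float)
    multi_results = (
        multivariable_logistic_mi(
            design, high.astype(int),
            m=config.mi_imputations, burn_in=config.mi_burn_in,
            seed=config.seed + 1_000_003,
        )
        if not design.empty
        else []
    )
    rho_cd28, p_cd28 = spearman(table[f"rank_{goi}"], table["rank_CD28"])
    rho_gitr, p_gitr = spearman(table[f"rank_{goi}"], table["rank_TNFRSF18"])
    sig = combined_signature(table)
    crosstab = crosstab_signature(high, sig)
    report["associate"] = {
        "high_fraction": float(high.mean()),
        "landscape": landscape,
        "agonist_profile": profile,
        "univariable": uni_results,
        "selected": selected,
        "multivariable": multi_results,
        "spearman": {
            "CD28": {"rho": rho_cd28, "p": p_cd28},
            "GITR": {"rho": rho_gitr, "p": p_gitr},
        },
        "cd4_cd8_crosstab": crosstab,
    }

    # --- contrast ------------------------------------------------------
    nrpm_wide = irio.percentiles_wide(percentiles, "nrpm")
    nrpm_wide = nrpm_wide.loc[table["sample"]]
    expr = pd.DataFrame(
        log_transform(nrpm_wide.to_numpy()), index=nrpm_wide.index, columns=nrpm_wide.columns
    )
    gene_class = {g: "checkpoint" for g in IMMUNE_GENES}
    gene_class.update({g: "non_immune_control" for g in CONTROL_GENES})
    contrast_res = moderated_t_contrast(expr, high.to_numpy(), gene_class=gene_class)
    contrast_res.to_csv(out / "contrast.tsv", sep="\t", index=False)
    zmat = zscore_rows(expr.T)
    zmat.to_csv(out / "zscores.tsv", sep="\t")
    volcano = volcano_table(contrast_res)
    report["contrast"] = {
        "prior_df": contrast_res.attrs["prior_df"],
        "n_deg": int(contrast_res["is_deg"].sum()),
        "results": contrast_res,
        "volcano": volcano,
    }

    # --- enrich --------------------------------------------------------
    mutations = cohort.mutations.loc[table["sample"]]
    gene_enr = gene_level_enrichment(
        mutations, high.to_numpy(), config.enrichment_min_altered
    )
    collapsed = pathway_collapse(mutations, gene_sets)
    path_enr = pathway_level_enrichment(collapsed, high.to_numpy())
    topk_table, threshold = bonferroni_topk_comparison(mutations, high.to_numpy(), config.topk)
    pd.DataFrame([dataclasses.asdict(r) for r in gene_enr]).to_csv(
        out / "enrichment_gene.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(r) for r in path_enr]).to_csv(
        out / "enrichment_pathway.tsv", sep="\t", index=False
    )
    topk_table.to_csv(out / "topk_comparison.tsv", sep="\t", index=False)
    report["enrich"] = {
        "gene": gene_enr,
        "pathway": path_enr,
        "topk": topk_table,
        "bonferroni_threshold": threshold,
        "topk_union_size": topk_table.attrs["union_size"],
    }

    # --- survive -------------------------------------------------------
    meta = table.set_index("sample")
    cohorts, rejected = build_survival_cohorts(cohort.clinical)
    surv_report: dict = {"rejected_samples": rejected}
    for name, rec in cohorts.items():
        rec = rec.join(meta[[f"rank_{goi}", f"category_{goi}", "age_years", "pdl1_positive"]], on="sample")
        rec["high"] = rec[f"category_{goi}"] == CATEGORY_HIGH
        rec["age_ge_61"] = (rec["age_years"] >= 61).astype(float)
        rec["pdl1_pos"] = (rec["pdl1_positive"].astype(str) == "true").astype(float)
        entry: dict = {
            "km_high": _km_summary(rec, rec["high"].to_numpy()),
            "km_low_moderate": _km_summary(rec, (~rec["high"]).to_numpy()),
        }
        chi2, p = logrank_test(rec["time_months"], rec["event"], rec["high"])
        entry["logrank"] = {"chi2": chi2, "p": p}
        rec["high_f"] = rec["high"].astype(float)
        fit_bin = cox_fit(
            rec, "time_months", "event", ["high_f", *config.survival_covariates]
        )
        fit_cont = cox_fit(rec, "time_months", "event", [f"rank_{goi}"])
        entry["cox_binary"] = fit_bin.coefficients
        entry["cox_continuous_rank"] = fit_cont.coefficients
        surv_report[name] = entry
    report["survive"] = surv_report

    report_json = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report_json, fh, indent=1)
    return report_json


def load_report(path) -> dict:
    """Load a report, failing loudly on a newer schema."""
    with open(path) as fh:
        report = json.load(fh)
    version = report.get("schema_version")
    if version is None or version > SCHEMA_VERSION:
        raise ValueError(
            f"report schema {version!r} is newer than supported ({SCHEMA_VERSION})"
        )
    return report


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Cross-file consistency checks; returns a list of violations."""
    violations: list[str] = []
    raw = clinical = percentiles = mutations = None
    try:
        if "counts" in paths:
            raw = irio.read_counts(paths["counts"])
    except Exception as exc:
        violations.append(f"counts unreadable: {exc}")
    try:
        if "clinical" in paths:
            clinical = irio.read_clinical(paths["clinical"])
    except Exception as exc:
        violations.append(f"clinical unreadable: {exc}")
    try:
        if "percentiles" in paths:
            percentiles = irio.read_percentiles(paths["percentiles"])
    except Exception as exc:
        violations.append(f"percentiles unreadable: {exc}")
    try:
        if "mutations" in paths:
            mutations = irio.read_mutations(paths["mutations"])
    except Exception as exc:
        violations.append(f"mutations unreadable: {exc}")
    try:
        if "gmt" in paths:
            irio.read_gmt(paths["gmt"])
    except Exception as exc:
        violations.append(f"gmt unreadable: {exc}")

    if raw is not None and clinical is not None:
        known = set(raw.sample_ids)
        for sid in clinical["sample"]:
            if sid not in known:
                violations.append(f"clinical sample {sid!r} absent from counts")
    if raw is not None and mutations is not None:
        known = set(raw.sample_ids)
        for sid in mutations.index:
            if sid not in known:
                violations.append(f"mutation sample {sid!r} absent from counts")
    if percentiles is not None:
        bad = percentiles[(percentiles["rank"] < 0) | (percentiles["rank"] > 100)]
        for _, row in bad.iterrows():
            violations.append(
                f"rank {row['rank']} outside [0, 100] for sample {row['sample']!r} gene {row['gene']!r}"
            )
        from .normalize import categorize

        in_range = percentiles[percentiles["rank"].between(0, 100)]
        mismatch = in_range[in_range["category"] != in_range["rank"].map(categorize)]
        for _, row in mismatch.iterrows():
            violations.append(
                f"category {row['category']!r} inconsistent with rank {row['rank']} "
                f"for sample {row['sample']!r} gene {row['gene']!r}"
            )
    return violations
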