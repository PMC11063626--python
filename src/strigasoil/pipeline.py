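"""End-to-end pipeline: simulate -> screen -> fit -> rank -> match.

Each stage reads and writes plain tabular files under the configured output
directory and contributes to a machine-readable run report.  Stages can be
run standalone (see :mod:`strigasoil.cli`) on a prior stage's files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import joint, matching, ranking, simulate as sim, traits as trait_stats
from .datasets import FeatureTable, ProductMassList, TaxaCountTable, TraitTable

log = logging.getLogger("strigasoil")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings (YAML/JSON share this schema)."""

    out_dir: str = "strigasoil_run"
    seed: int = 0
    alpha: float = 0.05
    simulate: dict | None = field(default_factory=dict)  # SimConfig overrides; None = read inputs
    inputs: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    taxa_filter: dict = field(default_factory=lambda: {"min_prevalence": 0.2, "max_taxa": 100})
    ranking: dict = field(default_factory=lambda: {"thr": 0.2, "k": 100})
    matching: dict = field(
        default_factory=lambda: {"tol_ppm": 25.0, "test": "welch", "alpha": 0.05, "lfc": 1.0}
    )
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.ranking.get("thr", 0.2) <= 0 or self.ranking.get("k", 100) <= 0:
            raise ConfigError("ranking thresholds must be positive")
        if self.matching.get("tol_ppm", 25.0) <= 0:
            raise ConfigError("tol_ppm must be positive")
        if self.simulate is None:
            required = ("counts", "metadata", "taxonomy", "traits")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ConfigError(f"not simulating and missing input paths: {missing}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ConfigError(f"input file for {key!r} does not exist: {path}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_tables(
    paths: dict,
) -> tuple[TaxaCountTable, TraitTable, FeatureTable | None, ProductMassList | None]:
    """Load and cross-validate the pipeline input tables."""
    taxa = TaxaCountTable.read(paths["counts"], paths["metadata"], paths["taxonomy"])
    trait_table = TraitTable.read(paths["traits"], paths["metadata"])
    features = products = None
    if "features" in paths and "feature_groups" in paths:
        features = FeatureTable.read(paths["features"], paths["feature_groups"])
    if "products" in paths:
        products = ProductMassList.read(paths["products"])
    return taxa, trait_table, features, products


def _mcmc_for_bundle(config: PipelineConfig, bundle_index: int) -> joint.McmcSettings:
    # per-bundle chain seeds derived deterministically from the run seed
    seed = (config.seed * 1_000 + 17 * bundle_index + 1) % (2**31 - 1)
    return joint.McmcSettings(seed=seed, **config.mcmc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {
        "parameters": {
            "seed": config.seed,
            "alpha": config.alpha,
            "mcmc": dict(config.mcmc),
            "taxa_filter": dict(config.taxa_filter),
            "ranking": dict(config.ranking),
            "matching": dict(config.matching),
            "simulated": config.simulate is not None,
        },
        "stages": {},
        "warnings": [],
    }
    manifest: list[str] = []

    # ---- stage: simulate or load --------------------------------------
    truth = feature_truth = None
    if config.simulate is not None:
        sim_config = sim.SimConfig(seed=config.seed, **config.simulate)
        log.info("simulating dataset (seed=%d, %d taxa)", config.seed, sim_config.n_taxa)
        taxa, trait_table, truth = sim.simulate_dataset(sim_config)
        features, products, feature_truth = sim.simulate_feature_table(
            sim_config, tol_ppm=config.matching.get("tol_ppm", 25.0)
        )
        for path in taxa.write(out_dir).values():
            manifest.append(path.name)
        manifest.append(trait_table.write(out_dir).name)
        for path in features.write(out_dir).values():
            manifest.append(path.name)
        manifest.append(products.write(out_dir).name)
        truth.to_json(out_dir / "ground_truth.json")
        feature_truth.to_json(out_dir / "feature_ground_truth.json")
        manifest += ["ground_truth.json", "feature_ground_truth.json"]
        report["stages"]["simulate"] = {
            "n_samples": len(taxa.samples),
            "n_taxa": len(taxa.taxa),
            "planted_suppressive_taxa": truth.suppressive_taxa,
        }
    else:
        taxa, trait_table, features, products = read_tables(config.inputs)
        report["stages"]["load"] = {
            "n_samples": len(taxa.samples),
            "n_taxa": len(taxa.taxa),
        }

    # ---- stage: trait screen ------------------------------------------
    screen = trait_stats.screen_traits(trait_table, alpha=config.alpha)
    screen_path = out_dir / "trait_screen.tsv"
    screen.to_csv(screen_path, sep="\t", index=False)
    manifest.append(screen_path.name)
    soil_only = {
        tp: trait_stats.soil_only_traits(screen, tp)
        for tp in sorted(trait_table.metadata["timepoint"].unique())
    }
    report["stages"]["screen"] = {
        "labels": {f"{r.trait}@{r.timepoint}": r.label for r in screen.itertuples()},
        "soil_only": soil_only,
    }
    forwarded = {
        tp: [t for t in names if t != sim.STRIGA] for tp, names in soil_only.items()
    }
    if not any(forwarded.values()):
        report["status"] = "stopped_after_screen"
        report["stages"]["screen"]["note"] = (
            "no trait classified soil_only: the joint model has no "
            "microbiome-dependent trait to explain"
        )
        _write_report(report, manifest, out_dir)
        return report

    # ---- stage: joint fits --------------------------------------------
    sub_categories = sorted(taxa.metadata["sub_category"].unique())
    timepoints = sorted(taxa.metadata["timepoint"].unique())
    rank_frames, top_summaries = [], {}
    candidates = ranking.CandidateSet()
    fit_meta = {}
    bundle_index = 0
    for sub_category in sub_categories:
        for tp in timepoints:
            bundle_index += 1
            bundle_traits = forwarded.get(tp, [])
            # the attachments column is always part of the response matrix:
            # it anchors the combined ranking
            fit_traits = [sim.STRIGA] + bundle_traits
            measured = trait_table.subset(sub_category, tp).values.columns
            fit_traits = [t for t in fit_traits if t in measured]
            if sim.STRIGA not in fit_traits or len(fit_traits) < 2:
                log.info("skipping %s/%s: no usable soil_only traits", sub_category, tp)
                continue
            log.info("fitting %s/%s with traits %s", sub_category, tp, fit_traits)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = joint.fit_bundle(
                    taxa,
                    trait_table,
                    sub_category,
                    tp,
                    fit_traits,
                    mcmc=_mcmc_for_bundle(config, bundle_index),
                    min_prevalence=config.taxa_filter.get("min_prevalence", 0.2),
                    max_taxa=config.taxa_filter.get("max_taxa", 100),
                )
            for w in caught:
                report["warnings"].append(f"{sub_category}/{tp}: {w.message}")
            resid = fit.resid_corr
            resid_path = out_dir / f"resid_corr_{sub_category}_{tp}.tsv"
            resid.round(6).to_csv(resid_path, sep="\t", index_label="response")
            manifest.append(resid_path.name)
            contrasts = joint.contrast_h1_h2(fit)
            contrasts_path = out_dir / f"contrasts_{sub_category}_{tp}.tsv"
            contrasts.round(6).to_csv(contrasts_path, sep="\t", index=False)
            manifest.append(contrasts_path.name)
            fit_meta[f"{sub_category}@{tp}"] = {
                "n_taxa_fit": sum(1 for r in fit.column_roles.values() if r == "taxon"),
                "traits": fit_traits,
                "n_draws": fit.n_draws,
                "geweke_max_abs_z": round(max(abs(z) for z in fit.geweke_z.values()), 3),
            }

            taxa_cols = [r for r, role in fit.column_roles.items() if role == "taxon"]
            ranks = ranking.rank_table(resid, taxa_cols, sub_category, tp)
            rank_frames.append(ranks)
            for trait in [t for t in fit_traits if t != sim.STRIGA]:
                combo = (
                    ranks[ranks["trait"] == trait]
                    .dropna(subset=["combined_rank"])
                    .set_index("taxon")["combined_rank"]
                )
                summary = ranking.top_k_summary(
                    combo, taxa.taxonomy, k=config.ranking.get("k", 100)
                )
                top_summaries[f"{sub_category}@{tp}@{trait}"] = summary.to_dict()
            candidates = candidates.merge(
                ranking.select_candidate_genera(
                    resid,
                    taxa_cols,
                    taxa.taxonomy,
                    thr=config.ranking.get("thr", 0.2),
                    sub_category=sub_category,
                    timepoint=tp,
                )
            )
    report["stages"]["fit"] = fit_meta
    if not rank_frames:
        report["status"] = "stopped_after_fit"
        _write_report(report, manifest, out_dir)
        return report

    rank_all = pd.concat(rank_frames, ignore_index=True)
    rank_path = out_dir / "rank_table.tsv"
    rank_all.round(6).to_csv(rank_path, sep="\t", index=False)
    manifest.append(rank_path.name)
    candidates.to_json(out_dir / "candidates.json")
    candidates.to_frame().to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    manifest += ["candidates.json", "candidates.tsv"]
    report["stages"]["rank"] = {
        "candidate_genera": {g: sorted(m) for g, m in candidates.candidates.items()},
        "top_k_class_summaries": top_summaries,
    }

    # ---- stage: HIF matching ------------------------------------------
    if features is not None and products is not None:
        matches = matching.match_features(
            features, products, tol_ppm=config.matching.get("tol_ppm", 25.0)
        )
        matches_path = out_dir / "hif_matches.tsv"
        matches.round(6).to_csv(matches_path, sep="\t", index=False)
        manifest.append(matches_path.name)
        differential = matching.differential_features(
            features,
            matches,
            test=config.matching.get("test", "welch"),
            alpha=config.matching.get("alpha", 0.05),
            lfc=config.matching.get("lfc", 1.0),
        )
        diff_path = out_dir / "hif_differential.tsv"
        differential.round(6).to_csv(diff_path, sep="\t", index=False)
        manifest.append(diff_path.name)
        frac_up = matching.significant_fraction_up(differential)
        report["stages"]["match"] = {
            "n_matched_pairs": int(len(matches)),
            "n_matched_features": int(matches["feature_id"].nunique()),
            "n_significant": int(differential["significant"].sum()),
            "fraction_up_in_natural": None if pd.isna(frac_up) else round(frac_up, 4),
        }

    # ---- planted-truth comparison (simulated runs only) ----------------
    if truth is not None:
        recovered = _planted_recovery(rank_all, truth)
        comparison: dict = {"suppressive_taxa_in_top10": recovered}
        if feature_truth is not None and "match" in report["stages"]:
            flagged = set(differential.loc[differential["significant"], "feature_id"])
            comparison["differential_features_recovered"] = sorted(
                set(feature_truth.differential_feature_ids) & flagged
            )
            comparison["differential_features_planted"] = (
                feature_truth.differential_feature_ids
            )
        report["truth_comparison"] = comparison

    report["status"] = "ok"
    _write_report(report, manifest, out_dir)
    return report


def _planted_recovery(rank_all: pd.DataFrame, truth: sim.GroundTruth) -> dict[str, bool]:
    """Is each planted suppressive taxon in a combined-rank top 10 somewhere?"""
    recovered = {}
    for taxon in truth.suppressive_taxa:
        hit = False
        for (sub, tp, trait), grp in rank_all.groupby(["sub_category", "timepoint", "trait"]):
            combo = grp.dropna(subset=["combined_rank"]).set_index("taxon")["combined_rank"]
            if taxon not in combo.index or len(combo) == 0:
                continue
            top = combo.sort_values(ascending=False).head(10).index
            if taxon in top:
                hit = True
                break
        recovered[taxon] = hit
    return recovered


def _write_report(report: dict, manifest: list[str], out_dir: Path) -> None:
    manifest = sorted(set(manifest + ["run_report.json", "manifest.json"]))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
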