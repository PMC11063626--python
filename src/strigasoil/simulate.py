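"""Seeded synthetic datasets with the factorial soil x Striga design.

The generator emulates the structure of the greenhouse experiment: two soils
(natural / sterilized) crossed with two Striga treatments (infected / control)
at two infection timepoints, sampled in up to four microbiome sub-categories
(bulk soil, rhizosphere, soil-plug-associated roots, sand-associated roots).

Responses (taxa and traits) are drawn jointly on a latent Gaussian scale,

    Z = X B + E,    E ~ MN(0, I_n, Sigma),

where ``Sigma`` is a correlation matrix carrying the *planted* residual
correlations between taxa and traits: the ground truth that downstream
residual-correlation estimation is meant to recover.  Taxon latents are mapped
to sequencing counts through a logistic-normal multinomial (softmax of the
latent plus a fixed per-taxon log-abundance offset, multinomial at a fixed
library size), so the planted correlations live on the same latent scale the
joint model estimates.  Soil sterilization is modeled as taxon dropout (a
seeded subset of taxa absent from all sterilized samples) plus per-taxon soil
mean shifts, which reproduces the reduced alpha diversity of the
gamma-irradiated soil.

All randomness flows from the single integer ``SimConfig.seed`` through a
fixed ``numpy.random.SeedSequence`` spawning order (taxon parameters, dropout,
then one stream per sub-category x timepoint bundle, then features), so equal
configs give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import FeatureTable, ProductMassList, TaxaCountTable, TraitTable

STRIGA = "striga_attachments"
AERENCHYMA = "aerenchyma"
SUBERIN = "suberin"
HIF_SYRINGIC = "hif_syringic"
HIF_VANILLIC = "hif_vanillic"

#: traits measured at each infection timepoint (suberin only scored at 3 wpi)
TRAITS_BY_TIMEPOINT: dict[str, tuple[str, ...]] = {
    "2wpi": (STRIGA, AERENCHYMA, HIF_SYRINGIC, HIF_VANILLIC),
    "3wpi": (STRIGA, AERENCHYMA, SUBERIN),
}

DEFAULT_SUB_CATEGORIES = ("bulk_soil", "rhizosphere", "soilplug_roots", "sand_roots")

# Genus pool for synthetic taxonomy; the first three are reserved for the
# default planted suppressive taxa.
_GENUS_POOL = [
    ("Actinobacteriota", "Actinobacteria", "Arthrobacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonas"),
    ("Actinobacteriota", "Actinobacteria", "Aeromicrobium"),
    ("Proteobacteria", "Alphaproteobacteria", "Bradyrhizobium"),
    ("Proteobacteria", "Alphaproteobacteria", "Mesorhizobium"),
    ("Firmicutes", "Bacilli", "Paenibacillus"),
    ("Actinobacteriota", "Actinobacteria", "Nocardia"),
    ("Proteobacteria", "Alphaproteobacteria", "Phenylobacterium"),
    ("Bacteroidota", "Bacteroidia", "Flavobacterium"),
    ("Proteobacteria", "Deltaproteobacteria", "Myxococcus"),
    ("Acidobacteriota", "Acidobacteriae", "Edaphobacter"),
    ("Verrucomicrobiota", "Verrucomicrobiae", "Opitutus"),
]


def _default_planted_corr() -> list[tuple[str, str, float]]:
    # three suppressive taxa, one per mechanism (HIF degradation, suberin,
    # aerenchyma); |rho| = 0.5 keeps the implied matrix positive definite
    return [
        ("OTU_0001", STRIGA, -0.5),
        ("OTU_0001", HIF_SYRINGIC, -0.5),
        ("OTU_0002", STRIGA, -0.5),
        ("OTU_0002", SUBERIN, 0.5),
        ("OTU_0003", STRIGA, -0.5),
        ("OTU_0003", AERENCHYMA, 0.5),
    ]


def _default_trait_corr() -> list[tuple[str, str, float]]:
    # trait-trait residual correlations consistent with the planted taxa:
    # more aerenchyma/suberin goes with fewer attachments, more HIF with more
    return [
        (STRIGA, AERENCHYMA, -0.4),
        (STRIGA, SUBERIN, -0.4),
        (STRIGA, HIF_SYRINGIC, 0.4),
        (STRIGA, HIF_VANILLIC, 0.4),
        (AERENCHYMA, SUBERIN, 0.3),
        (AERENCHYMA, HIF_SYRINGIC, -0.2),
        (AERENCHYMA, HIF_VANILLIC, -0.2),
        (HIF_SYRINGIC, HIF_VANILLIC, 0.3),
    ]


def _default_trait_intercepts() -> dict[str, float]:
    return {STRIGA: 4.0, AERENCHYMA: 10.0, SUBERIN: 10.0, HIF_SYRINGIC: 10.0, HIF_VANILLIC: 10.0}


def _default_soil_effects() -> dict[str, float]:
    # effect of natural (vs sterilized) soil: fewer attachments and HIFs,
    # more aerenchyma and suberin
    return {STRIGA: -2.0, AERENCHYMA: 1.5, SUBERIN: 1.5, HIF_SYRINGIC: -1.5, HIF_VANILLIC: -1.5}


def _default_striga_effects() -> dict[str, float]:
    return {STRIGA: 3.0, AERENCHYMA: 0.0, SUBERIN: 0.0, HIF_SYRINGIC: 0.0, HIF_VANILLIC: 0.0}


@dataclass
class PlantedFeature:
    """One metabolomics feature planted at a ppm offset from a product mass."""

    product_id: str
    offset_ppm: float
    log2_fc: float  # natural vs sterilized group means
    base_area: float = 1.0e5


def _default_feature_plant() -> list[PlantedFeature]:
    # scaled-down version of the exudate screen: 12 in-window features of
    # which 6 are differential (4 up in natural, 2 down), plus 3 near-misses
    # outside the 25 ppm window
    return [
        PlantedFeature("gallic_acid", 0.0, 2.0),
        PlantedFeature("pyrogallol", 2.0, 2.5),
        PlantedFeature("protocatechuic_acid", -3.0, 1.5),
        PlantedFeature("catechol", 5.0, 2.0),
        PlantedFeature("guaiacol", -8.0, -1.5),
        PlantedFeature("syringol", 12.0, -2.0),
        PlantedFeature("vanillyl_alcohol", 18.0, 0.0),
        PlantedFeature("methylgallate", 24.0, 0.0),
        PlantedFeature("dimethoxyhydroquinone", -15.0, 0.5),
        PlantedFeature("acetovanillone", 7.0, -0.5),
        PlantedFeature("vanillic_acid_prod", -20.0, 0.0),
        PlantedFeature("catechol", 25.0, 0.0),
        PlantedFeature("gallic_acid", 30.0, 2.0),
        PlantedFeature("pyrogallol", -40.0, 2.0),
        PlantedFeature("guaiacol", 35.0, 0.0),
    ]


# Predicted microbial conversion products of the five HIFs, with exact neutral
# monoisotopic masses (Da).  Demethylation / decarboxylation / reduction
# chemistry typical of soil bacteria acting on phenolics.
_DEFAULT_PRODUCTS = [
    # parent, product_id, formula, exact_mass, level
    ("syringic_acid", "gallic_acid", "C7H6O5", 170.02152, 1),
    ("syringic_acid", "methylgallate", "C8H8O5", 184.03717, 1),
    ("syringic_acid", "pyrogallol", "C6H6O3", 126.03169, 2),
    ("vanillic_acid", "protocatechuic_acid", "C7H6O4", 154.02661, 1),
    ("vanillic_acid", "guaiacol", "C7H8O2", 124.05243, 1),
    ("vanillic_acid", "catechol", "C6H6O2", 110.03678, 2),
    ("vanillin", "vanillyl_alcohol", "C8H10O3", 154.06299, 1),
    ("vanillin", "vanillic_acid_prod", "C8H8O4", 168.04226, 1),
    ("DMBQ", "dimethoxyhydroquinone", "C8H10O4", 170.05791, 1),
    ("acetosyringone", "acetovanillone", "C9H10O3", 166.06299, 1),
    ("acetosyringone", "syringol", "C8H10O3", 154.06299, 2),
]


def default_product_list() -> ProductMassList:
    """Built-in predicted conversion-product masses for the five HIFs."""
    return ProductMassList(
        products=pd.DataFrame(
            _DEFAULT_PRODUCTS,
            columns=["parent", "product_id", "formula", "exact_mass", "level"],
        )
    )


class SimConfigError(ValueError):
    """Raised when a simulation config is inconsistent or implies a non-PD Sigma."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the experimental design: 2 soils x 2 Striga treatments,
    two timepoints, six replicates per cell (the phenotyping replication),
    four sub-categories, and three planted suppressive taxa.
    """

    n_taxa: int = 50
    n_replicates: int = 6
    sub_categories: tuple[str, ...] = DEFAULT_SUB_CATEGORIES
    timepoints: tuple[str, ...] = ("2wpi", "3wpi")
    traits_by_timepoint: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(TRAITS_BY_TIMEPOINT)
    )
    planted_corr: list[tuple[str, str, float]] = field(default_factory=_default_planted_corr)
    trait_corr: list[tuple[str, str, float]] = field(default_factory=_default_trait_corr)
    trait_intercepts: dict[str, float] = field(default_factory=_default_trait_intercepts)
    soil_effects: dict[str, float] = field(default_factory=_default_soil_effects)
    striga_effects: dict[str, float] = field(default_factory=_default_striga_effects)
    interaction_effects: dict[str, float] = field(default_factory=dict)
    taxa_soil_effect_sd: float = 0.5
    taxa_striga_effect_sd: float = 0.2
    taxa_base_abundance_sd: float = 1.5
    sterilized_diversity_drop: float = 0.3
    library_size: int = 20000
    feature_plant: list[PlantedFeature] = field(default_factory=_default_feature_plant)
    n_feature_decoys: int = 10
    n_feature_replicates: int = 4
    feature_noise_sd: float = 0.25
    seed: int = 0

    def taxon_ids(self) -> list[str]:
        return [f"OTU_{i + 1:04d}" for i in range(self.n_taxa)]

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise SimConfigError("n_replicates must be >= 2")
        if not 0.0 <= self.sterilized_diversity_drop <= 1.0:
            raise SimConfigError("sterilized_diversity_drop must be in [0, 1]")
        if self.library_size <= 0:
            raise SimConfigError("library_size must be positive")
        taxa = set(self.taxon_ids())
        # planted entries for traits outside the configured timepoints are
        # allowed (and ignored) so defaults survive timepoint restriction
        traits = {t for tps in self.traits_by_timepoint.values() for t in tps}
        traits |= {t for tps in TRAITS_BY_TIMEPOINT.values() for t in tps}
        for taxon, trait, rho in self.planted_corr:
            if abs(rho) >= 1:
                raise SimConfigError(f"planted |rho| must be < 1, got {rho} for {taxon}/{trait}")
            if taxon not in taxa:
                raise SimConfigError(f"planted taxon {taxon!r} not among the {self.n_taxa} taxa")
            if trait not in traits:
                raise SimConfigError(f"planted trait {trait!r} not in {sorted(traits)}")
        for a, b, rho in self.trait_corr:
            if abs(rho) >= 1:
                raise SimConfigError(f"trait |rho| must be < 1, got {rho} for {a}/{b}")
        # building Sigma verifies positive definiteness for every timepoint
        for tp in self.timepoints:
            self.build_sigma(tp)

    def build_sigma(self, timepoint: str) -> pd.DataFrame:
        """Residual correlation matrix over [taxa | traits] for one timepoint.

        Raises :class:`SimConfigError` if the implied matrix is not positive
        definite (checked by Cholesky factorization).
        """
        traits = list(self.traits_by_timepoint[timepoint])
        ids = self.taxon_ids() + traits
        sigma = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        present = set(ids)
        for a, b, rho in self.trait_corr:
            if a in present and b in present:
                sigma.loc[a, b] = sigma.loc[b, a] = rho
        for taxon, trait, rho in self.planted_corr:
            if trait in present:
                sigma.loc[taxon, trait] = sigma.loc[trait, taxon] = rho
        try:
            np.linalg.cholesky(sigma.to_numpy())
        except np.linalg.LinAlgError:
            raise SimConfigError(
                f"implied residual covariance for timepoint {timepoint!r} is not "
                "positive definite; reduce planted |rho| or adjust trait_corr"
            ) from None
        return sigma


@dataclass
class GroundTruth:
    """Planted parameters behind a simulated dataset."""

    planted_corr: list[tuple[str, str, float]]
    trait_corr: list[tuple[str, str, float]]
    coefficients: dict[str, pd.DataFrame]  # timepoint -> (4 x q) B matrix
    sigma: dict[str, pd.DataFrame]  # timepoint -> (q x q) residual correlation
    suppressive_taxa: list[str]
    dropout_taxa: list[str]
    latents: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_corr": [list(t) for t in self.planted_corr],
            "trait_corr": [list(t) for t in self.trait_corr],
            "suppressive_taxa": self.suppressive_taxa,
            "dropout_taxa": self.dropout_taxa,
            "coefficients": {tp: b.round(10).to_dict() for tp, b in self.coefficients.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


DESIGN_ROWS = ("intercept", "soil_natural", "striga_infected", "interaction")


def _design_for_cells(metadata: pd.DataFrame) -> np.ndarray:
    soil = (metadata["soil"] == "natural").to_numpy(float)
    striga = (metadata["striga"] == "infected").to_numpy(float)
    return np.column_stack([np.ones(len(metadata)), soil, striga, soil * striga])


def _build_coefficients(config: SimConfig, timepoint: str, rng_taxa: np.random.Generator,
                        taxa_soil: np.ndarray, taxa_striga: np.ndarray) -> pd.DataFrame:
    traits = list(config.traits_by_timepoint[timepoint])
    ids = config.taxon_ids() + traits
    b = pd.DataFrame(0.0, index=list(DESIGN_ROWS), columns=ids)
    b.loc["soil_natural", config.taxon_ids()] = taxa_soil
    b.loc["striga_infected", config.taxon_ids()] = taxa_striga
    for trait in traits:
        b.loc["intercept", trait] = config.trait_intercepts.get(trait, 0.0)
        b.loc["soil_natural", trait] = config.soil_effects.get(trait, 0.0)
        b.loc["striga_infected", trait] = config.striga_effects.get(trait, 0.0)
        b.loc["interaction", trait] = config.interaction_effects.get(trait, 0.0)
    return b


def simulate_dataset(config: SimConfig) -> tuple[TaxaCountTable, TraitTable, GroundTruth]:
    """Generate count, trait and ground-truth tables for the full design.

    One latent bundle is drawn per sub-category x timepoint (shared taxa
    identities and planted parameters, independent noise).  Latent responses
    are stored in the returned :class:`GroundTruth` so tests can check
    empirical residual correlations against the planted values.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_bundles = len(config.sub_categories) * len(config.timepoints)
    seeds = root.spawn(2 + n_bundles)
    rng_taxa = np.random.default_rng(seeds[0])
    rng_drop = np.random.default_rng(seeds[1])

    taxa = config.taxon_ids()
    base_log_abundance = rng_taxa.normal(0.0, config.taxa_base_abundance_sd, config.n_taxa)
    taxa_soil = rng_taxa.normal(0.0, config.taxa_soil_effect_sd, config.n_taxa)
    taxa_striga = rng_taxa.normal(0.0, config.taxa_striga_effect_sd, config.n_taxa)

    planted_taxa = sorted({t for t, _, _ in config.planted_corr})
    candidates = [t for t in taxa if t not in planted_taxa]
    n_drop = int(round(config.sterilized_diversity_drop * config.n_taxa))
    n_drop = min(n_drop, len(candidates))
    dropout = sorted(rng_drop.choice(candidates, size=n_drop, replace=False).tolist())
    drop_mask = np.array([t in dropout for t in taxa])

    suppressive = sorted(
        {t for t, trait, rho in config.planted_corr if trait == STRIGA and rho < 0}
    )

    coefficients, sigmas = {}, {}
    for tp in config.timepoints:
        sigmas[tp] = config.build_sigma(tp)
        coefficients[tp] = _build_coefficients(config, tp, rng_taxa, taxa_soil, taxa_striga)

    count_blocks, meta_blocks, trait_blocks, latents = [], [], [], {}
    sample_counter = 0
    bundle_idx = 0
    for sub_category in config.sub_categories:
        for tp in config.timepoints:
            rng = np.random.default_rng(seeds[2 + bundle_idx])
            bundle_idx += 1
            traits_tp = list(config.traits_by_timepoint[tp])
            ids = taxa + traits_tp
            rows = []
            for soil in ("natural", "sterilized"):
                for striga in ("infected", "control"):
                    for rep in range(1, config.n_replicates + 1):
                        sample_counter += 1
                        rows.append(
                            {
                                "sample_id": f"S{sample_counter:05d}",
                                "soil": soil,
                                "striga": striga,
                                "timepoint": tp,
                                "sub_category": sub_category,
                                "replicate": rep,
                            }
                        )
            metadata = pd.DataFrame(rows).set_index("sample_id")
            n = len(metadata)
            x = _design_for_cells(metadata)
            chol = np.linalg.cholesky(sigmas[tp].to_numpy())
            noise = rng.standard_normal((n, len(ids))) @ chol.T
            z = x @ coefficients[tp].to_numpy() + noise
            z_frame = pd.DataFrame(z, index=metadata.index, columns=ids)
            latents[(sub_category, tp)] = z_frame

            logits = z[:, : config.n_taxa] + base_log_abundance
            sterilized = (metadata["soil"] == "sterilized").to_numpy()
            counts = np.zeros((n, config.n_taxa), dtype=np.int64)
            for i in range(n):
                row_logits = logits[i].copy()
                if sterilized[i]:
                    row_logits[drop_mask] = -np.inf
                row_logits -= row_logits.max()
                p = np.exp(row_logits)
                p /= p.sum()
                counts[i] = rng.multinomial(config.library_size, p)
            count_blocks.append(pd.DataFrame(counts, index=metadata.index, columns=taxa))
            trait_blocks.append(z_frame[traits_tp])
            meta_blocks.append(metadata)

    metadata = pd.concat(meta_blocks)
    counts = pd.concat(count_blocks)
    all_traits = sorted(
        {t for tp in config.timepoints for t in config.traits_by_timepoint[tp]}
    )
    trait_values = pd.concat(trait_blocks).reindex(columns=all_traits)
    trait_values = trait_values.loc[metadata.index]

    tax_rows = []
    for i, taxon in enumerate(taxa):
        phylum, class_, genus = _GENUS_POOL[i % len(_GENUS_POOL)]
        tax_rows.append({"taxon_id": taxon, "phylum": phylum, "class": class_, "genus": genus})
    taxonomy = pd.DataFrame(tax_rows).set_index("taxon_id")

    truth = GroundTruth(
        planted_corr=list(config.planted_corr),
        trait_corr=list(config.trait_corr),
        coefficients=coefficients,
        sigma=sigmas,
        suppressive_taxa=suppressive,
        dropout_taxa=dropout,
        latents=latents,
    )
    taxa_table = TaxaCountTable(counts=counts, metadata=metadata, taxonomy=taxonomy)
    trait_table = TraitTable(values=trait_values, metadata=metadata)
    return taxa_table, trait_table, truth


@dataclass
class FeatureGroundTruth:
    """Which planted features are within the ppm window and truly differential."""

    planted: list[dict]
    matched_feature_ids: list[str]
    differential_feature_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted": self.planted,
                    "matched_feature_ids": self.matched_feature_ids,
                    "differential_feature_ids": self.differential_feature_ids,
                },
                indent=2,
                sort_keys=True,
            )
        )


def simulate_feature_table(
    config: SimConfig, tol_ppm: float = 25.0
) -> tuple[FeatureTable, ProductMassList, FeatureGroundTruth]:
    """Generate an untargeted feature table around the predicted product masses.

    Planted features sit at ``exact_mass * (1 + offset_ppm / 1e6)``; group
    means realize the configured natural-vs-sterilized fold changes with
    lognormal noise.  Decoy features are placed away from every product mass.
    ``tol_ppm`` only labels the ground truth (which features count as
    within-window); it does not affect the generated masses.
    """
    config.validate()
    products = default_product_list()
    mass_by_id = dict(
        zip(products.products["product_id"], products.products["exact_mass"])
    )
    root = np.random.SeedSequence(config.seed)
    # dataset bundles consume the first 2 + n_bundles spawns; features get the next
    n_bundles = len(config.sub_categories) * len(config.timepoints)
    rng = np.random.default_rng(root.spawn(2 + n_bundles + 1)[-1])

    n_rep = config.n_feature_replicates
    samples = [f"nat_{i + 1}" for i in range(n_rep)] + [f"ster_{i + 1}" for i in range(n_rep)]
    groups = pd.Series(
        ["natural"] * n_rep + ["sterilized"] * n_rep, index=samples, name="group"
    )

    rows, planted_records = [], []
    matched_ids, differential_ids = [], []
    for j, plant in enumerate(config.feature_plant):
        if plant.product_id not in mass_by_id:
            raise SimConfigError(f"unknown product id {plant.product_id!r} in feature_plant")
        exact = mass_by_id[plant.product_id]
        fid = f"F{j + 1:04d}"
        mass = exact * (1.0 + plant.offset_ppm / 1.0e6)
        mean_ster = plant.base_area
        mean_nat = plant.base_area * 2.0 ** plant.log2_fc
        sd = config.feature_noise_sd
        areas_nat = mean_nat * np.exp(rng.normal(0.0, sd, n_rep) - sd**2 / 2)
        areas_ster = mean_ster * np.exp(rng.normal(0.0, sd, n_rep) - sd**2 / 2)
        row = {"neutral_mass": mass, "rt": float(rng.uniform(30.0, 1500.0))}
        row.update(dict(zip(samples, np.concatenate([areas_nat, areas_ster]))))
        rows.append(pd.Series(row, name=fid))
        within = abs(plant.offset_ppm) <= tol_ppm
        if within:
            matched_ids.append(fid)
            if abs(plant.log2_fc) > 1.0:
                differential_ids.append(fid)
        planted_records.append(
            {
                "feature_id": fid,
                "product_id": plant.product_id,
                "offset_ppm": plant.offset_ppm,
                "log2_fc": plant.log2_fc,
                "within_window": bool(within),
            }
        )

    product_masses = np.array(sorted(mass_by_id.values()))
    n_decoys = 0
    while n_decoys < config.n_feature_decoys:
        mass = float(rng.uniform(100.0, 400.0))
        rel = np.abs(mass - product_masses) / product_masses * 1.0e6
        if rel.min() <= 4 * tol_ppm:  # keep decoys unambiguously outside the window
            continue
        n_decoys += 1
        fid = f"D{n_decoys:04d}"
        areas = 5.0e4 * np.exp(rng.normal(0.0, config.feature_noise_sd, 2 * n_rep))
        row = {"neutral_mass": mass, "rt": float(rng.uniform(30.0, 1500.0))}
        row.update(dict(zip(samples, areas)))
        rows.append(pd.Series(row, name=fid))

    features = pd.DataFrame(rows)
    features.index.name = "feature_id"
    table = FeatureTable(features=features, groups=groups)
    truth = FeatureGroundTruth(
        planted=planted_records,
        matched_feature_ids=matched_ids,
        differential_feature_ids=differential_ids,
    )
    return table, products, truth
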