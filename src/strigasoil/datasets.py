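"""Tabular containers and TSV/CSV I/O shared by all pipeline stages.

All on-disk formats are plain text with headers:

* counts TSV      -- rows = samples, columns = OTUs, nonnegative integers
* metadata TSV    -- sample_id, soil, striga, timepoint, sub_category, replicate
* taxonomy TSV    -- taxon_id, phylum, class, genus
* traits TSV      -- long format: sample_id, trait, timepoint, value
* features CSV    -- feature_id, neutral_mass, rt, then one column per sample
* products CSV    -- parent, product_id, formula, exact_mass, level
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SOIL_LEVELS = ("natural", "sterilized")
STRIGA_LEVELS = ("infected", "control")
REQUIRED_METADATA_COLUMNS = ("soil", "striga", "timepoint", "sub_category", "replicate")
TAXONOMY_COLUMNS = ("phylum", "class", "genus")


class TableValidationError(ValueError):
    """Raised when an input table violates its schema."""


def _check_metadata(metadata: pd.DataFrame) -> None:
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in metadata.columns:
            raise TableValidationError(f"metadata is missing required column {col!r}")
    if metadata.index.duplicated().any():
        dupes = metadata.index[metadata.index.duplicated()].tolist()
        raise TableValidationError(f"duplicated sample ids in metadata: {dupes}")
    bad_soil = set(metadata["soil"]) - set(SOIL_LEVELS)
    if bad_soil:
        raise TableValidationError(
            f"unknown soil level(s) {sorted(bad_soil)}; expected {SOIL_LEVELS}"
        )
    bad_striga = set(metadata["striga"]) - set(STRIGA_LEVELS)
    if bad_striga:
        raise TableValidationError(
            f"unknown striga level(s) {sorted(bad_striga)}; expected {STRIGA_LEVELS}"
        )


@dataclass
class TaxaCountTable:
    """Sample x OTU count matrix with sample metadata and OTU taxonomy.

    ``counts`` is indexed by sample id with one integer column per OTU;
    ``metadata`` shares the sample index; ``taxonomy`` is indexed by OTU id.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_metadata(self.metadata)
        if not self.counts.index.equals(self.metadata.index):
            raise TableValidationError(
                "counts and metadata describe different samples "
                f"({len(self.counts)} vs {len(self.metadata)} rows)"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        neg = np.argwhere(values < 0)
        if neg.size:
            r, c = neg[0]
            raise TableValidationError(
                f"negative count {values[r, c]} at sample "
                f"{self.counts.index[r]!r}, taxon {self.counts.columns[c]!r}"
            )
        if not np.allclose(values, np.round(values)):
            raise TableValidationError("counts must be integers")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, sub_category: str, timepoint: str) -> "TaxaCountTable":
        """Restrict to one sub-category x timepoint bundle."""
        mask = (self.metadata["sub_category"] == sub_category) & (
            self.metadata["timepoint"] == timepoint
        )
        if not mask.any():
            raise TableValidationError(
                f"no samples for sub_category={sub_category!r}, timepoint={timepoint!r}"
            )
        return TaxaCountTable(
            counts=self.counts.loc[mask].copy(),
            metadata=self.metadata.loc[mask].copy(),
            taxonomy=self.taxonomy,
        )

    def write(self, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out_dir / f"{prefix}counts.tsv",
            "metadata": out_dir / f"{prefix}metadata.tsv",
            "taxonomy": out_dir / f"{prefix}taxonomy.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="sample_id")
        self.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
        self.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="taxon_id")
        return paths

    @classmethod
    def read(
        cls, counts_path: str | Path, metadata_path: str | Path, taxonomy_path: str | Path
    ) -> "TaxaCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="taxon_id")
        return cls(counts=counts, metadata=metadata, taxonomy=taxonomy)


@dataclass
class TraitTable:
    """Continuous per-sample trait measurements (long format internally wide).

    ``values`` is indexed by sample id with one column per trait; NaN marks a
    trait not measured for a sample (e.g. suberin before 3 wpi).  ``metadata``
    shares the sample index with :class:`TaxaCountTable`.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_metadata(self.metadata)
        if not self.values.index.equals(self.metadata.index):
            raise TableValidationError("trait values and metadata sample ids differ")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sub_category: str, timepoint: str) -> "TraitTable":
        mask = (self.metadata["sub_category"] == sub_category) & (
            self.metadata["timepoint"] == timepoint
        )
        if not mask.any():
            raise TableValidationError(
                f"no samples for sub_category={sub_category!r}, timepoint={timepoint!r}"
            )
        values = self.values.loc[mask].dropna(axis=1, how="all")
        return TraitTable(values=values, metadata=self.metadata.loc[mask].copy())

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="sample_id").melt(
            id_vars="sample_id", var_name="trait", value_name="value"
        )
        long = long.merge(
            self.metadata[["timepoint"]].reset_index(names="sample_id"), on="sample_id"
        )
        return long.dropna(subset=["value"])[["sample_id", "trait", "timepoint", "value"]]

    def write(self, out_dir: str | Path, prefix: str = "") -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{prefix}traits.tsv"
        self.to_long().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, traits_path: str | Path, metadata_path: str | Path) -> "TraitTable":
        long = pd.read_csv(traits_path, sep="\t")
        for col in ("sample_id", "trait", "value"):
            if col not in long.columns:
                raise TableValidationError(f"trait table is missing column {col!r}")
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        wide = long.pivot_table(index="sample_id", columns="trait", values="value")
        wide = wide.reindex(metadata.index)
        wide.columns.name = None
        return cls(values=wide, metadata=metadata)


@dataclass
class FeatureTable:
    """Untargeted LC-MS features: neutral mass, retention time, peak areas.

    ``features`` is indexed by feature id with columns ``neutral_mass``, ``rt``
    and one peak-area column per sample; ``groups`` maps sample id to its soil
    group (natural / sterilized).
    """

    features: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if "neutral_mass" not in self.features.columns:
            raise TableValidationError("feature table is missing column 'neutral_mass'")
        if (self.features["neutral_mass"] <= 0).any():
            bad = self.features.index[self.features["neutral_mass"] <= 0][0]
            raise TableValidationError(f"non-positive neutral mass for feature {bad!r}")
        missing = [s for s in self.groups.index if s not in self.features.columns]
        if missing:
            raise TableValidationError(f"sample columns missing from features: {missing}")

    @property
    def sample_columns(self) -> list[str]:
        return list(self.groups.index)

    def write(self, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": out_dir / f"{prefix}features.csv",
            "feature_groups": out_dir / f"{prefix}feature_groups.csv",
        }
        self.features.to_csv(paths["features"], index_label="feature_id")
        self.groups.rename("group").to_csv(paths["feature_groups"], index_label="sample_id")
        return paths

    @classmethod
    def read(cls, features_path: str | Path, groups_path: str | Path) -> "FeatureTable":
        features = pd.read_csv(features_path, index_col="feature_id")
        groups = pd.read_csv(groups_path, index_col="sample_id")["group"]
        return cls(features=features, groups=groups)


@dataclass
class ProductMassList:
    """Predicted HIF conversion products with exact neutral monoisotopic masses."""

    products: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in ("parent", "product_id", "exact_mass", "level"):
            if col not in self.products.columns:
                raise TableValidationError(f"product list is missing column {col!r}")
        if self.products["product_id"].duplicated().any():
            dupes = self.products.loc[
                self.products["product_id"].duplicated(), "product_id"
            ].tolist()
            raise TableValidationError(f"duplicated product ids: {dupes}")
        if (self.products["exact_mass"] <= 0).any():
            raise TableValidationError("product exact masses must be positive")

    def write(self, out_dir: str | Path, prefix: str = "") -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{prefix}products.csv"
        self.products.to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "ProductMassList":
        return cls(products=pd.read_csv(path))
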