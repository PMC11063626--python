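"""ppm mass matching of predicted HIF conversion products and the
natural-vs-sterilized differential abundance screen.

Features are matched to predicted degradation-product masses within a ppm
window (25 ppm by default, boundary inclusive, many-to-many).  Matched
features are then tested for differential abundance between soils with a
Welch (default) or Student t-test, Benjamini-Hochberg adjusted across the
matched set only, and flagged significant at adjusted p < 0.05 and
|log2 fold change| > 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .datasets import FeatureTable, ProductMassList

PROTON_MASS = 1.00727646688  # Da

#: optional adduct modes: observed m/z -> neutral mass correction
ADDUCT_OFFSETS = {None: 0.0, "M+H": -PROTON_MASS, "M-H": PROTON_MASS}


def ppm_error(m_obs: float, m_ref: float) -> float:
    """Relative mass deviation in parts per million: (obs - ref) / ref * 1e6."""
    if m_ref <= 0:
        raise ValueError("reference mass must be positive")
    return (m_obs - m_ref) / m_ref * 1.0e6


def match_features(
    features: FeatureTable,
    products: ProductMassList,
    tol_ppm: float = 25.0,
    adduct: str | None = None,
) -> pd.DataFrame:
    """All (feature, product) pairs within the ppm window (inclusive).

    Matching is many-to-many: a feature within tolerance of several predicted
    products yields one row per product.  ``adduct`` optionally treats the
    recorded feature mass as an [M+H]+ / [M-H]- ion and corrects by a proton
    mass before comparison; by default masses are assumed already neutral.
    Output is sorted by (feature_id, product_id).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if adduct not in ADDUCT_OFFSETS:
        raise ValueError(f"unknown adduct mode {adduct!r}; choose from {list(ADDUCT_OFFSETS)}")
    offset = ADDUCT_OFFSETS[adduct]
    rows = []
    masses = features.features["neutral_mass"]
    # 1e-9 ppm guard (1e-15 relative mass) so a half-ulp round-trip cannot
    # flip a feature sitting exactly on the inclusive boundary
    for _, product in products.products.iterrows():
        errors = (masses + offset - product["exact_mass"]) / product["exact_mass"] * 1.0e6
        hits = errors[errors.abs() <= tol_ppm + 1.0e-9]
        for feature_id, err in hits.items():
            rows.append(
                {
                    "feature_id": feature_id,
                    "product_id": product["product_id"],
                    "parent": product["parent"],
                    "ppm_error": float(err),
                }
            )
    out = pd.DataFrame(rows, columns=["feature_id", "product_id", "parent", "ppm_error"])
    return out.sort_values(["feature_id", "product_id"]).reset_index(drop=True)


def log2_fold_change(mean_natural: float, mean_sterilized: float, epsilon: float) -> float:
    """log2((mean_natural + eps) / (mean_sterilized + eps)); eps keeps zeros finite."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if mean_natural < 0 or mean_sterilized < 0:
        raise ValueError("group means must be nonnegative")
    return float(np.log2((mean_natural + epsilon) / (mean_sterilized + epsilon)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order restored."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    features: FeatureTable,
    matches: pd.DataFrame,
    test: str = "welch",
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Soil differential-abundance screen over the matched features.

    One test per distinct matched feature; BH adjustment is computed across
    the matched set only.  ``significant`` requires adjusted p < ``alpha``
    and |log2 fold change| > ``lfc``; ``direction`` records which soil the
    feature is higher in.
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    natural = [s for s in features.sample_columns if features.groups[s] == "natural"]
    sterilized = [s for s in features.sample_columns if features.groups[s] == "sterilized"]
    if len(natural) < 2 or len(sterilized) < 2:
        raise ValueError("need >= 2 samples per soil group")

    feature_ids = sorted(matches["feature_id"].unique())
    if not feature_ids:
        return pd.DataFrame(
            columns=[
                "feature_id", "mean_natural", "mean_sterilized", "log2_fc",
                "p_value", "p_adjusted", "significant", "direction",
            ]
        )
    areas = features.features.loc[feature_ids, natural + sterilized]
    positive = areas.to_numpy()[areas.to_numpy() > 0]
    epsilon = positive.min() / 2.0 if positive.size else 1.0

    rows = []
    for fid in feature_ids:
        x = areas.loc[fid, natural].to_numpy(float)
        y = areas.loc[fid, sterilized].to_numpy(float)
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
            p = 1.0
        else:
            p = float(st.ttest_ind(x, y, equal_var=(test == "student")).pvalue)
        fc = log2_fold_change(x.mean(), y.mean(), epsilon)
        rows.append(
            {
                "feature_id": fid,
                "mean_natural": float(x.mean()),
                "mean_sterilized": float(y.mean()),
                "log2_fc": fc,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = (out["p_adjusted"] < alpha) & (out["log2_fc"].abs() > lfc)
    out["direction"] = np.where(out["log2_fc"] > 0, "higher_in_natural", "higher_in_sterilized")
    out.loc[out["log2_fc"] == 0, "direction"] = "equal"
    return out


def significant_fraction_up(differential: pd.DataFrame) -> float:
    """Fraction of significant features higher in natural soil (NaN if none)."""
    flagged = differential[differential["significant"]]
    if flagged.empty:
        return float("nan")
    return float((flagged["direction"] == "higher_in_natural").mean())
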