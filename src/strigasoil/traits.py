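"""Trait screening and closed-form assay statistics.

Every trait and HIF abundance is screened with the factorial linear model

    trait ~ soil + striga + soil:striga

and classified by which terms reach significance.  Only traits the microbiome
changes independently of Striga infection ("soil_only") are forwarded to the
joint model.  The module also provides the small closed-form statistics used
by the wet-lab assays: Shannon diversity, Welch's t, hypergeometric
enrichment, germination/haustorium rates, root porosity, and the
fully-suberized odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datasets import TraitTable

TERMS = ("soil", "striga", "interaction")


@dataclass
class TermStats:
    ss: float
    df: int
    f: float
    p: float


@dataclass
class AnovaResult:
    """Two-way factorial ANOVA decomposition for one trait."""

    terms: dict[str, TermStats]
    residual_ss: float
    residual_df: int
    n: int
    ss_type: int  # 1 (sequential, balanced) or 2 (hierarchical, unbalanced)
    main_effects_only: bool = False

    def p_values(self) -> dict[str, float]:
        return {name: t.p for name, t in self.terms.items()}


class DegenerateDesignError(ValueError):
    pass


def two_way_anova(values, soil, striga) -> AnovaResult:
    """Factorial soil x Striga ANOVA of one trait.

    Sequential (type I) sums of squares on balanced designs, hierarchical
    (type II) otherwise.  An empty cell triggers a main-effects-only fallback
    with a warning; zero residual variance raises
    :class:`DegenerateDesignError`.
    """
    frame = pd.DataFrame(
        {"value": np.asarray(values, float), "soil": list(soil), "striga": list(striga)}
    ).dropna(subset=["value"])
    cells = frame.groupby(["soil", "striga"], observed=True).size()
    if (cells >= 2).sum() < 3:
        raise DegenerateDesignError(
            "need >= 2 observations in >= 3 of the 4 soil x striga cells, "
            f"got cell sizes {cells.to_dict()}"
        )
    full_cells = len(cells) == 4
    balanced = full_cells and cells.nunique() == 1

    formula = "value ~ C(soil) * C(striga)"
    main_only = not full_cells
    if main_only:
        warnings.warn(
            "empty soil x striga cell: falling back to main-effects-only model",
            stacklevel=2,
        )
        formula = "value ~ C(soil) + C(striga)"
    model = smf.ols(formula, data=frame).fit()
    if model.df_resid <= 0 or model.ssr <= 1e-12 * max(model.centered_tss, 1.0):
        raise DegenerateDesignError("degenerate design: zero residual variance")
    ss_type = 1 if balanced else 2
    table = sm.stats.anova_lm(model, typ=ss_type)

    name_map = {"C(soil)": "soil", "C(striga)": "striga", "C(soil):C(striga)": "interaction"}
    terms: dict[str, TermStats] = {}
    for raw, name in name_map.items():
        if raw in table.index:
            row = table.loc[raw]
            terms[name] = TermStats(
                ss=float(row["sum_sq"]), df=int(row["df"]),
                f=float(row["F"]), p=float(row["PR(>F)"]),
            )
    resid = table.loc["Residual"]
    return AnovaResult(
        terms=terms,
        residual_ss=float(resid["sum_sq"]),
        residual_df=int(resid["df"]),
        n=len(frame),
        ss_type=ss_type,
        main_effects_only=main_only,
    )


@dataclass
class TraitClassification:
    trait: str
    timepoint: str | None
    label: str  # soil_only | striga_only | interaction | none
    alpha: float


def classify_trait(
    res: AnovaResult, alpha: float = 0.05, trait: str = "", timepoint: str | None = None
) -> TraitClassification:
    """Deterministic label from the three term p-values.

    ``soil_only`` (the label that forwards a trait to the joint model) means a
    significant soil term without a significant interaction, i.e. the
    microbiome changed the trait independently of Striga.
    """
    p = res.p_values()
    p_soil = p.get("soil", 1.0)
    p_striga = p.get("striga", 1.0)
    p_inter = p.get("interaction", 1.0)
    if p_inter < alpha:
        label = "interaction"
    elif p_soil < alpha:
        label = "soil_only"
    elif p_striga < alpha:
        label = "striga_only"
    else:
        label = "none"
    return TraitClassification(trait=trait, timepoint=timepoint, label=label, alpha=alpha)


def screen_traits(trait_table: TraitTable, alpha: float = 0.05) -> pd.DataFrame:
    """Run the two-way ANOVA screen for every trait x timepoint.

    Returns a tidy frame with one row per trait and timepoint: term p-values
    and the classification label.
    """
    rows = []
    meta = trait_table.metadata
    for tp in sorted(meta["timepoint"].unique()):
        mask = meta["timepoint"] == tp
        values_tp = trait_table.values.loc[mask]
        for trait in trait_table.traits:
            col = values_tp[trait]
            if col.notna().sum() == 0:
                continue
            res = two_way_anova(col, meta.loc[mask, "soil"], meta.loc[mask, "striga"])
            cls = classify_trait(res, alpha=alpha, trait=trait, timepoint=tp)
            p = res.p_values()
            rows.append(
                {
                    "trait": trait,
                    "timepoint": tp,
                    "p_soil": p.get("soil", np.nan),
                    "p_striga": p.get("striga", np.nan),
                    "p_interaction": p.get("interaction", np.nan),
                    "f_soil": res.terms.get("soil").f if "soil" in res.terms else np.nan,
                    "label": cls.label,
                }
            )
    return pd.DataFrame(rows)


def soil_only_traits(screen: pd.DataFrame, timepoint: str) -> list[str]:
    mask = (screen["timepoint"] == timepoint) & (screen["label"] == "soil_only")
    return sorted(screen.loc[mask, "trait"])


def shannon_diversity(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) over positive counts."""
    counts = np.asarray(counts, float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("shannon_diversity needs at least one positive count")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(st.entropy(counts))


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * st.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def hypergeometric_enrichment(k: int, big_k: int, n: int, big_n: int) -> float:
    """One-sided over-representation p-value P(X >= k).

    ``k`` of ``n`` selected items fall in a category of size ``big_k`` within
    a universe of ``big_n``; equivalent to a one-sided Fisher exact test.
    """
    if not (0 <= k <= min(big_k, n) and big_k <= big_n and n <= big_n):
        raise ValueError(
            f"inconsistent counts: k={k}, K={big_k}, n={n}, N={big_n}"
        )
    return float(st.hypergeom.sf(k - 1, big_n, big_k, n))


@dataclass
class SeedCounts:
    """Striga seed counts from the in vitro germination/haustorium assay."""

    n_total: int
    n_germinated: int
    n_haustoria: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_haustoria <= self.n_germinated <= self.n_total:
            raise ValueError(
                f"need 0 <= NHs ({self.n_haustoria}) <= Ngs ({self.n_germinated})"
                f" <= Nts ({self.n_total})"
            )


def germination_rate(c: SeedCounts) -> float:
    """GR% = germinated / total x 100."""
    if c.n_total <= 0:
        raise ValueError("total seed count must be positive")
    return 100.0 * c.n_germinated / c.n_total


def haustorium_rate(c: SeedCounts) -> float | None:
    """HFR% = haustoria / germinated x 100; None (with warning) if none germinated."""
    if c.n_germinated == 0:
        warnings.warn("no germinated seeds: haustorium formation rate undefined", stacklevel=2)
        return None
    return 100.0 * c.n_haustoria / c.n_germinated


@dataclass
class PycnometerWeights:
    """Pycnometer weighings for whole-root-system porosity (grams)."""

    pycnometer_water: float  # Pw: pycnometer filled with water
    with_roots: float  # Pr: pycnometer + water + root system
    vacuum_infiltrated: float  # Pv: pycnometer + vacuum-infiltrated roots
    root_mass: float  # R: fresh root mass at harvest


def root_porosity(w: PycnometerWeights) -> float:
    """Root porosity = (Pv - Pr) / (Pw + R - Pr).

    The numerator is the water replacing air after vacuum infiltration; the
    denominator is the root volume.  Negative values (Pv < Pr, measurement
    noise) are returned as-is with a warning.
    """
    denom = w.pycnometer_water + w.root_mass - w.with_roots
    if denom == 0:
        raise ValueError("zero root volume: Pw + R - Pr must be nonzero")
    porosity = (w.vacuum_infiltrated - w.with_roots) / denom
    if porosity < 0:
        warnings.warn("negative porosity (Pv < Pr): likely measurement noise", stacklevel=2)
    return porosity


@dataclass
class SuberinCounts:
    """Suberization counts per treatment (cells and whole plants)."""

    n_suberized: int = 0
    n_nonsuberized: int = 0
    n_fully_suberized: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        for name in ("n_suberized", "n_nonsuberized", "n_fully_suberized", "n_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def suberin_odds_ratio(
    treated: SuberinCounts, mock: SuberinCounts, cells: bool = False
) -> tuple[float, float]:
    """Cross-product odds ratio and two-sided Fisher p for suberization.

    By default compares fully-suberized vs not plants; with ``cells=True``
    compares suberized vs non-suberized cell counts.  A zero cell gets the
    Haldane-Anscombe 0.5 correction for the odds ratio (the Fisher p uses the
    uncorrected table).
    """
    if cells:
        table = np.array(
            [
                [treated.n_suberized, treated.n_nonsuberized],
                [mock.n_suberized, mock.n_nonsuberized],
            ],
            float,
        )
    else:
        if treated.n_fully_suberized > treated.n_total or mock.n_fully_suberized > mock.n_total:
            raise ValueError("fully-suberized count exceeds total plants")
        table = np.array(
            [
                [treated.n_fully_suberized, treated.n_total - treated.n_fully_suberized],
                [mock.n_fully_suberized, mock.n_total - mock.n_fully_suberized],
            ],
            float,
        )
    if table.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    work = table + 0.5 if (table == 0).any() else table
    odds_ratio = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    _, p = st.fisher_exact(table.astype(int), alternative="two-sided")
    return float(odds_ratio), float(p)
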