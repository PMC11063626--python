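"""Rank aggregation of residual correlations into candidate suppressive taxa.

Per sub-category x timepoint, taxa are filtered by the desired correlation
sign for each trait (negative for Striga attachments and HIF abundances,
positive for suberin and aerenchyma), ranked by desirability (rank value m =
most desirable, 1 = least; ties get average ranks), and combined with the
Striga-attachment rank: the combined rank is the rank of the rank sum.
Candidate genera are those with at least one member OTU whose residual
correlation passes the +/-0.2 cutoffs for Striga attachments and at least one
mechanism trait.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import AERENCHYMA, HIF_SYRINGIC, HIF_VANILLIC, STRIGA, SUBERIN


@dataclass(frozen=True)
class TraitKind:
    label: str
    desired_sign: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        if self.desired_sign not in ("negative", "positive"):
            raise ValueError(f"unknown desired sign {self.desired_sign!r}")


#: desired residual-correlation sign per trait: suppressive taxa should be
#: negatively associated with attachments and HIF levels, positively with the
#: structural barriers
TRAIT_KINDS: dict[str, TraitKind] = {
    STRIGA: TraitKind(STRIGA, "negative"),
    HIF_SYRINGIC: TraitKind(HIF_SYRINGIC, "negative"),
    HIF_VANILLIC: TraitKind(HIF_VANILLIC, "negative"),
    SUBERIN: TraitKind(SUBERIN, "positive"),
    AERENCHYMA: TraitKind(AERENCHYMA, "positive"),
}

#: mechanism label per trait (Striga attachments is the gate, not a mechanism)
MECHANISM_BY_TRAIT: dict[str, str] = {
    SUBERIN: "suberin",
    AERENCHYMA: "aerenchyma",
    HIF_SYRINGIC: "hif_degradation",
    HIF_VANILLIC: "hif_degradation",
}


def trait_kind(trait: str) -> TraitKind:
    try:
        return TRAIT_KINDS[trait]
    except KeyError:
        raise KeyError(
            f"no desired sign registered for trait {trait!r}; known: {sorted(TRAIT_KINDS)}"
        ) from None


def filter_by_sign(corr: pd.Series, kind: TraitKind) -> pd.Series:
    """Keep taxa whose correlation is strictly on the desired side of zero."""
    if kind.desired_sign == "negative":
        return corr[corr < 0]
    return corr[corr > 0]


def rank_desirability(corr: pd.Series, kind: TraitKind) -> pd.Series:
    """Rank values 1..m with m for the most desirable correlation.

    For negative-desired traits the lowest correlation gets the highest rank
    value; for positive-desired traits the highest correlation does.  Ties
    receive the average of the covered positions.
    """
    if corr.empty:
        return pd.Series(dtype=float)
    desirability = -corr if kind.desired_sign == "negative" else corr
    ranks = rankdata(desirability.to_numpy(), method="average")
    return pd.Series(ranks, index=corr.index)


def combined_rank(rank_striga: pd.Series, rank_trait: pd.Series) -> pd.Series:
    """Rank of the rank sum over taxa ranked for both traits.

    The largest rank sum receives the highest combined rank value; tied sums
    are averaged.
    """
    common = rank_striga.index.intersection(rank_trait.index)
    if len(common) == 0:
        warnings.warn("no taxa ranked for both traits: empty combined rank", stacklevel=2)
        return pd.Series(dtype=float)
    sums = rank_striga.loc[common] + rank_trait.loc[common]
    ranks = rankdata(sums.to_numpy(), method="average")
    return pd.Series(ranks, index=common)


def top_k_summary(
    combined: pd.Series, taxonomy: pd.DataFrame, k: int = 100, level: str = "class"
) -> pd.Series:
    """Taxonomic membership counts of the top-k taxa by combined rank.

    Ties straddling the k-th position are all included (so more than k taxa
    may be counted).  Taxa missing from the taxonomy count as "unclassified".
    """
    if combined.empty:
        return pd.Series(dtype=int)
    if k >= len(combined):
        selected = combined.index
    else:
        threshold = combined.sort_values(ascending=False).iloc[k - 1]
        selected = combined[combined >= threshold].index
    labels = [
        taxonomy.loc[t, level] if t in taxonomy.index else "unclassified"
        for t in selected
    ]
    return pd.Series(labels).value_counts().sort_index()


def rank_table(
    resid_corr: pd.DataFrame,
    taxa: list[str],
    sub_category: str,
    timepoint: str,
) -> pd.DataFrame:
    """Per-trait rank table for one bundle's residual correlations.

    ``resid_corr`` is the square posterior-mean matrix over [taxa | traits];
    for every mechanism trait present, taxa are sign-filtered, ranked, and
    combined with the Striga-attachment rank.  Output is tidy: one row per
    (taxon, trait) that survived the sign filter.
    """
    traits = [c for c in resid_corr.columns if c in TRAIT_KINDS and c not in taxa]
    if STRIGA not in traits:
        raise ValueError("residual correlations must include the Striga-attachment column")
    striga_corr = resid_corr.loc[taxa, STRIGA]
    striga_kept = filter_by_sign(striga_corr, trait_kind(STRIGA))
    striga_ranks = rank_desirability(striga_kept, trait_kind(STRIGA))

    rows = []
    for trait in traits:
        kind = trait_kind(trait)
        corr = resid_corr.loc[taxa, trait]
        kept = filter_by_sign(corr, kind)
        ranks = rank_desirability(kept, kind)
        if trait == STRIGA:
            for taxon in striga_ranks.index:
                rows.append(
                    {
                        "taxon": taxon,
                        "trait": trait,
                        "corr": float(corr[taxon]),
                        "rank": float(ranks[taxon]),
                        "rank_sum": np.nan,
                        "combined_rank": np.nan,
                    }
                )
            continue
        combo = combined_rank(striga_ranks, ranks)
        sums = striga_ranks.add(ranks, fill_value=np.nan)
        for taxon in ranks.index:
            in_both = taxon in combo.index
            rows.append(
                {
                    "taxon": taxon,
                    "trait": trait,
                    "corr": float(corr[taxon]),
                    "rank": float(ranks[taxon]),
                    "rank_sum": float(sums[taxon]) if in_both else np.nan,
                    "combined_rank": float(combo[taxon]) if in_both else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["sub_category"] = sub_category
    out["timepoint"] = timepoint
    # deterministic output order: trait, then taxon id
    return out.sort_values(["trait", "taxon"]).reset_index(drop=True)


@dataclass
class CandidateSet:
    """Selected genera with their mechanisms and supporting OTU evidence."""

    candidates: dict[str, set[str]] = field(default_factory=dict)  # genus -> mechanisms
    evidence: list[dict] = field(default_factory=list)

    def genera(self) -> list[str]:
        return sorted(self.candidates)

    def merge(self, other: "CandidateSet") -> "CandidateSet":
        merged = CandidateSet(
            candidates={g: set(m) for g, m in self.candidates.items()},
            evidence=list(self.evidence),
        )
        for genus, mechanisms in other.candidates.items():
            merged.candidates.setdefault(genus, set()).update(mechanisms)
        merged.evidence.extend(other.evidence)
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genus": g, "mechanisms": ",".join(sorted(m))}
            for g, m in sorted(self.candidates.items())
        ]
        return pd.DataFrame(rows, columns=["genus", "mechanisms"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genera": {g: sorted(m) for g, m in self.candidates.items()},
            "evidence": sorted(
                self.evidence,
                key=lambda e: (e["genus"], e["taxon"], e["mechanism"], e["sub_category"]),
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def select_candidate_genera(
    resid_corr: pd.DataFrame,
    taxa: list[str],
    taxonomy: pd.DataFrame,
    thr: float = 0.2,
    sub_category: str = "",
    timepoint: str = "",
) -> CandidateSet:
    """Threshold-based candidate genus selection for one bundle.

    An OTU qualifies for a mechanism when its Striga-attachment residual
    correlation is below ``-thr`` and the mechanism-trait correlation passes
    ``thr`` in the desired direction.  A genus is selected when any member
    OTU qualifies; mechanisms are unioned across OTUs.
    """
    if thr <= 0:
        raise ValueError("threshold must be positive")
    traits = [
        c for c in resid_corr.columns
        if c in MECHANISM_BY_TRAIT and c not in taxa
    ]
    result = CandidateSet()
    striga_corr = resid_corr.loc[taxa, STRIGA]
    for taxon in taxa:
        if striga_corr[taxon] >= -thr:
            continue
        genus = (
            str(taxonomy.loc[taxon, "genus"]) if taxon in taxonomy.index else "unclassified"
        )
        for trait in traits:
            corr = float(resid_corr.loc[taxon, trait])
            kind = trait_kind(trait)
            passes = corr > thr if kind.desired_sign == "positive" else corr < -thr
            if not passes:
                continue
            mechanism = MECHANISM_BY_TRAIT[trait]
            result.candidates.setdefault(genus, set()).add(mechanism)
            result.evidence.append(
                {
                    "genus": genus,
                    "taxon": taxon,
                    "mechanism": mechanism,
                    "trait": trait,
                    "trait_corr": round(corr, 6),
                    "striga_corr": round(float(striga_corr[taxon]), 6),
                    "sub_category": sub_category,
                    "timepoint": timepoint,
                }
            )
    return result
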