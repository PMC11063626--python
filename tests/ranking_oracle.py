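"""Independent brute-force (sort-based) re-implementation of the ranking
scheme, used only as a test oracle.  Deliberately avoids scipy.rankdata."""

from __future__ import annotations


def oracle_filter(corr: dict[str, float], desired_sign: str) -> dict[str, float]:
    if desired_sign == "negative":
        return {t: c for t, c in corr.items() if c < 0}
    return {t: c for t, c in corr.items() if c > 0}


def _average_ranks_ascending(values: dict[str, float]) -> dict[str, float]:
    """Position ranks (1 = smallest) with ties averaged, by explicit sorting."""
    items = sorted(values.items(), key=lambda kv: kv[1])
    ranks: dict[str, float] = {}
    i = 0
    while i < len(items):
        j = i
        while j + 1 < len(items) and items[j + 1][1] == items[i][1]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[items[k][0]] = avg
        i = j + 1
    return ranks


def oracle_rank(corr: dict[str, float], desired_sign: str) -> dict[str, float]:
    """Rank value m for the most desirable correlation, 1 for the least."""
    desirability = {
        t: (-c if desired_sign == "negative" else c) for t, c in corr.items()
    }
    return _average_ranks_ascending(desirability)


def oracle_combined(rank_striga: dict[str, float], rank_trait: dict[str, float]) -> dict[str, float]:
    common = set(rank_striga) & set(rank_trait)
    sums = {t: rank_striga[t] + rank_trait[t] for t in common}
    return _average_ranks_ascending(sums)
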