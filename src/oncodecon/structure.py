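"""Co-mutation structure and overlap of lesions' transcriptional consequences.

Pairwise lesion co-occurrence is summarised by Haldane-corrected odds
ratios; the overlap between two lesions' target gene sets by the Jaccard
index (with a hypergeometric enrichment p-value for robustness).  A rank
correlation between log-OR and overlap, with a permutation p-value, tests
whether lesions that co-occur also converge on shared transcriptional
programmes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def comutation_odds_ratio(lesions, pair: tuple[str, str]) -> float:
    """Haldane-Anscombe-corrected odds ratio for joint lesion presence.

    ``OR = ((a + 1/2)(d + 1/2)) / ((b + 1/2)(c + 1/2))`` from the 2x2 table
    of presence/absence; the half-counts keep the estimate finite for
    empty cells.
    """
    a_name, b_name = pair
    values = lesions.values if hasattr(lesions, "values") and not isinstance(lesions, pd.DataFrame) else lesions
    for name in pair:
        if name not in values.columns:
            raise KeyError(f"lesion {name!r} not in matrix")
    x = values[a_name].to_numpy(dtype=float)
    y = values[b_name].to_numpy(dtype=float)
    a = float(np.sum((x == 1) & (y == 1)))
    b = float(np.sum((x == 1) & (y == 0)))
    c = float(np.sum((x == 0) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def target_set_overlap(set_a, set_b) -> float:
    """Jaccard index |A n B| / |A u B|; 0 (with a warning flag) if both empty."""
    A, B = set(set_a), set(set_b)
    union = A | B
    if not union:
        return 0.0
    return len(A & B) / len(union)


def overlap_enrichment_pvalue(set_a, set_b, universe_size: int) -> float:
    """Hypergeometric tail p-value for the observed target-set intersection."""
    A, B = set(set_a), set(set_b)
    k = len(A & B)
    if not A or not B:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, len(A), len(B)))


def pairwise_structure(lesions, target_sets: dict[str, list] | dict[str, set],
                       universe_size: int | None = None) -> pd.DataFrame:
    """One row per lesion pair: 2x2 counts, corrected OR, Jaccard overlap."""
    values = lesions.values if not isinstance(lesions, pd.DataFrame) else lesions
    names = [n for n in values.columns if n in target_sets]
    if universe_size is None:
        universe_size = len(set().union(*(set(s) for s in target_sets.values()))) or 1
    rows = []
    for a_name, b_name in combinations(names, 2):
        x = values[a_name].to_numpy(dtype=float)
        y = values[b_name].to_numpy(dtype=float)
        a = int(np.sum((x == 1) & (y == 1)))
        b = int(np.sum((x == 1) & (y == 0)))
        c = int(np.sum((x == 0) & (y == 1)))
        d = int(np.sum((x == 0) & (y == 0)))
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        sa, sb = set(target_sets[a_name]), set(target_sets[b_name])
        rows.append({
            "lesion_a": a_name, "lesion_b": b_name,
            "n11": a, "n10": b, "n01": c, "n00": d,
            "odds_ratio": orr, "log_odds_ratio": np.log(orr),
            "overlap_jaccard": target_set_overlap(sa, sb),
            "overlap_p_hypergeom": overlap_enrichment_pvalue(sa, sb, universe_size),
            "n_targets_a": len(sa), "n_targets_b": len(sb),
        })
    return pd.DataFrame(rows)


def structure_summary(lesions, target_sets: dict, n_perm: int = 1000,
                      seed: int = 0, universe_size: int | None = None) -> dict:
    """Pairwise table plus Spearman correlation of log-OR with overlap.

    The permutation p-value relabels pairs: overlap values are shuffled
    against log-OR values ``n_perm`` times, giving the null distribution of
    the rank correlation.
    """
    values = lesions.values if not isinstance(lesions, pd.DataFrame) else lesions
    names = [n for n in values.columns if n in target_sets]
    if len(names) < 3:
        raise ValueError(f"need >= 3 lesions with target sets, got {len(names)}")
    table = pairwise_structure(lesions, target_sets, universe_size=universe_size)
    log_or = table["log_odds_ratio"].to_numpy()
    overlap = table["overlap_jaccard"].to_numpy()
    rho = stats.spearmanr(log_or, overlap).statistic
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stats.spearmanr(log_or, rng.permutation(overlap)).statistic
    null = np.nan_to_num(null)
    rho0 = 0.0 if np.isnan(rho) else rho
    p_perm = float((np.sum(np.abs(null) >= abs(rho0)) + 1) / (n_perm + 1))
    return {"table": table, "spearman_rho": float(rho), "p_permutation": p_perm}


def venn_counts(sets: dict[str, set | list]) -> pd.DataFrame:
    """Exclusive region counts for 2-4 named sets; regions sum to the union."""
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts supports 2-4 sets")
    as_sets = {n: set(sets[n]) for n in names}
    universe = set().union(*as_sets.values())
    rows = []
    for mask in range(1, 2 ** len(names)):
        members = [n for i, n in enumerate(names) if mask >> i & 1]
        region = set(universe)
        for n in names:
            region &= as_sets[n] if n in members else (universe - as_sets[n])
        rows.append({"region": "&".join(members), "count": len(region)})
    return pd.DataFrame(rows)
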