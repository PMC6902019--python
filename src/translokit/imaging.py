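"""Per-cell nuclear/cytosol intensity statistics for microscopy validation.

Operates on per-cell intensity tables produced upstream by image
segmentation: normalization of all intensities to the unstimulated
population, condition-level nuclear/cytosolic shares with the total set to
1, and Mann-Whitney comparisons between cell populations.
"""
from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("cell_id", "condition", "nuclear", "cytosolic")

#: Cell counts at or below this trigger a small-sample warning.
SMALL_SAMPLE_N = 100


def _check(cells: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    total = cells["nuclear"] + cells["cytosolic"]
    if (total <= 0).any():
        raise ValueError("cells with non-positive total intensity are not analyzable")


def normalize_to_unstimulated(
    cells: pd.DataFrame, unstimulated: str
) -> pd.DataFrame:
    """Divide every intensity by the median total of the unstimulated cells.

    Normalizing to the unstimulated *population* (not per cell) preserves
    changes in total target expression between conditions.
    """
    _check(cells)
    ref = cells[cells["condition"] == unstimulated]
    if ref.empty:
        raise ValueError(f"unstimulated condition {unstimulated!r} has no cells")
    ref_median = float((ref["nuclear"] + ref["cytosolic"]).median())
    out = cells.copy()
    out["nuclear"] = out["nuclear"] / ref_median
    out["cytosolic"] = out["cytosolic"] / ref_median
    return out


def distribution_shares(cells: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Condition-level (nuclear, cytosolic) shares with total set to 1.

    Medians of the per-cell nuclear and cytosolic intensities, rescaled so
    they sum to 1.
    """
    grp = cells[cells["condition"] == condition]
    if grp.empty:
        raise ValueError(f"no cells in condition {condition!r}")
    med_n = float(grp["nuclear"].median())
    med_c = float(grp["cytosolic"].median())
    total = med_n + med_c
    if total <= 0:
        raise ValueError("median intensities sum to zero")
    return med_n / total, med_c / total


def _exact_rank_sum_p(ranks_a: np.ndarray, pooled_ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided P of the rank-sum via the shift-algorithm DP.

    Enumerates the permutation distribution of the group-A rank sum over
    all ways to assign n1 of the pooled midranks to group A; handles ties
    exactly.  Midranks are doubled to make them integers.
    """
    r2 = np.rint(pooled_ranks * 2).astype(int)
    obs = int(np.rint(ranks_a.sum() * 2))
    max_sum = int(r2.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        upper = min(n1, len(r2))
        for k in range(upper - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if len(nz):
                dp[k + 1, nz + r] += row[nz]
    counts = dp[n1]
    total = comb(len(r2), n1)
    p_le = counts[: obs + 1].sum() / total
    p_ge = counts[obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties; exact P for small groups.

    Returns (U of group A, two-sided P).  For groups of at least 20 cells
    each, P comes from the normal approximation with tie correction and
    continuity correction; otherwise from exact enumeration of the tied
    rank-sum permutation distribution.  Groups at or below 100 cells get a
    warning, since the intended scale of the comparison is >100 cells per
    population.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(a), len(b)) <= SMALL_SAMPLE_N:
        warnings.warn(
            f"group sizes {len(a)}/{len(b)}: the comparison is designed for "
            f">{SMALL_SAMPLE_N} cells per population",
            stacklevel=2,
        )
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    r_a = ranks[: len(a)]
    u = float(r_a.sum() - len(a) * (len(a) + 1) / 2.0)
    if min(len(a), len(b)) >= 20:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    else:
        p = _exact_rank_sum_p(r_a, ranks, len(a))
    return u, p


def compare_conditions(
    cells: pd.DataFrame,
    unstimulated: str,
    value: str = "nuclear_share",
) -> pd.DataFrame:
    """Normalize to the unstimulated population, then Mann-Whitney each
    condition against it on the chosen per-cell quantity.

    ``value`` may be ``nuclear``, ``cytosolic``, ``total`` or
    ``nuclear_share`` (nuclear / total).
    """
    norm = normalize_to_unstimulated(cells, unstimulated)
    norm["total"] = norm["nuclear"] + norm["cytosolic"]
    norm["nuclear_share"] = norm["nuclear"] / norm["total"]
    ref = norm.loc[norm["condition"] == unstimulated, value].to_numpy()
    rows = []
    for cond in sorted(set(norm["condition"]) - {unstimulated}):
        vals = norm.loc[norm["condition"] == cond, value].to_numpy()
        u, p = mann_whitney(vals, ref)
        shares = distribution_shares(norm, cond)
        rows.append(
            {
                "condition": cond,
                "n_cells": len(vals),
                "U": u,
                "pvalue": p,
                "nuclear_share": shares[0],
                "cytosolic_share": shares[1],
            }
        )
    return pd.DataFrame(rows)
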