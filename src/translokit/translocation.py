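"""Decision tree calling stimulation-induced translocating proteins.

A protein is called translocating when, within one contrast, two different
subcellular fractions change significantly in opposite directions: the
abundance mass lost by one fraction shows up in another.  Thresholds
default to |log2FC| > 0.201 and uncorrected P < 0.05 in each fraction,
both strict.
"""
from __future__ import annotations

from itertools import combinations

import pandas as pd

FC_THRESHOLD = 0.201
P_THRESHOLD = 0.05


def _pivot(stats: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    contrasts = stats["contrast"].unique()
    if len(contrasts) > 1:
        raise ValueError(f"stats mix contrasts {sorted(contrasts)}; filter to one first")
    fc = stats.pivot_table(index="gene", columns="fraction", values="log2fc")
    p = stats.pivot_table(index="gene", columns="fraction", values="pvalue")
    return fc, p


def candidate_changing_set(stats: pd.DataFrame, p_threshold: float = P_THRESHOLD) -> set[str]:
    """Genes changing (P < threshold, strict) in at least two fractions."""
    _, p = _pivot(stats)
    if p.shape[1] < 2:
        raise ValueError("need statistics for >= 2 fractions")
    n_sig = (p < p_threshold).sum(axis=1)
    return set(p.index[n_sig >= 2])


def call_translocations(
    stats: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Apply the opposite-direction decision tree to one contrast's stats.

    A gene passes iff some pair of fractions has log2FC strictly above
    ``fc_threshold`` in one and strictly below ``-fc_threshold`` in the
    other, with P strictly below ``p_threshold`` in both.  Returns one row
    per gene: pass flag, the qualifying (up_fraction, down_fraction) pairs,
    and the per-fraction statistics flattened for auditing.
    """
    if fc_threshold < 0:
        raise ValueError("fc_threshold must be >= 0")
    fc, p = _pivot(stats)
    fractions = [f for f in ("C", "M", "N") if f in fc.columns]
    fc = fc[fractions]
    p = p[fractions]
    sig = p < p_threshold
    up = (fc > fc_threshold) & sig
    down = (fc < -fc_threshold) & sig
    # a fraction cannot be both up and down, so any up + any down => a pair
    passed = up.any(axis=1) & down.any(axis=1)
    pair_strings = pd.Series("", index=fc.index, dtype=object)
    for gene in fc.index[passed]:
        ups = [f for f in fractions if up.at[gene, f]]
        downs = [f for f in fractions if down.at[gene, f]]
        pairs = sorted((u, d) for u in ups for d in downs)
        pair_strings.at[gene] = ";".join(f"{u}up|{d}down" for u, d in pairs)
    out = pd.DataFrame({"pass": passed, "pairs": pair_strings})
    for f in fractions:
        out[f"log2fc_{f}"] = fc[f]
        out[f"pvalue_{f}"] = p[f]
    out.index.name = "gene"
    return out


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Counts and fraction-involvement percentages of passing genes."""
    passing = calls[calls["pass"]]
    n_pass = int(len(passing))
    involvement = {f: 0 for f in ("C", "M", "N")}
    pair_tally: dict[str, int] = {}
    for pairs in passing["pairs"]:
        touched = set()
        for token in pairs.split(";"):
            if not token:
                continue
            up, down = token.split("|")
            touched.add(up[0])
            touched.add(down[0])
            pair_tally[token] = pair_tally.get(token, 0) + 1
        for f in touched:
            involvement[f] += 1
    pct = {
        f: (100.0 * involvement[f] / n_pass if n_pass else 0.0) for f in involvement
    }
    return {
        "n_calls": n_pass,
        "n_genes": int(len(calls)),
        "fraction_involvement_pct": pct,
        "pair_direction_counts": pair_tally,
    }
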