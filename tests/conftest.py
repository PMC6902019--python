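import numpy as np
import pandas as pd
import pytest

from translokit.design import DESIGN_COLUMNS, FRACTIONS, ExperimentDesign, sample_id
from translokit.quant import ProteinQuantMatrix
from translokit.simulate import SimulationConfig, simulate_experiment


def make_design(n_donors: int = 3, timepoints=(0, 15, 60)) -> ExperimentDesign:
    """Standard design: one 10-plex set per donor, channel 131 = internal
    standard, 9 sample channels = 3 fractions x 3 timepoints."""
    from translokit.design import CHANNELS, INTERNAL_STANDARD_CHANNEL

    rows = []
    for d in range(n_donors):
        set_id, donor = f"set{d + 1}", f"D{d + 1}"
        it = iter(CHANNELS[:-1])
        for f in FRACTIONS:
            for tp in timepoints:
                rows.append([set_id, next(it), donor, f, tp, False])
        rows.append([set_id, INTERNAL_STANDARD_CHANNEL, donor, "", -1, True])
    return ExperimentDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def matrix_from_values(values: dict, design: ExperimentDesign,
                       psm_counts: dict | None = None) -> ProteinQuantMatrix:
    """Build a ProteinQuantMatrix from {gene: {sample_id: value}}."""
    vals = pd.DataFrame.from_dict(values, orient="index")
    sample_order = [s for s in design.sample_table()["sample_id"] if s in vals.columns]
    vals = vals.reindex(columns=sample_order)
    genes = vals.index
    if psm_counts is None:
        counts = pd.DataFrame(1, index=genes, columns=design.set_ids)
    else:
        counts = pd.DataFrame.from_dict(psm_counts, orient="index").reindex(
            index=genes, columns=design.set_ids, fill_value=0
        )
    return ProteinQuantMatrix(values=vals, psm_counts=counts)


def matrix_from_deltas(deltas: dict, design: ExperimentDesign, fraction: str = "C",
                       treatment: int = 60, psm_counts: dict | None = None) -> ProteinQuantMatrix:
    """Matrix where gene g has baseline 0 and the given within-donor
    differences at the treatment timepoint of one fraction."""
    values = {}
    samples = design.sample_table()
    for gene, ds in deltas.items():
        row = {s: 0.0 for s in samples["sample_id"]}
        for d, delta in enumerate(ds):
            row[sample_id(f"set{d + 1}", f"D{d + 1}", fraction, treatment)] = float(delta)
        values[gene] = row
    return matrix_from_values(values, design, psm_counts)


def diffstat_table(rows) -> pd.DataFrame:
    """DiffStat table from (gene, fraction, log2fc, pvalue) tuples."""
    df = pd.DataFrame(rows, columns=["gene", "fraction", "log2fc", "pvalue"])
    df["contrast"] = "60min_vs_0min"
    return df


@pytest.fixture(scope="session")
def small_experiment():
    """A modest simulated experiment reused by read-only tests."""
    cfg = SimulationConfig(n_proteins=300, n_decoys=300, seed=42)
    return simulate_experiment(cfg), cfg


# ---------------------------------------------------------------------------
# independent oracles


def regularized_incomplete_beta(a: float, b: float, x: float) -> float:
    """Regularized incomplete beta I_x(a, b) by Lentz's continued fraction.

    Pure-python oracle used to compute t-distribution tail probabilities
    independently of any statistics library.
    """
    import math

    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_beta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    front = math.exp(a * math.log(x) + b * math.log(1.0 - x) - ln_beta) / a
    if x > (a + 1.0) / (a + b + 2.0):
        return 1.0 - regularized_incomplete_beta(b, a, 1.0 - x)
    # Lentz's algorithm for the continued fraction
    tiny = 1e-300
    f, c, d = 1.0, 1.0, 0.0
    for i in range(0, 400):
        m = i // 2
        if i == 0:
            num = 1.0
        elif i % 2 == 0:
            num = m * (b - m) * x / ((a + 2 * m - 1) * (a + 2 * m))
        else:
            num = -(a + m) * (a + b + m) * x / ((a + 2 * m) * (a + 2 * m + 1))
        d = 1.0 + num * d
        d = 1.0 / (d if abs(d) > tiny else tiny)
        c = 1.0 + num / (c if abs(c) > tiny else tiny)
        f *= c * d
        if abs(1.0 - c * d) < 1e-16:
            break
    return front * (f - 1.0)


def student_t_sf(t: float, df: float) -> float:
    """P(T > t) for Student's t, via the incomplete-beta oracle."""
    x = df / (df + t * t)
    p_half = 0.5 * regularized_incomplete_beta(df / 2.0, 0.5, x)
    return p_half if t >= 0 else 1.0 - p_half


def paired_t_pvalue(deltas) -> float:
    """Two-sided paired t-test P from raw within-pair differences, computed
    with explicit arithmetic only (the brute-force oracle)."""
    import math

    n = len(deltas)
    mean = sum(deltas) / n
    var = sum((d - mean) ** 2 for d in deltas) / (n - 1)
    if var == 0:
        return 1.0 if mean == 0 else 0.0
    t = mean / math.sqrt(var / n)
    return 2.0 * student_t_sf(abs(t), n - 1)


def picked_fdr_bruteforce(target_scores: dict, decoy_scores: dict, threshold: float) -> set:
    """Picked protein FDR by enumeration over all score cutoffs.

    For continuous (tie-free) scores: per gene keep the better of the
    target/decoy pair, then for every candidate cutoff count decoys/targets
    at or above it and keep the largest target set whose estimate is within
    the threshold.
    """
    picked = []
    for gene in set(target_scores) | set(decoy_scores):
        t = target_scores.get(gene, float("-inf"))
        d = decoy_scores.get(gene, float("-inf"))
        picked.append((t, False, gene) if t >= d else ((d, True, gene)))
    best_targets: set = set()
    for cutoff, _, _ in picked:
        above = [e for e in picked if e[0] >= cutoff]
        n_t = sum(1 for e in above if not e[1])
        n_d = sum(1 for e in above if e[1])
        if n_t and n_d / n_t <= threshold:
            targets = {g for s, isd, g in above if not isd}
            if len(targets) > len(best_targets):
                best_targets = targets
    return best_targets
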