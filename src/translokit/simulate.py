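"""Synthetic TMT subcellular-fractionation experiments with known ground truth.

The generator emulates the study design the analysis modules assume: per
donor, one TMT 10-plex set carrying 9 samples (3 fractions × 3 stimulation
timepoints) plus the pooled internal-standard channel 131 shared across
sets.  Fractionation is an enrichment, not an isolation: a row-stochastic
purity matrix mixes the true compartment profiles into the measured
fractions.  A configurable subset of proteins translocates — moves
abundance mass from a source to a sink compartment upon stimulation — with
mass conserved.  Per-PSM multiplicative reporter noise makes protein-level
variance shrink with PSM count, which is exactly the structure the
moderated statistics downstream exploit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    CHANNELS,
    DESIGN_COLUMNS,
    FRACTIONS,
    INTERNAL_STANDARD_CHANNEL,
    TIMEPOINTS,
    ExperimentDesign,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Resting compartment profiles: (dominant, secondary, remainder) masses.
_PROFILE_PLAIN = (0.8, 0.1, 0.1)
_PROFILE_TRANSLOCATOR = (0.55, 0.35, 0.10)  # (source, sink, third)


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment.

    ``effect_size`` is the log2 gain of the sink compartment at 60 min; the
    moved mass is ``p_sink * (2**effect_size - 1)``, debited from the source
    so total abundance is conserved.  ``attenuation_15min`` scales the
    effect size at the 15 min timepoint.
    """

    n_proteins: int = 2000
    n_decoys: int = 2000
    compartments: tuple = FRACTIONS
    purity_matrix: np.ndarray | None = None  # rows: measured fraction; cols: true compartment
    n_donors: int = 3
    timepoints: tuple = TIMEPOINTS
    translocator_fraction: float = 0.05
    effect_size: float = 0.6
    attenuation_15min: float = 0.5
    donor_sd: float = 0.1
    psm_noise_sd: float = 0.2
    psm_count_mean_extra: float = 2.0  # PSMs per gene per set ~ 1 + Poisson(this)
    abundance_log2_mean: float = 16.0
    abundance_log2_sd: float = 2.0
    decoy_score_shift: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.purity_matrix is None:
            self.purity_matrix = default_purity_matrix()
        self.purity_matrix = np.asarray(self.purity_matrix, dtype=float)
        if self.purity_matrix.shape != (3, 3):
            raise ValueError("purity_matrix must be 3x3")
        rowsums = self.purity_matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("purity_matrix rows must sum to 1")
        if np.any(self.purity_matrix < 0):
            raise ValueError("purity_matrix entries must be non-negative")
        if not 0.0 <= self.translocator_fraction <= 1.0:
            raise ValueError("translocator_fraction must lie in [0, 1]")
        if not set(self.timepoints) <= set(TIMEPOINTS):
            raise ValueError(f"timepoints must be a subset of {TIMEPOINTS}")
        if min(self.n_proteins, self.n_donors) < 1 or self.n_decoys < 0:
            raise ValueError("counts must be >= 1 (decoys >= 0)")
        if self.n_decoys > self.n_proteins:
            raise ValueError("n_decoys cannot exceed n_proteins (decoys pair with targets)")
        for name in ("donor_sd", "psm_noise_sd", "abundance_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.attenuation_15min <= 1.0:
            raise ValueError("attenuation_15min must lie in [0, 1]")


def default_purity_matrix() -> np.ndarray:
    """Enrichment, not isolation: 0.8 of a compartment ends up in its own
    fraction, 0.1 in each of the others."""
    return np.full((3, 3), 0.1) + np.eye(3) * 0.7


def _random_peptides(rng: np.random.Generator, n: int, length: int = 12) -> np.ndarray:
    idx = rng.integers(0, len(_AA), size=(n, length))
    return np.array(["".join(row) for row in _AA[idx]])


def profile_at(gt_row: pd.Series, timepoint: int) -> np.ndarray:
    """True compartment proportion vector (C, M, N) of a gene at a timepoint."""
    prof = np.array([gt_row["p_C"], gt_row["p_M"], gt_row["p_N"]], dtype=float)
    if gt_row.get("is_translocator", False) and timepoint in (15, 60):
        m = gt_row["moved_mass_15"] if timepoint == 15 else gt_row["moved_mass_60"]
        src = FRACTIONS.index(gt_row["source"])
        snk = FRACTIONS.index(gt_row["sink"])
        prof[src] -= m
        prof[snk] += m
    return prof


def simulate_experiment(config: SimulationConfig):
    """Simulate PSM-level reporter intensities for the full design.

    Returns ``(psm_table, design, ground_truth)``.  The internal-standard
    channel of every PSM carries the grand mean of that PSM's expected
    sample intensities over all donors, fractions and timepoints (the
    pooled-aliquot design), times its own PSM noise.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_proteins
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    set_ids = [f"set{i + 1}" for i in range(config.n_donors)]
    timepoints = sorted(config.timepoints)
    n_tp = len(timepoints)

    # --- ground truth -----------------------------------------------------
    dominant = rng.integers(0, 3, size=n_genes)
    n_trans = int(round(config.translocator_fraction * n_genes))
    trans_idx = rng.choice(n_genes, size=n_trans, replace=False)
    is_trans = np.zeros(n_genes, dtype=bool)
    is_trans[trans_idx] = True
    # sink: one of the two non-dominant compartments, uniformly
    sink = np.full(n_genes, -1)
    offs = rng.integers(1, 3, size=n_genes)  # dominant+1 or dominant+2 mod 3
    sink[trans_idx] = (dominant[trans_idx] + offs[trans_idx]) % 3

    profiles = np.zeros((n_genes, 3))
    dom_m, sec_m, rem_m = _PROFILE_PLAIN
    for c in range(3):
        sel = dominant == c
        profiles[sel] = rem_m
        profiles[sel, c] = dom_m
    src_m, snk_m, thr_m = _PROFILE_TRANSLOCATOR
    for g in trans_idx:
        profiles[g] = thr_m
        profiles[g, dominant[g]] = src_m
        profiles[g, sink[g]] = snk_m

    def moved_mass(effect: float) -> np.ndarray:
        m = np.zeros(n_genes)
        if n_trans:
            gain = profiles[trans_idx, sink[trans_idx]] * (2.0 ** effect - 1.0)
            avail = 0.95 * profiles[trans_idx, dominant[trans_idx]]
            m[trans_idx] = np.minimum(gain, avail)
        return m

    m60 = moved_mass(config.effect_size)
    m15 = moved_mass(config.effect_size * config.attenuation_15min)

    baseline = 2.0 ** rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, size=n_genes)
    donor_offset = rng.normal(0.0, config.donor_sd, size=config.n_donors)

    ground_truth = pd.DataFrame(
        {
            "gene": genes,
            "is_decoy": False,
            "dominant": [FRACTIONS[c] for c in dominant],
            "p_C": profiles[:, 0],
            "p_M": profiles[:, 1],
            "p_N": profiles[:, 2],
            "is_translocator": is_trans,
            "source": [FRACTIONS[dominant[g]] if is_trans[g] else "" for g in range(n_genes)],
            "sink": [FRACTIONS[sink[g]] if is_trans[g] else "" for g in range(n_genes)],
            "moved_mass_15": m15,
            "moved_mass_60": m60,
            "effect_size": np.where(is_trans, config.effect_size, 0.0),
            "baseline": baseline,
        }
    )

    # --- expected mixed signals: gene x fraction x timepoint --------------
    # profile per timepoint, with translocator mass moved
    prof_t = np.repeat(profiles[:, None, :], n_tp, axis=1)  # (gene, tp, compartment)
    for j, tp in enumerate(timepoints):
        if tp == 15:
            mv = m15
        elif tp == 60:
            mv = m60
        else:
            continue
        prof_t[trans_idx, j, dominant[trans_idx]] -= mv[trans_idx]
        prof_t[trans_idx, j, sink[trans_idx]] += mv[trans_idx]
    # mixed measured signal s(g, f, tp) = sum_c purity[f, c] * profile[g, tp, c]
    mixed = np.einsum("fc,gtc->gft", config.purity_matrix, prof_t)  # (gene, fraction, tp)

    # expected intensity per donor: baseline * mixed * 2**offset
    # internal standard: grand mean over all donors x fractions x timepoints
    is_base = baseline * mixed.mean(axis=(1, 2)) * np.mean(2.0 ** donor_offset)

    # --- design table -----------------------------------------------------
    design_rows = []
    for d in range(config.n_donors):
        ch_iter = iter(CHANNELS[:-1])
        for f in FRACTIONS:
            for tp in timepoints:
                design_rows.append([set_ids[d], next(ch_iter), donors[d], f, tp, False])
        design_rows.append([set_ids[d], INTERNAL_STANDARD_CHANNEL, donors[d], "", -1, True])
    design = ExperimentDesign(pd.DataFrame(design_rows, columns=DESIGN_COLUMNS))

    # channel order used for intensity columns within a set
    sample_ft = [(fi, ti) for fi in range(3) for ti in range(n_tp)]

    # --- PSM rows ---------------------------------------------------------
    frames = []
    psm_serial = 0
    for d in range(config.n_donors):
        n_psm = 1 + rng.poisson(config.psm_count_mean_extra, size=n_genes)
        total = int(n_psm.sum())
        gene_idx = np.repeat(np.arange(n_genes), n_psm)
        eps = rng.normal(0.0, config.psm_noise_sd, size=(total, 10))
        inten = np.empty((total, 10))
        scale = 2.0 ** donor_offset[d]
        for ch, (fi, ti) in enumerate(sample_ft):
            inten[:, ch] = baseline[gene_idx] * mixed[gene_idx, fi, ti] * scale * 2.0 ** eps[:, ch]
        inten[:, 9] = is_base[gene_idx] * 2.0 ** eps[:, 9]
        scores = rng.normal(config.decoy_score_shift, 1.0, size=total)
        peptides = _random_peptides(rng, total)

        # decoy PSMs: paired with the first n_decoys target genes
        if config.n_decoys:
            n_psm_dec = 1 + rng.poisson(config.psm_count_mean_extra, size=config.n_decoys)
            total_dec = int(n_psm_dec.sum())
            dec_gene_idx = np.repeat(np.arange(config.n_decoys), n_psm_dec)
            eps_d = rng.normal(0.0, config.psm_noise_sd, size=(total_dec, 10))
            inten_d = np.empty((total_dec, 10))
            for ch, (fi, ti) in enumerate(sample_ft):
                inten_d[:, ch] = (
                    baseline[dec_gene_idx] * mixed[dec_gene_idx, fi, ti] * scale * 2.0 ** eps_d[:, ch]
                )
            inten_d[:, 9] = is_base[dec_gene_idx] * 2.0 ** eps_d[:, 9]
            scores_d = rng.normal(0.0, 1.0, size=total_dec)
            peptides_d = _random_peptides(rng, total_dec)
            gene_idx = np.concatenate([gene_idx, dec_gene_idx])
            inten = np.vstack([inten, inten_d])
            scores = np.concatenate([scores, scores_d])
            peptides = np.concatenate([peptides, peptides_d])
            is_decoy = np.concatenate(
                [np.zeros(total, dtype=bool), np.ones(total_dec, dtype=bool)]
            )
        else:
            is_decoy = np.zeros(total, dtype=bool)

        n_rows = len(gene_idx)
        frame = pd.DataFrame(
            {
                "psm_id": [f"PSM{psm_serial + i:08d}" for i in range(n_rows)],
                "peptide": peptides,
                "gene": genes[gene_idx],
                "is_decoy": is_decoy,
                "score": scores,
                "set_id": set_ids[d],
                "ipg_fraction": rng.integers(1, 73, size=n_rows),
            }
        )
        for ch_i, ch in enumerate(CHANNELS):
            frame[f"tmt_{ch}"] = inten[:, ch_i]
        frames.append(frame)
        psm_serial += n_rows

    psm_table = pd.concat(frames, ignore_index=True)
    return psm_table, design, ground_truth


def simulate_cell_intensities(
    n_cells: int,
    conditions,
    nuclear_shift: float,
    seed: int,
    base_nuclear_share: float = 0.35,
    share_concentration: float = 30.0,
    total_log_mean: float = 7.0,
    total_log_sd: float = 0.4,
    unstimulated: str | None = None,
) -> pd.DataFrame:
    """Per-cell nuclear/cytosolic intensities for imaging-statistics tests.

    The first (or named) condition is the unstimulated reference; every
    other condition's expected nuclear share is shifted by ``nuclear_shift``.
    Per-cell shares follow a Beta law around the condition mean; total cell
    intensity is log-normal, and nuclear/cytosolic intensities are
    share-splits of the total.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    if unstimulated is None:
        unstimulated = conditions[0]
    if unstimulated not in conditions:
        raise ValueError(f"unstimulated condition {unstimulated!r} not in conditions")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        share = base_nuclear_share + (0.0 if cond == unstimulated else nuclear_shift)
        share = float(np.clip(share, 1e-3, 1.0 - 1e-3))
        a = share * share_concentration
        b = (1.0 - share) * share_concentration
        shares = rng.beta(a, b, size=n_cells)
        totals = np.exp(rng.normal(total_log_mean, total_log_sd, size=n_cells))
        for i in range(n_cells):
            rows.append(
                {
                    "cell_id": f"{cond}_{i:05d}",
                    "condition": cond,
                    "nuclear": shares[i] * totals[i],
                    "cytosolic": (1.0 - shares[i]) * totals[i],
                }
            )
    return pd.DataFrame(rows)


def write_tables(psm_table: pd.DataFrame, design: ExperimentDesign,
                 ground_truth: pd.DataFrame, outdir) -> None:
    """Write the simulated experiment as the three TSV artifacts."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    psm_table.to_csv(out / "psms.tsv", sep="\t", index=False)
    design.to_tsv(out / "design.tsv")
    ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
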