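"""PSM-level TMT reporter intensities → gene-level quantification matrix.

The chain is: per-PSM log2 ratios to the internal-standard channel,
median-centering per sample, median rollup over the PSMs of peptides unique
to a gene symbol, and a picked target-decoy FDR gate at the protein-group
(gene-symbol) level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign

TMT_PREFIX = "tmt_"


@dataclass
class ProteinQuantMatrix:
    """Gene × sample log2 ratios plus per-gene PSM bookkeeping.

    ``values``: DataFrame indexed by gene, columns are sample ids
    (``set:donor:fraction:timepoint``).  ``psm_counts``: genes × set ids,
    the number of PSMs used for each gene in each set (0 when absent).
    """

    values: pd.DataFrame
    psm_counts: pd.DataFrame

    @property
    def median_psm_count(self) -> pd.Series:
        """Median PSM count per gene across sets (sets where the gene is
        absent count as 0, mirroring a missing identification)."""
        return self.psm_counts.median(axis=1)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, values_path, counts_path=None) -> None:
        self.values.to_csv(values_path, sep="\t")
        if counts_path is not None:
            self.psm_counts.to_csv(counts_path, sep="\t")


def read_psm_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["is_decoy"] = table["is_decoy"].astype(bool)
    return table


def _intensity_columns(psms: pd.DataFrame) -> list[str]:
    cols = [c for c in psms.columns if c.startswith(TMT_PREFIX)]
    if not cols:
        raise ValueError("PSM table has no tmt_* intensity columns")
    return cols


def compute_psm_ratios(psms: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Per-PSM log2 ratios of each sample channel to the internal standard.

    Returns a long table (psm_id, peptide, gene, is_decoy, score, set_id,
    sample_id, fraction, timepoint_min, log2_ratio).  PSMs whose
    internal-standard intensity is zero (or whose reporter row is all zero)
    are dropped; the count of dropped PSMs is stored in ``.attrs["n_dropped"]``.
    """
    cols = _intensity_columns(psms)
    if (psms[cols].to_numpy(dtype=float) == 0).all(axis=1).any():
        raise ValueError("PSM with all-zero reporter intensities")
    frames = []
    n_dropped = 0
    for set_id, grp in psms.groupby("set_id", sort=True):
        is_channel = design.internal_standard_channel(set_id)
        is_col = f"{TMT_PREFIX}{is_channel}"
        if is_col not in grp.columns:
            raise KeyError(f"internal-standard column {is_col} missing from PSM table")
        inten = grp[cols].to_numpy(dtype=float)
        if np.any(inten < 0):
            raise ValueError("negative reporter intensity")
        quantifiable = grp[is_col].to_numpy(dtype=float) > 0
        n_dropped += int((~quantifiable).sum())
        grp = grp.loc[quantifiable]
        if grp.empty:
            continue
        is_vals = grp[is_col].to_numpy(dtype=float)
        samples = design.sample_channels(set_id)
        for _, srow in samples.iterrows():
            col = f"{TMT_PREFIX}{srow['channel']}"
            if col not in grp.columns:
                raise KeyError(f"missing design channel column {col} in PSM table")
            sample_vals = grp[col].to_numpy(dtype=float)
            with np.errstate(divide="ignore"):
                ratio = np.where(sample_vals > 0, np.log2(sample_vals / is_vals), np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "psm_id": grp["psm_id"].to_numpy(),
                        "peptide": grp["peptide"].to_numpy(),
                        "gene": grp["gene"].to_numpy(),
                        "is_decoy": grp["is_decoy"].to_numpy(),
                        "score": grp["score"].to_numpy(),
                        "set_id": set_id,
                        "sample_id": srow["sample_id"],
                        "fraction": srow["fraction"],
                        "timepoint_min": int(srow["timepoint_min"]),
                        "log2_ratio": ratio,
                    }
                )
            )
    if not frames:
        raise ValueError("no quantifiable PSMs")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def normalize_sample_median(ratios: pd.DataFrame) -> pd.DataFrame:
    """Center each sample column at median 0 (log-scale median normalization)."""
    out = ratios.copy()
    finite = np.isfinite(out["log2_ratio"])
    med = out.loc[finite].groupby("sample_id")["log2_ratio"].median()
    if med.isna().any():
        raise ValueError("sample with no quantified PSMs")
    out["log2_ratio"] = out["log2_ratio"] - out["sample_id"].map(med).to_numpy()
    out.attrs.update(ratios.attrs)
    return out


def unique_gene_peptides(ratios_or_psms: pd.DataFrame) -> pd.Series:
    """Boolean mask: True where the row's peptide maps to exactly one gene
    symbol across the whole table (decoys pair with their target symbol, so
    the decoy flag is part of the identity)."""
    key = ratios_or_psms["gene"].astype(str) + "|" + ratios_or_psms["is_decoy"].astype(int).astype(str)
    n_genes = key.groupby(ratios_or_psms["peptide"]).nunique()
    unique_peps = set(n_genes.index[n_genes == 1])
    return ratios_or_psms["peptide"].isin(unique_peps)


def rollup_to_protein(ratios: pd.DataFrame, design: ExperimentDesign,
                      include_decoys: bool = False) -> ProteinQuantMatrix:
    """Gene-level matrix: median over unique-peptide PSM log2 ratios.

    Peptides shared by more than one gene symbol are excluded entirely.
    Genes absent from a set simply yield missing values in that set's
    sample columns (removal is the job of :func:`filter_full_quantitation`).
    """
    mask = unique_gene_peptides(ratios)
    rows = ratios.loc[mask]
    if not include_decoys:
        rows = rows.loc[~rows["is_decoy"]]
    finite = rows.loc[np.isfinite(rows["log2_ratio"])]
    values = finite.pivot_table(
        index="gene", columns="sample_id", values="log2_ratio", aggfunc="median"
    )
    # order sample columns by design
    sample_order = [s for s in design.sample_table()["sample_id"] if s in values.columns]
    values = values.reindex(columns=sample_order)

    counts = (
        rows.groupby(["gene", "set_id"])["psm_id"].nunique().unstack(fill_value=0)
    )
    counts = counts.reindex(index=values.index, columns=design.set_ids, fill_value=0)
    return ProteinQuantMatrix(values=values, psm_counts=counts)


def best_scores_by_gene(psms: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Best PSM search score per gene symbol, split into target and decoy."""
    targets = psms.loc[~psms["is_decoy"]].groupby("gene")["score"].max()
    decoys = psms.loc[psms["is_decoy"]].groupby("gene")["score"].max()
    return targets, decoys


def picked_protein_fdr(
    target_scores: pd.Series,
    decoy_scores: pd.Series,
    threshold: float = 0.01,
) -> set[str]:
    """Picked target-decoy protein FDR on gene-symbol groups.

    Per gene, only the better-scoring of the target/decoy pair survives;
    picked entries are ranked by descending score and the decoy-based FDR
    estimate ``#decoys/#targets`` is walked down the list; targets above the
    deepest rank whose estimate is within ``threshold`` are retained.  Ties
    are broken target-before-decoy, then lexicographically by gene symbol.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    entries = []  # (score, is_decoy, gene)
    genes = set(target_scores.index) | set(decoy_scores.index)
    for gene in genes:
        t = target_scores.get(gene, -np.inf)
        d = decoy_scores.get(gene, -np.inf)
        if t >= d:  # tie goes to the target
            entries.append((float(t), 0, gene))
        else:
            entries.append((float(d), 1, gene))
    # descending score; at equal score target (0) before decoy (1); then gene
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    best_k = -1
    n_t = n_d = 0
    accepted: list[str] = []
    for score, is_decoy, gene in entries:
        if is_decoy:
            n_d += 1
        else:
            n_t += 1
            accepted.append(gene)
        fdr = n_d / n_t if n_t else np.inf
        if fdr <= threshold:
            best_k = len(accepted)
    return set(accepted[:best_k]) if best_k > 0 else set()


def filter_full_quantitation(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Keep only genes quantified in every sample channel of every set."""
    complete = matrix.values.notna().all(axis=1)
    return ProteinQuantMatrix(
        values=matrix.values.loc[complete],
        psm_counts=matrix.psm_counts.loc[complete],
    )


def quantify(psms: pd.DataFrame, design: ExperimentDesign,
             fdr_threshold: float = 0.01) -> tuple[ProteinQuantMatrix, dict]:
    """Full quantification chain with picked-FDR gating.

    Returns the (unfiltered) protein matrix restricted to FDR-retained
    genes, and a funnel-count dict (identified / overlapping /
    fully-quantified and dropped-PSM bookkeeping).
    """
    # decoys carry no meaningful quantification: they are kept only for the
    # protein-level picked FDR, so target PSMs alone feed ratios and medians
    ratios = compute_psm_ratios(psms.loc[~psms["is_decoy"]], design)
    ratios = normalize_sample_median(ratios)
    targets, decoys = best_scores_by_gene(psms)
    retained = picked_protein_fdr(targets, decoys, threshold=fdr_threshold)
    gated = ratios.loc[ratios["gene"].isin(retained)]
    matrix = rollup_to_protein(gated, design)
    n_sets = len(design.set_ids)
    overlapping = (matrix.psm_counts > 0).sum(axis=1) == n_sets
    full = filter_full_quantitation(
        ProteinQuantMatrix(matrix.values.loc[overlapping], matrix.psm_counts.loc[overlapping])
    )
    counts = {
        "psms_total": int(len(psms)),
        "psms_dropped_no_internal_standard": int(ratios.attrs.get("n_dropped", 0)),
        "genes_identified": int(len(matrix.genes)),
        "genes_overlapping_all_sets": int(overlapping.sum()),
        "genes_fully_quantified": int(len(full.genes)),
        "fdr_retained_genes": int(len(retained)),
    }
    return full, counts
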