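"""Compartment classification of quantified proteins and profile QC.

Genes are clustered into k = 3 groups by k-means under the 1 − Pearson
correlation distance, and each cluster is labeled with the fraction whose
sample columns carry its highest mean signal.  The correlation distance is
realised through its standard equivalence: on rows centered and scaled to
unit norm, squared Euclidean distance equals 2·(1 − r), so ordinary
k-means on the embedded rows optimises the correlation-distance objective.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .design import FRACTIONS, ExperimentDesign
from .quant import ProteinQuantMatrix


def row_normalize(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each gene row; returns (normalized rows, constant-row index).

    Constant rows (zero variance) carry no profile shape and are excluded
    from clustering; they are returned separately so callers can report them.
    """
    arr = values.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=0, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    normalized = pd.DataFrame(z, index=values.index, columns=values.columns)
    return normalized.loc[~constant], values.index[constant]


def _unit_norm_rows(z: pd.DataFrame) -> np.ndarray:
    arr = z.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(arr, axis=1, keepdims=True)
    return arr / norms


def kmeans_correlation(
    z: pd.DataFrame, k: int = 3, seed: int = 0, restarts: int = 25
) -> pd.Series:
    """K-means under 1 − Pearson distance; best of ``restarts`` inits."""
    if k > len(z):
        raise ValueError("k exceeds the number of rows")
    embedded = _unit_norm_rows(z)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(embedded)
    return pd.Series(labels, index=z.index, name="cluster")


def label_clusters(
    assignments: pd.Series, values: pd.DataFrame, design: ExperimentDesign
) -> pd.DataFrame:
    """Map clusters to compartments by their strongest fraction columns.

    Per cluster, the mean value over each fraction's sample columns is
    computed; the argmax fraction names the cluster (ties resolved in the
    fixed order C, M, N).  A confidence score is attached per gene: one
    minus the ratio of its mean 1 − r distance to own-cluster members over
    the distance to the nearest other cluster's members (higher = cleaner).
    """
    samples = design.sample_table()
    frac_cols = {
        f: [s for s in samples.loc[samples["fraction"] == f, "sample_id"] if s in values.columns]
        for f in FRACTIONS
    }
    labels = {}
    for cl in sorted(assignments.unique()):
        genes = assignments.index[assignments == cl]
        means = {f: values.loc[genes, cols].to_numpy().mean() for f, cols in frac_cols.items()}
        best = max(FRACTIONS, key=lambda f: (means[f], -FRACTIONS.index(f)))
        labels[cl] = best
    if len(set(labels.values())) < len(labels):
        warnings.warn("multiple clusters mapped to the same fraction", stacklevel=2)

    # correlation-distance confidence against cluster centroids
    z = _unit_norm_rows(values.loc[assignments.index])
    centroids = {}
    for cl in labels:
        member = z[(assignments == cl).to_numpy()]
        centroids[cl] = member.mean(axis=0)
    conf = np.zeros(len(assignments))
    for i, (gene, cl) in enumerate(assignments.items()):
        d_own = 1.0 - float(z[i] @ centroids[cl] / max(np.linalg.norm(centroids[cl]), 1e-12))
        others = [
            1.0 - float(z[i] @ c / max(np.linalg.norm(c), 1e-12))
            for ocl, c in centroids.items()
            if ocl != cl
        ]
        d_other = min(others) if others else np.inf
        conf[i] = 1.0 - d_own / d_other if d_other > 0 else 0.0
    return pd.DataFrame(
        {
            "cluster": assignments.to_numpy(),
            "compartment": [labels[c] for c in assignments],
            "confidence": conf,
        },
        index=assignments.index,
    )


def classify_compartments(
    matrix: ProteinQuantMatrix,
    design: ExperimentDesign,
    k: int = 3,
    seed: int = 0,
    restarts: int = 25,
) -> pd.DataFrame:
    """Row-normalize, cluster, and label: one compartment per gene."""
    z, constant = row_normalize(matrix.values)
    assignments = kmeans_correlation(z, k=k, seed=seed, restarts=restarts)
    table = label_clusters(assignments, matrix.values.loc[z.index], design)
    table.attrs["constant_rows"] = list(constant)
    return table


def pca_qc(matrix: ProteinQuantMatrix, design: ExperimentDesign) -> pd.DataFrame:
    """Per-sample scores on the first two principal components.

    Columns are observations; rows (genes) are centered first.  The
    returned frame carries the fraction of each sample and, in
    ``.attrs["fraction_silhouette"]``, the mean silhouette of the fraction
    grouping in PC space (positive = samples separate by fraction).
    """
    values = matrix.values.dropna(axis=0)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    centered = values.sub(values.mean(axis=1), axis=0)
    X = centered.to_numpy().T  # samples × genes
    scores = PCA(n_components=2, random_state=0).fit_transform(X)
    samples = design.sample_table().set_index("sample_id")
    out = pd.DataFrame(scores, index=values.columns, columns=["PC1", "PC2"])
    out["fraction"] = samples["fraction"].reindex(out.index)
    groups = out["fraction"].dropna()
    if groups.nunique() >= 2:
        sil = float(silhouette_score(scores[: len(groups)], groups.to_numpy()))
    else:
        sil = np.nan
    out.attrs["fraction_silhouette"] = sil
    return out


def column_cluster_order(values: pd.DataFrame) -> list[str]:
    """Average-linkage clustering of sample columns under 1 − Pearson.

    Columns are pre-sorted by name so the linkage (and hence the leaf
    order) is deterministic under ties.  Returns the dendrogram leaf order.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    ordered = values.reindex(sorted(values.columns), axis=1).dropna(axis=0)
    dist = pdist(ordered.to_numpy().T, metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    return [ordered.columns[i] for i in leaves]


def reference_crosstab(
    assignments: pd.DataFrame, reference: pd.Series
) -> pd.DataFrame:
    """Cross-tabulate called compartments against an external gene →
    compartment reference table (shared genes only)."""
    shared = assignments.index.intersection(reference.index)
    return pd.crosstab(
        assignments.loc[shared, "compartment"], reference.loc[shared]
    )
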