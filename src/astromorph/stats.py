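"""Population statistics: motif-structure associations, contact summaries,
the 20-parameter feature matrix, morphology embedding and the parameter
correlation dendrogram.

Motif->structure predictive power is quantified as the conditional
probability p(structure | motif), the fraction of motif instances whose
annotation flags a given underlying structure (axon, RGC soma, neighbouring
astrocyte).  Flags are not exclusive, so rows may sum past 100%.  The quoted
error is, by default, the binomial standard error of the mean flagged
proportion for that motif; a Wilson-interval half-width is available as an
alternative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

MOTIFS = ("sail", "bead", "pad", "bristle", "tube", "end-foot", "hole")
STRUCTURES = ("axon", "soma", "astrocyte")

#: Column order of the 20-parameter morphology feature matrix.
FEATURE_COLUMNS = (
    "fo_area",
    "fo_perimeter",
    "fo_major_axis",
    "fo_minor_axis",
    "fo_circularity",
    "fo_feret_diameter",
    "fo_roundness",
    "fo_solidity",
    "cvh_area",
    "cvh_perimeter",
    "cvh_feret_diameter",
    "latitude_rad",
    "longitude_rad",
    "pct_gfap",
    "dist_cvh_centroid_to_vessel",
    "dist_cvh_centroid_to_fo_com",
    "mean_vessel_diameter",
    "min_vessel_diameter",
    "max_vessel_diameter",
    "n_unique_vessels",
)

__all__ = [
    "MOTIFS",
    "STRUCTURES",
    "FEATURE_COLUMNS",
    "PopulationSummary",
    "motif_structure_probabilities",
    "population_summaries",
    "build_feature_matrix",
    "embed_cluster",
    "correlation_dendrogram",
]


@dataclass(frozen=True)
class PopulationSummary:
    """Cohort-level contact statistics."""

    n_cells: int
    pct_contacting_vessel: float
    pct_contacting_axon: float
    pct_contacting_soma: float
    pct_contacting_neuron: float
    mean_unique_contacts: float
    sem_unique_contacts: float
    contact_distribution: dict[int, int]


def motif_structure_probabilities(
    table: pd.DataFrame, error: str = "binomial", denominator: str = "instance"
) -> pd.DataFrame:
    """p(structure | motif) with error, from a motif annotation table.

    ``table`` has one row per motif instance with columns
    ``cell_id, motif, axon, soma, astrocyte`` (boolean flags).  Probabilities
    are exact percentages of flagged instances; ``denominator="cell"``
    collapses to one row per (cell, motif) first.  Missing motifs are simply
    omitted.  Returns a DataFrame with columns
    ``motif, p_axon, p_soma, p_astro, error, n``.
    """
    if error not in ("binomial", "wilson"):
        raise ValueError("error must be 'binomial' or 'wilson'")
    df = table.copy()
    if denominator == "cell":
        df = (
            df.groupby(["cell_id", "motif"], sort=False)[list(STRUCTURES)]
            .any()
            .reset_index()
        )
    rows = []
    for motif in MOTIFS:
        sub = df[df["motif"] == motif]
        n = len(sub)
        if n == 0:
            continue
        probs = {s: 100.0 * int(sub[s].sum()) / n for s in STRUCTURES}
        p_bar = np.mean([probs[s] for s in STRUCTURES]) / 100.0
        if error == "binomial":
            err = 100.0 * float(np.sqrt(p_bar * (1 - p_bar) / n))
        else:
            z = 1.959963984540054
            err = 100.0 * float(
                z * np.sqrt(p_bar * (1 - p_bar) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
            )
        rows.append(
            {
                "motif": motif,
                "p_axon": probs["axon"],
                "p_soma": probs["soma"],
                "p_astro": probs["astrocyte"],
                "error": err,
                "n": n,
            }
        )
    out = pd.DataFrame(rows, columns=["motif", "p_axon", "p_soma", "p_astro", "error", "n"])
    out.attrs["error_method"] = error
    out.attrs["denominator"] = denominator
    return out


def population_summaries(records: pd.DataFrame) -> PopulationSummary:
    """Cohort summary of vessel/neuron contact (fractions, mean +/- SEM).

    ``records`` needs a ``n_unique_vessels`` column and boolean
    ``contacts_axon`` / ``contacts_soma`` columns.
    """
    if len(records) == 0:
        raise ValueError("empty input")
    n = len(records)
    counts = records["n_unique_vessels"].to_numpy(float)
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    ax = records.get("contacts_axon", pd.Series(False, index=records.index)).to_numpy(bool)
    so = records.get("contacts_soma", pd.Series(False, index=records.index)).to_numpy(bool)
    dist: dict[int, int] = {}
    for c in counts.astype(int):
        dist[int(c)] = dist.get(int(c), 0) + 1
    return PopulationSummary(
        n_cells=n,
        pct_contacting_vessel=100.0 * float((counts >= 1).sum()) / n,
        pct_contacting_axon=100.0 * float(ax.sum()) / n,
        pct_contacting_soma=100.0 * float(so.sum()) / n,
        pct_contacting_neuron=100.0 * float((ax | so).sum()) / n,
        mean_unique_contacts=mean,
        sem_unique_contacts=sem,
        contact_distribution=dict(sorted(dist.items())),
    )


def build_feature_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 20-column feature matrix in the canonical column order.

    Raises on any missing column or missing value, naming the cell and
    column, so that incomplete records can never reach the embedding.
    """
    missing_cols = [c for c in FEATURE_COLUMNS if c not in records.columns]
    if missing_cols:
        raise KeyError(f"missing feature column(s): {missing_cols}")
    mat = records.loc[:, list(FEATURE_COLUMNS)].astype(float)
    bad = mat.isna() | ~np.isfinite(mat)
    if bad.any().any():
        cell = records.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[cell]][0]
        raise ValueError(f"cell {cell!r}: missing value in column {col!r}")
    return mat


def embed_cluster(
    matrix: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 15,
    min_samples: int = 3,
    min_cluster_size: int = 10,
    scale: bool = True,
    min_dist: float | None = None,
):
    """UMAP embedding of the feature matrix plus HDBSCAN density clusters.

    Features are z-scored by default (mixed units make unscaled distances
    meaningless); zero-variance columns are left centred.  Returns
    ``(embedding (n, 2) array, labels (noise = -1), metadata dict)``.
    """
    import umap  # deferred: numba-compiled import is slow
    from sklearn.cluster import HDBSCAN

    X = np.asarray(matrix, float)
    if len(X) < max(n_neighbors + 1, min_cluster_size):
        raise ValueError(
            f"need >= {max(n_neighbors + 1, min_cluster_size)} rows, got {len(X)}"
        )
    if scale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    kwargs = {} if min_dist is None else {"min_dist": min_dist}
    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2, random_state=seed, **kwargs)
    emb = reducer.fit_transform(X)
    labels = HDBSCAN(min_samples=min_samples, min_cluster_size=min_cluster_size).fit_predict(
        emb
    )
    meta = {
        "n_neighbors": n_neighbors,
        "min_dist": reducer.min_dist,
        "min_samples": min_samples,
        "min_cluster_size": min_cluster_size,
        "scaled": scale,
        "seed": seed,
        "clusterer": "sklearn.cluster.HDBSCAN",
    }
    return np.asarray(emb), np.asarray(labels), meta


def correlation_dendrogram(matrix: pd.DataFrame):
    """Average-linkage clustering of features at distance 1 - |Pearson r|.

    Zero-variance columns are excluded with a warning.  Returns
    ``(linkage matrix, leaf-ordered feature names, newick string)``.
    """
    import warnings

    df = pd.DataFrame(matrix)
    keep = [c for c in df.columns if df[c].std() > 0]
    dropped = [c for c in df.columns if c not in keep]
    if dropped:
        warnings.warn(f"zero-variance feature(s) excluded: {dropped}", stacklevel=2)
    if len(keep) < 3:
        raise ValueError("need >= 3 features with variance > 0")
    corr = df[keep].corr().to_numpy()
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)  # |r| can exceed 1 by epsilon
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = average(squareform(dist, checks=False))
    order = [keep[i] for i in leaves_list(Z)]
    newick = _linkage_to_newick(Z, keep)
    return Z, order, newick


def _linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    n = len(names)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int, buf: io.StringIO):
        if node < n:
            buf.write(str(names[node]).replace(" ", "_"))
            return
        row = Z[node - n]
        left, right, h = int(row[0]), int(row[1]), float(row[2])
        buf.write("(")
        render(left, buf)
        buf.write(f":{h - heights[left]:.6g},")
        render(right, buf)
        buf.write(f":{h - heights[right]:.6g})")
        heights[node] = h

    buf = io.StringIO()
    root = n + len(Z) - 1
    render(root, buf)
    buf.write(";")
    return buf.getvalue()
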