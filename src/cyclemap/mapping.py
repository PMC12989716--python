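"""The cell cycle map: graph, embedding, clustering and phase annotation.

Cells (rows of a z-scored marker table) are connected in a k-nearest-neighbor
graph on the full standardized feature space.  Communities found by Leiden
clustering on that graph are annotated with cell cycle phases — G1, S, G2,
M and the endocycle — by a rule table over conserved marker expression, and
a 2-D diffusion embedding lays the cells out so that progression through the
cycle (and the endocycle branch leaving G2) appears as a trajectory.

:class:`CellCycleMapper` is the estimator tying the stages together; the
module-level functions expose each stage individually.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .synthetic import feature_columns

__all__ = [
    "CellCycleMap",
    "CellCycleMapper",
    "build_knn_graph",
    "embed_2d",
    "leiden_cluster",
    "annotate_phases",
    "phase_marker_summary",
]

logger = logging.getLogger(__name__)

PHASE_LABELS = ("G1", "S", "G2", "M", "endocycle", "unassigned")


@dataclass
class CellCycleMap:
    """Result container: per-cell map assignments plus run metadata.

    ``cells`` has columns embed_x, embed_y, cluster, phase (indexed like the
    input table); ``cluster_phases`` maps cluster id -> phase label.
    """

    cells: pd.DataFrame
    cluster_phases: dict
    graph_meta: dict = field(default_factory=dict)
    clustering_meta: dict = field(default_factory=dict)

    @property
    def phases(self) -> pd.Series:
        return self.cells["phase"]

    @property
    def clusters(self) -> pd.Series:
        return self.cells["cluster"]

    @property
    def embedding(self) -> np.ndarray:
        return self.cells[["embed_x", "embed_y"]].to_numpy()


def build_knn_graph(table: pd.DataFrame, k: int = 30) -> ig.Graph:
    """Undirected kNN graph on z-scored features (Euclidean metric).

    Each cell is linked to its ``k`` nearest neighbors; the directed kNN
    relation is symmetrized by union, so an edge exists when either endpoint
    lists the other.  Distance ties are broken by row index (duplicated cells
    become zero-distance neighbors first).  The connected-component count is
    logged.
    """
    feats = feature_columns(table)
    X = np.asarray(table[feats].to_numpy(), dtype=float)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError(f"k must be in (0, n={n}), got {k}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(X)
    _, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self
    edges = {(min(a, b), max(a, b)) for a, b in zip(rows.tolist(), cols.tolist()) if a != b}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    g["k"] = k
    g["metric"] = "euclidean"
    n_comp = len(g.connected_components())
    logger.info("kNN graph: %d cells, %d edges, %d connected components",
                n, g.ecount(), n_comp)
    return g


def embed_2d(table: pd.DataFrame, n_neighbors: int = 30, seed: int = 0,
             method: str = "diffusion", diffusion_time: int = 3) -> np.ndarray:
    """2-D nonlinear embedding of cells (the cell cycle map layout).

    The default is a diffusion-map embedding: an adaptive-bandwidth Gaussian
    kernel on the kNN neighborhood, row-normalized into a diffusion operator,
    whose leading non-trivial eigenvectors (scaled by eigenvalue^t) give the
    coordinates.  Diffusion geometry preserves continuous, branched
    trajectories such as cell cycle progression.  ``method="umap"`` swaps in
    UMAP with the same neighborhood size.  Deterministic given ``seed``.
    """
    feats = feature_columns(table)
    X = np.asarray(table[feats].to_numpy(), dtype=float)
    n = X.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more cells ({n}) than neighbors ({n_neighbors})")
    if method == "umap":
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = umap.UMAP(
                n_components=2, n_neighbors=n_neighbors, random_state=seed
            ).fit_transform(X)
        return np.asarray(coords, dtype=float)
    if method != "diffusion":
        raise ValueError(f"unknown embedding method {method!r}")

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    sigma = dist[:, -1]  # adaptive bandwidth: distance to k-th neighbor
    sigma = np.maximum(sigma, 1e-12)
    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), n_neighbors + 1)
    W = sp.csr_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n, n))
    W = (W + W.T) / 2.0
    d = np.asarray(W.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(d)
    S = sp.diags(d_inv_sqrt) @ W @ sp.diags(d_inv_sqrt)  # symmetric conjugate
    # deterministic start vector derived from the seed
    v0 = np.random.default_rng(seed).standard_normal(n)
    vals, vecs = eigsh(S, k=3, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = d_inv_sqrt[:, None] * vecs  # right eigenvectors of the Markov operator
    coords = psi[:, 1:3] * (vals[1:3] ** diffusion_time)
    # fix sign convention so coordinates are reproducible across LAPACK builds
    for j in range(2):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def leiden_cluster(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community detection on the cell graph (RB-configuration quality).

    Deterministic given ``seed``.  Returns an integer cluster id per node.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def scan_resolution(graph: ig.Graph, target: int = 5, seed: int = 0,
                    grid: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Pick the smallest resolution on a log grid yielding >= ``target`` clusters.

    Returns ``(resolution, labels)``.  Falls back to the largest grid value
    (with a warning) if the target count is never reached.
    """
    if grid is None:
        grid = np.logspace(-2.5, 1, 22)
    labels = None
    for res in grid:
        labels = leiden_cluster(graph, resolution=float(res), seed=seed)
        if labels.max() + 1 >= target:
            return float(res), labels
    warnings.warn(
        f"resolution scan never reached {target} clusters "
        f"(max {labels.max() + 1}); using largest resolution", UserWarning,
    )
    return float(grid[-1]), labels


def _unique_argmax(series: pd.Series) -> object | None:
    """Index of the unique maximum, or None on an exact tie."""
    mx = series.max()
    top = series.index[series == mx]
    return top[0] if len(top) == 1 else None


def annotate_phases(table: pd.DataFrame, clusters: np.ndarray) -> CellCycleMap:
    """Assign one cell cycle phase per cluster by conserved-marker rules.

    Rule table (applied to cluster means of the z-scored markers):

    1. **endocycle** — the cluster maximizing mean RAIDD, provided its mean
       CDK1 is below the across-cluster median while mean Wee1 and mean CDK2
       are above it (the endocycle signature);
    2. among the remaining clusters, **M** = max mean CDK1 (mitotic entry),
       **G1** = max mean Cyclin D1, **S** = max mean of the Cyclin E1/E2
       composite, and **G2** = the cluster left over.

    Exact ties or failed signature checks leave phases unassigned with a
    warning; a cluster count other than five is annotated best-effort.
    """
    needed = ["Cyclin E1", "Cyclin E2", "Cyclin D1", "CDK1", "Wee1", "CDK2", "RAIDD"]
    missing = [m for m in needed if m not in table.columns]
    if missing:
        raise ValueError(f"annotation requires markers {missing}")
    clusters = np.asarray(clusters)
    if clusters.shape[0] != len(table):
        raise ValueError("clusters must align with table rows")
    n_clusters = clusters.max() + 1
    if n_clusters != 5:
        warnings.warn(
            f"expected 5 clusters, got {n_clusters}; annotating best-effort",
            UserWarning,
        )
    means = table[needed].groupby(clusters).mean()
    cluster_phases: dict[int, str] = {int(c): "unassigned" for c in means.index}

    remaining = list(means.index)
    endo = _unique_argmax(means["RAIDD"])
    if endo is not None and len(means) >= 2:
        med_cdk1 = means["CDK1"].median()
        med_wee1 = means["Wee1"].median()
        med_cdk2 = means["CDK2"].median()
        sig_ok = (
            means.loc[endo, "CDK1"] < med_cdk1
            and means.loc[endo, "Wee1"] > med_wee1
            and means.loc[endo, "CDK2"] > med_cdk2
        )
        if sig_ok:
            cluster_phases[int(endo)] = "endocycle"
            remaining.remove(endo)
        else:
            warnings.warn(
                "max-RAIDD cluster lacks the endocycle signature "
                "(CDK1 low, Wee1/CDK2 high); no endocycle cluster assigned",
                UserWarning,
            )
    elif endo is None:
        warnings.warn("RAIDD tie across clusters; no endocycle cluster assigned", UserWarning)

    composite = (means["Cyclin E1"] + means["Cyclin E2"]) / 2.0
    for phase, score in (
        ("M", means["CDK1"]),
        ("G1", means["Cyclin D1"]),
        ("S", composite),
    ):
        if not remaining:
            break
        pick = _unique_argmax(score.loc[remaining])
        if pick is None:
            warnings.warn(f"tie while assigning {phase}; left unassigned", UserWarning)
            continue
        cluster_phases[int(pick)] = phase
        remaining.remove(pick)
    if len(remaining) == 1:
        cluster_phases[int(remaining[0])] = "G2"
    elif remaining:
        warnings.warn(
            f"{len(remaining)} clusters left unassigned after rule table", UserWarning
        )

    phases = pd.Series(clusters).map(cluster_phases).to_numpy()
    cells = pd.DataFrame(
        {"cluster": clusters, "phase": phases}, index=table.index
    )
    return CellCycleMap(cells=cells, cluster_phases=cluster_phases)


def phase_marker_summary(cc_map: CellCycleMap, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-phase mean and SD of every marker (the heatmap matrix).

    Phases with no cells yield rows of NaN and are flagged with a warning.
    """
    feats = feature_columns(table)
    by = table[feats].groupby(cc_map.phases.to_numpy())
    means = by.mean()
    sds = by.std(ddof=0)
    present = set(means.index)
    expected = {p for p in cc_map.cluster_phases.values()}
    empty = expected - present
    if empty:
        warnings.warn(f"phases with no cells: {sorted(empty)}", UserWarning)
        for p in empty:
            means.loc[p] = np.nan
            sds.loc[p] = np.nan
    return {"mean": means, "sd": sds}


class CellCycleMapper(BaseEstimator):
    """End-to-end cell cycle mapping estimator.

    ``fit`` builds the kNN graph on the standardized features, clusters it
    with Leiden (auto-scanning the resolution to reach ``target_clusters``
    when ``resolution`` is None), embeds the cells in 2-D and annotates each
    cluster with a phase.  ``fit_transform`` returns the embedding.

    Attributes (after fit)
    ----------------------
    graph_ : igraph.Graph
    labels_ : ndarray of cluster ids
    embedding_ : ndarray (n_cells, 2)
    map_ : CellCycleMap with per-cell phase annotation
    resolution_ : the Leiden resolution actually used
    """

    def __init__(self, n_neighbors: int = 30, resolution: float | None = None,
                 target_clusters: int = 5, embedding_method: str = "diffusion",
                 diffusion_time: int = 3, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.target_clusters = target_clusters
        self.embedding_method = embedding_method
        self.diffusion_time = diffusion_time
        self.random_state = random_state

    def fit(self, table: pd.DataFrame, y=None) -> "CellCycleMapper":
        self.graph_ = build_knn_graph(table, k=self.n_neighbors)
        if self.resolution is None:
            self.resolution_, self.labels_ = scan_resolution(
                self.graph_, target=self.target_clusters, seed=self.random_state
            )
        else:
            self.resolution_ = float(self.resolution)
            self.labels_ = leiden_cluster(
                self.graph_, resolution=self.resolution_, seed=self.random_state
            )
        self.embedding_ = embed_2d(
            table,
            n_neighbors=self.n_neighbors,
            seed=self.random_state,
            method=self.embedding_method,
            diffusion_time=self.diffusion_time,
        )
        cc_map = annotate_phases(table, self.labels_)
        cc_map.cells.insert(0, "embed_y", self.embedding_[:, 1])
        cc_map.cells.insert(0, "embed_x", self.embedding_[:, 0])
        cc_map.graph_meta = {"k": self.n_neighbors, "metric": "euclidean"}
        cc_map.clustering_meta = {
            "resolution": self.resolution_,
            "seed": self.random_state,
            "n_clusters": int(self.labels_.max() + 1),
        }
        self.map_ = cc_map
        return self

    def fit_transform(self, table: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(table).embedding_
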