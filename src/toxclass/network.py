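"""Transcription-factor co-expression network: kNN mutual information,
CLR background correction, edge thresholding, communities, layout and
gene-set overlays.

Pairwise dependence between gene expression profiles is estimated with the
Kraskov k-nearest-neighbour mutual-information estimator (variant 1,
Chebyshev-norm neighbourhoods, k = 9 by default). The context likelihood
of relatedness (CLR) transform converts each MI value into a background-
corrected z-score combination, which removes promiscuous hubs. The network
keeps only the top 0.1% of pairwise scores, restricted to transcription
factors; communities come from greedy modularity agglomeration and node
positions from a Fruchterman-Reingold force-directed layout. Gene sets are
overlaid per community with one-sided hypergeometric (Fisher) enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.spatial import cKDTree

from .datatypes import ExpressionMatrix, GeneSet, ValidationError

DEFAULT_K = 9
DEFAULT_RETENTION = 0.001
DEFAULT_AREA = 1e9
DEFAULT_TOP_COMMUNITIES = 18
_JITTER = 1e-10


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Kraskov estimator 1 for one pair, Chebyshev norm, in nats."""
    n = x.size
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # distance to the k-th neighbour (excluding self)
    eps = tree.query(pts, k=k + 1, p=np.inf)[0][:, -1]
    xs = np.sort(x)
    ys = np.sort(y)
    # strictly-closer marginal counts, self excluded
    nx_ = (
        np.searchsorted(xs, x + eps, side="left")
        - np.searchsorted(xs, x - eps, side="right")
        - 1
    )
    ny_ = (
        np.searchsorted(ys, y + eps, side="left")
        - np.searchsorted(ys, y - eps, side="right")
        - 1
    )
    mi = (
        special.digamma(k)
        + special.digamma(n)
        - np.mean(special.digamma(nx_ + 1) + special.digamma(ny_ + 1))
    )
    return float(max(mi, 0.0))


def knn_mutual_information(
    expr: ExpressionMatrix, k: int = DEFAULT_K, seed: int = 0
) -> pd.DataFrame:
    """Pairwise kNN mutual information between all genes (rows), in nats.

    A seeded jitter of amplitude 1e-10 breaks ties from quantized values;
    negative estimates are floored at 0. The diagonal is set to 0 and
    ignored downstream.
    """
    n_genes, n_samples = expr.shape
    if k >= n_samples:
        raise ValidationError(f"k={k} must be < number of samples {n_samples}")
    if n_samples < k + 2:
        raise ValidationError("too few samples for the kNN estimator")
    rng = np.random.default_rng(seed)
    X = expr.values + rng.uniform(-_JITTER, _JITTER, size=expr.shape)
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            mi[i, j] = mi[j, i] = _ksg_mi(X[i], X[j], k)
    return pd.DataFrame(mi, index=expr.probe_ids, columns=expr.probe_ids)


def clr_scores(mi: pd.DataFrame) -> pd.DataFrame:
    """Context-likelihood-of-relatedness transform of an MI matrix.

    Per gene i, z_i(j) = max(0, (MI_ij - mu_i) / sigma_i) over the
    off-diagonal row; the pair score is sqrt(z_i(j)^2 + z_j(i)^2). Genes
    with a degenerate (constant) MI row contribute 0.
    """
    M = mi.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-9):
        raise ValidationError("MI matrix must be square and symmetric")
    n = M.shape[0]
    off = ~np.eye(n, dtype=bool)
    mu = np.array([M[i, off[i]].mean() for i in range(n)])
    sd = np.array([M[i, off[i]].std(ddof=0) for i in range(n)])
    z = np.zeros_like(M)
    for i in range(n):
        if sd[i] > 0:
            z[i] = np.maximum(0.0, (M[i] - mu[i]) / sd[i])
        # sigma = 0 -> row contributes 0
    score = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(score, 0.0)
    return pd.DataFrame(score, index=mi.index, columns=mi.columns)


@dataclass
class TFNetwork:
    """Thresholded TF co-expression network with annotations attached."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: node1, node2, score
    threshold: float
    communities: dict[str, int] | None = None
    modularity: float | None = None
    top_communities: list[int] | None = None
    layout: pd.DataFrame | None = None  # index node, columns x, y

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["node1"], row["node2"], weight=row["score"])
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def threshold_edges(
    scores: pd.DataFrame,
    tf_list: GeneSet | list[str],
    retention: float = DEFAULT_RETENTION,
) -> TFNetwork:
    """Keep the top ``retention`` fraction of TF-TF pair scores as edges.

    The cut point is the (1 - retention) empirical quantile (linear
    interpolation) of the upper-triangle scores among TF nodes; pairs at
    or above it are kept, so ties at the threshold all survive.
    """
    if not (0.0 < retention <= 1.0):
        raise ValidationError("retention must be in (0, 1]")
    tfs = list(tf_list.genes) if isinstance(tf_list, GeneSet) else list(tf_list)
    nodes = [g for g in scores.index if g in set(tfs)]
    if not nodes:
        raise ValidationError("no TF symbols found among score matrix genes")
    S = scores.loc[nodes, nodes].to_numpy()
    iu = np.triu_indices(len(nodes), k=1)
    vals = S[iu]
    if vals.size == 0:
        raise ValidationError("need >= 2 TF nodes")
    if retention == 1.0:
        cut = -np.inf
    else:
        cut = float(np.quantile(vals, 1.0 - retention))
    keep = vals >= cut
    edges = pd.DataFrame(
        {
            "node1": [nodes[i] for i in iu[0][keep]],
            "node2": [nodes[j] for j in iu[1][keep]],
            "score": vals[keep],
        }
    ).sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return TFNetwork(nodes=nodes, edges=edges, threshold=cut)


def fastgreedy_communities(
    network: TFNetwork, top_n: int = DEFAULT_TOP_COMMUNITIES
) -> TFNetwork:
    """Greedy modularity agglomeration over the thresholded graph.

    Community ids are assigned by decreasing community size (ties by
    smallest member node); the ``top_n`` largest are flagged for
    enrichment analysis. Isolated nodes form singleton communities.
    """
    g = network.graph()
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if g.number_of_edges() == 0:
        comms = [{n} for n in g.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    comms.sort(key=lambda c: (-len(c), sorted(map(str, c))[0]))
    membership = {n: i for i, c in enumerate(comms) for n in c}
    mod = (
        nx.community.modularity(g, comms) if g.number_of_edges() else 0.0
    )
    network.communities = membership
    network.modularity = float(mod)
    network.top_communities = list(range(min(top_n, len(comms))))
    return network


def fruchterman_reingold_layout(
    network: TFNetwork,
    area: float = DEFAULT_AREA,
    iterations: int = 100,
    seed: int = 0,
) -> TFNetwork:
    """Force-directed node placement, deterministic under ``seed``.

    The area parameter sets the linear scale of the drawing region (side
    length sqrt(area)); a single node is placed at the origin.
    """
    g = network.graph()
    side = float(np.sqrt(area))
    if g.number_of_nodes() == 1:
        pos = {next(iter(g.nodes)): np.zeros(2)}
    else:
        pos = nx.spring_layout(g, iterations=iterations, seed=seed)
        pos = {n: np.asarray(p) * side / 2.0 for n, p in pos.items()}
    layout = pd.DataFrame(
        [(n, p[0], p[1]) for n, p in pos.items()], columns=["node", "x", "y"]
    ).set_index("node")
    if not np.isfinite(layout.to_numpy()).all():
        raise ValidationError("layout produced non-finite coordinates")
    network.layout = layout
    return network


@dataclass
class EnrichmentResult:
    """Fisher (hypergeometric) gene-set enrichment per community."""

    table: pd.DataFrame  # set_name, community, overlap, term_size, community_size, universe_size, p_value


def overlay_gene_sets(network: TFNetwork, sets: list[GeneSet]) -> EnrichmentResult:
    """Mark gene-set members per community and test for over-representation.

    The universe is the network node set; p values are one-sided
    hypergeometric tails (empty overlap gives p = 1).
    """
    if network.communities is None:
        raise ValidationError("run fastgreedy_communities first")
    universe = list(network.nodes)
    M = len(universe)
    by_comm: dict[int, list[str]] = {}
    for node, cid in network.communities.items():
        by_comm.setdefault(cid, []).append(node)
    records = []
    for gene_set in sets:
        members = set(gene_set.genes) & set(universe)
        K = len(members)
        for cid, nodes in sorted(by_comm.items()):
            n = len(nodes)
            overlap = len(members & set(nodes))
            if overlap == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
            records.append(
                {
                    "set_name": gene_set.name,
                    "community": cid,
                    "overlap": overlap,
                    "term_size": K,
                    "community_size": n,
                    "universe_size": M,
                    "p_value": min(max(p, np.nextafter(0, 1)), 1.0),
                }
            )
    return EnrichmentResult(table=pd.DataFrame(records))


def build_tf_network(
    expr: ExpressionMatrix,
    tf_list: GeneSet | list[str] | None = None,
    k: int = DEFAULT_K,
    retention: float = DEFAULT_RETENTION,
    area: float = DEFAULT_AREA,
    iterations: int = 100,
    top_n: int = DEFAULT_TOP_COMMUNITIES,
    seed: int = 0,
) -> tuple[TFNetwork, pd.DataFrame, pd.DataFrame]:
    """Full chain: MI -> CLR -> threshold -> communities -> layout.

    ``tf_list`` defaults to all genes in the matrix. Returns the network
    plus the MI and CLR matrices.
    """
    mi = knn_mutual_information(expr, k=k, seed=seed)
    clr = clr_scores(mi)
    tfs = tf_list if tf_list is not None else list(expr.probe_ids)
    net = threshold_edges(clr, tfs, retention=retention)
    net = fastgreedy_communities(net, top_n=top_n)
    net = fruchterman_reingold_layout(net, area=area, seed=seed)
    return net, mi, clr
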