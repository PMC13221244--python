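"""Network propagation from driver seeds and driver-gene prediction.

Personalized PageRank spreads "heat" from a seed set (known cancer driver
genes) over the weighted network: the stationary distribution of a random
walk that follows link weights with probability ``damping`` and restarts at
a seed otherwise. The resulting per-gene visit probabilities quantify
closeness to the drivers and feed the therapeutic-candidate scoring.

Guided propagation runs two stages: a first PageRank from prior-knowledge
genes re-weights the network into a directed graph (each node distributes
its outgoing probability proportionally to its neighbours' stage-1 scores),
and a second PageRank on that graph seeds from new information such as
per-gene mutation frequencies. Genes pulled up by both stages rank highest.

Guilt-by-association scores a gene by the fraction of its incident link
weight that reaches known drivers; leave-one-out AUROC over the network's
genes measures how well the network encodes driver identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationResult",
    "GBAScore",
    "personalized_pagerank",
    "reweight_graph",
    "guided_propagation",
    "ukin_benchmark",
    "guilt_by_association",
    "loocv_driver_auroc",
    "without_network_score",
]


@dataclass
class PropagationResult:
    """Per-gene visit probabilities from a personalized PageRank run."""

    scores: pd.Series  # gene -> probability, sums to 1
    seeds: frozenset
    damping: float
    tol: float

    def __post_init__(self) -> None:
        total = float(self.scores.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"propagation probabilities sum to {total}, not 1")


@dataclass
class GBAScore:
    gene: str
    score: float
    isolated: bool = False


def _personalization_vector(net: nx.Graph, weights: dict) -> dict:
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("personalization weights must have a positive sum")
    return {g: weights.get(g, 0.0) / total for g in net}


def personalized_pagerank(
    net: nx.Graph,
    seeds,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PropagationResult:
    """Personalized PageRank with restart mass uniform over the seed genes.

    Solves the fixed point ``p = (1 - d) v + d W^T p`` by power iteration
    (``W`` is the row-normalised weighted transition matrix, ``v`` uniform
    over the seeds) until the L1 change drops below ``tol``.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = seeds - set(net)
    if missing:
        raise ValueError(f"seed gene(s) not in network: {sorted(missing)[:10]}")
    pers = _personalization_vector(net, {g: 1.0 for g in seeds})
    try:
        # networkx's convergence test is err < n * tol on the L1 residual
        p = nx.pagerank(
            net,
            alpha=damping,
            personalization=pers,
            tol=tol / max(len(net), 1),
            max_iter=max_iter,
            weight="weight",
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"propagation failed to converge within {max_iter} iterations"
        ) from exc
    scores = pd.Series(p, name="propagation").reindex(sorted(net.nodes()))
    return PropagationResult(
        scores=scores, seeds=frozenset(seeds), damping=damping, tol=tol
    )


def reweight_graph(net: nx.Graph, stage1: PropagationResult) -> nx.DiGraph:
    """Directed re-weighting by stage-1 scores: ``w_ij = p_j / sum_k p_k``.

    Every node's outgoing weights sum to 1 over its neighbours ``N(i)``. If
    all of a node's neighbours scored zero, its out-weights fall back to
    uniform (logged once).
    """
    p = stage1.scores
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes())
    warned = False
    for i in net:
        nbrs = list(net[i])
        if not nbrs:
            continue
        denom = float(sum(p[j] for j in nbrs))
        if denom <= 0:
            if not warned:
                logger.warning("zero-score neighbourhood at %r; uniform out-weights", i)
                warned = True
            for j in nbrs:
                g.add_edge(i, j, weight=1.0 / len(nbrs))
        else:
            for j in nbrs:
                g.add_edge(i, j, weight=float(p[j]) / denom)
    return g


def guided_propagation(
    net: nx.Graph,
    prior_genes,
    new_info: dict,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[PropagationResult, nx.DiGraph]:
    """Two-stage guided propagation (uKIN-style).

    Stage 1 propagates from the prior-knowledge genes; the network is then
    re-weighted into a directed graph by the stage-1 scores; stage 2 runs
    PageRank on that graph with the restart distribution proportional to
    ``new_info`` (non-negative, at least one positive entry). Dangling-node
    mass is redistributed to the restart distribution.
    """
    info = {g: v for g, v in new_info.items() if g in net}
    if any(v < 0 for v in info.values()):
        raise ValueError("new_info scores must be non-negative")
    if sum(info.values()) <= 0:
        raise ValueError("new_info must contain at least one positive in-network score")
    stage1 = personalized_pagerank(net, prior_genes, damping, tol, max_iter)
    directed = reweight_graph(net, stage1)
    pers = _personalization_vector(directed, info)
    try:
        p = nx.pagerank(
            directed,
            alpha=damping,
            personalization=pers,
            tol=tol / max(len(net), 1),
            max_iter=max_iter,
            weight="weight",
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"stage-2 propagation failed to converge within {max_iter} iterations"
        ) from exc
    scores = pd.Series(p, name="guided_propagation").reindex(sorted(net.nodes()))
    result = PropagationResult(
        scores=scores, seeds=frozenset(set(prior_genes)), damping=damping, tol=tol
    )
    return result, directed


def ukin_benchmark(
    net: nx.Graph,
    positive_pool,
    mutation_freq: dict,
    n_iter: int = 100,
    n_hidden: int = 400,
    n_prior: int = 20,
    top_k: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean AUROC of guided propagation at recovering hidden positives.

    Each iteration splits the positive pool into a disjoint hidden set
    (evaluation positives) and prior set (stage-1 seeds), runs guided
    propagation with ``mutation_freq`` as the stage-2 restart weights, keeps
    the top ``top_k`` genes' scores (all others tied at 0), and computes the
    AUROC with the hidden genes as positives against all other network genes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(set(positive_pool) & set(net))
    if len(pool) < 2:
        raise ValueError("positive pool too small")
    if len(pool) < n_hidden + n_prior:
        scale = len(pool) / (n_hidden + n_prior)
        n_hidden = max(1, int(n_hidden * scale))
        n_prior = max(1, len(pool) - n_hidden)
        logger.warning(
            "positive pool smaller than hidden+prior; scaled to %d hidden / %d prior",
            n_hidden,
            n_prior,
        )
    nodes = sorted(net.nodes())
    aurocs = []
    for _ in range(n_iter):
        chosen = rng.choice(len(pool), size=n_hidden + n_prior, replace=False)
        hidden = {pool[i] for i in chosen[:n_hidden]}
        prior = {pool[i] for i in chosen[n_hidden:]}
        result, _ = guided_propagation(net, prior, mutation_freq)
        scores = result.scores
        cutoff = scores.sort_values(ascending=False).iloc[min(top_k, len(scores)) - 1]
        clipped = scores.where(scores >= cutoff, 0.0)
        y = np.fromiter((g in hidden for g in nodes), int, len(nodes))
        aurocs.append(roc_auc_score(y, clipped.loc[nodes].to_numpy()))
    return float(np.mean(aurocs))


def guilt_by_association(net: nx.Graph, drivers, gene) -> GBAScore:
    """Weighted fraction of a gene's links that connect to driver genes."""
    if gene not in net:
        raise ValueError(f"gene {gene!r} not in network")
    drivers = set(drivers) - {gene}
    w_all = 0.0
    w_driver = 0.0
    for nbr, d in net[gene].items():
        w_all += d["weight"]
        if nbr in drivers:
            w_driver += d["weight"]
    if w_all == 0:
        return GBAScore(gene=gene, score=0.0, isolated=True)
    return GBAScore(gene=gene, score=w_driver / w_all)


def loocv_driver_auroc(net: nx.Graph, drivers) -> float:
    """Leave-one-out AUROC of guilt-by-association driver prediction.

    Each driver is scored with itself withheld from the driver set;
    non-drivers are scored against the full set. The AUROC is taken over all
    network genes with drivers as positives (ties count 1/2).
    """
    drivers = set(drivers) & set(net)
    if len(drivers) < 2:
        raise ValueError("need at least 2 in-network drivers for LOOCV")
    nodes = sorted(net.nodes())
    idx = {g: i for i, g in enumerate(nodes)}
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, weight="weight", format="csr")
    total = np.asarray(a.sum(axis=1)).ravel()
    driver_mask = np.zeros(len(nodes))
    driver_mask[[idx[g] for g in drivers]] = 1.0
    to_driver = a @ driver_mask  # self excluded: no self-loops in the graph
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, to_driver / total, 0.0)
    y = driver_mask.astype(int)
    return float(roc_auc_score(y, s))


def without_network_score(matrix, cancer_type: str) -> pd.Series:
    """Network-free control: mean essentiality across a cancer type's lines.

    Returns the per-gene average essentiality over the cell lines whose
    lineage matches ``cancer_type``. For driver ranking, more negative mean
    essentiality is the stronger prediction, so callers should rank by the
    negated value.
    """
    if matrix.lineage is None:
        raise ValueError("matrix has no lineage labels")
    cols = matrix.lineage[matrix.lineage == cancer_type].index
    if len(cols) == 0:
        raise ValueError(f"no cell lines with cancer type {cancer_type!r}")
    return matrix.values[cols].mean(axis=1)
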