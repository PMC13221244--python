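"""Gene-set modularity in a weighted network, with degree-matched nulls.

A gene set that forms a functional module keeps most of its link weight
inside the set. Two raw measures are used: weighted cohesiveness
``W_in / (W_in + W_out)`` and the unweighted mean local clustering
coefficient. Both are biased by node degree, so they are normalised as
Z-scores against the modularity of random gene sets matched in size and
degree distribution (log2-spaced degree bins).

The cancer-related-pathway (CRP) enrichment analysis converts the Z-scores
of a pathway collection to rank percentiles ("relative modularity"), splits
at the median, and tests CRP over-representation above the split with a
two-sided Fisher exact test; a preranked GSEA on the same percentiles gives
the threshold-free counterpart.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, preranked_gsea

logger = logging.getLogger(__name__)

__all__ = [
    "ModularityResult",
    "cohesiveness",
    "clustering_coefficient",
    "degree_matched_sample",
    "normalized_modularity",
    "relative_modularity",
    "crp_enrichment",
    "crp_enrichment_from_counts",
    "modularity_gsea",
]


@dataclass
class ModularityResult:
    """Raw and (optionally) degree-matched-normalised modularity of a gene set."""

    metric: str
    raw: float
    w_in: float | None = None
    w_out: float | None = None
    z: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_samples: int = 0
    z_undefined: bool = False


def _check_genes(net: nx.Graph, genes) -> list:
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in net]
    if missing:
        raise ValueError(f"gene(s) not in network: {missing[:10]}")
    return genes


def cohesiveness(net: nx.Graph, genes) -> ModularityResult:
    """Weighted fraction of the set's incident link weight staying inside it.

    ``W_in`` counts each within-set edge once; ``W_out`` is the total weight
    of edges crossing the set boundary.
    """
    genes = _check_genes(net, genes)
    gset = set(genes)
    w_in = 0.0
    w_out = 0.0
    for g in genes:
        for nbr, d in net[g].items():
            w = d["weight"]
            if nbr in gset:
                w_in += w / 2.0  # each internal edge visited from both ends
            else:
                w_out += w
    if w_in + w_out == 0:
        raise ValueError("isolated gene set: no incident edges")
    return ModularityResult(
        metric="cohesiveness", raw=w_in / (w_in + w_out), w_in=w_in, w_out=w_out
    )


def clustering_coefficient(net: nx.Graph, genes) -> ModularityResult:
    """Mean unweighted local clustering coefficient over the gene set.

    Triangles and degrees are taken over the full network topology; nodes
    with degree <= 1 contribute 0.
    """
    genes = _check_genes(net, genes)
    if not genes:
        raise ValueError("empty gene set")
    cc = nx.clustering(net, genes)  # unweighted: 2T_v / (k_v (k_v - 1))
    return ModularityResult(
        metric="clustering_coefficient", raw=float(np.mean([cc[g] for g in genes]))
    )


class DegreeBins:
    """Log2-spaced degree bins (1, 2-3, 4-7, ...) over the network's nodes.

    Precomputed once so repeated degree-matched sampling is cheap.
    """

    def __init__(self, net: nx.Graph):
        self.bin_of: dict = {}
        members: dict[int, list] = {}
        for node, deg in net.degree():
            b = int(math.floor(math.log2(deg))) if deg >= 1 else -1
            self.bin_of[node] = b
            members.setdefault(b, []).append(node)
        self.members = {b: np.asarray(sorted(m)) for b, m in members.items()}
        self.bins = sorted(self.members)

    def nearest_nonempty(self, b: int, exclude_empty_after_use: set | None = None):
        candidates = sorted(self.bins, key=lambda x: (abs(x - b), x))
        return candidates


def degree_matched_sample(
    net: nx.Graph,
    genes,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    bins: DegreeBins | None = None,
) -> list[list]:
    """Random gene sets matching the query set's size and degree-bin histogram.

    Each query gene is replaced by a node drawn uniformly from its log2 degree
    bin; nodes are distinct within a sample. A bin exhausted of unused nodes
    falls back to the nearest non-empty bin (warning logged once).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    genes = _check_genes(net, genes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if bins is None:
        bins = DegreeBins(net)
    query_bins = [bins.bin_of[g] for g in genes]
    samples = []
    warned = False
    for _ in range(n_samples):
        used: set = set()
        sample = []
        for b in query_bins:
            pool = bins.members[b]
            # rejection sampling first; fall back to explicit filtering
            node = None
            for _try in range(4):
                cand = pool[rng.integers(len(pool))]
                if cand not in used:
                    node = cand
                    break
            if node is None:
                avail = [x for x in pool if x not in used]
                if not avail:
                    if not warned:
                        logger.warning(
                            "degree bin %d exhausted; falling back to nearest bin", b
                        )
                        warned = True
                    for nb in bins.nearest_nonempty(b):
                        avail = [x for x in bins.members[nb] if x not in used]
                        if avail:
                            break
                    if not avail:
                        raise ValueError("network too small for distinct sample")
                node = avail[rng.integers(len(avail))]
            used.add(node)
            sample.append(node)
        samples.append(sample)
    return samples


def normalized_modularity(
    net: nx.Graph,
    genes,
    metric: str = "cohesiveness",
    n_samples: int = 100,
    seed: int | np.random.Generator = 0,
    bins: DegreeBins | None = None,
) -> ModularityResult:
    """Z-score the observed modularity against degree-matched random sets."""
    fn = {"cohesiveness": cohesiveness, "clustering_coefficient": clustering_coefficient}
    if metric not in fn:
        raise ValueError(f"unknown metric {metric!r}")
    observed = fn[metric](net, genes)
    nulls = np.array(
        [
            fn[metric](net, s).raw
            for s in degree_matched_sample(net, genes, n_samples, seed, bins=bins)
        ]
    )
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if n_samples > 1 else 0.0
    if null_sd == 0:
        return ModularityResult(
            metric=metric,
            raw=observed.raw,
            w_in=observed.w_in,
            w_out=observed.w_out,
            null_mean=null_mean,
            null_sd=0.0,
            n_samples=n_samples,
            z_undefined=True,
        )
    return ModularityResult(
        metric=metric,
        raw=observed.raw,
        w_in=observed.w_in,
        w_out=observed.w_out,
        z=(observed.raw - null_mean) / null_sd,
        null_mean=null_mean,
        null_sd=null_sd,
        n_samples=n_samples,
    )


def relative_modularity(z_scores: pd.Series, is_crp=None) -> pd.DataFrame:
    """Convert per-pathway modularity Z-scores to rank percentiles in (0, 1].

    Percentile = average rank (ascending, ties share the mean rank) divided
    by the pathway count; the highest-Z pathway gets 1.0.
    """
    if len(z_scores) < 2:
        raise ValueError("need at least 2 pathways for relative modularity")
    ranks = stats.rankdata(z_scores.to_numpy(), method="average")
    table = pd.DataFrame(
        {
            "pathway_id": z_scores.index,
            "z": z_scores.to_numpy(),
            "relative_modularity": ranks / len(z_scores),
        }
    ).set_index("pathway_id")
    if is_crp is not None:
        crp = set(is_crp)
        table["is_crp"] = [p in crp for p in table.index]
    return table


def _fisher_table(a: int, b: int, c: int, d: int):
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        logger.warning(
            "degenerate contingency table; Haldane-corrected odds ratio = %.4g",
            a_ * d_ / (b_ * c_),
        )
    return float(odds), float(p)


def crp_enrichment(table: pd.DataFrame, threshold: float | None = None):
    """Fisher test of CRP over-representation above the median modularity split.

    Pathways with relative modularity strictly above the threshold (default:
    the median) are "network-specific". Returns the 2x2 contingency counts
    ``(a, b, c, d)`` = (specific CRP, non-specific CRP, specific non-CRP,
    non-specific non-CRP), the odds ratio ``ad/bc`` and the two-sided Fisher
    exact p-value.
    """
    if "is_crp" not in table:
        raise ValueError("table must carry is_crp labels")
    rm = table["relative_modularity"].to_numpy()
    if threshold is None:
        threshold = float(np.median(rm))
    specific = rm > threshold
    crp = table["is_crp"].to_numpy(dtype=bool)
    a = int((specific & crp).sum())
    b = int((~specific & crp).sum())
    c = int((specific & ~crp).sum())
    d = int((~specific & ~crp).sum())
    odds, p = _fisher_table(a, b, c, d)
    return (a, b, c, d), odds, p


def crp_enrichment_from_counts(n_pathways: int, n_crp: int, n_crp_specific: int):
    """CRP enrichment arithmetic from summary counts under an exact half split.

    Returns the contingency table, odds ratio, two-sided Fisher p and the
    number of CRPs expected above the split by chance
    (``n_crp * (n_pathways / 2) / n_pathways``).
    """
    n_specific = n_pathways // 2
    a = n_crp_specific
    b = n_crp - n_crp_specific
    c = n_specific - n_crp_specific
    d = (n_pathways - n_specific) - b
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts")
    odds, p = _fisher_table(a, b, c, d)
    expected = n_crp * n_specific / n_pathways
    return (a, b, c, d), odds, p, expected


def modularity_gsea(
    table: pd.DataFrame, crp_set, n_perm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Threshold-free CRP enrichment: preranked GSEA on relative modularity.

    Pathways play the role of "genes", ranked by relative modularity in
    descending order, with the CRP list as the query set.
    """
    scores = pd.Series(
        table["relative_modularity"].to_numpy(), index=table.index, name="relative_modularity"
    )
    return preranked_gsea(scores, set(crp_set), n_perm=n_perm, seed=seed)
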