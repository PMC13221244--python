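"""Preranked GSEA, ssGSEA, driver-module selection and survival comparison.

The preranked GSEA here is the classic weighted Kolmogorov-Smirnov running
sum: walking down a ranked gene list, members of the query set push the sum
up by ``|score|**weight`` (normalised over the set) and non-members pull it
down by ``1/(N - m)``; the enrichment score (ES) is the extremum of largest
magnitude. Significance comes from gene-label permutation: the set's
positions in the list are redrawn uniformly, ES is renormalised by the mean
permuted ES of the same sign (NES), and the FDR uses the sign-stratified
permutation estimator over the pooled normalised null.

ssGSEA scores one sample at a time with rank weights raised to a small
exponent (default 0.25) and integrates the running-sum difference; scores
are comparable across samples after dividing by the score range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "rank_scores",
    "preranked_gsea",
    "preranked_gsea_batch",
    "ssgsea",
    "ssgsea_matrix",
    "select_driver_modules",
    "stratify_patients",
    "logrank_test",
    "bh_adjust",
]


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    pval: float
    fdr: float
    n_perm: int
    n_hits: int


def rank_scores(scores: pd.Series) -> pd.Series:
    """Descending ranked list; ties broken lexicographically by gene symbol."""
    if scores.index.has_duplicates:
        raise ValueError("gene symbols in the ranked list must be unique")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


def _es_from_positions(absw: np.ndarray, positions: np.ndarray) -> float:
    """ES of a hit-position set within a ranked list of length N.

    ``absw`` holds |score|**weight in rank order; ``positions`` are the
    (sorted, 0-based) ranks of the set members.
    """
    n = len(absw)
    m = len(positions)
    h = absw[positions]
    total = h.sum()
    if total == 0:
        # set carries no weight: running sum only decreases
        if n == m:
            return 0.0
        cumh = np.zeros(m)
    else:
        cumh = np.cumsum(h) / total
    if n == m:  # no misses: hit-only running sum, max at the end
        return float(cumh.max())
    miss = 1.0 / (n - m)
    idx = np.arange(m)
    after_hit = cumh - (positions - idx) * miss
    before_hit = np.concatenate(([0.0], cumh[:-1])) - (positions - idx) * miss
    pos_ext = after_hit.max()
    neg_ext = min(before_hit.min(), 0.0)
    return float(pos_ext if pos_ext >= -neg_ext else neg_ext)


def _perm_es(absw: np.ndarray, m: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    n = len(absw)
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=m, replace=False))
        out[i] = _es_from_positions(absw, pos)
    return out


def _observed_es(scores: pd.Series, gene_set, weight: float):
    ranked = rank_scores(scores)
    absw = np.abs(ranked.to_numpy(dtype=float)) ** weight
    in_set = np.fromiter((g in gene_set for g in ranked.index), bool, len(ranked))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if absw[in_set].sum() == 0 and weight > 0:
        raise ValueError("all scores of the gene set are zero")
    es = _es_from_positions(absw, np.flatnonzero(in_set))
    return es, absw, m


def _nes_p(es: float, null: np.ndarray):
    """Same-sign normalisation and one-sided nominal p for one ES."""
    same = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same) == 0 or np.mean(np.abs(same)) == 0:
        return float("nan"), 1.0
    denom = float(np.mean(np.abs(same)))
    nes = es / denom
    p = float(np.mean(np.abs(same) >= abs(es)))
    return nes, p


def preranked_gsea(
    scores: pd.Series,
    gene_set,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Preranked GSEA of one gene set against a gene -> score ranking.

    For a single set the FDR equals the nominal permutation p (there is no
    cross-set pool to stratify over); use :func:`preranked_gsea_batch` for a
    collection.
    """
    gene_set = set(gene_set)
    es, absw, m = _observed_es(scores, gene_set, weight)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _perm_es(absw, m, n_perm, rng)
    nes, p = _nes_p(es, null)
    return EnrichmentResult(es=es, nes=nes, pval=p, fdr=p, n_perm=n_perm, n_hits=m)


def preranked_gsea_batch(
    scores: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection with sign-stratified FDR.

    Permuted ES values are normalised per set by the mean same-sign permuted
    ES and pooled; a set's FDR is the fraction of pooled same-sign null NES
    at least as extreme as its NES, divided by the corresponding fraction of
    observed NES, clipped to [0, 1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = {}
    pooled: list[np.ndarray] = []
    for name, gset in gene_sets.items():
        gset = set(gset)
        try:
            es, absw, m = _observed_es(scores, gset, weight)
        except ValueError as exc:
            logger.warning("gene set %r skipped: %s", name, exc)
            continue
        null = _perm_es(absw, m, n_perm, rng)
        nes, p = _nes_p(es, null)
        pos = null[null >= 0]
        neg = null[null < 0]
        norm = np.empty_like(null)
        norm[null >= 0] = pos / np.mean(pos) if len(pos) and pos.mean() > 0 else 0.0
        norm[null < 0] = neg / np.mean(np.abs(neg)) if len(neg) else 0.0
        pooled.append(norm)
        rows[name] = {"es": es, "nes": nes, "pval": p, "n_hits": m}
    if not rows:
        return pd.DataFrame(columns=["es", "nes", "pval", "fdr", "n_hits"])
    table = pd.DataFrame.from_dict(rows, orient="index")
    null_nes = np.concatenate(pooled)
    obs_nes = table["nes"].to_numpy()
    fdr = np.empty(len(table))
    for i, nes in enumerate(obs_nes):
        if np.isnan(nes):
            fdr[i] = 1.0
            continue
        if nes >= 0:
            num_pool = null_nes[null_nes >= 0]
            num = np.mean(num_pool >= nes) if len(num_pool) else 0.0
            obs_pool = obs_nes[obs_nes >= 0]
            den = np.mean(obs_pool >= nes)
        else:
            num_pool = null_nes[null_nes < 0]
            num = np.mean(num_pool <= nes) if len(num_pool) else 0.0
            obs_pool = obs_nes[obs_nes < 0]
            den = np.mean(obs_pool <= nes)
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    table["fdr"] = fdr
    table["n_perm"] = n_perm
    return table[["es", "nes", "pval", "fdr", "n_hits", "n_perm"]]


def ssgsea(sample: pd.Series, gene_set, exponent: float = 0.25) -> float:
    """Single-sample GSEA enrichment score for one expression profile.

    Genes are ranked by expression (highest value -> rank N, ties averaged);
    the score integrates the difference between the rank-weighted hit CDF
    (weights ``rank**exponent``) and the uniform miss CDF down the list.
    """
    gene_set = set(gene_set)
    if sample.index.has_duplicates:
        raise ValueError("gene symbols must be unique")
    in_set = np.fromiter((g in gene_set for g in sample.index), bool, len(sample))
    if not in_set.any():
        raise ValueError("gene set does not intersect the expressed genes")
    n = len(sample)
    m = int(in_set.sum())
    values = sample.to_numpy(dtype=float)
    ranks = stats.rankdata(values, method="average")  # highest value -> n
    order = np.lexsort((np.asarray(sample.index), -values))
    hit = in_set[order]
    w = ranks[order] ** exponent
    hit_w = np.where(hit, w, 0.0)
    cum_hit = np.cumsum(hit_w) / hit_w.sum()
    if n == m:
        cum_miss = np.zeros(n)
    else:
        cum_miss = np.cumsum(~hit) / (n - m)
    return float(np.sum(cum_hit - cum_miss))


def ssgsea_matrix(
    expr: pd.DataFrame, gene_set, exponent: float = 0.25, normalize: bool = True
) -> pd.Series:
    """ssGSEA scores for every sample (row) of an expression matrix.

    With ``normalize=True`` the raw scores are divided by their range across
    samples, making scores comparable between cohorts.
    """
    scores = pd.Series(
        {p: ssgsea(expr.loc[p], gene_set, exponent) for p in expr.index},
        name="ssgsea",
    )
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return scores


def select_driver_modules(
    prop_scores: pd.Series,
    pathways: dict,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    fdr_threshold: float = 1e-3,
) -> list:
    """Pathways enriched in high-propagation genes (driver modules).

    Runs preranked GSEA of each pathway against the propagation scores and
    keeps those with FDR below the threshold and a positive NES. An empty
    result is valid (some networks yield no driver module).
    """
    if not pathways:
        raise ValueError("need at least one pathway")
    table = preranked_gsea_batch(prop_scores, pathways, n_perm=n_perm, seed=seed)
    keep = table[(table["fdr"] < fdr_threshold) & (table["nes"] > 0)]
    return list(keep.index)


def stratify_patients(
    expr: pd.DataFrame, module_genes, exponent: float = 0.25
) -> pd.DataFrame:
    """Split patients 50/50 by their ssGSEA score on a driver module.

    The top half are the "up" (upregulated) group; with an odd patient count
    the median patient goes to the "down" group. Returns a patient-indexed
    frame with the score and group label.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    scores = ssgsea_matrix(expr, module_genes, exponent)
    if scores.max() == scores.min():
        raise ValueError("degenerate stratification: constant module scores")
    order = sorted(scores.index, key=lambda p: (-scores[p], str(p)))
    n_up = len(order) // 2
    group = {p: ("up" if i < n_up else "down") for i, p in enumerate(order)}
    out = pd.DataFrame({"score": scores})
    out["group"] = pd.Series(group)
    return out.loc[expr.index]


def logrank_test(surv: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test.

    ``surv`` has columns ``time`` (positive durations), ``event`` (1 = death
    observed, 0 = censored) and ``group`` with exactly two labels. Returns
    the chi-square statistic (1 df) and its p-value.
    """
    labels = surv["group"].unique()
    if len(labels) != 2:
        raise ValueError("log-rank test requires exactly two non-empty groups")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if surv["event"].sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    a = surv[surv["group"] == labels[0]]
    b = surv[surv["group"] == labels[1]]
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
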