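"""Build a CLR-weighted co-essentiality network from a gene essentiality matrix.

The pipeline mirrors how co-essentiality (and co-expression / co-methylation)
networks are inferred from perturbation screens: impute missing entries with a
k-nearest-neighbour scheme, compute absolute Pearson correlations between all
gene pairs, apply the context-likelihood-of-relatedness (CLR) background
correction, drop zero-weight links, and keep the largest connected component.

CLR z-scores each raw correlation r_ij against the empirical background of both
genes' correlation profiles and combines the two directions as
``sqrt(z_ij**2 + z_ji**2)``; sub-threshold z contributions are clamped to zero.
This suppresses promiscuous genes whose profiles correlate with everything.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

__all__ = [
    "EssentialityMatrix",
    "impute_knn",
    "pairwise_abs_pcc",
    "clr_transform",
    "build_network",
    "build_coessentiality_network",
    "read_depmap_matrix",
    "write_edgelist",
    "read_edgelist",
]

_HEADER_RE = re.compile(r"^(?P<symbol>.+?)\s\([^()]*\)$")


@dataclass
class EssentialityMatrix:
    """Gene x cell-line matrix of essentiality scores.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are cell lines. Missing entries allowed
        (``NaN``). Essentiality scores are dimensionless; more negative means
        the gene knockout is more deleterious in that cell line.
    lineage : pandas.Series, optional
        Cell line -> cancer-type label, indexed by cell-line ID.
    """

    values: pd.DataFrame
    lineage: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell-line IDs: {dupes}")
        if self.values.shape[1] < 3:
            raise ValueError("at least 3 cell lines are required for correlation")
        if self.lineage is not None:
            self.lineage = self.lineage.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)


def impute_knn(matrix: EssentialityMatrix, k: int = 10) -> EssentialityMatrix:
    """Impute missing entries by k-nearest-neighbour averaging.

    Cell lines act as the observations: a missing value for (gene g, cell c)
    is replaced by the mean of g's values in the k cell lines nearest to c by
    (nan-)Euclidean distance over shared non-missing genes. Non-missing
    entries are left untouched.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    vals = matrix.values
    if not vals.isna().any().any():
        return EssentialityMatrix(vals.copy(), matrix.lineage)

    all_missing_genes = vals.index[vals.isna().all(axis=1)]
    if len(all_missing_genes):
        raise ValueError(f"gene(s) with all values missing: {list(all_missing_genes)}")
    all_missing_cells = vals.columns[vals.isna().all(axis=0)]
    if len(all_missing_cells):
        raise ValueError(f"cell line(s) with all values missing: {list(all_missing_cells)}")
    if k >= vals.shape[1]:
        raise ValueError(
            f"k={k} must be smaller than the number of cell lines ({vals.shape[1]})"
        )

    # KNNImputer treats rows as observations; our observations are cell lines.
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(vals.to_numpy(dtype=float).T).T
    out = pd.DataFrame(filled, index=vals.index, columns=vals.columns)
    return EssentialityMatrix(out, matrix.lineage)


def pairwise_abs_pcc(matrix: EssentialityMatrix) -> pd.DataFrame:
    """Absolute Pearson correlation between all gene pairs.

    Absolute values capture both co-essential (positive) and anti-correlated
    relationships. Zero-variance genes get off-diagonal correlation 0 (they
    drop out at the zero-weight filter) with a logged warning.
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("matrix contains missing values; run impute_knn first")
    x = vals.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d zero-variance gene(s) assigned correlation 0: %s",
            flat.sum(),
            list(vals.index[flat][:10]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.abs(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    np.clip(r, 0.0, 1.0, out=r)
    r = (r + r.T) / 2.0  # enforce exact symmetry against fp noise
    return pd.DataFrame(r, index=vals.index, columns=vals.index)


def clr_transform(R: pd.DataFrame, t: float = 2.0) -> pd.DataFrame:
    """Context-likelihood-of-relatedness background correction.

    For each ordered pair (i, j), ``z_ij = (r_ij - mu_i) / sigma_i`` when that
    quantity is >= ``t`` and 0 otherwise, where ``mu_i`` and ``sigma_i`` are
    the sample mean and standard deviation of row i's off-diagonal
    correlations (the self-correlation of 1 is excluded from the background).
    The link weight is ``CLR_ij = sqrt(z_ij**2 + z_ji**2)``.

    Rows with a constant background (``sigma_i == 0``) contribute z = 0.
    """
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    n = R.shape[0]
    if n < 3:
        raise ValueError("CLR background undefined for fewer than 3 genes")
    if R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    r = R.to_numpy(dtype=float)

    # Off-diagonal row mean / sample sd without materialising row copies.
    diag = np.diag(r)
    row_sum = r.sum(axis=1) - diag
    mu = row_sum / (n - 1)
    row_sq = (r**2).sum(axis=1) - diag**2
    var = (row_sq - (n - 1) * mu**2) / (n - 2)
    var = np.maximum(var, 0.0)
    sigma = np.sqrt(var)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (r - mu[:, None]) / sigma[:, None]
    z[sigma == 0, :] = 0.0
    z[z < t] = 0.0
    np.fill_diagonal(z, 0.0)
    clr = np.sqrt(z**2 + z.T**2)
    return pd.DataFrame(clr, index=R.index, columns=R.columns)


def build_network(weights: pd.DataFrame) -> nx.Graph:
    """Assemble the weighted network and keep its largest connected component.

    Zero-weight links are filtered; ties between equally large components are
    broken by the lexicographically smallest member gene.
    """
    w = weights.to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("link weights must be non-negative")
    iu, ju = np.nonzero(np.triu(w, k=1))
    if len(iu) == 0:
        raise ValueError("empty network: all link weights are zero")
    genes = np.asarray(weights.index)
    g = nx.Graph()
    g.add_weighted_edges_from(zip(genes[iu], genes[ju], w[iu, ju]))
    components = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(c))
    )
    lcc = g.subgraph(components[0]).copy()
    logger.info(
        "network: %d nodes, %d links in largest component (of %d components)",
        lcc.number_of_nodes(),
        lcc.number_of_edges(),
        len(components),
    )
    return lcc


def build_coessentiality_network(
    matrix: EssentialityMatrix, t: float = 2.0, k: int = 10
) -> nx.Graph:
    """Full construction: impute -> |PCC| -> CLR(t) -> zero filter -> LCC."""
    imputed = impute_knn(matrix, k=k)
    R = pairwise_abs_pcc(imputed)
    weights = clr_transform(R, t=t)
    return build_network(weights)


def _parse_header(header: str) -> str:
    m = _HEADER_RE.match(header)
    if m is None:
        logger.warning("column header %r lacks an ' (ID)' suffix; kept verbatim", header)
        return header
    return m.group("symbol")


def read_depmap_matrix(path, lineage: pd.Series | None = None) -> EssentialityMatrix:
    """Read a DepMap-dialect gene-effect CSV.

    The file has cell lines as rows (first column is the cell-line ID) and
    columns headed ``"SYMBOL (EntrezID)"``; headers are parsed down to the
    bare symbol. The matrix is transposed to genes x cell lines.
    """
    df = pd.read_csv(path, index_col=0)
    symbols = [_parse_header(c) for c in df.columns]
    counts = pd.Series(symbols).value_counts()
    dupes = counts[counts > 1].index.tolist()
    if dupes:
        raise ValueError(f"duplicate gene symbols after header parsing: {dupes}")
    df.columns = symbols
    return EssentialityMatrix(df.T, lineage=lineage)


def write_edgelist(net: nx.Graph, path) -> None:
    """Write the network as a TSV edge list (gene_a, gene_b, weight)."""
    rows = (
        (a, b, repr(float(d["weight"])))
        for a, b, d in sorted(net.edges(data=True))
    )
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w}\n")


def read_edgelist(path) -> nx.Graph:
    """Read a TSV edge list written by :func:`write_edgelist`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    g.add_weighted_edges_from(
        zip(df["gene_a"], df["gene_b"], df["weight"].astype(float))
    )
    return g
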