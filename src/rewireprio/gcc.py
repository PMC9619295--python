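"""Gray correlation coefficients and weighted differential co-expression networks.

The gray correlation coefficient (GCC), from grey relational analysis,
scores the similarity of two expression profiles without distributional
assumptions and remains informative at the small per-condition sample
sizes typical of a single developmental stage.  With gene p as reference
and Delta_k(q) = |x_kp - x_kq| the per-sample absolute difference,

    r_pq = (1/n) * sum_k (Dmin(p) + rho * Dmax(p)) / (Delta_k(q) + rho * Dmax(p))

where Dmin(p) and Dmax(p) are the minimum and maximum of |x_tp - x_ts|
over ALL comparison genes s in the candidate set and all samples t, and
rho (the resolution ratio, 0.5 by default) damps the influence of the
global maximum.  Because the reference gene itself belongs to the
comparison set, Dmin(p) = 0.  GCC is asymmetric; the corrected coefficient
is (r_pq + r_qp) / 2.

The weighted gene differential co-expression network (WGDCN) joins genes
whose corrected GCC crosses a hard threshold r0 in opposite directions
between treatment and control — i.e. (r_treat - r0) * (r_ctrl - r0) <= 0 —
with edge weight |r_treat - r_ctrl|, the rewiring strength.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GCCConfig:
    """Parameters of GCC estimation and network construction."""

    rho: float = 0.5        # resolution ratio
    r0: float = 0.9         # hard co-expression threshold
    delta: float = 0.95     # strong-rewiring cutoff (used by the HMRF stage)
    pairwise_extremes: bool = False

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if not 0 < self.r0 < 1:
            raise ValueError("r0 must be in (0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def gcc_matrix(values, rho: float = 0.5, pairwise_extremes: bool = False) -> np.ndarray:
    """Corrected (symmetrized) GCC matrix of a genes x samples array.

    The raw coefficients use global extremes taken over the whole gene set
    per reference gene (the default); ``pairwise_extremes`` restricts the
    extremes to each (p, q) pair instead.  Rows are streamed so the extra
    memory per reference gene is O(m * n).

    Returns an m x m symmetric matrix with unit diagonal, entries in (0, 1].
    """
    if isinstance(values, ExpressionMatrix):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D genes x samples array")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 genes")
    if n < 1:
        raise ValueError("need at least 1 sample")
    raw = np.empty((m, m))
    degenerate = False
    for p in range(m):
        diffs = np.abs(x - x[p][None, :])  # m x n, Delta over all genes/samples
        if pairwise_extremes:
            dmin = diffs.min(axis=1, keepdims=True)
            dmax = diffs.max(axis=1, keepdims=True)
        else:
            dmin = diffs.min()
            dmax = diffs.max()
        if np.all(dmax == 0):
            degenerate = True
            raw[p, :] = 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = (dmin + rho * dmax) / (diffs + rho * dmax)
        if pairwise_extremes:
            # a pair with dmax == 0 is an identical pair: coefficient 1
            terms = np.where(np.broadcast_to(dmax == 0, terms.shape), 1.0, terms)
        raw[p, :] = terms.mean(axis=1)
    if degenerate:
        warnings.warn("all expression profiles identical for some reference gene; "
                      "GCC row set to 1", stacklevel=2)
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    return sym


def gcc_by_condition(
    expr: ExpressionMatrix, y, cfg: GCCConfig = GCCConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected GCC matrices for the treatment and control sample subsets."""
    y = np.asarray(y).ravel()
    if y.shape[0] != expr.n_samples:
        raise ValueError("label vector does not match sample count")
    vals = expr.values
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both conditions need at least one sample")
    g_treat = gcc_matrix(vals[:, y == 1], rho=cfg.rho, pairwise_extremes=cfg.pairwise_extremes)
    g_ctrl = gcc_matrix(vals[:, y == 0], rho=cfg.rho, pairwise_extremes=cfg.pairwise_extremes)
    return g_treat, g_ctrl


def build_wgdcn(
    gcc_treat: np.ndarray,
    gcc_ctrl: np.ndarray,
    gene_ids,
    cfg: GCCConfig = GCCConfig(),
    stage: int | None = None,
) -> nx.Graph:
    """Weighted gene differential co-expression network.

    An edge {p, q} is added when (r_treat - r0)(r_ctrl - r0) <= 0 and the
    rewiring strength |r_treat - r_ctrl| is strictly positive (a zero-weight
    edge would be inert in the downstream Ising model).  Every candidate
    gene is a node, including isolated ones.
    """
    gt = np.asarray(gcc_treat, dtype=float)
    gc = np.asarray(gcc_ctrl, dtype=float)
    gene_ids = list(gene_ids)
    m = len(gene_ids)
    if gt.shape != (m, m) or gc.shape != (m, m):
        raise ValueError("GCC matrices and gene list have mismatching sizes")
    g = nx.Graph()
    if stage is not None:
        g.graph["stage"] = int(stage)
    g.add_nodes_from(gene_ids)
    iu, ju = np.triu_indices(m, k=1)
    crossing = (gt[iu, ju] - cfg.r0) * (gc[iu, ju] - cfg.r0) <= 0
    weight = np.abs(gt[iu, ju] - gc[iu, ju])
    keep = crossing & (weight > 0)
    for p, q, w in zip(iu[keep], ju[keep], weight[keep]):
        g.add_edge(gene_ids[p], gene_ids[q], weight=float(w))
    logger.info("WGDCN: %d nodes, %d edges (r0=%g)", m, g.number_of_edges(), cfg.r0)
    return g


def differential_network(
    expr: ExpressionMatrix, y, cfg: GCCConfig = GCCConfig(), stage: int | None = None
) -> nx.Graph:
    """GCC per condition + thresholded rewiring network, in one call."""
    gt, gc = gcc_by_condition(expr, y, cfg)
    return build_wgdcn(gt, gc, expr.gene_ids, cfg, stage=stage)


def export_network(net: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Write a WGDCN as a weighted TSV edge list or as GEXF (Gephi-readable)."""
    if fmt == "edgelist":
        rows = [(u, v, d["weight"]) for u, v, d in net.edges(data=True)]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "gexf":
        nx.write_gexf(net, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_edgelist(path, gene_ids=None) -> nx.Graph:
    """Read a weighted edge-list TSV written by :func:`export_network`.

    ``gene_ids`` optionally supplies the full node set so isolated genes
    survive the round trip.
    """
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if gene_ids is not None:
        g.add_nodes_from(gene_ids)
    for _, row in df.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], weight=float(row["weight"]))
    return g


class DifferentialCoexpressionNetwork(BaseEstimator):
    """Estimator building a WGDCN from a two-condition expression sample.

    scikit-learn style: ``X`` is samples x genes, ``y`` binary condition
    labels (1 = treatment).

    Attributes
    ----------
    gcc_treatment_, gcc_control_ : ndarray (n_genes, n_genes)
        Corrected GCC matrices per condition.
    network_ : networkx.Graph
        The rewiring network; nodes are column indices (or ``gene_ids``
        passed to ``fit``), edges weighted by |r_treat - r_ctrl|.
    """

    def __init__(self, rho: float = 0.5, r0: float = 0.9, delta: float = 0.95,
                 pairwise_extremes: bool = False):
        self.rho = rho
        self.r0 = r0
        self.delta = delta
        self.pairwise_extremes = pairwise_extremes

    def fit(self, X, y, gene_ids=None):
        X = validate_data(self, X, ensure_min_samples=2, ensure_min_features=2)
        y = np.asarray(y).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        cfg = GCCConfig(rho=self.rho, r0=self.r0, delta=self.delta,
                        pairwise_extremes=self.pairwise_extremes)
        if gene_ids is None:
            gene_ids = list(range(X.shape[1]))
        vals = X.T
        self.gcc_treatment_ = gcc_matrix(vals[:, y == 1], rho=cfg.rho,
                                         pairwise_extremes=cfg.pairwise_extremes)
        self.gcc_control_ = gcc_matrix(vals[:, y == 0], rho=cfg.rho,
                                       pairwise_extremes=cfg.pairwise_extremes)
        self.network_ = build_wgdcn(self.gcc_treatment_, self.gcc_control_, gene_ids, cfg)
        return self

    def transform(self, X=None):
        """Return the fitted rewiring network (X is ignored)."""
        check_is_fitted(self, "network_")
        return self.network_
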