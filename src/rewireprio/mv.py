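"""Mean-variance (MV) independence screening.

The MV index measures dependence between a continuous covariate (a gene's
expression across samples) and a categorical response (the experimental
condition) as the weighted squared discrepancy between the conditional and
marginal empirical CDFs:

    T_n = n * MV(X|Y) = sum_theta sum_j  p_theta * (F_theta(x_j) - F(x_j))^2

where F_theta is the empirical CDF of X within response class theta, F is
the marginal empirical CDF, and p_theta the class proportion.  T_n is zero
iff the conditional distributions all coincide with the marginal on the
sample, is invariant to strictly increasing transforms of X (it depends on
ranks only), and needs no distributional assumptions — which suits small
per-stage RNA-seq sample sizes.

Significance is assessed by permutation: the response vector is uniformly
shuffled K times and the p-value is the fraction of permuted statistics at
least as large as the observed one.  Genes with p <= alpha (0.01 by
default) are retained as candidates for network construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

DEFAULT_K = 5000
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class MVResult:
    """Permutation-test result for one gene."""

    gene_id: str
    t_obs: float
    p_mv: float
    k_perms: int
    seed: int


def _check_xy(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: x has {x.shape[0]}, y has {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")
    return x, y


def mv_statistic(x, y) -> float:
    """MV index of dependence between ``x`` and categorical ``y``.

    Empirical CDFs use the <= convention; ties in ``x`` are handled exactly
    as the indicator sums dictate (no jittering).
    """
    x, y = _check_xy(x, y)
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    # marginal CDF at each observation: #{x_v <= x_j} / n
    f_marg = np.searchsorted(xs, x, side="right") / n
    t = 0.0
    for theta in np.unique(y):
        mask = y == theta
        n_theta = int(mask.sum())
        p_theta = n_theta / n
        xs_theta = np.sort(x[mask], kind="stable")
        f_cond = np.searchsorted(xs_theta, x, side="right") / n_theta
        d = f_cond - f_marg
        t += p_theta * float(d @ d)
    return t


def _permuted_statistics(x: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator):
    """MV statistics for ``k`` uniform permutations of ``y``, vectorized.

    Uses the n x n comparison matrix C[v, j] = I(x_v <= x_j); for each
    class, class-conditional CDF counts under every permutation are a
    single matrix product.
    """
    n = x.shape[0]
    cmp = (x[:, None] <= x[None, :]).astype(float)  # C[v, j]
    f_marg = cmp.mean(axis=0)
    perms = rng.permuted(np.tile(y, (k, 1)), axis=1)
    t = np.zeros(k)
    for theta in np.unique(y):
        z = (perms == theta).astype(float)  # k x n membership
        n_theta = float((y == theta).sum())
        p_theta = n_theta / n
        f_cond = (z @ cmp) / n_theta  # k x n conditional CDFs
        d = f_cond - f_marg[None, :]
        t += p_theta * np.einsum("ij,ij->i", d, d)
    return t


def mv_permutation_pvalue(
    x, y, k_perms: int = DEFAULT_K, seed: int = 0, gene_id: str = ""
) -> MVResult:
    """Permutation p-value for the MV test of X independent of Y.

    p = (1/K) * #{permuted T >= observed T}; a multiple of 1/K.  The same
    seed gives a bit-identical p-value.
    """
    if k_perms < 1:
        raise ValueError("k_perms must be >= 1")
    x, y = _check_xy(x, y)
    t_obs = mv_statistic(x, y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t_perm = _permuted_statistics(x, y, k_perms, rng)
    p = float(np.count_nonzero(t_perm >= t_obs - 1e-15) / k_perms)
    return MVResult(gene_id=gene_id, t_obs=float(t_obs), p_mv=p, k_perms=k_perms, seed=seed)


def _gene_seed(master_seed: int, gene_index: int) -> np.random.SeedSequence:
    # deterministic per-gene stream, independent of execution order
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(gene_index,))


def mv_screen_matrix(
    values: np.ndarray,
    y,
    gene_ids,
    k_perms: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the MV permutation test on every row of a genes x samples array.

    Returns a table with columns gene_id, t_obs, p_mv, retained.  Per-gene
    permutation streams are derived from ``(seed, gene index)`` so results
    do not depend on execution order.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y).ravel()
    if values.shape[1] != y.shape[0]:
        raise ValueError("number of samples and labels differ")
    rows = []
    for i, gid in enumerate(gene_ids):
        x = values[i]
        t_obs = mv_statistic(x, y)
        rng = np.random.default_rng(_gene_seed(seed, i))
        t_perm = _permuted_statistics(x, y, k_perms, rng)
        p = float(np.count_nonzero(t_perm >= t_obs - 1e-15) / k_perms)
        rows.append((gid, float(t_obs), p))
    out = pd.DataFrame(rows, columns=["gene_id", "t_obs", "p_mv"])
    out["retained"] = out["p_mv"] <= alpha
    out["k_perms"] = k_perms
    logger.info(
        "MV screen: %d / %d genes retained at alpha=%g (K=%d)",
        int(out["retained"].sum()), len(out), alpha, k_perms,
    )
    return out


def filter_candidates(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> list:
    """Gene ids with p_mv <= alpha (boundary inclusive), input order kept."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    kept = results.loc[results["p_mv"] <= alpha, "gene_id"].tolist()
    if not kept:
        logger.warning("MV filter retained no genes at alpha=%g", alpha)
    return kept


class MVScreen(SelectorMixin, BaseEstimator):
    """Feature selector keeping genes dependent on the condition label.

    scikit-learn style: ``X`` is samples x genes, ``y`` the condition
    labels.  ``fit`` computes the MV statistic and permutation p-value per
    gene; ``transform`` keeps columns with ``p_values_ <= alpha``.

    Parameters
    ----------
    k_perms : int, default 5000
        Number of label permutations per gene.
    alpha : float, default 0.01
        Retention threshold on the permutation p-value (inclusive).
    random_state : int, default 0
        Master seed; per-gene streams derive from (seed, column index).

    Attributes
    ----------
    statistics_ : ndarray of shape (n_genes,)
        Observed MV statistics.
    p_values_ : ndarray of shape (n_genes,)
        Permutation p-values (multiples of ``1/k_perms``).
    support_ : ndarray of bool
        Mask of retained genes.
    """

    def __init__(self, k_perms: int = DEFAULT_K, alpha: float = DEFAULT_ALPHA,
                 random_state: int = 0):
        self.k_perms = k_perms
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=2)
        y = np.asarray(y).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        res = mv_screen_matrix(
            X.T, y, gene_ids=np.arange(X.shape[1]),
            k_perms=self.k_perms, alpha=self.alpha, seed=self.random_state,
        )
        self.statistics_ = res["t_obs"].to_numpy()
        self.p_values_ = res["p_mv"].to_numpy()
        self.support_ = res["retained"].to_numpy()
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
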