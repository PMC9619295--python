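"""Guilt-by-rewiring gene prioritization with a hidden Markov random field.

Each candidate gene p carries a hidden association label w_p in {-1, +1}
(+1 = phenotype-associated).  The joint label distribution over the
rewiring network G is an Ising model,

    P(W) = (1/Z) exp{ -h * sum_p I(w_p=+1)
                      + tau1 * sum_{edges pq} rewire_pq * I(w_p=+1, w_q=+1)
                      - tau2 * sum_{edges pq, rewire_pq > delta} rewire_pq * I(w_p=-1, w_q=-1) }

so strongly rewired neighbors pull each other toward the same label
(guilt by rewiring).  The observed evidence per gene is the normal score
xi_p = Phi^{-1}(1 - p_mv), distributed N(0,1) under the null (f0) and,
under association, modeled by the prior-predictive Student-t marginal (f1)
of a Normal/Inverse-Gamma conjugate prior on (mu_p, sigma_p^2).

The full conditional is logistic in

    Q_p = ln(f1(xi_p)/f0(xi_p)) - h
          + tau1 * sum_{pq in E} rewire_pq * I(w_q=+1)
          + tau2 * sum_{pq in E, rewire_pq > delta} rewire_pq * I(w_q=-1)

and labels are inferred by iterated conditional modes (ICM): repeated
full sweeps setting each w_p to the mode of its conditional until no label
flips.  The external field h is the 90th percentile of the association
potentials under the initial labeling (genes with p_mv <= 0.005 start as
+1, the rest as -1), expressing the belief that marginally significant
genes may still be associated.  The converged conditional probabilities
are the reported posteriors, and genes are ranked by them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HMRFConfig:
    """Hyperparameters of the Ising prior and the evidence model.

    tau1 rewards agreeing associated neighbor pairs, tau2 penalizes
    agreeing null pairs on strongly rewired edges (weight > delta).  h is
    not stored here: it is derived from the data as the ``h_quantile``
    percentile of the initial association potentials.  mu_bar, a, g, d are
    the Normal/Inverse-Gamma hyperparameters behind the alternative
    evidence density f1 (a Student-t with g degrees of freedom, location
    mu_bar and squared scale d*(1 + 1/a)).
    """

    tau1: float = 0.01
    tau2: float = 0.01
    delta: float = 0.95
    h_quantile: float = 0.90
    init_alpha: float = 0.005
    filter_alpha: float = 0.01
    mu_bar: float = 2.0
    a: float = 1.0
    g: float = 1.0
    d: float = 1.0
    max_sweeps: int = 100
    p_clamp: float | None = None  # None -> 1 / (2 * k_perms), set by callers
    refresh_h: bool = False

    def __post_init__(self):
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("tau1 and tau2 must be >= 0")
        if not 0 < self.h_quantile < 1:
            raise ValueError("h_quantile must be in (0, 1)")
        if min(self.a, self.g, self.d) <= 0:
            raise ValueError("a, g, d must be > 0")
        if self.p_clamp is not None and not 0 < self.p_clamp < 0.5:
            raise ValueError("p_clamp must be in (0, 0.5)")


@dataclass
class HMRFState:
    """Fitted state of the prioritization model."""

    gene_ids: list
    xi: np.ndarray
    omega: np.ndarray          # labels in {-1, +1}
    potential: np.ndarray      # association potential under the initial labels
    h: float
    posterior: np.ndarray      # P(w_p = +1 | xi, w_-p) at convergence
    n_sweeps: int
    converged: bool


def normal_scores(p_mv, clamp: float = 1e-4) -> np.ndarray:
    """Evidence scores xi = Phi^{-1}(1 - p), with p clamped to [clamp, 1-clamp]
    so the scores stay finite even at permutation p-values of exactly 0 or 1."""
    p = np.asarray(p_mv, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if not 0 < clamp < 0.5:
        raise ValueError("clamp must be in (0, 0.5)")
    return special.ndtri(1.0 - np.clip(p, clamp, 1.0 - clamp))


def init_labels(p_mv, init_alpha: float = 0.005, filter_alpha: float = 0.01) -> np.ndarray:
    """Initial labels: +1 for p_mv <= init_alpha, -1 otherwise.

    All genes must already have passed the candidate filter
    (p_mv <= filter_alpha); anything above that signals pipeline misuse.
    """
    p = np.asarray(p_mv, dtype=float)
    if np.any(p > filter_alpha):
        bad = float(p.max())
        raise ValueError(
            f"p_mv={bad} exceeds the candidate threshold {filter_alpha}; "
            "run the MV filter before prioritization"
        )
    return np.where(p <= init_alpha, 1, -1).astype(int)


def _neighbor_arrays(net: nx.Graph, gene_ids):
    """Per-gene neighbor index/weight arrays aligned to ``gene_ids`` order."""
    index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in net.nodes if g not in index]
    if missing:
        raise ValueError(f"network nodes absent from gene list: {missing[:5]}")
    nbrs = [([], []) for _ in gene_ids]
    for u, v, d in net.edges(data=True):
        w = float(d.get("weight", 1.0))
        iu, iv = index[u], index[v]
        nbrs[iu][0].append(iv)
        nbrs[iu][1].append(w)
        nbrs[iv][0].append(iu)
        nbrs[iv][1].append(w)
    return [(np.asarray(i, dtype=int), np.asarray(w, dtype=float)) for i, w in nbrs]


def _network_terms(nbr, omega: np.ndarray, tau1: float, tau2: float, delta: float) -> float:
    idx, w = nbr
    if idx.size == 0:
        return 0.0
    lab = omega[idx]
    t1 = tau1 * float(w[lab == 1].sum())
    strong = (lab == -1) & (w > delta)
    t2 = tau2 * float(w[strong].sum())
    return t1 + t2


def association_potential(
    net: nx.Graph, omega, cfg: HMRFConfig = HMRFConfig(), gene_ids=None
) -> np.ndarray:
    """Per-gene association potential under a labeling.

    Potential(p) = tau1 * sum of rewire weights to +1-labeled neighbors
                 + tau2 * sum of rewire weights > delta to -1-labeled neighbors.
    """
    if gene_ids is None:
        gene_ids = list(net.nodes)
    omega = np.asarray(omega, dtype=int)
    if omega.shape[0] != len(gene_ids):
        raise ValueError("labels and gene list have different lengths")
    nbrs = _neighbor_arrays(net, gene_ids)
    return np.array([_network_terms(nb, omega, cfg.tau1, cfg.tau2, cfg.delta) for nb in nbrs])


def compute_h(potential, q: float = 0.90) -> float:
    """Empirical q-quantile of the potential vector (linear interpolation
    between order statistics — numpy's default convention)."""
    potential = np.asarray(potential, dtype=float)
    if potential.size == 0:
        raise ValueError("potential vector is empty")
    return float(np.quantile(potential, q))


def evidence_log_ratio(xi, cfg: HMRFConfig = HMRFConfig()) -> np.ndarray:
    """ln(f1(xi)/f0(xi)): Student-t prior-predictive vs standard normal."""
    xi = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("evidence scores must be finite")
    scale = np.sqrt(cfg.d * (1.0 + 1.0 / cfg.a))
    log_f1 = stats.t.logpdf(xi, df=cfg.g, loc=cfg.mu_bar, scale=scale)
    log_f0 = stats.norm.logpdf(xi)
    return log_f1 - log_f0


def evidence_densities(xi_p: float, cfg: HMRFConfig = HMRFConfig()) -> tuple[float, float]:
    """(f0, f1) density values at one evidence score."""
    if not np.isfinite(xi_p):
        raise ValueError("evidence score must be finite")
    scale = np.sqrt(cfg.d * (1.0 + 1.0 / cfg.a))
    f0 = float(stats.norm.pdf(xi_p))
    f1 = float(stats.t.pdf(xi_p, df=cfg.g, loc=cfg.mu_bar, scale=scale))
    return f0, f1


def conditional_logit(
    p: int, omega: np.ndarray, base: np.ndarray, nbrs, cfg: HMRFConfig
) -> float:
    """Q_p = ln(f1/f0) - h + network terms, at the current labels."""
    return float(base[p] + _network_terms(nbrs[p], omega, cfg.tau1, cfg.tau2, cfg.delta))


def conditional_posterior(p: int, state: HMRFState, net: nx.Graph,
                          cfg: HMRFConfig = HMRFConfig()) -> float:
    """P(w_p = +1 | xi, w_-p) for one gene of a fitted state."""
    nbrs = _neighbor_arrays(net, state.gene_ids)
    base = evidence_log_ratio(state.xi, cfg) - state.h
    return float(special.expit(conditional_logit(p, state.omega, base, nbrs, cfg)))


def icm_fit(
    net: nx.Graph,
    p_mv,
    cfg: HMRFConfig = HMRFConfig(),
    gene_ids=None,
    k_perms: int | None = None,
    seed: int | None = None,
    random_order: bool = False,
) -> HMRFState:
    """Fit labels and posteriors by iterated conditional modes.

    ICM is deterministic for fixed inputs: sweeps visit genes in a fixed
    ascending order (``random_order`` with ``seed`` switches to a seeded
    shuffled order) and set each label to the mode of its conditional,
    with ties at probability 0.5 resolved to +1.  h is computed once from
    the initial labeling unless ``cfg.refresh_h`` is set.
    """
    if gene_ids is None:
        gene_ids = list(net.nodes)
    gene_ids = list(gene_ids)
    p = np.asarray(p_mv, dtype=float)
    if p.shape[0] != len(gene_ids):
        raise ValueError("p_mv and gene list have different lengths")
    clamp = cfg.p_clamp
    if clamp is None:
        clamp = 1.0 / (2.0 * k_perms) if k_perms else 1e-4
    xi = normal_scores(p, clamp=clamp)
    omega = init_labels(p, cfg.init_alpha, cfg.filter_alpha)
    nbrs = _neighbor_arrays(net, gene_ids)
    potential = np.array(
        [_network_terms(nb, omega, cfg.tau1, cfg.tau2, cfg.delta) for nb in nbrs]
    )
    h = compute_h(potential, cfg.h_quantile)
    base = evidence_log_ratio(xi, cfg) - h

    m = len(gene_ids)
    order = np.arange(m)
    rng = np.random.default_rng(seed) if (random_order and seed is not None) else None
    converged = False
    sweeps = 0
    for sweeps in range(1, cfg.max_sweeps + 1):
        if rng is not None:
            order = rng.permutation(m)
        flips = 0
        for i in order:
            q_i = base[i] + _network_terms(nbrs[i], omega, cfg.tau1, cfg.tau2, cfg.delta)
            new = 1 if q_i >= 0 else -1  # posterior >= 0.5 <=> Q >= 0
            if new != omega[i]:
                omega[i] = new
                flips += 1
        if cfg.refresh_h:
            pot = np.array(
                [_network_terms(nb, omega, cfg.tau1, cfg.tau2, cfg.delta) for nb in nbrs]
            )
            h_new = compute_h(pot, cfg.h_quantile)
            base = base + (h - h_new)
            h = h_new
        if flips == 0:
            converged = True
            break
    if not converged:
        warnings.warn(f"ICM did not converge within {cfg.max_sweeps} sweeps", stacklevel=2)
    q_final = np.array(
        [base[i] + _network_terms(nbrs[i], omega, cfg.tau1, cfg.tau2, cfg.delta)
         for i in range(m)]
    )
    posterior = special.expit(q_final)
    return HMRFState(
        gene_ids=gene_ids, xi=xi, omega=omega, potential=potential, h=h,
        posterior=posterior, n_sweeps=sweeps, converged=converged,
    )


def rank_genes(state: HMRFState, top_k: int = 20) -> pd.DataFrame:
    """Top genes by posterior (descending), ties broken by larger xi then
    lexicographic gene id; deterministic."""
    m = len(state.gene_ids)
    if top_k > m:
        warnings.warn(f"top_k={top_k} exceeds {m} genes; returning all", stacklevel=2)
        top_k = m
    df = pd.DataFrame({
        "gene_id": state.gene_ids,
        "xi": state.xi,
        "label": state.omega,
        "potential": state.potential,
        "posterior": state.posterior,
    })
    df = df.sort_values(
        ["posterior", "xi", "gene_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, m + 1)
    return df.head(top_k)


def discrimination_ability(scores) -> float:
    """Fraction of unique values in a score vector: R = U / m.

    Measures a ranking's resolution; a lattice-valued score (permutation
    p-values at small K) has low R, a continuous posterior approaches 1.
    """
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score vector")
    return float(np.unique(scores).size / scores.size)


class HMRFPrioritizer(BaseEstimator):
    """Estimator interface around :func:`icm_fit`.

    ``fit(network, p_mv)`` takes the rewiring network (networkx graph with
    ``weight`` edge attributes) and the candidate genes' MV p-values,
    aligned to ``network.nodes`` order or given as a pandas Series indexed
    by gene id.

    Attributes
    ----------
    state_ : HMRFState
    posterior_ : ndarray
        P(associated) per gene, aligned to ``gene_ids_``.
    labels_ : ndarray of {-1, +1}
    ranking_ : pandas.DataFrame
        Full ranking table (all genes).
    """

    def __init__(self, tau1: float = 0.01, tau2: float = 0.01, delta: float = 0.95,
                 h_quantile: float = 0.90, init_alpha: float = 0.005,
                 filter_alpha: float = 0.01, mu_bar: float = 2.0, a: float = 1.0,
                 g: float = 1.0, d: float = 1.0, max_sweeps: int = 100,
                 p_clamp: float | None = None, k_perms: int | None = None,
                 random_state: int | None = None):
        self.tau1 = tau1
        self.tau2 = tau2
        self.delta = delta
        self.h_quantile = h_quantile
        self.init_alpha = init_alpha
        self.filter_alpha = filter_alpha
        self.mu_bar = mu_bar
        self.a = a
        self.g = g
        self.d = d
        self.max_sweeps = max_sweeps
        self.p_clamp = p_clamp
        self.k_perms = k_perms
        self.random_state = random_state

    def _config(self) -> HMRFConfig:
        return HMRFConfig(
            tau1=self.tau1, tau2=self.tau2, delta=self.delta,
            h_quantile=self.h_quantile, init_alpha=self.init_alpha,
            filter_alpha=self.filter_alpha, mu_bar=self.mu_bar, a=self.a,
            g=self.g, d=self.d, max_sweeps=self.max_sweeps, p_clamp=self.p_clamp,
        )

    def fit(self, network: nx.Graph, p_mv):
        if isinstance(p_mv, pd.Series):
            gene_ids = list(p_mv.index)
            p_vals = p_mv.to_numpy()
        else:
            gene_ids = list(network.nodes)
            p_vals = np.asarray(p_mv, dtype=float)
        self.state_ = icm_fit(
            network, p_vals, self._config(), gene_ids=gene_ids,
            k_perms=self.k_perms, seed=self.random_state,
        )
        self.gene_ids_ = self.state_.gene_ids
        self.posterior_ = self.state_.posterior
        self.labels_ = self.state_.omega
        self.ranking_ = rank_genes(self.state_, top_k=len(gene_ids))
        return self

    def top_genes(self, top_k: int = 20) -> list:
        check_is_fitted(self, "state_")
        return rank_genes(self.state_, top_k=top_k)["gene_id"].tolist()
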