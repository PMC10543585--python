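"""Phylogenetic signal statistics: Blomberg's K and the delta statistic.

Blomberg's K (continuous traits) compares the observed ratio of the mean
squared deviation from the phylogenetically corrected mean (MSE0) to the
variance of phylogenetically corrected residuals (MSE) against its
expectation under Brownian motion on the given tree:

    K = (MSE0 / MSE) / [(tr(C) - n / (1' C^-1 1)) / (n - 1)]

K ~ 1 for traits evolving by BM, K < 1 when close relatives resemble
each other less than BM predicts, K > 1 when they resemble each other
more.  Significance comes from permuting trait values across the tips.

For binary traits the delta statistic measures signal through the
uncertainty of ancestral-state estimates: a symmetric two-state Markov
(Mk) model is fitted by maximum likelihood, marginal ancestral-state
probabilities are computed at every internal node, each node's
probability vector is reduced to a linearised entropy in [0, 1], and a
Beta(a, b) distribution is fitted to the node entropies by ML.  delta is
b_hat / a_hat: when ancestral states are confidently resolved the
entropies pile up near zero and delta grows.  This ML construction is a
deterministic approximation to the original Bayesian MCMC averaging over
ancestral reconstructions; significance again comes from tip-label
randomisation, so the approximation cancels between observed and null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .tree import PhyloTree, bm_covariance

logger = logging.getLogger("phyloconverge")

__all__ = [
    "SignalResult",
    "blomberg_k",
    "blomberg_k_pvalue",
    "delta_signal",
]


@dataclass
class SignalResult:
    """A phylogenetic-signal statistic with its permutation test."""

    statistic_name: str  # "K" | "delta"
    value: float
    p_value: float | None
    n_iterations: int
    trait_name: str


# ---------------------------------------------------------------------------
# Blomberg's K


def _k_statistic(x: np.ndarray, Cinv: np.ndarray, expected_ratio: float) -> float:
    n = x.size
    ones = np.ones(n)
    a = float(ones @ Cinv @ x) / float(ones @ Cinv @ ones)
    d = x - a
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ Cinv @ d) / (n - 1)
    return (mse0 / mse) / expected_ratio


def _prepare_k(tree: PhyloTree, trait) -> tuple[np.ndarray, np.ndarray, float]:
    taxa, x = _align_trait(tree, trait)
    if np.ptp(x) == 0:
        raise ValueError("Blomberg's K undefined for a constant trait")
    C = bm_covariance(tree, taxa=taxa).matrix
    Cinv = linalg.inv(C)
    n = x.size
    expected = (np.trace(C) - n / float(Cinv.sum())) / (n - 1)
    return x, Cinv, expected


def blomberg_k(tree: PhyloTree, trait) -> float:
    """Blomberg's K for a continuous per-species trait.

    ``trait`` is a mapping / pandas Series keyed by species label (or an
    array in the tree's tip order).  K is invariant to shifting and
    positively rescaling the trait.
    """
    x, Cinv, expected = _prepare_k(tree, trait)
    return float(_k_statistic(x, Cinv, expected))


def blomberg_k_pvalue(
    tree: PhyloTree, trait, n_perm: int = 100_000, seed: int | None = None
) -> SignalResult:
    """Permutation test for K: shuffle trait values across tips.

    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1) — the add-one estimator,
    which can never return an exact zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, Cinv, expected = _prepare_k(tree, trait)
    k_obs = _k_statistic(x, Cinv, expected)
    rng = np.random.default_rng(seed)
    count = 0
    xp = x.copy()
    for _ in range(n_perm):
        rng.shuffle(xp)
        if _k_statistic(xp, Cinv, expected) >= k_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    name = trait.name if hasattr(trait, "name") and trait.name else "trait"
    return SignalResult("K", float(k_obs), float(p), n_perm, str(name))


# ---------------------------------------------------------------------------
# delta statistic (binary traits)


def _align_trait(tree: PhyloTree, trait) -> tuple[list[str], np.ndarray]:
    labels = tree.tip_labels
    if hasattr(trait, "reindex"):  # pandas Series keyed by species
        missing = [t for t in labels if t not in trait.index]
        if missing:
            raise KeyError(f"trait missing for taxa: {missing}")
        return labels, trait.reindex(labels).to_numpy(float)
    if isinstance(trait, dict):
        missing = [t for t in labels if t not in trait]
        if missing:
            raise KeyError(f"trait missing for taxa: {missing}")
        return labels, np.array([trait[t] for t in labels], float)
    x = np.asarray(trait, float).ravel()
    if x.size != len(labels):
        raise ValueError("trait length does not match tip count")
    return labels, x


def _mk2_transition(q: float, t: float) -> np.ndarray:
    """Transition matrix of the symmetric 2-state Markov model."""
    e = np.exp(-2.0 * q * t)
    same, diff = 0.5 * (1 + e), 0.5 * (1 - e)
    return np.array([[same, diff], [diff, same]])


def _mk2_partials(tree: PhyloTree, states: dict[str, int], q: float):
    """Felsenstein pruning: per-node conditional likelihoods (tipward)."""
    down: dict[int, np.ndarray] = {}
    for node in tree.dendropy_tree().postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(2)
            vec[states[node.taxon.label]] = 1.0
            down[id(node)] = vec
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                P = _mk2_transition(q, child.edge.length)
                vec = vec * (P @ down[id(child)])
            down[id(node)] = vec
    return down


def _mk2_loglik(tree: PhyloTree, states: dict[str, int], q: float) -> float:
    down = _mk2_partials(tree, states, q)
    root = down[id(tree.dendropy_tree().seed_node)]
    lik = 0.5 * root.sum()  # uniform (stationary) root prior
    return float(np.log(max(lik, 1e-300)))


def fit_mk2(tree: PhyloTree, states: dict[str, int]) -> float:
    """ML rate of the symmetric 2-state Mk model (bounded in log-space)."""
    height = tree.height()
    res = optimize.minimize_scalar(
        lambda lq: -_mk2_loglik(tree, states, np.exp(lq)),
        bounds=(np.log(1e-4 / height), np.log(1e3 / height)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def mk2_marginal_probabilities(
    tree: PhyloTree, states: dict[str, int], q: float
) -> np.ndarray:
    """Marginal ancestral-state probabilities at internal nodes.

    Standard up-down algorithm: the marginal at a node is proportional to
    the product of its tipward partial and a rootward message assembled
    from its parent's prior/message and its siblings' partials.  Rows are
    internal nodes in preorder; columns are the two states.
    """
    dtree = tree.dendropy_tree()
    down = _mk2_partials(tree, states, q)
    up: dict[int, np.ndarray] = {id(dtree.seed_node): np.array([0.5, 0.5])}
    rows = []
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            parent = node.parent_node
            msg = up[id(parent)].copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                P = _mk2_transition(q, sib.edge.length)
                msg = msg * (P @ down[id(sib)])
            P = _mk2_transition(q, node.edge.length)
            up[id(node)] = P.T @ msg
        if not node.is_leaf():
            raw = up[id(node)] * down[id(node)]
            rows.append(raw / raw.sum())
    return np.array(rows)


def _linearised_entropy(probs: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Per-node uncertainty in [0, 1]: for two states, 2 * (1 - max prob).

    Each state probability above 1/k is mapped to (1 - p)/(k - 1) and the
    mapped values are summed, the piecewise-linear entropy surrogate of
    the delta statistic; exact 0/1 values are clipped away from the
    boundary so the Beta likelihood stays finite.
    """
    k = probs.shape[1]
    mapped = np.where(probs > 1.0 / k, (1.0 - probs) / (k - 1.0), probs)
    ent = mapped.sum(axis=1)
    return np.clip(ent, eps, 1.0 - eps)


def _beta_ml(x: np.ndarray) -> tuple[float, float]:
    """ML fit of Beta(a, b) to values in (0, 1) via the profile score."""
    m1, lx, l1x = x.mean(), np.log(x).mean(), np.log1p(-x).mean()
    # method-of-moments start
    v = max(x.var(), 1e-6)
    common = max(m1 * (1 - m1) / v - 1.0, 1e-3)
    a0, b0 = max(m1 * common, 1e-3), max((1 - m1) * common, 1e-3)

    def nll(params):
        la, lb = params
        a, b = np.exp(la), np.exp(lb)
        from scipy.special import betaln

        return betaln(a, b) - (a - 1) * lx - (b - 1) * l1x

    res = optimize.minimize(nll, [np.log(a0), np.log(b0)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, b = np.exp(res.x)
    return float(a), float(b)


def _delta_value(tree: PhyloTree, states: dict[str, int]) -> float:
    q = fit_mk2(tree, states)
    probs = mk2_marginal_probabilities(tree, states, q)
    ent = _linearised_entropy(probs)
    a, b = _beta_ml(ent)
    return b / a


def delta_signal(
    tree: PhyloTree, trait, n_iter: int = 10_000, seed: int | None = None
) -> SignalResult:
    """delta statistic for a binary trait with randomisation p-value.

    ``p`` is the add-one proportion of tip-label randomisations whose
    delta meets or exceeds the observed value — large delta (confident,
    clustered ancestral states) is the signal direction.
    """
    labels, x = _align_trait(tree, trait)
    vals = np.unique(x)
    if not np.isin(vals, [0.0, 1.0]).all():
        raise ValueError("delta requires a 0/1 trait")
    if vals.size < 2:
        raise ValueError("delta undefined when only one state is present")
    states = {lab: int(v) for lab, v in zip(labels, x)}
    d_obs = _delta_value(tree, states)
    rng = np.random.default_rng(seed)
    count = 0
    xs = x.astype(int).copy()
    for _ in range(n_iter):
        rng.shuffle(xs)
        d_null = _delta_value(tree, dict(zip(labels, xs)))
        if d_null >= d_obs:
            count += 1
    p = (1 + count) / (n_iter + 1)
    name = trait.name if hasattr(trait, "name") and trait.name else "trait"
    return SignalResult("delta", float(d_obs), float(p), n_iter, str(name))
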