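"""Convergence testing: the Wheatsheaf index and phylogenetic ANOVA.

Wheatsheaf index
----------------
The Wheatsheaf index W asks whether a designated *focal* set of species
(here, the cooperative breeders and domesticated species) is more
phenotypically similar than the phylogeny would predict.  Traits are
standardised to unit variance, pairwise Euclidean phenotypic distances
are computed, and each pairwise distance is penalised for phylogenetic
relatedness so that similarity between close relatives counts for less:

    D'_ij = D_ij * (1 + rho_ij),   rho_ij = C_ij / sqrt(C_ii * C_jj)

with C the Brownian-motion covariance of the tree (rho is the expected
trait correlation of the pair).  Then

    W = mean(D'_ij over all pairs) / mean(D'_ij over focal pairs),

so W >> 1 when focal species cluster tightly in trait space despite
being phylogenetically scattered.  Significance and a 95% CI come from
bootstrapping species (within the focal and non-focal strata) and
comparing the bootstrap distribution of W against the index's
expectation under non-convergence, estimated by randomly re-drawing
focal sets of the same size.

Phylogenetic ANOVA
------------------
The classical one-way F statistic is computed on the species trait
values, but its null distribution is generated by simulating Brownian
motion on the tree (rate estimated from the data by REML), which
accounts for the non-independence of related species.  Post-hoc pairwise
t statistics are referred to their own simulated null distributions and
corrected for multiple comparisons (Holm by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .tree import PhyloTree, bm_covariance

logger = logging.getLogger("phyloconverge")

__all__ = [
    "WheatsheafResult",
    "PhyloAnovaResult",
    "wheatsheaf",
    "wheatsheaf_test",
    "phylo_anova",
]


@dataclass
class WheatsheafResult:
    w: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    focal_species: tuple[str, ...]
    trait_name: str


@dataclass
class PhyloAnovaResult:
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    n_sim: int
    groups: tuple[str, ...]


# ---------------------------------------------------------------------------
# Wheatsheaf index


def _standardize(T: np.ndarray) -> np.ndarray:
    sd = T.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("traits must be non-constant for the Wheatsheaf index")
    return (T - T.mean(axis=0)) / sd


def _penalized_distances(T: np.ndarray, C: np.ndarray) -> np.ndarray:
    diff = T[:, None, :] - T[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    diag = np.sqrt(np.diag(C))
    rho = C / np.outer(diag, diag)
    return D * (1.0 + rho)


def _w_from_distances(
    Dp: np.ndarray, focal_idx: np.ndarray, valid: np.ndarray | None = None
) -> float:
    """W from a penalized distance matrix.

    ``valid`` masks pairs that correspond to two copies of the same
    original species in a bootstrap resample; such self-pairs have zero
    distance by construction and are excluded from both means.
    """
    n = Dp.shape[0]
    iu = np.triu_indices(n, k=1)
    ok = np.ones(len(iu[0]), bool) if valid is None else valid[iu]
    mean_all = Dp[iu][ok].mean()
    f = np.asarray(focal_idx)
    sub = Dp[np.ix_(f, f)]
    iuf = np.triu_indices(f.size, k=1)
    ok_f = np.ones(len(iuf[0]), bool) if valid is None else valid[np.ix_(f, f)][iuf]
    if not ok_f.any():
        return np.nan
    mean_focal = sub[iuf][ok_f].mean()
    if mean_focal == 0.0:
        return np.inf
    return float(mean_all / mean_focal)


def _prepare_wheatsheaf(tree: PhyloTree, traits, focal):
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = pd.DataFrame(traits)
    from .tree import normalize_label

    traits.index = [normalize_label(s) for s in traits.index]
    taxa = [t for t in tree.tip_labels if t in set(traits.index)]
    if len(taxa) < len(tree.tip_labels):
        missing = sorted(set(tree.tip_labels) - set(taxa))
        raise KeyError(f"trait values missing for taxa: {missing}")
    focal = [normalize_label(s) for s in focal]
    bad = sorted(set(focal) - set(taxa))
    if bad:
        raise KeyError(f"focal species not in tree/table: {bad}")
    if not 2 <= len(focal) < len(taxa):
        raise ValueError("need 2 <= |focal| < n species")
    T = _standardize(traits.loc[taxa].to_numpy(float))
    C = bm_covariance(tree, taxa=taxa).matrix
    focal_idx = np.array([taxa.index(s) for s in focal])
    return taxa, T, C, focal_idx


def wheatsheaf(tree: PhyloTree, traits, focal) -> float:
    """Wheatsheaf index W for the given focal species set.

    ``traits`` is a per-species Series or DataFrame (one or more
    columns); columns are standardised to unit variance and combined by
    Euclidean distance.
    """
    _, T, C, focal_idx = _prepare_wheatsheaf(tree, traits, focal)
    w = _w_from_distances(_penalized_distances(T, C), focal_idx)
    if np.isinf(w):
        logger.warning("all focal phenotypes identical; Wheatsheaf index is +inf")
    return w


def wheatsheaf_test(
    tree: PhyloTree,
    traits,
    focal,
    n_boot: int = 10_000,
    seed: int | None = None,
    trait_name: str | None = None,
) -> WheatsheafResult:
    """Bootstrap test of the Wheatsheaf index.

    Species are resampled with replacement within the focal and
    non-focal strata; each resample's W gives the bootstrap distribution
    (2.5/97.5 percentiles form the 95% CI).  The expectation of W under
    non-convergence is estimated by recomputing W for ``n_boot`` random
    focal sets of the observed size, and p is the add-one proportion of
    bootstrap replicates in which W fails to exceed that expectation.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    taxa, T, C, focal_idx = _prepare_wheatsheaf(tree, traits, focal)
    n = len(taxa)
    Dp = _penalized_distances(T, C)
    w_obs = _w_from_distances(Dp, focal_idx)
    rng = np.random.default_rng(seed)

    nonfocal_idx = np.array([i for i in range(n) if i not in set(focal_idx)])
    w_boot = np.empty(n_boot)
    for b in range(n_boot):
        fb = rng.choice(focal_idx, size=focal_idx.size, replace=True)
        nb = rng.choice(nonfocal_idx, size=nonfocal_idx.size, replace=True)
        idx = np.concatenate([fb, nb])
        sub_T, sub_C = T[idx], C[np.ix_(idx, idx)]
        valid = idx[:, None] != idx[None, :]  # drop duplicated-species self-pairs
        w_boot[b] = _w_from_distances(
            _penalized_distances(sub_T, sub_C), np.arange(fb.size), valid
        )
    finite = w_boot[np.isfinite(w_boot)]
    if finite.size < n_boot // 2:
        raise RuntimeError("bootstrap degenerate: most resampled W undefined")
    ci_low, ci_high = np.percentile(finite, [2.5, 97.5])

    w_null = np.empty(n_boot)
    for b in range(n_boot):
        f_rand = rng.choice(n, size=focal_idx.size, replace=False)
        w_null[b] = _w_from_distances(Dp, f_rand)
    null_expectation = float(np.mean(w_null[np.isfinite(w_null)]))

    valid_boot = w_boot[~np.isnan(w_boot)]  # +inf counts as exceeding
    p = (1 + int((valid_boot <= null_expectation).sum())) / (valid_boot.size + 1)
    name = trait_name or (traits.name if hasattr(traits, "name") else None) or "trait"
    return WheatsheafResult(
        w=float(w_obs),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        n_boot=n_boot,
        focal_species=tuple(taxa[i] for i in focal_idx),
        trait_name=str(name),
    )


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA


def _anova_f(x: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way F; ``x`` may be (n,) or (n_sim, n) for vectorised nulls."""
    X = np.atleast_2d(x)
    n = X.shape[1]
    grand = X.mean(axis=1, keepdims=True)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for g in range(n_groups):
        sel = codes == g
        m = X[:, sel].mean(axis=1, keepdims=True)
        ss_between += (sel.sum() * (m - grand) ** 2).ravel()
        ss_within += ((X[:, sel] - m) ** 2).sum(axis=1)
    df1, df2 = n_groups - 1, n - n_groups
    return (ss_between / df1) / (ss_within / df2)


def _pairwise_t(x: np.ndarray, codes: np.ndarray, pairs) -> np.ndarray:
    """Pooled-variance pairwise t statistics (vectorised over rows of x)."""
    X = np.atleast_2d(x)
    out = np.empty((X.shape[0], len(pairs)))
    for j, (a, b) in enumerate(pairs):
        xa, xb = X[:, codes == a], X[:, codes == b]
        na, nb = xa.shape[1], xb.shape[1]
        ma, mb = xa.mean(axis=1), xb.mean(axis=1)
        sp2 = (((xa - ma[:, None]) ** 2).sum(axis=1)
               + ((xb - mb[:, None]) ** 2).sum(axis=1)) / max(na + nb - 2, 1)
        out[:, j] = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb) + 1e-300)
    return out


def _reml_bm_rate(x: np.ndarray, C: np.ndarray) -> float:
    """REML estimate of the BM rate sigma^2 from a single trait."""
    n = x.size
    Cinv = linalg.inv(C)
    ones = np.ones(n)
    mu = float(ones @ Cinv @ x) / float(ones @ Cinv @ ones)
    d = x - mu
    return float(d @ Cinv @ d) / (n - 1)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def phylo_anova(
    tree: PhyloTree,
    trait,
    groups,
    n_sim: int = 10_000,
    seed: int | None = None,
    correction: str = "holm",
) -> PhyloAnovaResult:
    """Simulation-based phylogenetic ANOVA with corrected post-hoc tests.

    The observed one-way F statistic is referred to a null distribution
    of F values computed from ``n_sim`` Brownian-motion traits simulated
    on the tree (rate estimated from the data by REML).  Pairwise
    post-hoc |t| statistics are referred to their own simulated nulls;
    the resulting p-values are Holm-corrected (``correction="none"``
    disables the correction).  All p-values use the add-one estimator.
    """
    from .tree import normalize_label

    trait = pd.Series(trait)
    groups = pd.Series(groups)
    trait.index = [normalize_label(s) for s in trait.index]
    groups.index = [normalize_label(s) for s in groups.index]
    taxa = tree.tip_labels
    x = trait.reindex(taxa)
    g = groups.reindex(taxa)
    if x.isna().any() or g.isna().any():
        raise KeyError("trait/groups missing for some tree taxa")
    levels = tuple(sorted(map(str, g.unique())))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    codes = np.array([levels.index(str(v)) for v in g])
    counts = np.bincount(codes, minlength=len(levels))
    if (counts < 1).any():
        raise ValueError("every group must be non-empty")
    xv = x.to_numpy(float)

    C = bm_covariance(tree, taxa=taxa).matrix
    rate = _reml_bm_rate(xv, C)
    L = linalg.cholesky(rate * C, lower=True)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, len(taxa))) @ L.T

    f_obs = float(_anova_f(xv, codes, len(levels))[0])
    f_null = _anova_f(sims, codes, len(levels))
    p = (1 + int((f_null >= f_obs).sum())) / (n_sim + 1)

    pairs = list(itertools.combinations(range(len(levels)), 2))
    t_obs = np.abs(_pairwise_t(xv, codes, pairs)[0])
    t_null = np.abs(_pairwise_t(sims, codes, pairs))
    p_pair = (1 + (t_null >= t_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    if correction == "holm":
        p_pair = _holm(p_pair)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    pairwise = {
        (levels[a], levels[b]): float(pv) for (a, b), pv in zip(pairs, p_pair)
    }
    return PhyloAnovaResult(f_obs, float(p), pairwise, n_sim, levels)
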