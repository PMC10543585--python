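"""Synthetic study generator: trees and trait tables with known truth.

The generator emulates the statistical structure of a 17-species
comparative study of amygdala nucleus volumes: an ultrametric pure-birth
phylogeny (depth ~170 Ma), Brownian-motion log body-of-reference volumes
(log BLA) spanning several natural-log units, nucleus volumes tied to
BLA by a log-log allometry with small BM residuals, a known intercept
shift injected into the six focal species (three "cooperative breeders"
plus three "domesticated", disjoint), and seven allomaternal-care
component scores whose per-species sums fall in two well-separated
clusters so that the discretization step recovers exactly the designed
cooperative breeders.

Anatomical nesting is enforced by construction: the lateral (L) and
basal (B) volumes are generated from the allometric model, the accessory
basal (AB) is the remainder BLA - L - B (so the three always sum to the
BLA), and AC = BLA / u with u in (0.5, 0.72), keeping BLA inside AC.
Every random draw flows from a single seed, so generation is exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .tree import PhyloTree, bm_covariance, lambda_transform
from .traits import (
    ALLOCARE_COMPONENTS,
    CARRYING_COMPONENTS,
    TraitTable,
    kmeans_discretize_1d,
    make_elicit_care,
)

logger = logging.getLogger("phyloconverge")

__all__ = [
    "SyntheticScenario",
    "GenerationError",
    "simulate_tree",
    "simulate_bm",
    "make_synthetic_study",
    "individual_table",
    "fixture_tree",
]


def fixture_tree() -> PhyloTree:
    """The packaged deterministic 17-tip ultrametric tree (depth 170 Ma)."""
    from importlib import resources

    from .tree import parse_newick

    text = resources.files("phyloconverge.data").joinpath("tree17.nwk").read_text()
    return parse_newick(text)


class GenerationError(RuntimeError):
    """Raised when a scenario cannot produce a valid trait table."""


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic comparative study.

    Defaults reproduce the study design the generator emulates: 17
    species, 3 + 3 disjoint focal species, a unit allometric slope, an
    upward lateral shift of 0.353 and a downward basal shift of -0.298
    (natural-log units), strong allometric spread (log BLA tip s.d. 1.8)
    with small residual noise (tip s.d. 0.05), and full phylogenetic
    dependence (lambda = 1).
    """

    n_species: int = 17
    tree_depth: float = 170.0  # Ma
    n_coop: int = 3
    n_dom: int = 3
    beta: float = 1.0  # allometric slope on log BLA
    frac_l: float = 0.28  # baseline L / BLA volume fraction
    frac_b: float = 0.46  # baseline B / BLA volume fraction
    shift_l: float = 0.353  # intercept shift of log L in focal species
    shift_b: float = -0.298  # intercept shift of log B in focal species
    root_log_bla: float = -3.0
    sd_bla: float = 1.8  # tip s.d. of log BLA
    sd_resid: float = 0.05  # tip s.d. of allometric residuals
    lambda_true: float = 1.0
    coop_sum_range: tuple[float, float] = (3.8, 5.0)
    noncoop_sum_range: tuple[float, float] = (0.2, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coop + self.n_dom >= self.n_species:
            raise ValueError("focal species must be a strict subset")
        if min(self.n_coop, self.n_dom) < 1:
            raise ValueError("need at least one cooperative breeder and one domesticate")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")


# ---------------------------------------------------------------------------
# Tree and BM simulation


def simulate_tree(n_tips: int, seed: int | None = None, depth: float = 170.0) -> PhyloTree:
    """Ultrametric pure-birth tree with ``n_tips`` extant tips.

    Generated by a Yule process (all lineages extant, hence ultrametric
    by construction) and rescaled so every root-to-tip path equals
    ``depth``.  Tips are labelled ``sp01 .. spNN``.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    birth_time = {id(root): 0.0}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):  # the root is the first split
        child = dendropy.Node()
        root.add_child(child)
        birth_time[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.edge.length = t - birth_time[id(parent)]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / n_tips)  # final waiting time: no zero tips
    taxon_namespace = tree.taxon_namespace
    for i, leaf in enumerate(active, start=1):
        leaf.edge.length = t - birth_time[id(leaf)]
        leaf.taxon = taxon_namespace.new_taxon(label=f"sp{i:02d}")
    root.edge.length = 0.0
    scale = depth / t
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return PhyloTree.from_dendropy(tree)


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    lambda_true: float = 1.0,
    seed=None,
) -> pd.Series:
    """One draw of a Brownian-motion trait at the tips.

    Multivariate normal with mean ``root_value`` and covariance
    ``sigma2 * C_lambda``.  ``seed`` may be an int or a numpy Generator.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = lambda_transform(bm_covariance(tree), lambda_true)
    taxa = cov.taxa
    if sigma2 == 0:
        return pd.Series(root_value, index=list(taxa))
    L = linalg.cholesky(sigma2 * cov.matrix, lower=True)
    x = root_value + L @ rng.standard_normal(len(taxa))
    return pd.Series(x, index=list(taxa))


# ---------------------------------------------------------------------------
# Allocare scores


def _allocare_scores(
    rng: np.random.Generator, species, coop: pd.Series, lo_hi_coop, lo_hi_non
) -> pd.DataFrame:
    """Seven component scores whose sums form two separated clusters.

    A target sum is drawn per species (high range for cooperative
    breeders, low range otherwise); 10-20% of it goes to the two
    infant-carrying components and the rest is split over the other five
    by a flat Dirichlet, so the no-carry variant preserves the cluster
    separation (the same species sit in the upper cluster).
    """
    rows = {}
    others = [c for c in ALLOCARE_COMPONENTS if c not in CARRYING_COMPONENTS]
    for sp in species:
        lo, hi = lo_hi_coop if coop[sp] else lo_hi_non
        total = rng.uniform(lo, hi)
        carry_share = rng.uniform(0.10, 0.20)
        carry_split = rng.dirichlet(np.ones(len(CARRYING_COMPONENTS)))
        other_split = rng.dirichlet(np.ones(len(others)))
        row = dict(zip(CARRYING_COMPONENTS, total * carry_share * carry_split))
        row.update(zip(others, total * (1 - carry_share) * other_split))
        rows[sp] = row
    return pd.DataFrame.from_dict(rows, orient="index")[ALLOCARE_COMPONENTS]


# ---------------------------------------------------------------------------
# Full study


def make_synthetic_study(
    scenario: SyntheticScenario | None = None, **overrides
) -> tuple[TraitTable, PhyloTree]:
    """Generate a (trait table, tree) pair under a known-truth scenario.

    The returned table satisfies every structural invariant (volumes
    positive, L + B + AB = BLA exactly, BLA < AC, binary regimes
    consistent, allocare sums consistent with their components) and its
    discretized cooperative-breeder labels equal the designed ones; a
    scenario whose draws violate positivity or separation raises
    :class:`GenerationError` rather than silently adjusting.
    """
    sc = scenario or SyntheticScenario()
    if overrides:
        sc = replace(sc, **overrides)
    ss = np.random.SeedSequence(sc.seed)
    s_tree, s_traits, s_care = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    tree = simulate_tree(sc.n_species, seed=s_tree, depth=sc.tree_depth)
    species = tree.tip_labels
    rng = np.random.default_rng(s_traits)

    focal = rng.choice(species, size=sc.n_coop + sc.n_dom, replace=False)
    coop = pd.Series(0, index=species)
    dom = pd.Series(0, index=species)
    coop[focal[: sc.n_coop]] = 1
    dom[focal[sc.n_coop :]] = 1
    elicit = make_elicit_care(coop, dom)

    depth = sc.tree_depth
    log_bla = simulate_bm(tree, sc.sd_bla**2 / depth, sc.root_log_bla,
                          sc.lambda_true, rng).reindex(species)
    sig_r = sc.sd_resid**2 / depth
    ev = elicit.to_numpy(float)
    log_l = (np.log(sc.frac_l) + sc.beta * log_bla + sc.shift_l * ev
             + simulate_bm(tree, sig_r, 0.0, sc.lambda_true, rng).reindex(species))
    log_b = (np.log(sc.frac_b) + sc.beta * log_bla + sc.shift_b * ev
             + simulate_bm(tree, sig_r, 0.0, sc.lambda_true, rng).reindex(species))
    bla, l_vol, b_vol = np.exp(log_bla), np.exp(log_l), np.exp(log_b)
    ab_vol = bla - l_vol - b_vol
    if (ab_vol <= 0).any():
        raise GenerationError(
            "accessory basal volume nonpositive; shrink shifts or residual s.d."
        )
    # AC contains the BLA plus the remaining nuclei: BLA is 50-72% of AC
    # (fraction noise has its own small fixed scale, tip s.d. 0.05)
    u = 0.6 * np.exp(simulate_bm(tree, 0.05**2 / depth, 0.0, sc.lambda_true, rng)
                     .reindex(species))
    if (u >= 0.95).any():
        raise GenerationError("BLA/AC fraction reached implausible values")
    ac = bla / u

    care_rng = np.random.default_rng(s_care)
    comp = _allocare_scores(care_rng, species, coop, sc.coop_sum_range,
                            sc.noncoop_sum_range)
    df = pd.DataFrame(
        {
            "AC": np.log(ac),
            "BLA": log_bla,
            "L": log_l,
            "B": log_b,
            "AB": np.log(ab_vol),
        },
        index=species,
    )
    df = df.join(comp)
    df["allocare_sum"] = comp.sum(axis=1)
    df["allocare_sum_nocarry"] = comp.drop(columns=CARRYING_COMPONENTS).sum(axis=1)
    df["cooperative_breeder"] = coop
    df["domesticated"] = dom
    df["elicit_care"] = elicit

    split = kmeans_discretize_1d(df["allocare_sum"])
    if not (split.labels.to_numpy() == coop.to_numpy()).all():
        raise GenerationError("discretization does not recover the designed breeders")
    split_nc = kmeans_discretize_1d(df["allocare_sum_nocarry"])
    if not (split_nc.labels.to_numpy() == coop.to_numpy()).all():
        raise GenerationError("no-carry discretization does not recover the breeders")

    table = TraitTable(df)
    table.validate(strict=True)
    return table, tree


def individual_table(
    table: TraitTable,
    n_per_species: int = 3,
    cv: float = 0.03,
    hemispheres: bool = False,
    seed=None,
) -> pd.DataFrame:
    """Expand a species table into an individual-level measurement CSV.

    Emits one row per individual with volumes on the cm^3 scale,
    multiplicative lognormal noise of coefficient ``cv`` (within-species
    variance of volumetric measures is small), random sex and adult age,
    and optionally separate left/right hemisphere columns.  Feeding the
    result to :func:`~phyloconverge.traits.load_traits` round-trips the
    species means up to the within-species noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .traits import VOLUME_COLS

    rows = []
    for sp in table.species:
        means = np.exp(table.data.loc[sp, VOLUME_COLS].astype(float))
        for _ in range(n_per_species):
            row = {"species": sp.replace("_", " "),
                   "sex": rng.choice(["F", "M"]),
                   "age": round(float(rng.uniform(3, 20)), 1)}
            for col in VOLUME_COLS:
                v = float(means[col] * np.exp(rng.normal(0.0, cv)))
                if hemispheres:
                    asym = np.exp(rng.normal(0.0, cv / 2))
                    row[f"{col}_left"], row[f"{col}_right"] = v * asym, v / asym
                else:
                    row[col] = v
            for col in ALLOCARE_COMPONENTS + ["domesticated"]:
                if col in table.data.columns:
                    row[col] = table.data.loc[sp, col]
            rows.append(row)
    return pd.DataFrame(rows)
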