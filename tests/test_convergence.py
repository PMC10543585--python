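"""Wheatsheaf convergence index and phylogenetic ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyloconverge import (
    parse_newick,
    phylo_anova,
    simulate_bm,
    simulate_tree,
    wheatsheaf,
    wheatsheaf_test,
)
from tests.conftest import star_newick


def _convergent_dataset(seed, n=17, n_focal=6, tightness=0.03):
    """Focal species pulled to a common phenotype; the rest spread by BM."""
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n, seed=seed)
    trait = simulate_bm(tree, 1.0 / tree.height(), seed=rng)
    focal = list(rng.choice(tree.tip_labels, size=n_focal, replace=False))
    target = trait.mean()
    trait[focal] = target + tightness * trait.std() * rng.standard_normal(n_focal)
    trait.name = "x"
    return tree, trait, focal


class TestWheatsheaf:
    def test_order_and_scale_invariance(self, tree17, rng):
        trait = pd.Series(rng.standard_normal(17), index=tree17.tip_labels, name="x")
        focal = tree17.tip_labels[:4]
        w = wheatsheaf(tree17, trait, focal)
        shuffled = trait.sample(frac=1.0, random_state=0)
        assert wheatsheaf(tree17, shuffled, focal) == pytest.approx(w, rel=1e-10)
        assert wheatsheaf(tree17, 10.0 * trait + 3.0, focal) == pytest.approx(
            w, rel=1e-10
        )

    def test_convergent_focal_set_gives_large_w(self):
        ws = [wheatsheaf(*_convergent_dataset(seed)) for seed in range(10)]
        assert np.median(ws) > 2

    def test_tighter_focal_cluster_increases_w(self):
        tree, trait, focal = _convergent_dataset(0, tightness=0.5)
        w_loose = wheatsheaf(tree, trait, focal)
        tree2, trait2, focal2 = _convergent_dataset(0, tightness=0.01)
        assert wheatsheaf(tree2, trait2, focal2) > w_loose

    def test_identical_focal_phenotypes_infinite(self, tree17):
        trait = pd.Series(
            np.arange(17, dtype=float), index=tree17.tip_labels, name="x"
        )
        focal = tree17.tip_labels[:3]
        trait[focal] = 5.0
        assert np.isinf(wheatsheaf(tree17, trait, focal))

    def test_unknown_focal_species(self, tree17, rng):
        trait = pd.Series(rng.standard_normal(17), index=tree17.tip_labels)
        with pytest.raises(KeyError):
            wheatsheaf(tree17, trait, ["nope", "sp01"])

    def test_focal_size_bounds(self, tree17, rng):
        trait = pd.Series(rng.standard_normal(17), index=tree17.tip_labels)
        with pytest.raises(ValueError):
            wheatsheaf(tree17, trait, ["sp01"])

    def test_convergence_detected(self):
        tree, trait, focal = _convergent_dataset(1)
        res = wheatsheaf_test(tree, trait, focal, n_boot=500, seed=0)
        assert res.w > 2 and res.p_value < 0.05
        assert res.ci_low < res.ci_high

    def test_null_w_near_random_focal_median(self):
        """Without convergence, observed W sits inside the random-focal spread."""
        rng = np.random.default_rng(2)
        inside = 0
        for seed in range(20):
            tree = simulate_tree(17, seed=300 + seed)
            trait = simulate_bm(tree, 1.0 / tree.height(), seed=seed)
            trait.name = "x"
            focal = list(rng.choice(tree.tip_labels, size=6, replace=False))
            w = wheatsheaf(tree, trait, focal)
            null = [
                wheatsheaf(tree, trait, list(rng.choice(tree.tip_labels, 6, False)))
                for _ in range(50)
            ]
            lo, hi = np.percentile(null, [5, 95])
            inside += lo <= w <= hi
        assert inside >= 14  # most cases; W has heavy sampling noise at n=17

    def test_reproducible_under_seed(self):
        tree, trait, focal = _convergent_dataset(4)
        r1 = wheatsheaf_test(tree, trait, focal, n_boot=300, seed=11)
        r2 = wheatsheaf_test(tree, trait, focal, n_boot=300, seed=11)
        assert (r1.w, r1.ci_low, r1.ci_high, r1.p_value) == (
            r2.w, r2.ci_low, r2.ci_high, r2.p_value
        )


class TestPhyloAnova:
    @staticmethod
    def _groups(labels, rng, k=3):
        g = rng.integers(0, k, size=len(labels))
        while len(set(g)) < k:
            g = rng.integers(0, k, size=len(labels))
        return pd.Series([f"g{v}" for v in g], index=labels)

    def test_star_tree_matches_classical_anova(self, rng):
        tree = parse_newick(star_newick(17, edge=1.0))
        labels = tree.tip_labels
        x = pd.Series(rng.standard_normal(17), index=labels)
        g = self._groups(labels, rng)
        res = phylo_anova(tree, x, g, n_sim=10_000, seed=0)
        classical = stats.f_oneway(
            *[x[g == lev].to_numpy() for lev in res.groups]
        ).pvalue
        mc_se = np.sqrt(classical * (1 - classical) / 10_000)
        assert res.p_value == pytest.approx(classical, abs=4 * mc_se + 0.005)

    def test_shifted_group_detected(self):
        tree = simulate_tree(18, seed=40, depth=1.0)
        labels = tree.tip_labels
        rng = np.random.default_rng(0)
        x = simulate_bm(tree, 1.0, seed=1)
        g = self._groups(labels, rng)
        x[g == "g0"] += 5 * x.std()
        res = phylo_anova(tree, x, g, n_sim=2_000, seed=2)
        assert res.p_value < 0.01

    def test_pairwise_correction_monotone(self, tree17, rng):
        x = simulate_bm(tree17, 1.0 / 170, seed=3)
        g = self._groups(tree17.tip_labels, rng)
        holm = phylo_anova(tree17, x, g, n_sim=500, seed=4)
        raw = phylo_anova(tree17, x, g, n_sim=500, seed=4, correction="none")
        for pair in holm.pairwise_p:
            assert holm.pairwise_p[pair] >= raw.pairwise_p[pair] - 1e-12

    def test_empty_group_rejected(self, tree17, rng):
        x = simulate_bm(tree17, 1.0 / 170, seed=5)
        g = pd.Series(["a"] * 17, index=tree17.tip_labels)
        with pytest.raises(ValueError):
            phylo_anova(tree17, x, g, n_sim=200)

    def test_reproducible_under_seed(self, tree17, rng):
        x = simulate_bm(tree17, 1.0 / 170, seed=6)
        g = self._groups(tree17.tip_labels, rng)
        r1 = phylo_anova(tree17, x, g, n_sim=400, seed=9)
        r2 = phylo_anova(tree17, x, g, n_sim=400, seed=9)
        assert r1.p_value == r2.p_value and r1.pairwise_p == r2.pairwise_p
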