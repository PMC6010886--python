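"""Conditioned tree simulators and rate/richness conversions."""

import dendropy
import numpy as np
import pytest

import treerates as tr
from treerates import sim as sim_mod


def _patristic(tree):
    """Yield (taxon1, taxon2, distance) for every tip pair."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    present = {lf.taxon for lf in tree.leaf_node_iter()}
    taxa = [t for t in taxa if t in present]
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            yield t1, t2, pdm.patristic_distance(t1, t2)


class TestSimulateCrownBD:
    def test_no_events_possible(self):
        tree = tr.simulate_crown_bd(
            tr.SimConfig(lam=0.0, mu=0.0, depth=7.5, min_tips=2, seed=1)
        )
        bt = tr.branching_times(tree)
        assert bt.n == 2
        assert bt.crown_age == pytest.approx(7.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_acceptance_contract(self, seed):
        config = tr.SimConfig(lam=0.06, mu=0.02, depth=60.0, min_tips=5, seed=seed)
        tree = tr.simulate_crown_bd(config)
        bt = tr.branching_times(tr.assert_ultrametric(tree))
        assert bt.n >= 5
        assert bt.crown_age == pytest.approx(60.0, rel=1e-12)

    def test_extinct_lineages_pruned_to_ultrametric(self):
        # strong extinction: pendant ages all 0 in the reconstructed tree
        tree = tr.simulate_crown_bd(
            tr.SimConfig(lam=0.15, mu=0.1, depth=40.0, min_tips=5, seed=11)
        )
        depths = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            depths[node] = (depths[parent] + node.edge.length) if parent else 0.0
        tip_depths = [depths[lf] for lf in tree.leaf_node_iter()]
        assert max(tip_depths) - min(tip_depths) < 1e-9 * max(tip_depths)

    def test_times_fast_path_matches_tree_path(self):
        config = tr.SimConfig(lam=0.06, mu=0.02, depth=60.0, min_tips=5)
        bt_tree = tr.branching_times(
            tr.simulate_crown_bd(config, rng=np.random.default_rng(21))
        )
        bt_fast = tr.simulate_crown_bd_times(config, rng=np.random.default_rng(21))
        assert bt_fast.n == bt_tree.n
        np.testing.assert_allclose(bt_fast.ages, bt_tree.ages, rtol=1e-9)

    def test_pure_birth_mean_tip_count(self):
        """Unconditioned Yule expectation 2 e^{lam T} = 20 (min_tips=2)."""
        lam, T = 0.04, np.log(10.0) / 0.04
        rng = np.random.default_rng(17)
        config = tr.SimConfig(lam=lam, mu=0.0, depth=T, min_tips=2)
        counts = [
            tr.simulate_crown_bd_times(config, rng=rng).n for _ in range(2000)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_subsampled_run_keeps_crown_age(self):
        config = tr.SimConfig(lam=0.08, mu=0.01, rho=0.5, depth=50.0, min_tips=5, seed=3)
        bt = tr.branching_times(tr.simulate_crown_bd(config))
        assert bt.crown_age == pytest.approx(50.0, rel=1e-12)

    def test_exact_n_conditioning_with_extinction(self):
        config = tr.SimConfig(
            lam=0.08, mu=0.02, depth=40.0, min_tips=2,
            condition="crown-survival-N", n_target=7, seed=5,
        )
        for _ in range(3):
            assert tr.simulate_crown_bd_times(config).n == 7

    def test_survival_scheme_allows_younger_crowns(self):
        """Without the crown-survival requirement the reconstructed crown
        (the extant tips' MRCA) may postdate the simulation start."""
        cfg = tr.SimConfig(
            lam=0.06, mu=0.04, depth=60.0, min_tips=2, condition="survival"
        )
        rng = np.random.default_rng(0)
        crowns = [
            tr.simulate_crown_bd_times(cfg, rng=rng).crown_age for _ in range(30)
        ]
        assert all(c <= 60.0 + 1e-9 for c in crowns)
        assert any(c < 60.0 - 1e-9 for c in crowns)  # some crown lineages died
        # tree path and branching-times path agree under this scheme too
        bt_tree = tr.branching_times(
            tr.simulate_crown_bd(cfg, rng=np.random.default_rng(3))
        )
        bt_fast = tr.simulate_crown_bd_times(cfg, rng=np.random.default_rng(3))
        assert bt_tree.n == bt_fast.n
        np.testing.assert_allclose(bt_tree.ages, bt_fast.ages, rtol=1e-9)

    def test_impossible_acceptance_raises(self, monkeypatch):
        monkeypatch.setattr(sim_mod, "_MAX_REJECTIONS", 500)
        with pytest.raises(tr.SimulationError, match="adjust"):
            tr.simulate_crown_bd(
                tr.SimConfig(lam=0.0, mu=0.0, depth=10.0, min_tips=5, seed=0)
            )

    def test_determinism_from_seed(self):
        config = tr.SimConfig(lam=0.06, mu=0.01, depth=50.0, min_tips=5, seed=99)
        s1 = tr.simulate_crown_bd(config).as_string(schema="newick")
        s2 = tr.simulate_crown_bd(config).as_string(schema="newick")
        assert s1 == s2


class TestSimulateYuleNT:
    def test_two_tips_is_cherry_of_depth_T(self):
        bt = tr.branching_times(tr.simulate_yule_NT(lam=0.1, n=2, depth=12.0, seed=0))
        assert bt.n == 2 and bt.crown_age == pytest.approx(12.0)

    def test_hard_conditioning_contract(self):
        T = np.log(10.0) / 0.04
        rng = np.random.default_rng(2)
        for _ in range(20):
            bt = tr.branching_times(
                tr.simulate_yule_NT(lam=0.04, n=20, depth=T, rng=rng)
            )
            assert bt.n == 20
            assert bt.crown_age == pytest.approx(T, rel=1e-12)

    def test_age_distribution_matches_rejection_oracle(self):
        """Inverse-CDF ages vs brute-force rejection on the forward simulator."""
        lam, n = 0.05, 6
        T = np.log(n / 2.0) / lam  # E(N) = n so acceptance is not too rare
        rng = np.random.default_rng(7)
        direct = np.concatenate(
            [
                tr.branching_times(
                    tr.simulate_yule_NT(lam=lam, n=n, depth=T, rng=rng)
                ).ages[1:]
                for _ in range(400)
            ]
        )
        config = tr.SimConfig(
            lam=lam, mu=0.0, depth=T, min_tips=2,
            condition="crown-survival-N", n_target=n,
        )
        oracle = np.concatenate(
            [tr.simulate_crown_bd_times(config, rng=rng).ages[1:] for _ in range(400)]
        )
        from scipy.stats import ks_2samp

        assert ks_2samp(direct, oracle).pvalue > 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            tr.simulate_yule_NT(lam=0.1, n=1, depth=5.0)
        with pytest.raises(ValueError):
            tr.simulate_yule_NT(lam=0.0, n=5, depth=5.0)


class TestSubsampleTips:
    def test_rho_one_is_identity(self):
        tree = tr.simulate_yule_NT(lam=0.1, n=10, depth=20.0, seed=4)
        out = tr.subsample_tips(tree, rho=1.0, seed=0)
        np.testing.assert_allclose(
            tr.branching_times(out).ages, tr.branching_times(tree).ages
        )

    def test_mean_survivor_count(self):
        rho = 0.3
        n = 200
        rng = np.random.default_rng(12)
        tree = tr.simulate_yule_NT(lam=0.1, n=n, depth=40.0, seed=6)
        counts = []
        for _ in range(300):
            try:
                kept = tr.subsample_tips(tree, rho=rho, rng=rng)
                counts.append(tr.branching_times(kept).n)
            except ValueError:
                counts.append(0)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - n * rho) < 3 * se

    def test_pairwise_divergence_preserved(self, newick_file):
        tree = tr.read_newick(newick_file("(((A:1,B:1):2,C:3):2,D:5);"))[0]
        original = {
            frozenset((t1.label, t2.label)): d
            for t1, t2, d in _patristic(tree)
        }
        for seed in range(6):
            try:
                pruned = tr.subsample_tips(tree, rho=0.6, seed=seed)
            except ValueError:
                continue
            for t1, t2, d in _patristic(pruned):
                assert d == pytest.approx(original[frozenset((t1.label, t2.label))])

    def test_too_few_survivors_is_error(self):
        tree = tr.simulate_yule_NT(lam=0.1, n=4, depth=10.0, seed=2)
        with pytest.raises(ValueError, match="redraw"):
            # force the degenerate draw deterministically
            tr.subsample_tips(tree, rho=1e-9, seed=0)


class TestRateConversions:
    @pytest.mark.parametrize(
        "en,eps,lam_expect,mu_expect",
        [
            (100.0, 0.25, 0.052, 0.013),
            (50.0, 0.25, 0.043, 0.011),
            (500.0, 0.25, 0.074, 0.018),
        ],
    )
    def test_reference_grid_rates(self, en, eps, lam_expect, mu_expect):
        lam, mu = tr.rates_from_EN(en, 100.0, eps)
        assert lam == pytest.approx(lam_expect, abs=6e-4)
        assert mu == pytest.approx(mu_expect, abs=6e-4)

    def test_inverse_pair(self):
        for en in (20.0, 100.0, 1000.0):
            lam, mu = tr.rates_from_EN(en, 137.0, 0.4)
            assert tr.expected_N(lam, mu, 137.0) == pytest.approx(en, rel=1e-12)

    def test_expected_n_examples(self):
        assert tr.expected_N(0.052, 0.013, 0.0) == 2.0
        assert tr.expected_N(0.052, 0.013, 100.0) == pytest.approx(98.9, abs=0.1)
        # the unrounded rates behind the unequal-depth design give exactly 500
        lam, mu = tr.rates_from_EN(100.0, 100.0, 0.25)
        assert tr.expected_N(lam, mu, 141.14) == pytest.approx(500.0, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tr.rates_from_EN(2.0, 100.0, 0.25)
        with pytest.raises(ValueError):
            tr.rates_from_EN(100.0, 100.0, 1.0)


class TestSimulateBatch:
    def test_manifest_and_determinism(self):
        config = tr.SimConfig(lam=0.06, mu=0.01, depth=40.0, min_tips=2, seed=8)
        trees1, man1 = tr.simulate_batch(config, reps=5)
        trees2, man2 = tr.simulate_batch(config, reps=5)
        assert list(man1.columns)[:4] == ["replicate", "seed", "n_extant", "n_sampled"]
        assert man1.equals(man2)
        for t1, t2 in zip(trees1, trees2):
            assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert (man1["n_sampled"] >= 2).all()
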