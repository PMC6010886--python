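"""Model specification, starting values, and maximum-likelihood fitting."""

import math

import numpy as np
import pytest

import treerates as tr
from treerates.fit import _PackedData, start_from_estimates


class TestModelSpec:
    @pytest.mark.parametrize(
        "name,m,k",
        [
            ("equal", 3, 2),
            ("free", 3, 6),
            ("free-speciation", 3, 4),
            ("free-extinction", 3, 4),
            ("yule-equal", 3, 1),
            ("yule-free", 3, 3),
        ],
    )
    def test_parameter_counts(self, name, m, k):
        assert tr.ModelSpec(name).k(m) == k

    def test_grouped_counts_groups_not_trees(self):
        spec = tr.ModelSpec("grouped", groups=(1, 1, 2, 1))
        assert spec.k(4) == 4  # 2 groups -> 2g parameters

    def test_grouped_requires_groups(self):
        with pytest.raises(ValueError, match="groups"):
            tr.ModelSpec("grouped")

    @pytest.mark.parametrize(
        "null,alt,nested",
        [
            ("equal", "free", True),
            ("equal", "free-speciation", True),
            ("equal", "free-extinction", True),
            ("free-speciation", "free", True),
            ("free-extinction", "free", True),
            ("yule-equal", "yule-free", True),
            ("yule-equal", "equal", True),
            ("yule-free", "free", True),
            ("free-speciation", "free-extinction", False),
            ("free", "equal", False),
            ("equal", "yule-free", False),  # alt forbids mu > 0
        ],
    )
    def test_nesting(self, null, alt, nested):
        assert tr.ModelSpec(null).nested_in(tr.ModelSpec(alt), 3) is nested

    def test_grouped_nesting(self):
        grouped = tr.ModelSpec("grouped", groups=(0, 0, 1))
        assert tr.ModelSpec("equal").nested_in(grouped, 3)
        assert grouped.nested_in(tr.ModelSpec("free"), 3)
        assert not grouped.nested_in(tr.ModelSpec("equal"), 3)


class TestInitParams:
    def test_single_tree_moment_match(self):
        bt = tr.BranchingTimes(n=100, ages=np.linspace(100, 1, 99))
        data = tr.MultiTreeData([bt])
        x0 = tr.init_params(data, tr.ModelSpec("equal"))
        lam0, mu0 = np.exp(x0)
        assert lam0 == pytest.approx(math.log(50) / 100, rel=1e-6)  # 0.0391
        assert mu0 == pytest.approx(lam0 / 4, rel=1e-6)

    def test_yule_model_has_no_mu_entry(self):
        bt = tr.BranchingTimes(n=100, ages=np.linspace(100, 1, 99))
        x0 = tr.init_params(tr.MultiTreeData([bt]), tr.ModelSpec("yule-equal"))
        assert x0.shape == (1,)
        assert np.exp(x0[0]) == pytest.approx(math.log(50) / 100, rel=1e-6)

    def test_floor_applies_for_two_tip_tree(self):
        bt = tr.BranchingTimes(n=2, ages=np.array([1.0]))
        x0 = tr.init_params(tr.MultiTreeData([bt]), tr.ModelSpec("equal"))
        assert np.exp(x0[0]) == pytest.approx(1e-6)  # ln(1) = 0 floored


class TestYuleMLE:
    @pytest.mark.parametrize(
        "n,ages,expected",
        [(4, (3.0, 2.0, 1.0), 2 / 9), (3, (2.0, 1.0), 1 / 5)],
    )
    def test_closed_form(self, n, ages, expected):
        res = tr.yule_mle(tr.BranchingTimes(n=n, ages=np.array(ages)))
        assert res.lam == pytest.approx(expected)
        assert not res.at_boundary

    def test_two_tip_boundary(self):
        res = tr.yule_mle(tr.BranchingTimes(n=2, ages=np.array([4.0])))
        assert res.lam == 0.0 and res.loglik == 0.0 and res.at_boundary

    def test_optimizer_agrees_with_closed_form(self, four_tip_bt):
        data = tr.MultiTreeData([four_tip_bt])
        fit = tr.fit_model(data, tr.ModelSpec("yule-equal"))
        oracle = tr.yule_mle(four_tip_bt)
        assert fit.estimates[0][0] == pytest.approx(oracle.lam, abs=1e-6)
        assert fit.loglik == pytest.approx(oracle.loglik, abs=1e-8)


class TestFitModel:
    def test_single_yule_tree_exact(self, four_tip_bt):
        data = tr.MultiTreeData([four_tip_bt])
        fit = tr.fit_model(data, tr.ModelSpec("yule-equal"))
        assert fit.estimates[0] == pytest.approx((2 / 9, 0.0), abs=1e-6)
        assert fit.loglik == pytest.approx(math.log(6) + 2 * math.log(2 / 9) - 2)
        assert fit.converged

    def test_replication_symmetry(self, simulated_pair):
        single = tr.MultiTreeData([simulated_pair.trees[0]])
        fit1 = tr.fit_model(single, tr.ModelSpec("equal"))
        triple = tr.MultiTreeData([simulated_pair.trees[0]] * 3)
        fit3 = tr.fit_model(triple, tr.ModelSpec("equal"))
        assert fit3.estimates[0] == pytest.approx(fit1.estimates[0], rel=1e-3)
        assert fit3.loglik == pytest.approx(3 * fit1.loglik, rel=1e-6)

    def test_free_model_equals_independent_fits(self, simulated_pair):
        """Independence oracle: joint free fit vs per-tree 2-parameter fits."""
        free = tr.fit_model(simulated_pair, tr.ModelSpec("free"))
        total = 0.0
        for i, bt in enumerate(simulated_pair.trees):
            single = tr.fit_model(
                tr.MultiTreeData([bt]), tr.ModelSpec("equal")
            )
            total += single.loglik
            assert free.estimates[i] == pytest.approx(single.estimates[0], abs=1e-3)
        assert free.loglik == pytest.approx(total, abs=1e-4)

    def test_nested_loglik_ordering(self, simulated_pair):
        fits = {
            name: tr.fit_model(simulated_pair, tr.ModelSpec(name)).loglik
            for name in ("equal", "free-speciation", "free-extinction", "free")
        }
        assert fits["free"] >= fits["free-speciation"] - 1e-4
        assert fits["free-speciation"] >= fits["equal"] - 1e-4
        assert fits["free"] >= fits["free-extinction"] - 1e-4
        assert fits["free-extinction"] >= fits["equal"] - 1e-4

    def test_estimates_respect_constraints(self, simulated_pair):
        fs = tr.fit_model(simulated_pair, tr.ModelSpec("free-speciation"))
        mus = [e[1] for e in fs.estimates]
        assert mus[0] == mus[1]
        fe = tr.fit_model(simulated_pair, tr.ModelSpec("free-extinction"))
        lams = [e[0] for e in fe.estimates]
        assert lams[0] == lams[1]

    def test_restart_stability(self):
        """Default restarts find the same optimum as many differently-seeded fits."""
        rng = np.random.default_rng(77)
        agree = 0
        n_data = 20
        for i in range(n_data):
            bts = [
                tr.simulate_crown_bd_times(
                    tr.SimConfig(lam=0.052, mu=0.013, depth=100.0, min_tips=5),
                    rng=rng,
                )
                for _ in range(2)
            ]
            data = tr.MultiTreeData(bts)
            base = tr.fit_model(data, tr.ModelSpec("free"))
            best = max(
                tr.fit_model(
                    data, tr.ModelSpec("free"), tr.FitSettings(seed=s)
                ).loglik
                for s in range(1, 11)
            )
            if abs(base.loglik - best) < 1e-3:
                agree += 1
        assert agree >= n_data - 1

    def test_two_tip_only_data_is_handled(self):
        bt = tr.BranchingTimes(n=2, ages=np.array([5.0]))
        fit = tr.fit_model(tr.MultiTreeData([bt]), tr.ModelSpec("yule-equal"))
        assert fit.loglik == pytest.approx(0.0, abs=1e-6)

    def test_packed_matches_reference_loglik(self, simulated_pair):
        packed = _PackedData(simulated_pair)
        lam = np.array([0.05, 0.06])
        mu = np.array([0.01, 0.02])
        ref = tr.joint_loglik(
            simulated_pair,
            [tr.BDParams(lam=l, mu=m) for l, m in zip(lam, mu)],
        )
        assert packed.loglik(lam, mu) == pytest.approx(ref, rel=1e-12)

    def test_warm_start_projection_recovers_loglik(self, simulated_pair):
        null = tr.fit_model(simulated_pair, tr.ModelSpec("equal"))
        warm = start_from_estimates(null.estimates, tr.ModelSpec("free"), 2)
        packed = _PackedData(simulated_pair)
        lam = np.exp(warm[:2])
        mu = np.exp(warm[2:])
        assert packed.loglik(lam, mu) == pytest.approx(null.loglik, rel=1e-9)
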