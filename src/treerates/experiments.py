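"""Scripted simulation studies: type-I error, power, and parameter recovery.

Each experiment simulates replicate sets of trees under stated
conditions, fits a family of nested rate models to every replicate, and
summarizes rejection rates at ``alpha = 0.05`` together with an exact
binomial test against the nominal level, a KS test of p-value
uniformity, Monte-Carlo standard errors, and estimate means/SDs.
Replicate ``r`` of condition ``c`` draws from the dedicated stream
``(seed, c, r)``, so any run is bit-for-bit reproducible and
parallelizable from its seed alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bdcore import MultiTreeData
from .fit import FitSettings, ModelSpec
from .infer import binomial_exceedance_test, fit_and_test, fit_family, pvalue_uniformity
from .sim import SimConfig, expected_N, rates_from_EN, simulate_crown_bd_times, simulate_yule_NT
from .treeio import branching_times

__all__ = [
    "ExperimentResult",
    "run_null_grid",
    "run_unequal_depth",
    "run_power_sweep",
    "run_multitree",
    "run_yule_small",
    "EXPERIMENTS",
]

ALPHA = 0.05

#: default minimum extant tips per simulated tree; applied to every
#: experiment (the power analyses require it; the null grids adopt it
#: for consistency and flag it in metadata)
DEFAULT_MIN_TIPS = 5


@dataclass
class ExperimentResult:
    """Outputs of one experiment: grid, per-replicate records, summaries."""

    name: str
    conditions: pd.DataFrame
    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def rejection_rate(self, condition: object, model: str) -> float:
        row = self.summary[
            (self.summary["condition"] == condition) & (self.summary["model"] == model)
        ]
        if len(row) != 1:
            raise KeyError(f"no unique summary row for {condition!r}/{model!r}")
        return float(row["rejection_rate"].iloc[0])

    def write(self, outdir: str) -> None:
        """Write per-replicate CSV, summary CSV, and JSON metadata."""
        os.makedirs(outdir, exist_ok=True)
        self.per_replicate.to_csv(
            os.path.join(outdir, f"{self.name}_replicates.csv"), index=False
        )
        self.summary.to_csv(
            os.path.join(outdir, f"{self.name}_summary.csv"), index=False
        )
        self.conditions.to_csv(
            os.path.join(outdir, f"{self.name}_conditions.csv"), index=False
        )
        with open(os.path.join(outdir, f"{self.name}_metadata.json"), "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _simulate_set(rates, depths, rng, min_tips):
    """One replicate: a list of BranchingTimes, one per (lam, mu, T) setting.

    Uses ``condition="survival"`` (any run with >= min_tips extant tips
    is kept, so a tree whose crown lineage died early has a
    correspondingly younger reconstructed crown): the acceptance rule
    the study designs' richness expectations and reference rejection
    rates correspond to.
    """
    out = []
    for (lam, mu), depth in zip(rates, depths):
        config = SimConfig(
            lam=lam, mu=mu, depth=depth, min_tips=min_tips, condition="survival"
        )
        out.append(simulate_crown_bd_times(config, rng=rng))
    return out


def _replicate_record(cond_id, rep, seed_label, data, alt_models, fit_seed):
    """Fit the equal-rates null and each alternative; one row per alternative."""
    rows = []
    settings = FitSettings(seed=fit_seed)
    null_fit, tests = fit_family(
        data, ModelSpec("equal"), [ModelSpec(a) for a in alt_models], settings
    )
    for alt_name, (alt_fit, res) in zip(alt_models, tests):
        rows.append(
            {
                "condition": cond_id,
                "replicate": rep,
                "seed": seed_label,
                "model": alt_name,
                "n_tips": ",".join(str(bt.n) for bt in data.trees),
                "lam_hats": ",".join(f"{e[0]:.8g}" for e in alt_fit.estimates),
                "mu_hats": ",".join(f"{e[1]:.8g}" for e in alt_fit.estimates),
                "null_loglik": null_fit.loglik,
                "alt_loglik": alt_fit.loglik,
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
            }
        )
    return rows


def _yule_replicate_record(cond_id, rep, seed_label, data, fit_seed):
    rows = []
    settings = FitSettings(seed=fit_seed)
    null_fit, alt_fit, res = fit_and_test(
        data, ModelSpec("yule-equal"), ModelSpec("yule-free"), settings
    )
    rows.append(
        {
            "condition": cond_id,
            "replicate": rep,
            "seed": seed_label,
            "model": "yule-free",
            "n_tips": ",".join(str(bt.n) for bt in data.trees),
            "lam_hats": ",".join(f"{e[0]:.8g}" for e in alt_fit.estimates),
            "mu_hats": ",".join("0" for _ in alt_fit.estimates),
            "null_loglik": null_fit.loglik,
            "alt_loglik": alt_fit.loglik,
            "statistic": res.statistic,
            "df": res.df,
            "pvalue": res.pvalue,
        }
    )
    return rows


def _summarize(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, model) rejection rate, binomial and KS p, estimate stats."""
    rows = []
    for (cond, model), grp in per_replicate.groupby(["condition", "model"], sort=False):
        p = grp["pvalue"].to_numpy()
        n = len(p)
        nrej = int((p < ALPHA).sum())
        rate = nrej / n
        lam_mat = np.array(
            [[float(v) for v in s.split(",")] for s in grp["lam_hats"]]
        )
        mu_mat = np.array(
            [[float(v) for v in s.split(",")] for s in grp["mu_hats"]]
        )
        row = {
            "condition": cond,
            "model": model,
            "n_reps": n,
            "rejection_rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / n)),
            "binomial_p": binomial_exceedance_test(nrej, n, ALPHA),
            "ks_p": pvalue_uniformity(p).pvalue,
        }
        for i in range(lam_mat.shape[1]):
            row[f"mean_lam{i + 1}"] = lam_mat[:, i].mean()
            row[f"sd_lam{i + 1}"] = lam_mat[:, i].std(ddof=1)
            row[f"mean_mu{i + 1}"] = mu_mat[:, i].mean()
            row[f"sd_mu{i + 1}"] = mu_mat[:, i].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def _rng_for(seed: int, cond_idx: int, rep: int):
    return np.random.default_rng([seed, cond_idx, rep])


def _build_result(name, conditions, rows, seed, reps, min_tips, extra_meta=None):
    per_replicate = pd.DataFrame(rows)
    metadata = {
        "experiment": name,
        "seed": seed,
        "reps": reps,
        "min_tips": min_tips,
        "alpha": ALPHA,
        "note": "min_tips acceptance applied to all simulated trees",
    }
    if extra_meta:
        metadata.update(extra_meta)
    return ExperimentResult(
        name=name,
        conditions=pd.DataFrame(conditions),
        per_replicate=per_replicate,
        summary=_summarize(per_replicate),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

_ALT_MODELS = ("free", "free-speciation", "free-extinction")


def run_null_grid(
    reps: int = 500,
    seed: int = 0,
    en_values: Sequence[float] = (20, 50, 100, 200, 500),
    min_tips: int = DEFAULT_MIN_TIPS,
    n_trees: int = 3,
) -> ExperimentResult:
    """Type-I error grid: triples of trees at shared rates, T = 100.

    For each target richness ``E(N)`` the shared rates come from
    ``rates_from_EN`` at extinction fraction 0.25; every replicate is
    tested against the equal-rates null with all three alternatives.
    """
    conditions, rows = [], []
    for c, en in enumerate(en_values):
        lam, mu = rates_from_EN(en, 100.0, 0.25)
        conditions.append({"condition": en, "lam": lam, "mu": mu, "T": 100.0})
        for rep in range(reps):
            rng = _rng_for(seed, c, rep)
            trees = _simulate_set([(lam, mu)] * n_trees, [100.0] * n_trees, rng, min_tips)
            data = MultiTreeData(trees)
            rows.extend(
                _replicate_record(
                    en, rep, f"{seed}-{c}-{rep}", data, _ALT_MODELS,
                    fit_seed=int(rng.integers(2**31)),
                )
            )
    return _build_result("null-grid", conditions, rows, seed, reps, min_tips)


def run_unequal_depth(
    reps: int = 500,
    seed: int = 0,
    min_tips: int = DEFAULT_MIN_TIPS,
) -> ExperimentResult:
    """Type-I error with unequal tree depths.

    Pairs of trees at identical rates (lam = 0.052, mu = 0.013) but
    depths 100 and 141.14, chosen so the expected richnesses are about
    100 and 500; all three alternatives vs the equal-rates null.
    """
    lam, mu = 0.052, 0.013
    depths = (100.0, 141.14)
    conditions = [
        {"condition": "unequal-depth", "lam": lam, "mu": mu,
         "T1": depths[0], "T2": depths[1]}
    ]
    rows = []
    for rep in range(reps):
        rng = _rng_for(seed, 0, rep)
        trees = _simulate_set([(lam, mu)] * 2, depths, rng, min_tips)
        data = MultiTreeData(trees)
        rows.extend(
            _replicate_record(
                "unequal-depth", rep, f"{seed}-0-{rep}", data, _ALT_MODELS,
                fit_seed=int(rng.integers(2**31)),
            )
        )
    return _build_result("unequal-depth", conditions, rows, seed, reps, min_tips)


_SWEEP_EN2 = (50.0, 100.0, 200.0, 500.0, 1000.0)
#: shared speciation rate of the variable-extinction sweep: the smallest
#: round value among the sweep designs' rates for which every E(N2) up to
#: 1000 stays reachable with mu >= 0
_EXTINCTION_SWEEP_LAM = 0.075


def run_power_sweep(
    which: str = "speciation",
    reps: int = 500,
    seed: int = 0,
    min_tips: int = DEFAULT_MIN_TIPS,
    conditions_subset: Optional[Sequence[int]] = None,
) -> ExperimentResult:
    """Power and parameter recovery for pairs of trees, T = 100.

    ``which="speciation"``: shared mu = 0.013, lam1 = 0.052, lam2 swept
    over {0.045, 0.052, 0.059, 0.068, 0.075} (tree-2 richness targets
    50..1000); the generating ``free-speciation`` model is fit against
    the equal-rates null.  ``which="extinction"`` is the mirror design
    (shared lam, mu2 solved per richness target); ``which="both"`` varies
    both rates with crossing extinction fractions 0.35 -> 0.15 and
    0.15 -> 0.35, fitting the ``free`` model.

    ``conditions_subset`` selects grid indices (e.g. only the largest
    contrast).
    """
    T = 100.0
    if which == "speciation":
        lam1, mu = 0.052, 0.013
        grid = [((lam1, mu), (lam2, mu)) for lam2 in (0.045, 0.052, 0.059, 0.068, 0.075)]
        labels = [r2[0] for _, r2 in grid]
        alt = "free-speciation"
    elif which == "extinction":
        lam = _EXTINCTION_SWEEP_LAM
        mu1 = lam - np.log(100.0 / 2.0) / T
        grid = []
        for en2 in _SWEEP_EN2:
            mu2 = lam - np.log(en2 / 2.0) / T
            if mu2 < 0:
                raise ValueError(f"infeasible condition: E(N2)={en2} needs mu < 0")
            grid.append(((lam, mu1), (lam, mu2)))
        labels = [f"EN2={en2:g}" for en2 in _SWEEP_EN2]
        alt = "free-extinction"
    elif which == "both":
        en1_grid = (50.0, 100.0, 200.0, 500.0, 1000.0)
        eps1_grid = (0.35, 0.30, 0.25, 0.20, 0.15)
        grid = []
        for en1, en2, eps1, eps2 in zip(
            en1_grid, en1_grid[::-1], eps1_grid, eps1_grid[::-1]
        ):
            grid.append((rates_from_EN(en1, T, eps1), rates_from_EN(en2, T, eps2)))
        labels = [f"EN1={en1:g}" for en1 in en1_grid]
        alt = "free"
    else:
        raise ValueError(f"unknown sweep {which!r}")

    if conditions_subset is not None:
        grid = [grid[i] for i in conditions_subset]
        labels = [labels[i] for i in conditions_subset]

    conditions, rows = [], []
    for c, (rates, label) in enumerate(zip(grid, labels)):
        (l1, m1), (l2, m2) = rates
        conditions.append(
            {"condition": label, "lam1": l1, "mu1": m1, "lam2": l2, "mu2": m2, "T": T}
        )
        for rep in range(reps):
            rng = _rng_for(seed, c, rep)
            trees = _simulate_set(rates, [T, T], rng, min_tips)
            data = MultiTreeData(trees)
            rows.extend(
                _replicate_record(
                    label, rep, f"{seed}-{c}-{rep}", data, (alt,),
                    fit_seed=int(rng.integers(2**31)),
                )
            )
    return _build_result(
        f"power-{which}", conditions, rows, seed, reps, min_tips,
        extra_meta={"sweep": which},
    )


def run_multitree(
    reps: int = 500,
    seed: int = 0,
    n_trees_list: Sequence[int] = tuple(range(2, 12)),
    min_tips: int = DEFAULT_MIN_TIPS,
) -> ExperimentResult:
    """Power as a function of the number of trees sharing the lower rate.

    Tree 1 has lam = 0.067 (richness target about 300 at T = 100);
    trees 2..n have lam = 0.056 (target about 100); mu = 0.017 shared.
    The generating ``free-speciation`` model is tested against the
    equal-rates null for each total tree count n.
    """
    lam1, lam_rest, mu, T = 0.067, 0.056, 0.017, 100.0
    conditions, rows = [], []
    for c, n in enumerate(n_trees_list):
        if n < 2:
            raise ValueError("each tree count must be >= 2")
        conditions.append(
            {"condition": n, "lam1": lam1, "lam_rest": lam_rest, "mu": mu, "T": T}
        )
        rates = [(lam1, mu)] + [(lam_rest, mu)] * (n - 1)
        for rep in range(reps):
            rng = _rng_for(seed, c, rep)
            trees = _simulate_set(rates, [T] * n, rng, min_tips)
            data = MultiTreeData(trees)
            rows.extend(
                _replicate_record(
                    n, rep, f"{seed}-{c}-{rep}", data, ("free-speciation",),
                    fit_seed=int(rng.integers(2**31)),
                )
            )
    return _build_result("multitree", conditions, rows, seed, reps, min_tips)


def run_yule_small(
    reps: int = 500,
    seed: int = 0,
    n_values: Sequence[int] = (5, 10, 20, 40, 80),
    min_tips: int = 2,
) -> ExperimentResult:
    """Power for small pure-birth trees conditioned jointly on N and T.

    Pairs with lam1 = 0.04, lam2 = 0.08; for each target tip count N the
    depths are ``T_i = ln(N/2)/lam_i`` so both trees have richness
    expectation N, and each simulated tree has exactly N tips and crown
    age T_i.  Fits ``yule-free`` vs ``yule-equal`` (df = 1).
    """
    lam1, lam2 = 0.04, 0.08
    conditions, rows = [], []
    for c, n in enumerate(n_values):
        T1 = np.log(n / 2.0) / lam1
        T2 = np.log(n / 2.0) / lam2
        conditions.append(
            {"condition": n, "lam1": lam1, "lam2": lam2, "T1": T1, "T2": T2}
        )
        for rep in range(reps):
            rng = _rng_for(seed, c, rep)
            trees = [
                branching_times(simulate_yule_NT(lam=lam1, n=n, depth=T1, rng=rng)),
                branching_times(simulate_yule_NT(lam=lam2, n=n, depth=T2, rng=rng)),
            ]
            data = MultiTreeData(trees)
            rows.extend(
                _yule_replicate_record(
                    n, rep, f"{seed}-{c}-{rep}", data,
                    fit_seed=int(rng.integers(2**31)),
                )
            )
    return _build_result(
        "yule-small", conditions, rows, seed, reps, min_tips,
        extra_meta={"conditioning": "exact (N, T) pure-birth"},
    )


EXPERIMENTS = {
    "null-grid": run_null_grid,
    "unequal-depth": run_unequal_depth,
    "power-speciation": lambda reps, seed: run_power_sweep("speciation", reps, seed),
    "power-extinction": lambda reps, seed: run_power_sweep("extinction", reps, seed),
    "power-both": lambda reps, seed: run_power_sweep("both", reps, seed),
    "multitree": run_multitree,
    "yule-small": run_yule_small,
}
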