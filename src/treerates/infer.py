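"""Hypothesis tests between nested diversification-rate models.

The workhorse is the likelihood-ratio test: twice the log-likelihood
difference between a nested null/alternative pair referred to the
chi-square distribution whose degrees of freedom equal the difference in
free-parameter counts (2m - 2 for free vs equal, m - 1 for the
single-rate-free variants, 2g - 2 for grouped vs equal).  Because the
chi-square reference can be anticonservative when extinction sits at its
``mu = 0`` boundary, a parametric-bootstrap null is also provided: the
null model is refit, replicate tree sets are simulated under its ML
rates (matching each observed tree's crown age, and optionally its tip
count), and the observed statistic is ranked within the simulated ones.

Also here: the small summary statistics used to evaluate the method on
simulated data — an exact one-sided binomial test for rejection rates
exceeding the nominal level, and a Kolmogorov-Smirnov check of p-value
uniformity under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bdcore import MultiTreeData
from .fit import FitResult, FitSettings, ModelSpec, fit_model, start_from_estimates
from .treeio import branching_times

__all__ = [
    "LRTResult",
    "UniformityResult",
    "lrt",
    "fit_and_test",
    "fit_family",
    "bootstrap_pvalue",
    "binomial_exceedance_test",
    "pvalue_uniformity",
]

#: negative 2*delta-logL larger than this is an optimization failure, not noise
_CLAMP_TOL = 1e-4


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test outcome."""

    statistic: float
    df: int
    pvalue: float
    method: str  # "chisq" or "bootstrap"
    null_loglik: float = np.nan
    alt_loglik: float = np.nan

    def __post_init__(self):
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if not (0 <= self.pvalue <= 1):
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")
        if self.statistic < 0:
            raise ValueError(f"statistic must be >= 0, got {self.statistic}")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "method": self.method,
            "null_loglik": self.null_loglik,
            "alt_loglik": self.alt_loglik,
        }


def lrt(null_fit: FitResult, alt_fit: FitResult, m: Optional[int] = None) -> LRTResult:
    """Chi-square likelihood-ratio test of a nested model pair.

    ``m`` (the number of trees) defaults to the length of the fits'
    estimate vectors and is used to verify nesting structurally.
    """
    if m is None:
        m = len(null_fit.estimates)
    if len(alt_fit.estimates) != m:
        raise ValueError("fits describe different numbers of trees")
    if not null_fit.model.nested_in(alt_fit.model, m):
        raise ValueError(
            f"model {null_fit.model.name!r} is not nested in "
            f"{alt_fit.model.name!r}"
        )
    df = alt_fit.k - null_fit.k
    if df < 1:
        raise ValueError(
            f"alternative must have more parameters than null "
            f"(k_alt={alt_fit.k}, k_null={null_fit.k})"
        )
    delta = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if delta < -_CLAMP_TOL:
        raise RuntimeError(
            f"alternative log-likelihood is below the null's by "
            f"{-delta / 2:.3g} — optimization failure; refit with more restarts"
        )
    statistic = max(delta, 0.0)
    return LRTResult(
        statistic=statistic,
        df=df,
        pvalue=float(stats.chi2.sf(statistic, df)),
        method="chisq",
        null_loglik=null_fit.loglik,
        alt_loglik=alt_fit.loglik,
    )


def fit_and_test(
    data: MultiTreeData,
    null_model: ModelSpec,
    alt_model: ModelSpec,
    settings: FitSettings = FitSettings(),
) -> tuple[FitResult, FitResult, LRTResult]:
    """Fit a nested pair (alternative warm-started at the null optimum) and test."""
    null_fit, tests = fit_family(data, null_model, (alt_model,), settings)
    alt_fit, res = tests[0]
    return null_fit, alt_fit, res


def fit_family(
    data: MultiTreeData,
    null_model: ModelSpec,
    alt_models: Sequence[ModelSpec],
    settings: FitSettings = FitSettings(),
) -> tuple[FitResult, list]:
    """Fit one null and several nested alternatives, sharing the null fit.

    Each alternative gets an extra optimizer start at the null optimum
    (projected into its parameterization), so its fitted log-likelihood
    can only improve on the null's and every LRT statistic is
    non-negative by construction.  Returns the null fit and a list of
    ``(alt_fit, LRTResult)`` pairs in the order given.
    """
    null_fit = fit_model(data, null_model, settings)
    out = []
    for alt_model in alt_models:
        warm = start_from_estimates(null_fit.estimates, alt_model, data.m)
        alt_settings = FitSettings(
            n_restarts=settings.n_restarts,
            seed=settings.seed,
            tol=settings.tol,
            extra_starts=settings.extra_starts + (tuple(warm),),
        )
        alt_fit = fit_model(data, alt_model, alt_settings)
        out.append((alt_fit, lrt(null_fit, alt_fit, data.m)))
    return null_fit, out


def bootstrap_pvalue(
    data: MultiTreeData,
    null_model: ModelSpec,
    alt_model: ModelSpec,
    n_boot: int = 199,
    conditioning: str = "depth-rates",
    seed: int = 0,
    settings: FitSettings = FitSettings(),
) -> LRTResult:
    """Parametric-bootstrap p-value for the likelihood-ratio statistic.

    The null model is fit to the observed data; ``n_boot`` replicate
    tree sets are simulated under the null's ML rates, each replicate
    tree matching the corresponding observed tree's crown age (and, with
    ``conditioning="depth-rates-N"``, its tip count as well — whether
    bootstrap replicates should also fix N is genuinely unsettled, so
    both schemes are exposed).  Each replicate is refit under both
    models and the add-one estimator reported:
    ``p = (1 + #{boot stat >= observed}) / (n_boot + 1)``.

    Replicates that end up unusable (fewer than 2 sampled tips) are
    redrawn, at most 100 redraws each; exact tip-count matching with
    ``mu > 0`` is by rejection and may exhaust the redraw cap if the
    observed N is far from its expectation.
    """
    from . import sim  # deferred: sim imports treeio only, no cycle at runtime

    if conditioning not in ("depth-rates", "depth-rates-N"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    null_fit, alt_fit, observed = fit_and_test(data, null_model, alt_model, settings)

    rng = np.random.default_rng(seed)
    match_n = conditioning == "depth-rates-N"
    n_exceed = 0
    for _ in range(n_boot):
        boot_trees = []
        for bt, (lam, mu), rho in zip(data.trees, null_fit.estimates, data.rhos):
            boot_trees.append(
                _simulate_matched(
                    sim, lam, mu, rho, bt.crown_age, bt.n if match_n else None, rng
                )
            )
        boot_data = MultiTreeData(boot_trees, data.rhos)
        _, _, boot_res = fit_and_test(boot_data, null_model, alt_model, settings)
        if boot_res.statistic >= observed.statistic:
            n_exceed += 1
    pvalue = (1.0 + n_exceed) / (n_boot + 1.0)
    return LRTResult(
        statistic=observed.statistic,
        df=observed.df,
        pvalue=pvalue,
        method="bootstrap",
        null_loglik=null_fit.loglik,
        alt_loglik=alt_fit.loglik,
    )


def _simulate_matched(sim, lam, mu, rho, depth, n_target, rng, max_redraws=100):
    """One bootstrap tree at the null rates, crown age fixed, optionally N fixed."""
    if n_target is not None and mu == 0.0 and rho == 1.0 and lam > 0:
        tree = sim.simulate_yule_NT(lam=lam, n=n_target, depth=depth, rng=rng)
        return branching_times(tree)
    config = sim.SimConfig(
        lam=max(lam, 1e-8), mu=mu, rho=rho, depth=depth, min_tips=2
    )
    for _ in range(max_redraws):
        bt = sim.simulate_crown_bd_times(config, rng=rng)
        if n_target is None or bt.n == n_target:
            return bt
    raise RuntimeError(
        f"could not draw a bootstrap tree matching N={n_target} at "
        f"lam={lam:.4g}, mu={mu:.4g} within {max_redraws} redraws"
    )


# ---------------------------------------------------------------------------
# simulation-study summaries
# ---------------------------------------------------------------------------

def binomial_exceedance_test(errors: int, n: int, nominal: float = 0.05) -> float:
    """Exact one-sided binomial tail P(X >= errors | n, nominal).

    One-sided because the question is whether an observed rejection rate
    significantly *exceeds* the nominal level.
    """
    if not (0 <= errors <= n):
        raise ValueError(f"errors must be in [0, {n}], got {errors}")
    return float(
        stats.binomtest(errors, n, nominal, alternative="greater").pvalue
    )


@dataclass(frozen=True)
class UniformityResult:
    """One-sample KS test of p-values against U(0, 1), plus a 10-bin table."""

    statistic: float
    pvalue: float
    histogram: tuple  # counts in [0,0.1), [0.1,0.2), ..., [0.9,1.0]

    def to_dict(self) -> dict:
        return {
            "ks_statistic": self.statistic,
            "ks_pvalue": self.pvalue,
            "histogram": list(self.histogram),
        }


def pvalue_uniformity(pvals: Sequence[float]) -> UniformityResult:
    """Kolmogorov-Smirnov test of a p-value sample against U(0, 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    ks = stats.kstest(p, "uniform")
    hist, _ = np.histogram(p, bins=10, range=(0.0, 1.0))
    return UniformityResult(
        statistic=float(ks.statistic),
        pvalue=float(ks.pvalue),
        histogram=tuple(int(c) for c in hist),
    )
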