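"""Crown-conditioned constant-rate birth-death likelihood with incomplete sampling.

The model: each tree grows from its crown (the most recent common
ancestor, at known age ``t1``) under a constant-rate birth-death process
with speciation rate ``lam``, extinction rate ``mu``, and a known
sampling fraction ``rho`` (each extant species appears in the tree
independently with probability ``rho``).  Conditioning is on the crown
age and on both crown lineages leaving sampled descendants.  For a tree
with ``N`` sampled tips and branching times ``t1 >= t2 >= ... >= t_{N-1}``
(ages from the present) the log-likelihood is::

    log L = log((N-1)!) + 2 log p1(t1) - 2 log(1 - p0(t1))
            + sum_{j=2}^{N-1} [ log lam + log p1(t_j) ]

with, writing ``r = lam - mu``::

    p0(t) = 1 - rho * r / (rho*lam + (lam*(1-rho) - mu) * exp(-r t))
    p1(t) = rho * r^2 * exp(-r t)
            / (rho*lam + (lam*(1-rho) - mu) * exp(-r t))^2

``p0(t)`` is the probability that a single lineage of age ``t`` leaves no
sampled descendant; ``p1(t)`` that it leaves exactly one.

Numerics
--------
Everything is evaluated on the log scale through the scaled denominator
``Q(t) = D(t)/r = exp(-r t) + rho*lam*(1 - exp(-r t))/r``, which is
strictly positive for every real ``r`` (including ``mu > lam``) and has
the finite limit ``1 + rho*lam*t`` as ``r -> 0``, so the critical ridge
``lam = mu`` is crossed smoothly and ``1 - p0 = rho / Q`` is obtained
without catastrophic cancellation.  ``log((N-1)!)`` uses the log-gamma
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .treeio import BranchingTimes

__all__ = ["BDParams", "MultiTreeData", "p0", "p1", "tree_loglik", "joint_loglik"]

#: |lam - mu| below this (times max(lam, 1)) switches to the lam -> mu limit
_EQUAL_RATES_RTOL = 1e-9


@dataclass(frozen=True)
class BDParams:
    """Birth-death rate triple for one tree.

    Attributes
    ----------
    lam : float
        Speciation rate, per lineage per unit time (>= 0).
    mu : float
        Extinction rate (>= 0).  ``mu = 0`` is the Yule (pure-birth) case.
    rho : float
        Sampling fraction in (0, 1]; treated as known, never estimated.
    """

    lam: float
    mu: float = 0.0
    rho: float = 1.0

    def __post_init__(self):
        if not (self.lam >= 0):
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not (self.mu >= 0):
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")

    @property
    def is_yule(self) -> bool:
        return self.mu == 0.0


@dataclass(frozen=True)
class MultiTreeData:
    """Branching times and sampling fractions for a collection of trees."""

    trees: tuple
    rhos: tuple

    def __init__(self, trees, rhos=None):
        trees = tuple(trees)
        if len(trees) < 1:
            raise ValueError("need at least one tree")
        for bt in trees:
            if not isinstance(bt, BranchingTimes):
                raise TypeError(f"expected BranchingTimes, got {type(bt).__name__}")
        if rhos is None:
            rhos = (1.0,) * len(trees)
        rhos = tuple(float(r) for r in rhos)
        if len(rhos) != len(trees):
            raise ValueError(
                f"got {len(trees)} trees but {len(rhos)} sampling fractions"
            )
        for r in rhos:
            if not (0 < r <= 1):
                raise ValueError(f"sampling fractions must be in (0, 1], got {r}")
        object.__setattr__(self, "trees", trees)
        object.__setattr__(self, "rhos", rhos)

    @property
    def m(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# p0 / p1
# ---------------------------------------------------------------------------

def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be >= 0")
    return t


def p0(t, params: BDParams):
    """Probability that a lineage of age ``t`` leaves no sampled descendant.

    ``1 - p0`` is computed as ``rho / Q`` (its algebraic form) rather
    than by subtraction, so no precision is lost as ``p0 -> 1``.
    """
    t = _check_t(t)
    out = 1.0 - np.exp(
        np.log(params.rho) - _log_q(t, params.lam, params.mu, params.rho)
    )
    return out if out.shape else float(out)


def p1(t, params: BDParams):
    """Probability that a lineage of age ``t`` leaves exactly one sampled descendant."""
    t = _check_t(t)
    x = (params.lam - params.mu) * t
    out = np.exp(
        np.log(params.rho)
        - x
        - 2.0 * _log_q(t, params.lam, params.mu, params.rho)
    )
    return out if out.shape else float(out)


def _log_q(t, lam: float, mu: float, rho: float):
    """log of Q(t) = D(t)/(lam - mu); Q > 0 for all real rate differences.

    Overflow-free: with ``x = r t`` and ``a = rho lam / r``,
    ``Q = e^{-x} + a (1 - e^{-x})``.  For ``r > 0`` both terms are
    positive and bounded; for ``r < 0`` factor out ``e^{-x}`` so the
    exponent lives on the log scale: ``log Q = -x + log1p(a expm1(x))``.
    """
    r = lam - mu
    if abs(r) < _EQUAL_RATES_RTOL * max(lam, 1.0):
        return np.log1p(rho * lam * t)
    x = r * t
    a = rho * lam / r
    if r > 0:
        return np.log(np.exp(-x) - a * np.expm1(-x))
    return -x + np.log1p(a * np.expm1(x))


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------

def tree_loglik(bt: BranchingTimes, params: BDParams) -> float:
    """Crown-conditioned birth-death log-likelihood of one tree.

    Returns ``-inf`` when ``lam == 0`` and ``N > 2`` (more than one
    branching event is impossible without speciation).  Any other
    non-finite intermediate raises ``FloatingPointError``.
    """
    lam, mu, rho = params.lam, params.mu, params.rho
    t = bt.ages
    if lam == 0.0 and bt.n > 2:
        return -np.inf
    r = lam - mu
    with np.errstate(divide="raise", invalid="raise", over="raise"):
        try:
            ll = gammaln(bt.n) - 2.0 * r * t[0] - 2.0 * _log_q(t[0], lam, mu, rho)
            if bt.n > 2:
                tj = t[1:]
                ll += np.sum(
                    np.log(lam * rho) - r * tj - 2.0 * _log_q(tj, lam, mu, rho)
                )
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"non-finite term in log-likelihood at lam={lam}, mu={mu}, "
                f"rho={rho} (crown age {t[0]}): {exc}"
            ) from exc
    return float(ll)


def joint_loglik(data: MultiTreeData, params_list) -> float:
    """Sum of per-tree log-likelihoods across the collection.

    ``params_list`` supplies one :class:`BDParams` per tree; its ``rho``
    must match the data's sampling fraction for that tree.
    """
    params_list = list(params_list)
    if len(params_list) != data.m:
        raise ValueError(
            f"got {data.m} trees but {len(params_list)} parameter sets"
        )
    total = 0.0
    for bt, params, rho in zip(data.trees, params_list, data.rhos):
        if params.rho != rho:
            raise ValueError(
                f"params.rho={params.rho} disagrees with data rho={rho}"
            )
        total += tree_loglik(bt, params)
    return total
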