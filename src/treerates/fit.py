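"""Maximum-likelihood fitting of multi-tree diversification-rate models.

A model is a constraint map assigning each tree's speciation and
extinction rate to a shared or tree-specific parameter:

========================  =======================================  ======
name                      constraints                              k
========================  =======================================  ======
``equal``                 one (lam, mu) shared by all m trees      2
``free``                  tree-specific lam_i and mu_i             2m
``free-speciation``       tree-specific lam_i, shared mu           m + 1
``free-extinction``       shared lam, tree-specific mu_i           m + 1
``yule-equal``            shared lam, mu = 0                       1
``yule-free``             tree-specific lam_i, mu = 0              m
``grouped``               (lam, mu) shared within g groups         2g
========================  =======================================  ======

Optimization is on ``(log lam, log mu)`` per rate class (positivity for
free), with ``mu`` floored at 1e-10 and an explicit ``mu = 0`` profile
evaluated alongside so the pure-birth boundary is reachable — extinction
estimates pile up against ``mu = 0``, which is where their documented
upward mean bias comes from.  Local search is quasi-Newton (L-BFGS-B)
from a moment-matched start plus multiplicatively jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln

from .bdcore import _EQUAL_RATES_RTOL, BDParams, MultiTreeData, tree_loglik
from .treeio import BranchingTimes

__all__ = [
    "ModelSpec",
    "FitSettings",
    "FitResult",
    "MODEL_NAMES",
    "init_params",
    "fit_model",
    "yule_mle",
]

MODEL_NAMES = (
    "equal",
    "free",
    "free-speciation",
    "free-extinction",
    "yule-equal",
    "yule-free",
    "grouped",
)

_MU_FLOOR = 1e-10
_AGREE_TOL = 1e-6
_LOG_LOWER = np.log(_MU_FLOOR)  # also the lam lower bound during search
_LOG_UPPER = 12.0


@dataclass(frozen=True)
class ModelSpec:
    """A named constraint map from trees to shared/free rate parameters."""

    name: str
    groups: Optional[tuple] = None

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {MODEL_NAMES}"
            )
        if self.name == "grouped":
            if self.groups is None:
                raise ValueError("grouped model requires a groups vector")
            object.__setattr__(self, "groups", tuple(self.groups))
        elif self.groups is not None:
            raise ValueError(f"model {self.name!r} does not take groups")

    # -- constraint maps ----------------------------------------------------

    def lam_classes(self, m: int) -> np.ndarray:
        """Class index of each tree's speciation rate (0..n_classes-1)."""
        if self.name in ("free", "free-speciation", "yule-free"):
            return np.arange(m)
        if self.name == "grouped":
            return self._group_index(m)
        return np.zeros(m, dtype=int)

    def mu_classes(self, m: int) -> Optional[np.ndarray]:
        """Class index of each tree's extinction rate, or None when mu = 0."""
        if self.name in ("yule-equal", "yule-free"):
            return None
        if self.name in ("free", "free-extinction"):
            return np.arange(m)
        if self.name == "grouped":
            return self._group_index(m)
        return np.zeros(m, dtype=int)

    def _group_index(self, m: int) -> np.ndarray:
        if len(self.groups) != m:
            raise ValueError(
                f"groups vector has length {len(self.groups)} but m={m}"
            )
        labels = {}
        idx = np.empty(m, dtype=int)
        for i, g in enumerate(self.groups):
            idx[i] = labels.setdefault(g, len(labels))
        return idx

    @property
    def is_yule(self) -> bool:
        return self.name.startswith("yule")

    def k(self, m: int) -> int:
        """Number of free parameters for m trees."""
        n_lam = int(self.lam_classes(m).max()) + 1
        mu = self.mu_classes(m)
        n_mu = 0 if mu is None else int(mu.max()) + 1
        return n_lam + n_mu

    def nested_in(self, other: "ModelSpec", m: int) -> bool:
        """True if this model's parameter space is contained in ``other``'s.

        Holds when ``other``'s equality constraints are implied by this
        model's (its partitions refine this model's) and this model's
        ``mu = 0`` restriction, if any, is reachable in ``other``
        (``mu = 0`` sits on the boundary of an unconstrained ``mu``).
        """
        if not _refines(other.lam_classes(m), self.lam_classes(m)):
            return False
        mu_null, mu_alt = self.mu_classes(m), other.mu_classes(m)
        if mu_null is None:
            return True  # mu = 0 lies in (the closure of) any mu space
        if mu_alt is None:
            return False  # alt forces mu = 0, null does not
        return _refines(mu_alt, mu_null)


def _refines(finer: np.ndarray, coarser: np.ndarray) -> bool:
    """Every class of ``finer`` must sit inside one class of ``coarser``."""
    seen = {}
    for f, c in zip(finer, coarser):
        if seen.setdefault(f, c) != c:
            return False
    return True


@dataclass(frozen=True)
class FitSettings:
    """Optimizer controls for :func:`fit_model`.

    ``n_restarts`` local searches are run: the first from the
    moment-matched start of :func:`init_params`, the rest from
    multiplicative jitters of it (factor ``exp(U(-1, 1))``, seeded).
    Convergence tolerance is on the log-likelihood.
    """

    n_restarts: int = 5
    seed: int = 0
    tol: float = 1e-8
    extra_starts: tuple = ()


class YuleMLE(NamedTuple):
    lam: float
    loglik: float
    at_boundary: bool


@dataclass(frozen=True)
class FitResult:
    """ML estimates and diagnostics for one fitted model."""

    model: ModelSpec
    estimates: tuple  # per-tree (lam_hat, mu_hat), constraints expanded
    loglik: float
    k: int
    converged: bool
    n_restarts_used: int

    def params_list(self, rhos: Sequence[float]) -> list[BDParams]:
        return [
            BDParams(lam=la, mu=mu, rho=rho)
            for (la, mu), rho in zip(self.estimates, rhos)
        ]

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "groups": list(self.model.groups) if self.model.groups else None,
            "estimates": [
                {"tree": i, "lam": float(la), "mu": float(mu)}
                for i, (la, mu) in enumerate(self.estimates)
            ],
            "loglik": float(self.loglik),
            "k": int(self.k),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
        }


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

_INIT_FLOOR = 1e-6


def init_params(data: MultiTreeData, model: ModelSpec) -> np.ndarray:
    """Moment-matched starting vector on the optimizer's log scale.

    For each speciation class, ``lam0 = max(ln(Nbar/2)/Tbar, 1e-6)``
    with ``Nbar``, ``Tbar`` the class means of tip count and crown age
    (inverting the crown expectation ``E(N) = 2 exp(lam T)`` of a
    pure-birth tree); each extinction class starts at a quarter of its
    class's ``lam0``.
    """
    m = data.m
    n = np.array([bt.n for bt in data.trees], dtype=float)
    T = np.array([bt.crown_age for bt in data.trees], dtype=float)

    def class_lam0(idx: np.ndarray) -> np.ndarray:
        ncls = int(idx.max()) + 1
        out = np.empty(ncls)
        for c in range(ncls):
            sel = idx == c
            out[c] = max(np.log(n[sel].mean() / 2.0) / T[sel].mean(), _INIT_FLOOR)
        return out

    lam0 = class_lam0(model.lam_classes(m))
    mu_idx = model.mu_classes(m)
    if mu_idx is None:
        return np.log(lam0)
    mu0 = class_lam0(mu_idx) / 4.0
    return np.log(np.concatenate([lam0, mu0]))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _expand(x: np.ndarray, lam_idx, mu_idx):
    """Map an optimizer vector to per-tree (lam, mu) arrays."""
    n_lam = int(lam_idx.max()) + 1
    lam = np.exp(x[:n_lam])[lam_idx]
    if mu_idx is None:
        mu = np.zeros(len(lam_idx))
    else:
        mu = np.exp(x[n_lam:])[mu_idx]
        mu = np.where(mu <= _MU_FLOOR, 0.0, mu)
    return lam, mu


class _PackedData:
    """All trees' node ages flattened into one array for vectorized evaluation.

    Entry ``e`` carries the tree index ``tree_of[e]``; crown entries
    (``j = 1``) contribute ``-2 r t - 2 log Q(t)`` and later entries
    ``log(lam rho) - r t - 2 log Q(t)``; the ``log((N-1)!)`` terms are a
    data constant.  Equals the sum of :func:`treerates.bdcore.tree_loglik`
    over trees (a tested identity), but in one numpy pass.
    """

    __slots__ = ("tree_of", "ages", "is_crown", "rho", "const", "m")

    def __init__(self, data: MultiTreeData):
        tree_of, ages, is_crown, rho = [], [], [], []
        for i, (bt, rh) in enumerate(zip(data.trees, data.rhos)):
            k = bt.n - 1
            tree_of.extend([i] * k)
            ages.extend(bt.ages)
            is_crown.extend([True] + [False] * (k - 1))
            rho.extend([rh] * k)
        self.tree_of = np.asarray(tree_of, dtype=np.intp)
        self.ages = np.asarray(ages, dtype=float)
        self.is_crown = np.asarray(is_crown, dtype=bool)
        self.rho = np.asarray(rho, dtype=float)
        self.const = float(sum(gammaln(bt.n) for bt in data.trees))
        self.m = data.m

    def loglik(self, lam: np.ndarray, mu: np.ndarray) -> float:
        """Joint log-likelihood at per-tree rates (vectors of length m).

        Same overflow-free branches as :func:`treerates.bdcore._log_q`:
        with ``x = r t`` and ``a = rho lam / r``, ``log Q`` is
        ``log(e^{-x} - a expm1(-x))`` for ``r > 0`` (both terms
        positive) and ``-x + log1p(a expm1(x))`` for ``r < 0``, with the
        ``log1p(rho lam t)`` limit across the ``lam = mu`` ridge.
        """
        return float(
            _packed_loglik_nb(
                self.tree_of, self.ages, self.is_crown, self.rho,
                np.asarray(lam, float), np.asarray(mu, float), self.const,
            )
        )


@njit(cache=False)
def _packed_loglik_nb(tree_of, ages, is_crown, rho, lam, mu, const):
    total = const
    for e in range(ages.shape[0]):
        i = tree_of[e]
        la = lam[i]
        rh = rho[e]
        t = ages[e]
        r = la - mu[i]
        x = r * t
        scale = la if la > 1.0 else 1.0
        if abs(r) < _EQUAL_RATES_RTOL * scale:
            log_q = np.log1p(rh * la * t)
        elif x >= 0.0:
            a = rh * la / r
            log_q = np.log(np.exp(-x) - a * np.expm1(-x))
        else:
            a = rh * la / r
            log_q = -x + np.log1p(a * np.expm1(x))
        term = -x - 2.0 * log_q
        if is_crown[e]:
            term -= x
        else:
            term += np.log(la * rh)
        total += term
    return total


def _neg_loglik_packed(x, packed: _PackedData, lam_idx, mu_idx):
    lam, mu = _expand(np.asarray(x, float), lam_idx, mu_idx)
    with np.errstate(all="ignore"):
        ll = packed.loglik(lam, mu)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _neg_loglik(x, data, lam_idx, mu_idx):
    """Reference objective: per-tree :func:`tree_loglik` summation."""
    lam, mu = _expand(np.asarray(x, float), lam_idx, mu_idx)
    total = 0.0
    try:
        for bt, la, m_, rho in zip(data.trees, lam, mu, data.rhos):
            total += tree_loglik(bt, BDParams(lam=la, mu=m_, rho=rho))
    except FloatingPointError:
        return 1e12
    if not np.isfinite(total):
        return 1e12
    return -total


def _closed_form_yule_lam(data: MultiTreeData, lam_idx: np.ndarray) -> np.ndarray:
    """Per-class pure-birth MLE when rho = 1: sum(N-2)/sum(2 t1 + sum t_j)."""
    ncls = int(lam_idx.max()) + 1
    lam = np.empty(ncls)
    for c in range(ncls):
        num = sum(data.trees[i].n - 2 for i in range(data.m) if lam_idx[i] == c)
        den = sum(
            2.0 * data.trees[i].crown_age + data.trees[i].ages[1:].sum()
            for i in range(data.m)
            if lam_idx[i] == c
        )
        lam[c] = num / den if num > 0 else 0.0
    return lam


def _yule_profile(data, packed, lam_idx: np.ndarray, x_lam0: np.ndarray):
    """Best (lam, loglik) with all mu fixed at 0 for the given lam partition."""
    if all(r == 1.0 for r in data.rhos):
        lam = _closed_form_yule_lam(data, lam_idx)
    else:
        res = minimize(
            _neg_loglik_packed,
            x_lam0,
            args=(packed, lam_idx, None),
            method="L-BFGS-B",
            bounds=[(_LOG_LOWER, _LOG_UPPER)] * len(x_lam0),
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        lam = np.exp(res.x)
    ll = -_neg_loglik_packed(np.log(np.maximum(lam, _MU_FLOOR)), packed, lam_idx, None)
    return lam, ll


def fit_model(
    data: MultiTreeData,
    model: ModelSpec,
    settings: FitSettings = FitSettings(),
) -> FitResult:
    """Maximize the joint log-likelihood under ``model``'s constraint map.

    Returns the best point over all restarts (ties broken by fewest
    iterations) and, for non-Yule models, over the ``mu = 0`` profile.
    A fit that never converges is returned with ``converged=False``
    rather than raised.
    """
    m = data.m
    for bt in data.trees:
        if bt.n < 2:
            raise ValueError("every tree needs at least 2 tips")
    lam_idx = model.lam_classes(m)
    mu_idx = model.mu_classes(m)
    x0 = init_params(data, model)
    n_lam = int(lam_idx.max()) + 1
    packed = _PackedData(data)

    rng = np.random.default_rng(settings.seed)
    starts = [x0]
    for xs in settings.extra_starts:
        xs = np.asarray(xs, dtype=float)
        if xs.shape == x0.shape:
            starts.append(xs)
    for _ in range(max(settings.n_restarts - 1, 0)):
        starts.append(x0 + rng.uniform(-1.0, 1.0, size=x0.shape))

    bounds = [(_LOG_LOWER, _LOG_UPPER)] * len(x0)
    best = None
    second = np.inf
    any_success = False
    n_used = 0
    for x_start in starts:
        res = minimize(
            _neg_loglik_packed,
            x_start,
            args=(packed, lam_idx, mu_idx),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": settings.tol * 1e-2, "gtol": 1e-9, "maxiter": 500},
        )
        n_used += 1
        any_success = any_success or bool(res.success)
        if (
            best is None
            or res.fun < best.fun - 1e-12
            or (abs(res.fun - best.fun) <= 1e-12 and res.nit < best.nit)
        ):
            best, second = res, (np.inf if best is None else best.fun)
        else:
            second = min(second, res.fun)
        # two independent starts landing on the same optimum is enough
        if n_used >= 2 and second - best.fun <= _AGREE_TOL:
            break

    lam, mu = _expand(best.x, lam_idx, mu_idx)
    loglik = -float(best.fun)

    if mu_idx is not None:
        # pure-birth boundary: evaluate the mu = 0 profile and keep the better
        prof_lam_cls, prof_ll = _yule_profile(data, packed, lam_idx, best.x[:n_lam])
        if prof_ll > loglik:
            lam = prof_lam_cls[lam_idx]
            mu = np.zeros(m)
            loglik = prof_ll
            any_success = True

    estimates = tuple((float(la), float(mv)) for la, mv in zip(lam, mu))
    return FitResult(
        model=model,
        estimates=estimates,
        loglik=loglik,
        k=model.k(m),
        converged=any_success and np.isfinite(loglik),
        n_restarts_used=n_used,
    )


def start_from_estimates(
    estimates: Sequence[tuple], model: ModelSpec, m: int
) -> np.ndarray:
    """Project per-tree (lam, mu) estimates onto ``model``'s optimizer vector.

    Used to warm-start an alternative model at a nested null's optimum,
    which guarantees the fitted alternative log-likelihood can only
    improve on the null's.
    """
    lam_hat = np.array([e[0] for e in estimates], dtype=float)
    mu_hat = np.array([e[1] for e in estimates], dtype=float)
    lam_idx = model.lam_classes(m)
    mu_idx = model.mu_classes(m)
    n_lam = int(lam_idx.max()) + 1
    x_lam = np.array(
        [np.log(max(lam_hat[lam_idx == c].mean(), _MU_FLOOR)) for c in range(n_lam)]
    )
    if mu_idx is None:
        return x_lam
    n_mu = int(mu_idx.max()) + 1
    x_mu = np.array(
        [np.log(max(mu_hat[mu_idx == c].mean(), _MU_FLOOR)) for c in range(n_mu)]
    )
    return np.concatenate([x_lam, x_mu])


# ---------------------------------------------------------------------------
# Yule closed form (internal oracle; rho = 1)
# ---------------------------------------------------------------------------

def yule_mle(bt: BranchingTimes) -> YuleMLE:
    """Closed-form pure-birth MLE for a single fully-sampled tree.

    ``lam_hat = (N - 2) / (2 t1 + sum_{j>=2} t_j)``.  For ``N = 2`` the
    estimate sits on the ``lam = 0`` boundary and the log-likelihood is 0.
    """
    if bt.n == 2:
        return YuleMLE(lam=0.0, loglik=0.0, at_boundary=True)
    denom = 2.0 * bt.crown_age + float(bt.ages[1:].sum())
    lam_hat = (bt.n - 2) / denom
    ll = tree_loglik(bt, BDParams(lam=lam_hat, mu=0.0, rho=1.0))
    return YuleMLE(lam=float(lam_hat), loglik=float(ll), at_boundary=False)
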