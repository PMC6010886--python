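"""Simulation of reconstructed birth-death and pure-birth trees.

Trees are grown forward in time (Gillespie) from the two crown lineages
for a fixed duration ``T``, so that after pruning extinct and unsampled
lineages the reconstructed crown age equals ``T`` deterministically —
matching the likelihood's conditioning on the crown age.  A run is
accepted only if both crown lineages leave extant descendants and the
extant count reaches ``min_tips``; with a sampling fraction ``rho < 1``
extant tips are then dropped independently and the run is redrawn if
fewer than 2 tips survive or the crown condition breaks.

For the pure-birth case an exact joint ``(N, T)`` conditioning is
available: given ``n`` tips and crown age ``T``, the ``n - 2``
non-crown node ages are i.i.d. with CDF ``F(t) = (1 - e^{-lam t}) /
(1 - e^{-lam T})`` on ``(0, T)``, drawn by analytic inversion, and the
topology follows by sequential uniform attachment in age order.
Joint ``(N, T)`` conditioning with extinction has no such closed form
and is handled by rejection where it is needed (bootstrap nulls).

Also here: the deterministic conversions between rates and expected
crown richness, ``E(N) = 2 e^{(lam - mu) T}``, used to lay out
simulation grids at constant extinction fraction ``mu / lam``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .treeio import BranchingTimes

__all__ = [
    "SimConfig",
    "SimulationError",
    "simulate_crown_bd",
    "simulate_crown_bd_times",
    "simulate_yule_NT",
    "subsample_tips",
    "expected_N",
    "rates_from_EN",
    "simulate_batch",
]

_MAX_REJECTIONS = 1_000_000


class SimulationError(RuntimeError):
    """Raised when the rejection sampler cannot produce an acceptable tree."""


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one reconstructed-tree simulation.

    Attributes
    ----------
    lam, mu : float
        Speciation and extinction rates (per lineage per unit time).
    rho : float
        Sampling fraction in (0, 1]; applied to extant tips after
        pruning extinct lineages.
    depth : float
        Crown age ``T`` of the simulated clade (time units).
    min_tips : int
        Minimum extant tip count for acceptance (before sampling);
        default 5, lowerable to 2.
    condition : str
        ``"crown-survival"`` (default): both crown lineages must leave
        sampled descendants, so the reconstructed crown age equals
        ``depth`` exactly — the scheme matching the likelihood's
        conditioning.  ``"survival"``: accept any run with enough
        extant tips; if one crown lineage died out, the reconstructed
        crown (the extant tips' MRCA) is younger than ``depth``.
        ``"crown-survival-N"`` additionally requires exactly
        ``n_target`` sampled tips.
    n_target : int, optional
        Required tip count under ``"crown-survival-N"``.
    seed : int
        RNG seed; replicate ``r`` of a batch uses the derived stream
        ``(seed, r)``.
    """

    lam: float
    mu: float = 0.0
    rho: float = 1.0
    depth: float = 100.0
    min_tips: int = 5
    condition: str = "crown-survival"
    n_target: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be >= 0")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.min_tips < 2:
            raise ValueError("min_tips must be >= 2")
        if self.condition not in ("crown-survival", "survival", "crown-survival-N"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "crown-survival-N":
            if self.n_target is None or self.n_target < 2:
                raise ValueError("crown-survival-N requires n_target >= 2")


# ---------------------------------------------------------------------------
# forward Gillespie simulation
# ---------------------------------------------------------------------------

class _Forest:
    """Flat-array record of one forward simulation from 2 crown lineages."""

    __slots__ = ("birth", "end", "children", "extant", "sampled", "depth")

    def __init__(self, depth: float):
        self.birth = [0.0, 0.0]
        self.end = [depth, depth]
        self.children = [None, None]
        self.extant = []  # filled after the run
        self.sampled = None
        self.depth = depth


def _gillespie(lam: float, mu: float, depth: float, rng) -> _Forest:
    """Run a birth-death process from 2 crown lineages for ``depth`` time."""
    f = _Forest(depth)
    birth, end, children = f.birth, f.end, f.children
    alive = [0, 1]
    total = lam + mu
    t = 0.0
    if total > 0.0:
        p_birth = lam / total
        while alive:
            n = len(alive)
            t += rng.exponential(1.0 / (n * total))
            if t >= depth:
                break
            pos = int(rng.integers(n))
            i = alive[pos]
            end[i] = t
            if rng.random() < p_birth:
                j = len(birth)
                birth.extend((t, t))
                end.extend((depth, depth))
                children.extend((None, None))
                children[i] = (j, j + 1)
                alive[pos] = j
                alive.append(j + 1)
            else:
                children[i] = ()  # extinct tip
                alive[pos] = alive[-1]
                alive.pop()
    f.extant = alive
    return f


def _count_sampled(f: _Forest) -> list:
    """Sampled-descendant count per lineage (children precede parents in reverse)."""
    ndesc = [0] * len(f.birth)
    for i in f.sampled:
        ndesc[i] = 1
    for i in range(len(f.birth) - 1, -1, -1):
        kids = f.children[i]
        if kids:
            ndesc[i] = sum(ndesc[k] for k in kids)
    return ndesc


def _attempt(config: SimConfig, rng) -> Optional[_Forest]:
    """One simulation attempt; returns the forest or None if rejected."""
    crown = config.condition != "survival"
    f = _gillespie(config.lam, config.mu, config.depth, rng)
    if len(f.extant) < config.min_tips:
        return None
    f.sampled = f.extant
    if crown:
        # survival of both crown lineages (before sampling)
        ndesc = _count_sampled(f)
        if ndesc[0] == 0 or ndesc[1] == 0:
            return None
    if config.rho < 1.0:
        keep = [i for i in f.extant if rng.random() < config.rho]
        if len(keep) < 2:
            return None
        f.sampled = keep
        if crown:
            ndesc = _count_sampled(f)
            if ndesc[0] == 0 or ndesc[1] == 0:
                return None
    if config.condition == "crown-survival-N" and len(f.sampled) != config.n_target:
        return None
    return f


def _accepted_forest(config: SimConfig, rng) -> _Forest:
    for _ in range(_MAX_REJECTIONS):
        f = _attempt(config, rng)
        if f is not None:
            return f
    raise SimulationError(
        f"no acceptable tree in {_MAX_REJECTIONS} attempts at lam={config.lam}, "
        f"mu={config.mu}, depth={config.depth}, min_tips={config.min_tips}, "
        f"condition={config.condition!r}; adjust the parameters"
    )


def _reconstructed_ages(f: _Forest) -> np.ndarray:
    """Ages of the reconstructed tree's internal nodes, oldest first.

    A simulated split survives reconstruction iff both its daughter
    subtrees contain a sampled tip; the time-0 crown split qualifies
    only when both crown lineages do (otherwise the reconstructed crown
    is the oldest surviving split and is younger than ``depth``).
    """
    ndesc = _count_sampled(f)
    ages = []
    if ndesc[0] > 0 and ndesc[1] > 0:
        ages.append(f.depth)  # crown split at time 0
    for i, kids in enumerate(f.children):
        if kids and len(kids) == 2 and ndesc[kids[0]] > 0 and ndesc[kids[1]] > 0:
            ages.append(f.depth - f.end[i])
    return np.sort(np.asarray(ages))[::-1]


def _to_dendropy(f: _Forest) -> dendropy.Tree:
    """Build the reconstructed (extant, sampled only) tree, tips at age 0."""
    ndesc = _count_sampled(f)
    sampled = set(f.sampled)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    tip_counter = [0]

    def _first_event(i: int) -> int:
        """Descend through unifurcations to the next sampled split or tip."""
        while True:
            kids = f.children[i]
            if not kids:
                return i
            live = [k for k in kids if ndesc[k] > 0]
            if len(live) == 2:
                return i
            i = live[0]

    # seed the traversal at the reconstructed root: the crown if both
    # crown lineages carry sampled tips, else the oldest surviving split
    # (stack holds (lineage index, parent dendropy node, parent age))
    if ndesc[0] > 0 and ndesc[1] > 0:
        stack = [(_first_event(0), root, f.depth), (_first_event(1), root, f.depth)]
    else:
        side = 0 if ndesc[0] > 0 else 1
        top = _first_event(side)
        age = f.depth - f.end[top]
        stack = [
            (_first_event(k), root, age)
            for k in f.children[top]
            if ndesc[k] > 0
        ]
    while stack:
        i, parent, parent_age = stack.pop()
        kids = f.children[i]
        if not kids:  # sampled extant tip, age 0
            tip_counter[0] += 1
            taxon = ns.new_taxon(label=f"t{tip_counter[0]}")
            node = parent.new_child(taxon=taxon, edge_length=parent_age)
            assert i in sampled and node is not None
        else:
            age = f.depth - f.end[i]
            node = parent.new_child(edge_length=parent_age - age)
            for k in kids:
                if ndesc[k] > 0:
                    stack.append((_first_event(k), node, age))
    return tree


def simulate_crown_bd(config: SimConfig, rng=None) -> dendropy.Tree:
    """Simulate one reconstructed birth-death tree conditioned on its crown age.

    The returned tree is ultrametric with tips at age 0 and crown age
    exactly ``config.depth``.  Raises :class:`SimulationError` when the
    acceptance probability is too low.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _to_dendropy(_accepted_forest(config, rng))


def simulate_crown_bd_times(config: SimConfig, rng=None) -> BranchingTimes:
    """Like :func:`simulate_crown_bd` but return branching times directly.

    Skips tree construction; identical acceptance and randomness stream,
    so with the same generator state it describes the same tree that
    :func:`simulate_crown_bd` would have built.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _accepted_forest(config, rng)
    ages = _reconstructed_ages(f)
    return BranchingTimes(n=len(f.sampled), ages=ages)


# ---------------------------------------------------------------------------
# exact (N, T) pure-birth conditioning
# ---------------------------------------------------------------------------

def simulate_yule_NT(
    lam: float, n: int, depth: float, seed: int = 0, rng=None
) -> dendropy.Tree:
    """Pure-birth tree with exactly ``n`` tips and crown age exactly ``depth``.

    The crown age is fixed at ``depth``; the remaining ``n - 2`` node
    ages are drawn i.i.d. from the single-age density conditioned on the
    process having ``n`` tips at ``depth``, ``F(t) = (1 - e^{-lam t}) /
    (1 - e^{-lam T})``, inverted analytically and sorted.  Topology is
    assembled by splitting a uniformly chosen open lineage at each
    branching age, oldest first.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if lam <= 0 or depth <= 0:
        raise ValueError("lam and depth must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    u = rng.random(n - 2)
    ages = -np.log1p(u * np.expm1(-lam * depth)) / lam
    ages = np.sort(ages)[::-1]

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    # open lineages as (dendropy parent node, age at which the lineage began)
    open_lineages = [(root, depth), (root, depth)]
    for age in ages:
        pos = int(rng.integers(len(open_lineages)))
        parent, start_age = open_lineages[pos]
        node = parent.new_child(edge_length=start_age - age)
        open_lineages[pos] = (node, age)
        open_lineages.append((node, age))
    for idx, (parent, start_age) in enumerate(open_lineages, start=1):
        taxon = ns.new_taxon(label=f"t{idx}")
        parent.new_child(taxon=taxon, edge_length=start_age)
    return tree


# ---------------------------------------------------------------------------
# subsampling and rate/richness conversions
# ---------------------------------------------------------------------------

def subsample_tips(
    tree: dendropy.Tree, rho: float, seed: int = 0, rng=None
) -> dendropy.Tree:
    """Keep each tip independently with probability ``rho``; prune the rest.

    Pairwise divergence times among survivors are unchanged.  Fewer than
    2 survivors is an error (the caller decides whether to redraw).
    """
    if not (0 < rho <= 1):
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rho == 1.0:
        return tree.clone(depth=1)
    leaves = [lf.taxon for lf in tree.leaf_node_iter()]
    keep = [tx for tx in leaves if rng.random() < rho]
    if len(keep) < 2:
        raise ValueError(
            f"subsampling at rho={rho} left {len(keep)} tips (< 2); redraw"
        )
    return tree.extract_tree_with_taxa(taxa=keep)


def expected_N(lam: float, mu: float, depth: float) -> float:
    """Expected extant tip count of a crown process, ``2 e^{(lam - mu) T}``.

    Expectation without survival conditioning.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return 2.0 * np.exp((lam - mu) * depth)


def rates_from_EN(
    expected_n: float, depth: float, extinction_fraction: float = 0.0
) -> tuple[float, float]:
    """Invert :func:`expected_N` at a fixed extinction fraction ``mu/lam``.

    Returns ``(lam, mu)`` with ``lam = ln(expected_n/2) / (T (1 - eps))``
    and ``mu = eps * lam``.
    """
    if expected_n <= 2:
        raise ValueError("expected_n must be > 2")
    if not (0 <= extinction_fraction < 1):
        raise ValueError("extinction_fraction must be in [0, 1)")
    lam = np.log(expected_n / 2.0) / (depth * (1.0 - extinction_fraction))
    return float(lam), float(extinction_fraction * lam)


# ---------------------------------------------------------------------------
# batch simulation (CLI backend)
# ---------------------------------------------------------------------------

def simulate_batch(config: SimConfig, reps: int) -> tuple[list, pd.DataFrame]:
    """Simulate ``reps`` trees; replicate ``r`` uses the stream ``(seed, r)``.

    Returns the trees and a manifest with per-replicate seeds, extant
    and sampled tip counts, depth and rates.
    """
    trees = []
    rows = []
    for r in range(reps):
        rng = np.random.default_rng([config.seed, r])
        f = _accepted_forest(config, rng)
        trees.append(_to_dendropy(f))
        rows.append(
            {
                "replicate": r,
                "seed": f"{config.seed}-{r}",
                "n_extant": len(f.extant),
                "n_sampled": len(f.sampled),
                "depth": config.depth,
                "lam": config.lam,
                "mu": config.mu,
                "rho": config.rho,
            }
        )
    return trees, pd.DataFrame(rows)
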