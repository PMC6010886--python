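"""Reading, validating, and summarizing time-calibrated trees.

Trees are handled as rooted :class:`dendropy.Tree` objects with branch
lengths in units of time.  The only statistic the diversification
likelihood needs is the vector of internal-node ages ("branching times"),
so this module reduces a validated ultrametric tree to a
:class:`BranchingTimes` record: the tip count ``N`` and the ``N - 1``
node ages measured backward from the present, ordered root-to-tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeFormatError",
    "UltrametricityError",
    "NonMonophyleticError",
    "BranchingTimes",
    "read_newick",
    "write_newick",
    "assert_ultrametric",
    "branching_times",
    "extract_clade",
]

#: default relative tolerance for ultrametricity checks (fraction of depth)
DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeFormatError(ValueError):
    """Raised when a Newick source cannot be parsed or is structurally invalid."""


class UltrametricityError(ValueError):
    """Raised when root-to-tip path lengths differ beyond tolerance."""


class NonMonophyleticError(ValueError):
    """Raised when a requested tip set does not form a clade."""

    def __init__(self, intruders: Iterable[str]):
        self.intruders = sorted(intruders)
        super().__init__(
            "tip set is not monophyletic; MRCA also contains: "
            + ", ".join(self.intruders)
        )


@dataclass(frozen=True)
class BranchingTimes:
    """Sufficient statistic of an ultrametric tree for the birth-death likelihood.

    Attributes
    ----------
    n : int
        Number of tips (``N >= 2``).
    ages : numpy.ndarray
        The ``N - 1`` internal-node ages measured backward from the
        present (tips at age 0), sorted non-increasing.  ``ages[0]`` is
        the crown age: the depth of the most recent common ancestor of
        all tips.
    """

    n: int
    ages: np.ndarray = field(repr=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        ages = np.sort(ages)[::-1].copy()
        object.__setattr__(self, "ages", ages)
        self.ages.setflags(write=False)
        if self.n < 2:
            raise ValueError(f"need at least 2 tips, got N={self.n}")
        if ages.shape != (self.n - 1,):
            raise ValueError(
                f"expected {self.n - 1} node ages for N={self.n}, got {ages.shape[0]}"
            )
        if not np.all(ages > 0):
            raise ValueError("all node ages must be strictly positive")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(path: str, multi: bool = False) -> list[dendropy.Tree]:
    """Read one or more rooted Newick trees from ``path``.

    Parameters
    ----------
    path : str
        File containing ';'-terminated Newick strings.
    multi : bool
        Allow more than one tree in the file.  With ``multi=False`` a
        file holding several trees is an error.

    Returns
    -------
    list of dendropy.Tree
        One tree per Newick string, labels and branch lengths preserved.

    Raises
    ------
    TreeFormatError
        On parse failure (message carries dendropy's line/column report),
        on an empty file, or if any non-root branch lacks a length.
    """
    try:
        trees = dendropy.TreeList.get(
            path=path,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeFormatError(f"could not parse Newick file {path!r}: {exc}") from exc
    if len(trees) == 0:
        raise TreeFormatError(f"no trees found in {path!r}")
    if not multi and len(trees) > 1:
        raise TreeFormatError(
            f"{path!r} contains {len(trees)} trees; pass multi=True to accept them"
        )
    for idx, tree in enumerate(trees):
        _check_branch_lengths(tree, f"tree {idx} in {path!r}")
    return list(trees)


def _check_branch_lengths(tree: dendropy.Tree, label: str) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeFormatError(
                f"{label}: branch leading to {name} has no length; "
                "branch lengths are required on every non-root edge"
            )
        if node.edge.length < 0:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeFormatError(
                f"{label}: branch leading to {name} has negative length "
                f"{node.edge.length}"
            )


def write_newick(trees: Sequence[dendropy.Tree] | dendropy.Tree, path: str) -> None:
    """Write trees to ``path``, one Newick string per line, full precision."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(
                tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    real_value_format_specifier=".17g",
                ).strip()
                + "\n"
            )


# ---------------------------------------------------------------------------
# Validation and reduction
# ---------------------------------------------------------------------------

def _root_distances(tree: dendropy.Tree) -> dict:
    dist = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dist[node] = 0.0
        else:
            dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
    return dist


def assert_ultrametric(
    tree: dendropy.Tree, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> dendropy.Tree:
    """Validate that all root-to-tip path lengths agree within ``rel_tol``.

    The check passes when ``max - min <= rel_tol * max`` over root-to-tip
    distances.  Returns the tree unchanged so calls can be chained.

    Raises
    ------
    UltrametricityError
        Reporting the maximum deviation and the shallowest/deepest tips.
    """
    dist = _root_distances(tree)
    leaves = [(node, dist[node]) for node in tree.leaf_node_iter()]
    if not leaves:
        raise TreeFormatError("tree has no tips")
    dmax = max(d for _, d in leaves)
    dmin = min(d for _, d in leaves)
    if dmax - dmin > rel_tol * dmax:
        hi = max(leaves, key=lambda nd: nd[1])[0]
        lo = min(leaves, key=lambda nd: nd[1])[0]
        raise UltrametricityError(
            f"tree is not ultrametric: root-to-tip distances span "
            f"[{dmin:.12g}, {dmax:.12g}] (deviation {dmax - dmin:.12g} > "
            f"{rel_tol:g} * depth); offending tips: "
            f"{lo.taxon.label if lo.taxon else '?'} (shallowest), "
            f"{hi.taxon.label if hi.taxon else '?'} (deepest)"
        )
    return tree


def branching_times(
    tree: dendropy.Tree, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> BranchingTimes:
    """Reduce an ultrametric binary tree to its ordered branching times.

    Node ages are ``depth - distance_from_root``; the returned vector is
    sorted non-increasing so that ``ages[0]`` is the crown age.

    Raises
    ------
    UltrametricityError
        If the tree fails :func:`assert_ultrametric` at ``rel_tol``.
    TreeFormatError
        If the tree has fewer than 2 tips, a polytomy or unifurcation
        (the likelihood's ``(N-1)!`` term and per-node ``lambda * p1``
        product assume a binary tree), or an internal node at age 0.
    """
    assert_ultrametric(tree, rel_tol=rel_tol)
    dist = _root_distances(tree)
    depth = max(dist[node] for node in tree.leaf_node_iter())
    n_tips = 0
    ages = []
    for node in tree.preorder_node_iter():
        nchild = len(node.child_nodes())
        if nchild == 0:
            n_tips += 1
        elif nchild == 2:
            ages.append(depth - dist[node])
        else:
            raise TreeFormatError(
                f"tree is not strictly binary: internal node with {nchild} "
                "children; resolve polytomies/unifurcations before analysis"
            )
    if n_tips < 2:
        raise TreeFormatError(f"need at least 2 tips, got {n_tips}")
    ages_arr = np.sort(np.asarray(ages, dtype=float))[::-1]
    if ages_arr[-1] <= 0:
        raise TreeFormatError(
            "internal node at age <= 0; zero-age branching events are not "
            "supported by the ordered branching-time model"
        )
    return BranchingTimes(n=n_tips, ages=ages_arr)


def extract_clade(tree: dendropy.Tree, tip_set: Iterable[str]) -> dendropy.Tree:
    """Extract the subtree spanned by ``tip_set``, rooted at their MRCA.

    ``tip_set`` must be monophyletic: the most recent common ancestor of
    the named tips may contain no other tips.  Branch lengths below the
    MRCA are preserved exactly; the MRCA becomes the new root (with no
    root edge).  The input tree is not modified.

    Raises
    ------
    NonMonophyleticError
        Listing the intruding tips.
    KeyError
        If a requested label is absent from the tree.
    """
    wanted = set(tip_set)
    present = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    missing = wanted - present
    if missing:
        raise KeyError(f"tip labels not in tree: {sorted(missing)}")
    if wanted == present:
        return tree.clone(depth=1)
    clone = tree.clone(depth=1)
    mrca = clone.mrca(taxon_labels=sorted(wanted))
    under = {lf.taxon.label for lf in mrca.leaf_iter() if lf.taxon}
    intruders = under - wanted
    if intruders:
        raise NonMonophyleticError(intruders)
    mrca.parent_node = None
    mrca.edge.length = None
    sub = dendropy.Tree(seed_node=mrca, taxon_namespace=clone.taxon_namespace)
    sub.is_rooted = True
    return sub
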