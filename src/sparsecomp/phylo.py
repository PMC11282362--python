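"""Phylogeny container, Newick I/O, tree simulation, and covariance structures.

The :class:`Phylogeny` container is deliberately minimal: integer node ids,
a parent map, optional branch lengths (``None`` means *unknown*, which is
distinct from zero), and tip labels.  Polytomies are first-class; nothing
here assumes bifurcation.  Newick parsing and writing are delegated to
dendropy and converted to/from this container.

Covariance construction covers the standard comparative-methods structures:

* ``identity`` — star phylogeny / no phylogenetic correlation;
* ``brownian`` — tip covariance equals the shared root-to-MRCA path length
  under a Brownian trait model;
* ``pagel_lambda`` — Brownian off-diagonals scaled by Pagel's λ ∈ [0, 1];
* ``martins_hansen`` — OU-derived correlation exp(−α·d) in patristic
  distance d;
* ``grafen`` — path sums on Grafen height-derived branch lengths, with the
  heights raised to a power ρ (usable on trees without measured lengths).

Trees whose branch lengths are unknown get unit lengths substituted before
any length-dependent computation; the substitution is logged once per call.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("sparsecomp")

__all__ = [
    "Phylogeny",
    "CovarianceSpec",
    "NewickParseError",
    "make_balanced_tree",
    "simulate_birth_death_tree",
    "birth_death_tip_count",
    "read_newick",
    "write_newick",
    "covariance_matrix",
    "patristic_distances",
    "mrca",
    "extract_subtree",
    "prune_to_tips",
    "assign_clades",
]

COVARIANCE_MODELS = ("identity", "brownian", "grafen", "pagel_lambda", "martins_hansen")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted."""


class Phylogeny:
    """Rooted phylogeny with optional branch lengths and labeled tips.

    Nodes are integers ``0..n_nodes-1``; the root has no parent and no
    branch length.  A branch length of ``None`` means the length is
    unknown (taxonomy trees), which is treated differently from ``0.0``.
    """

    def __init__(self) -> None:
        self._parent: list[int | None] = []
        self._children: list[list[int]] = []
        self._length: list[float | None] = []
        self._label: dict[int, str] = {}
        self.root: int = 0

    # -- construction -------------------------------------------------

    def add_node(
        self,
        parent: int | None,
        length: float | None = None,
        label: str | None = None,
    ) -> int:
        node = len(self._parent)
        if parent is None:
            if node != 0:
                raise ValueError("tree already has a root")
        elif parent < 0 or parent >= node:
            raise ValueError(f"unknown parent node {parent}")
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length}")
        self._parent.append(parent)
        self._children.append([])
        self._length.append(length if parent is not None else None)
        if parent is not None:
            self._children[parent].append(node)
        if label is not None:
            self._label[node] = label
        return node

    # -- basic queries ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._parent)

    def parent(self, node: int) -> int | None:
        return self._parent[node]

    def children(self, node: int) -> tuple[int, ...]:
        return tuple(self._children[node])

    def branch_length(self, node: int) -> float | None:
        return self._length[node]

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_tip(v)]

    def tip_label(self, node: int) -> str:
        return self._label[node]

    def tip_labels(self) -> list[str]:
        return [self._label[v] for v in self.tips()]

    def node_for_label(self, label: str) -> int:
        for v, lab in self._label.items():
            if lab == label and self.is_tip(v):
                return v
        raise KeyError(f"no tip labeled {label!r}")

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def preorder(self) -> Iterable[int]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self._children[v]))

    def postorder(self) -> Iterable[int]:
        return reversed(list(self.preorder()))

    def has_branch_lengths(self) -> bool:
        """True if every non-root branch carries a length."""
        return all(
            self._length[v] is not None for v in range(self.n_nodes) if v != self.root
        )

    def effective_lengths(self) -> np.ndarray:
        """Branch lengths with unit substitution when any are unknown.

        Index ``v`` gives the length of the branch above node ``v``; the
        root entry is 0.  If any non-root branch lacks a length, *every*
        branch is given length 1 (the unknown-length trees in scope are
        taxonomies, where partial lengths are not meaningful).
        """
        out = np.zeros(self.n_nodes)
        if self.has_branch_lengths():
            for v in range(self.n_nodes):
                if v != self.root:
                    out[v] = self._length[v]  # type: ignore[assignment]
        else:
            logger.info(
                "tree lacks branch lengths on some branches; substituting unit lengths"
            )
            out[:] = 1.0
            out[self.root] = 0.0
        return out

    def node_depths(self, lengths: np.ndarray | None = None) -> np.ndarray:
        """Root-to-node path lengths (root depth 0)."""
        if lengths is None:
            lengths = self.effective_lengths()
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self._parent[v]
            if p is not None:
                depth[v] = depth[p] + lengths[v]
        return depth

    def descendant_tips(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(reversed(self._children[v]))
        return out

    def validate(self) -> None:
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip labels: {dup}")
        if any(not lab for lab in labels):
            raise NewickParseError("empty tip label")
        for v in range(self.n_nodes):
            bl = self._length[v]
            if bl is not None and bl < 0:
                raise ValueError(f"negative branch length on node {v}")

    def __repr__(self) -> str:
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


@dataclass
class CovarianceSpec:
    """Residual covariance structure for phylogenetic regression.

    ``parameter`` holds λ (pagel_lambda), α (martins_hansen), or ρ
    (grafen); it may be the string ``"estimate"`` to request maximum
    likelihood profiling by the fitting routines.  ``identity`` and
    ``brownian`` carry no free parameter.
    """

    model: str
    parameter: float | str | None = None

    def __post_init__(self) -> None:
        if self.model not in COVARIANCE_MODELS:
            raise ValueError(
                f"unknown covariance model {self.model!r}; expected one of {COVARIANCE_MODELS}"
            )
        if self.model in ("identity", "brownian"):
            if self.parameter not in (None, "estimate"):
                raise ValueError(f"{self.model} covariance carries no free parameter")
            self.parameter = None
            return
        if self.parameter is None:
            raise ValueError(f"{self.model} covariance requires a parameter")
        if self.parameter == "estimate":
            return
        val = float(self.parameter)
        if self.model == "pagel_lambda" and not 0.0 <= val <= 1.0:
            raise ValueError(f"Pagel's lambda must lie in [0, 1], got {val}")
        if self.model == "martins_hansen" and val <= 0:
            raise ValueError(f"Martins-Hansen alpha must be positive, got {val}")
        if self.model == "grafen" and val <= 0:
            raise ValueError(f"Grafen rho must be positive, got {val}")
        self.parameter = val


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------


def make_balanced_tree(depth: int, branch_length: float = 1.0) -> Phylogeny:
    """Full bifurcating tree with ``2**depth`` tips and uniform branch lengths.

    ``depth=0`` gives the degenerate single-tip tree.
    """
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    if branch_length <= 0:
        raise ValueError(f"branch_length must be positive, got {branch_length}")
    tree = Phylogeny()
    counter = [0]

    def grow(parent: int | None, level: int) -> None:
        if level == 0:
            counter[0] += 1
            tree.add_node(parent, None if parent is None else branch_length,
                          label=f"t{counter[0]}")
            return
        node = tree.add_node(parent, None if parent is None else branch_length)
        grow(node, level - 1)
        grow(node, level - 1)

    grow(None, depth)
    return tree


def simulate_birth_death_tree(
    n_tips: int,
    birth: float = 1.0,
    death_nu: float = 0.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> Phylogeny:
    """Forward birth-death simulation conditioned on reaching ``n_tips``.

    Two lineages start at the root.  Lineages split at rate ``birth`` and
    die at rate ``death_nu`` (the ν parameter); waiting times are
    exponential.  Simulation stops the instant the extant count reaches
    ``n_tips``; extinct lineages are pruned.  Runs where the whole tree
    dies are discarded and redrawn, up to ``max_retries`` times.
    """
    if n_tips < 1:
        raise ValueError(f"n_tips must be positive, got {n_tips}")
    if birth <= 0:
        raise ValueError(f"birth rate must be positive, got {birth}")
    if death_nu < 0:
        raise ValueError(f"death rate must be non-negative, got {death_nu}")
    if death_nu >= birth:
        raise ValueError(
            f"death rate ({death_nu}) must be below the birth rate ({birth}) "
            "to guarantee the target tip count is reached"
        )
    if n_tips == 1:
        tree = Phylogeny()
        tree.add_node(None, label="t1")
        return tree

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        result = _grow_birth_death(n_tips, birth, death_nu, rng)
        if result is not None:
            return result
    raise RuntimeError(
        f"birth-death simulation went extinct in {max_retries} consecutive runs"
    )


def _grow_birth_death(
    n_tips: int, birth: float, death: float, rng: np.random.Generator
) -> Phylogeny | None:
    # children-of mapping built on the fly; node 0 is the root
    parent: list[int | None] = [None, 0, 0]
    birth_time: list[float] = [0.0, 0.0, 0.0]  # time the branch above each node began
    end_time: dict[int, float] = {}  # set on split or death
    alive = [1, 2]
    is_dead: set[int] = set()
    t = 0.0
    p_birth = birth / (birth + death)
    while len(alive) < n_tips:
        if not alive:
            return None
        rate = len(alive) * (birth + death)
        t += rng.exponential(1.0 / rate)
        v = alive[rng.integers(len(alive))]
        if rng.random() < p_birth:
            end_time[v] = t
            for _ in range(2):
                parent.append(v)
                birth_time.append(t)
                alive.append(len(parent) - 1)
            alive.remove(v)
        else:
            end_time[v] = t
            alive.remove(v)
            is_dead.add(v)
    # run the clock forward to just before the next event would occur, so
    # the final split does not leave zero-length sister tips
    rate = len(alive) * (birth + death)
    t += rng.exponential(1.0 / rate)
    for v in alive:
        end_time[v] = t

    # prune extinct lineages: keep nodes with at least one alive descendant
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for v in range(1, n):
        children[parent[v]].append(v)  # type: ignore[index]
    keep = [False] * n
    for v in reversed(range(n)):
        if not children[v]:
            keep[v] = v in set(alive)
        else:
            keep[v] = any(keep[c] for c in children[v])
    if not keep[0]:
        return None

    # rebuild, suppressing pruned branches and unary pass-through nodes
    tree = Phylogeny()
    tip_counter = [0]

    def build(v: int, new_parent: int | None, pending_len: float) -> None:
        kept_children = [c for c in children[v] if keep[c]]
        length = end_time[v] - birth_time[v] if v != 0 else 0.0
        total = pending_len + length
        if not kept_children:
            tip_counter[0] += 1
            tree.add_node(new_parent, None if new_parent is None else total,
                          label=f"t{tip_counter[0]}")
            return
        if len(kept_children) == 1 and v != 0:
            build(kept_children[0], new_parent, total)
            return
        if v == 0 and len(kept_children) == 1:
            # root's only surviving child becomes the new root
            build(kept_children[0], None, 0.0)
            return
        node = tree.add_node(new_parent, None if new_parent is None else total)
        for c in kept_children:
            build(c, node, 0.0)

    build(0, None, 0.0)
    return tree if tree.n_tips == n_tips else None


def birth_death_tip_count(
    birth: float, death_nu: float, time: float, seed: int = 0
) -> int:
    """Extant lineage count of one birth-death run stopped at a fixed time.

    Diagnostic companion to :func:`simulate_birth_death_tree` sharing the
    same event dynamics; the analytic expectation starting from two root
    lineages is ``2 * exp((birth - death_nu) * time)``.
    """
    rng = np.random.default_rng(seed)
    t = 0.0
    n_alive = 2
    p_birth = birth / (birth + death_nu)
    while n_alive > 0:
        rate = n_alive * (birth + death_nu)
        dt = rng.exponential(1.0 / rate)
        if t + dt > time:
            break
        t += dt
        n_alive += 1 if rng.random() < p_birth else -1
    return n_alive


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are optional and, when absent, recorded as unknown
    (``None``) rather than zero.  Polytomies are preserved.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    tree = Phylogeny()

    def convert(dnode: dendropy.Node, parent: int | None) -> None:
        length = dnode.edge.length
        if length is not None:
            length = float(length)
        label = None
        if dnode.is_leaf():
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            if not label:
                raise NewickParseError("tip without a label")
        node = tree.add_node(parent, None if parent is None else length, label=label)
        for child in dnode.child_nodes():
            convert(child, node)

    convert(dtree.seed_node, None)
    tree.validate()
    return tree


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; branches with unknown lengths carry no ``:len``."""

    def render(v: int) -> str:
        if tree.is_tip(v):
            core = tree.tip_label(v)
        else:
            core = "(" + ",".join(render(c) for c in tree.children(v)) + ")"
        bl = tree.branch_length(v)
        if v != tree.root and bl is not None:
            core += f":{bl:.12g}"
        return core

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# covariance / distance construction
# ---------------------------------------------------------------------------


def _brownian_matrix(tree: Phylogeny, depths: np.ndarray) -> np.ndarray:
    """V_ij = depth of the MRCA of tips i and j; V_ii = tip depth."""
    tips = tree.tips()
    index = {v: i for i, v in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    for i, v in enumerate(tips):
        V[i, i] = depths[v]
    # tips under each node, accumulated bottom-up; cross-child pairs share
    # exactly this node as their MRCA
    below: dict[int, list[int]] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            below[v] = [index[v]]
            continue
        groups = [below[c] for c in tree.children(v)]
        merged: list[int] = []
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        V[a, b] = V[b, a] = depths[v]
            merged.extend(groups[gi])
        below[v] = merged
    return V


def _grafen_depths(tree: Phylogeny, rho: float) -> np.ndarray:
    """Root-to-node depths on the Grafen-height transformed tree.

    Node height = (number of descendant tips − 1)/(n − 1), so the root has
    height 1 and tips height 0; heights are raised to the power ρ and the
    depth of a node is root-height^ρ − height^ρ.
    """
    n = tree.n_tips
    if n < 2:
        return np.zeros(tree.n_nodes)
    counts = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if tree.is_tip(v):
            counts[v] = 1
        else:
            counts[v] = sum(counts[c] for c in tree.children(v))
    heights = (counts - 1) / (n - 1)
    return heights[tree.root] ** rho - heights**rho


def covariance_matrix(tree: Phylogeny, spec: CovarianceSpec) -> pd.DataFrame:
    """Tip covariance (or correlation) matrix under the given structure.

    Returned as a DataFrame indexed by tip label in tree tip order.  For
    ``martins_hansen`` the result is a correlation matrix (unit diagonal);
    the other models scale with tree depth.
    """
    labels = tree.tip_labels()
    n = len(labels)
    if n < 2:
        raise ValueError("covariance requires at least 2 tips")
    if spec.parameter == "estimate":
        raise ValueError(
            "covariance_matrix needs a fixed parameter; use the fitting "
            "routines to profile it"
        )
    if spec.model == "identity":
        V = np.eye(n)
    elif spec.model == "brownian":
        V = _brownian_matrix(tree, tree.node_depths())
    elif spec.model == "pagel_lambda":
        V = _brownian_matrix(tree, tree.node_depths())
        lam = float(spec.parameter)  # type: ignore[arg-type]
        diag = np.diag(V).copy()
        V = V * lam
        np.fill_diagonal(V, diag)
    elif spec.model == "martins_hansen":
        D = patristic_distances(tree).to_numpy()
        V = np.exp(-float(spec.parameter) * D)  # type: ignore[arg-type]
    elif spec.model == "grafen":
        V = _brownian_matrix(tree, _grafen_depths(tree, float(spec.parameter)))  # type: ignore[arg-type]
    else:  # pragma: no cover - guarded by CovarianceSpec
        raise ValueError(spec.model)
    return pd.DataFrame(V, index=labels, columns=labels)


def patristic_distances(tree: Phylogeny) -> pd.DataFrame:
    """Pairwise tip-to-tip path lengths; d_ij = V_ii + V_jj − 2 V_ij."""
    depths = tree.node_depths()
    V = _brownian_matrix(tree, depths)
    d = np.diag(V)
    D = d[:, None] + d[None, :] - 2 * V
    np.fill_diagonal(D, 0.0)
    labels = tree.tip_labels()
    return pd.DataFrame(D, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# tree queries
# ---------------------------------------------------------------------------


def mrca(tree: Phylogeny, tips: Iterable[str]) -> int:
    """Most recent common ancestor (node id) of the given tip labels."""
    tips = list(tips)
    if not tips:
        raise ValueError("mrca of an empty tip set is undefined")
    paths = []
    for label in tips:
        v = tree.node_for_label(label)  # KeyError on unknown label
        path = [v]
        while (p := tree.parent(path[-1])) is not None:
            path.append(p)
        paths.append(list(reversed(path)))
    # longest shared prefix of the root-to-tip paths
    anc = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        nodes = {p[depth] for p in paths}
        if len(nodes) == 1:
            anc = nodes.pop()
        else:
            break
    return anc


def extract_subtree(tree: Phylogeny, root_node: int) -> Phylogeny:
    """Copy of the clade rooted at ``root_node`` (branch lengths preserved)."""
    if root_node < 0 or root_node >= tree.n_nodes:
        raise KeyError(f"unknown node {root_node}")
    sub = Phylogeny()

    def build(v: int, parent: int | None) -> None:
        label = tree.tip_label(v) if tree.is_tip(v) else None
        node = sub.add_node(
            parent, None if parent is None else tree.branch_length(v), label=label
        )
        for c in tree.children(v):
            build(c, node)

    build(root_node, None)
    return sub


def prune_to_tips(tree: Phylogeny, keep_labels: Iterable[str]) -> Phylogeny:
    """Restrict the tree to a subset of tips.

    The new root is the MRCA of the kept tips; pass-through (unary) nodes
    are suppressed with their branch lengths summed (a sum involving an
    unknown length is unknown).
    """
    keep = set(keep_labels)
    if not keep:
        raise ValueError("cannot prune to an empty tip set")
    missing = keep - set(tree.tip_labels())
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    top = mrca(tree, keep)
    retain: dict[int, bool] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            retain[v] = tree.tip_label(v) in keep
        else:
            retain[v] = any(retain[c] for c in tree.children(v))
    sub = Phylogeny()

    def add_len(a: float | None, b: float | None) -> float | None:
        if a is None or b is None:
            return None
        return a + b

    def build(v: int, parent: int, pending: float | None) -> None:
        total = add_len(pending, tree.branch_length(v))
        kids = [c for c in tree.children(v) if retain[c]]
        if tree.is_tip(v):
            sub.add_node(parent, total, label=tree.tip_label(v))
            return
        if len(kids) == 1:
            build(kids[0], parent, total)  # suppress unary node, merging lengths
            return
        node = sub.add_node(parent, total)
        for c in kids:
            build(c, node, 0.0)

    if tree.is_tip(top):
        sub.add_node(None, label=tree.tip_label(top))
    else:
        node = sub.add_node(None)
        for c in tree.children(top):
            if retain[c]:
                build(c, node, 0.0)
    return sub


def assign_clades(tree: Phylogeny) -> dict[str, int]:
    """Map each tip label to the index of the root child clade containing it.

    This is the coarsest phylogenetic blocking: one block per branch off
    the root.  A single-tip tree maps its tip to clade 0.
    """
    out: dict[str, int] = {}
    if tree.is_tip(tree.root):
        out[tree.tip_label(tree.root)] = 0
        return out
    for i, child in enumerate(tree.children(tree.root)):
        for v in tree.descendant_tips(child):
            out[tree.tip_label(v)] = i
    return out
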