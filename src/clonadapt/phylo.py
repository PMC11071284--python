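"""Tree ingestion, height normalization, and regime painting.

A rooted phylogeny of clonal sublines, with branch lengths given in
expressed-mutation counts, carries all the temporal structure the
Ornstein-Uhlenbeck machinery needs: node depths (root-to-node path
lengths), most-recent-common-ancestor depths between tips, and, for the
two-optima model, a "painting" of every branch into a selective regime
(0 = background, 1 = chosen).  Trees are normalized to unit height so
that the selection strength alpha and diffusion variance sigma^2 are on
a comparable scale across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

BACKGROUND = 0
CHOSEN = 1


class TreeError(ValueError):
    """Raised for malformed or degenerate phylogeny input."""


@dataclass(frozen=True, eq=False)
class Phylogeny:
    """Rooted tree stored in parent-pointer form.

    Nodes are integers ``0..n_nodes-1`` in preorder; node 0 is the root.
    ``parent[0] == -1`` and ``branch_length[0] == 0.0`` (a root edge in
    the Newick source is ignored).  Tips carry unique subline names.
    Instances hash by identity, so structural quantities (MRCA depths)
    can be memoized per tree.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 for root
    branch_length: np.ndarray   # (n_nodes,) float, length of edge above node
    depth: np.ndarray           # (n_nodes,) float, sum of branch lengths from root
    tip_ids: np.ndarray         # (n_tips,) int node ids of tips
    tip_names: tuple[str, ...]  # aligned with tip_ids
    children: tuple[tuple[int, ...], ...] = field(repr=False, default=())

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def tip_index(self, name: str) -> int:
        """Position of a tip name in ``tip_names`` (column order of matrices)."""
        try:
            return self.tip_names.index(name)
        except ValueError:
            raise TreeError(f"unknown tip name: {name!r}") from None

    def tip_depths(self) -> np.ndarray:
        return self.depth[self.tip_ids]

    def path_to_root(self, node: int) -> list[int]:
        """Node ids from ``node`` up to (and including) the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca_depths(self) -> np.ndarray:
        """Symmetric (n_tips, n_tips) matrix of MRCA depths (memoized).

        Diagonal entries are the tip depths themselves: the shared path
        of a tip with itself is its full root-to-tip path.
        """
        cached = getattr(self, "_mrca_cache", None)
        if cached is not None:
            return cached
        n = self.n_tips
        ancestors = [set(self.path_to_root(int(t))) for t in self.tip_ids]
        out = np.empty((n, n))
        for i in range(n):
            out[i, i] = self.depth[self.tip_ids[i]]
            for j in range(i + 1, n):
                shared = ancestors[i] & ancestors[j]
                d = max(self.depth[k] for k in shared)
                out[i, j] = out[j, i] = d
        object.__setattr__(self, "_mrca_cache", out)
        return out


def parse_tree(newick_text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny` with depths computed.

    Every non-root edge must carry a branch length; a length on the root
    edge is ignored.  Duplicate tip names are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    if n < 2:
        raise TreeError("tree must have at least two nodes")

    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    tip_ids: list[int] = []
    tip_names: list[str] = []
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                label = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise TreeError(f"missing branch length on edge above {label}")
            if nd.edge.length < 0:
                raise TreeError(f"negative branch length above node {i}")
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabeled tip")
            tip_ids.append(i)
            tip_names.append(str(nd.taxon.label).replace(" ", "_"))

    if len(set(tip_names)) != len(tip_names):
        dupes = sorted({t for t in tip_names if tip_names.count(t) > 1})
        raise TreeError(f"duplicate tip names: {dupes}")

    depth = np.zeros(n)
    for i in range(1, n):  # preorder: parent before child
        depth[i] = depth[parent[i]] + blen[i]

    kids: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        kids[parent[i]].append(i)

    zero_tips = [tip_names[k] for k, t in enumerate(tip_ids) if blen[t] == 0]
    if zero_tips:
        logger.warning("zero-length terminal branches: %s", zero_tips)

    return Phylogeny(
        parent=parent,
        branch_length=blen,
        depth=depth,
        tip_ids=np.array(tip_ids, dtype=int),
        tip_names=tuple(tip_names),
        children=tuple(tuple(k) for k in kids),
    )


def normalize_height(tree: Phylogeny) -> Phylogeny:
    """Rescale branch lengths so the deepest tip sits at depth 1."""
    h = float(tree.tip_depths().max())
    if h <= 0:
        raise TreeError("degenerate phylogeny: all tip depths are zero")
    return Phylogeny(
        parent=tree.parent,
        branch_length=tree.branch_length / h,
        depth=tree.depth / h,
        tip_ids=tree.tip_ids,
        tip_names=tree.tip_names,
        children=tree.children,
    )


@dataclass(frozen=True, eq=False)
class RegimePainting:
    """Assignment of every branch (edge above each non-root node) to a regime.

    ``branch_regime[node]`` is 0 (background) or 1 (chosen); the root entry
    is fixed at 0: the ancestral state lives in the background regime.
    """

    branch_regime: np.ndarray   # (n_nodes,) int
    chosen_tips: frozenset[str]
    regime_labels: tuple[str, str] = ("background", "chosen")

    @property
    def n_regimes(self) -> int:
        return 2

    def tip_regimes(self, tree: Phylogeny) -> np.ndarray:
        return self.branch_regime[tree.tip_ids]


def paint_regime(tree: Phylogeny, chosen_tips: set[str] | frozenset[str]) -> RegimePainting:
    """Paint regime 1 on every branch whose descendant tips are all chosen.

    This is the "shared ancestry" rule: each maximal clade containing
    only chosen tips is painted entirely, including its stem branch;
    everything else — in particular the root — stays background.  The
    chosen set need not be monophyletic; each maximal chosen-only clade
    is painted independently.
    """
    chosen = frozenset(chosen_tips)
    if not chosen:
        raise TreeError("chosen tip set is empty")
    unknown = chosen - set(tree.tip_names)
    if unknown:
        raise TreeError(f"chosen tips not in tree: {sorted(unknown)}")
    if chosen == set(tree.tip_names):
        raise TreeError("chosen set covers all tips; no background remains")

    n = tree.n_nodes
    all_chosen = np.zeros(n, dtype=bool)
    tip_set = set(int(t) for t in tree.tip_ids)
    name_of = {int(t): nm for t, nm in zip(tree.tip_ids, tree.tip_names)}
    # postorder: children before parents
    for i in range(n - 1, -1, -1):
        if i in tip_set:
            all_chosen[i] = name_of[i] in chosen
        else:
            kids = tree.children[i]
            all_chosen[i] = bool(kids) and all(all_chosen[k] for k in kids)

    regime = np.where(all_chosen, CHOSEN, BACKGROUND)
    regime[0] = BACKGROUND
    return RegimePainting(branch_regime=regime, chosen_tips=chosen)


@dataclass(frozen=True)
class RegimeSegments:
    """Root-to-tip path of one tip cut into contiguous regime segments.

    ``segments`` is an ordered tuple of ``(start_depth, end_depth, regime)``
    covering ``[0, depth(tip)]`` with no gaps or overlaps.  Zero-length
    branches contribute no segment.
    """

    tip_name: str
    segments: tuple[tuple[float, float, int], ...]

    @property
    def tip_depth(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0


def regime_segments(tree: Phylogeny, painting: RegimePainting, tip: str) -> RegimeSegments:
    """Decompose the root-to-tip path of ``tip`` by branch regime.

    Consecutive branches in the same regime are merged into one segment.
    """
    node = int(tree.tip_ids[tree.tip_index(tip)])
    path = tree.path_to_root(node)[::-1]  # root ... tip
    segs: list[tuple[float, float, int]] = []
    for nd in path[1:]:  # skip root (no edge above it)
        s, e = float(tree.depth[tree.parent[nd]]), float(tree.depth[nd])
        if e == s:
            continue
        r = int(painting.branch_regime[nd])
        if segs and segs[-1][2] == r:
            segs[-1] = (segs[-1][0], e, r)
        else:
            segs.append((s, e, r))
    return RegimeSegments(tip_name=tip, segments=tuple(segs))
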