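"""Phylogenetic conservation of intervention responses.

Builds a neighbor-joining tree from aligned 16S fragments (uncorrected
p-distance, pairwise deletion), finds maximal clades in which at least a
cutoff fraction of tips share a binary trait (consenTRAIT), and reports
their mean ancestor-to-tip depth tau_D, with permutation significance.
A Mantel test compares cophenetic matrices of alternative trees.

tau_D is measured on the tree's own branch-length scale; for trees built
from 16S p-distances this is substitutions per site, so tau_D ~ 0.02 means
the trait is conserved in clades of roughly genus-level sequence
divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .data_model import TraitVector, validate_trait_vector

logger = logging.getLogger(__name__)

__all__ = [
    "ConsenTraitClade",
    "ConsenTraitResult",
    "MantelResult",
    "read_alignment",
    "p_distance",
    "neighbor_joining",
    "cophenetic",
    "midpoint_root",
    "consentrait",
    "consentrait_test",
    "mantel",
]


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> sequence mapping."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def p_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """Uncorrected pairwise distance: mismatches / compared positions.

    Positions where either sequence carries ``N`` or a gap are excluded
    for that pair (pairwise deletion).
    """
    ids = list(alignment)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")
    arr = np.array([list(alignment[i]) for i in ids], dtype="U1")
    valid = (arr != "N") & (arr != "-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            both = valid[i] & valid[k]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable positions between {ids[i]!r} and {ids[k]!r}"
                )
            mismatch = int((arr[i, both] != arr[k, both]).sum())
            d[i, k] = d[k, i] = mismatch / n_comp
    return DistanceMatrix(d, ids=ids)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative limb to 0, transferring the deficit to its sibling."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Agglomerates via the Q-criterion ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``
    with the standard limb-length formulas; negative limb estimates are
    clamped to zero with the deficit moved to the sibling edge.  The result
    is rooted at the final three-way join (the root is trifurcating, as is
    conventional for NJ); ties in Q are broken by row-major order.  NJ
    reconstructs any additive (tree-realizable) distance matrix exactly.
    """
    ids = list(dist.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dist.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        parent = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = new_d[keep]
        d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d_next

    # resolve the final three clusters around a trifurcating root
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    root = TreeNode(children=[a, b, c])
    return root


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length distances."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"node {node.name!r} has no branch length")
    return tree.tip_tip_distances()


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path."""
    return tree.root_at_midpoint()


@dataclass(frozen=True)
class ConsenTraitClade:
    node_id: str
    n_tips: int
    mean_depth: float
    trait_fraction: float
    tip_names: tuple[str, ...]


@dataclass(frozen=True)
class ConsenTraitResult:
    """Trait-conservation depth summary for one binarized response."""

    tau_d: float
    clades: tuple[ConsenTraitClade, ...]
    n_singletons: int
    cutoff: float
    count_singletons: bool
    p_value: float | None = None
    n_permutations: int = 0

    def to_dict(self) -> dict:
        return {
            "tau_d": self.tau_d,
            "cutoff": self.cutoff,
            "count_singletons": self.count_singletons,
            "n_clades": len(self.clades),
            "n_singletons": self.n_singletons,
            "clades": [
                {
                    "node_id": c.node_id,
                    "n_tips": c.n_tips,
                    "mean_depth": c.mean_depth,
                    "trait_fraction": c.trait_fraction,
                }
                for c in self.clades
            ],
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


class _TreeIndex:
    """Precomputed per-node tip sets and depths for fast repeated scoring.

    ``nodes`` lists internal nodes in preorder; for each we store the indices
    of its descendant tips, the mean node-to-tip path length, and the indices
    of its internal children, so one trait evaluation is a root-down walk
    over numpy index arrays with no tree traversal.
    """

    def __init__(self, tree: TreeNode):
        self.tip_names: list[str] = [t.name for t in tree.tips()]
        tip_pos = {name: k for k, name in enumerate(self.tip_names)}
        self.half_terminal = np.array(
            [(t.length or 0.0) / 2.0 for t in tree.tips()]
        )
        self.node_tips: list[np.ndarray] = []
        self.node_mean_depth: list[float] = []
        self.node_children: list[list[int]] = []
        self.node_labels: list[str] = []

        def build(node: TreeNode) -> tuple[int, dict[str, float]]:
            """Returns (index of this internal node, tip -> depth-below-node)."""
            depths: dict[str, float] = {}
            idx = len(self.node_tips)
            self.node_tips.append(np.empty(0, dtype=int))  # placeholder
            self.node_mean_depth.append(0.0)
            self.node_children.append([])
            self.node_labels.append(node.name or f"node_{idx}")
            for child in node.children:
                length = child.length or 0.0
                if child.is_tip():
                    depths[child.name] = length
                else:
                    child_idx, child_depths = build(child)
                    self.node_children[idx].append(child_idx)
                    for name, dep in child_depths.items():
                        depths[name] = dep + length
            self.node_tips[idx] = np.array(
                sorted(tip_pos[name] for name in depths), dtype=int
            )
            self.node_mean_depth[idx] = float(np.mean(list(depths.values())))
            return idx, depths

        build(tree)

    def score(
        self, states: np.ndarray, cutoff: float, count_singletons: bool
    ) -> tuple[float, list[int], int]:
        """(tau_d, accepted node indices, n_singletons) for a 0/1 tip vector."""
        accepted: list[int] = []
        stack = [0]
        while stack:
            idx = stack.pop()
            tips = self.node_tips[idx]
            if states[tips].mean() >= cutoff:
                accepted.append(idx)
                continue
            # tip children of this node can never form a clade on their own
            stack.extend(self.node_children[idx])
        covered = np.zeros(len(self.tip_names), dtype=bool)
        for idx in accepted:
            covered[self.node_tips[idx]] = True
        singles = (states == 1) & ~covered
        n_singletons = int(singles.sum())
        depths = [self.node_mean_depth[idx] for idx in accepted]
        if count_singletons:
            depths += list(self.half_terminal[singles])
        tau_d = float(np.mean(depths)) if depths else 0.0
        return tau_d, accepted, n_singletons


def _consentrait_core(
    index: _TreeIndex, states: np.ndarray, cutoff: float, count_singletons: bool
) -> tuple[float, list[ConsenTraitClade], int]:
    tau_d, accepted, n_singletons = index.score(states, cutoff, count_singletons)
    clades = [
        ConsenTraitClade(
            node_id=index.node_labels[idx],
            n_tips=len(index.node_tips[idx]),
            mean_depth=index.node_mean_depth[idx],
            trait_fraction=float(states[index.node_tips[idx]].mean()),
            tip_names=tuple(index.tip_names[k] for k in index.node_tips[idx]),
        )
        for idx in sorted(accepted)
    ]
    return tau_d, clades, n_singletons


def consentrait(
    tree: TreeNode,
    trait: TraitVector,
    cutoff: float = 0.9,
    count_singletons: bool = True,
) -> ConsenTraitResult:
    """Mean depth tau_D of maximal clades sharing a binary trait.

    Traversing from the root, a node is a consensus clade when at least
    ``cutoff`` of its descendant tips carry state 1 and no ancestor already
    qualifies; its depth is the mean path length from the node to its tips.
    Trait-positive tips outside every clade are singletons, contributing
    half their terminal branch length when ``count_singletons``.
    """
    validate_trait_vector(trait, tree)
    index = _TreeIndex(tree)
    missing = set(index.tip_names) - set(trait)
    if missing:
        raise ValueError(f"trait states missing for tips: {sorted(missing)[:5]}")
    states = np.array([int(trait[t]) for t in index.tip_names])
    if states.sum() == 0:
        raise ValueError("trait absent: no tip has state 1")
    tau_d, clades, n_singletons = _consentrait_core(
        index, states, cutoff, count_singletons
    )
    return ConsenTraitResult(
        tau_d=tau_d,
        clades=tuple(clades),
        n_singletons=n_singletons,
        cutoff=cutoff,
        count_singletons=count_singletons,
    )


def consentrait_test(
    tree: TreeNode,
    trait: TraitVector,
    cutoff: float = 0.9,
    count_singletons: bool = True,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> ConsenTraitResult:
    """consenTRAIT with a label-shuffling permutation test.

    The null redistributes the observed number of state-1 labels uniformly
    across tips; ``p = (1 + #{tau_null >= tau_obs}) / (1 + n_permutations)``
    (one-sided: deeper-than-random conservation).
    """
    observed = consentrait(tree, trait, cutoff, count_singletons)
    index = _TreeIndex(tree)
    values = np.array([int(trait[t]) for t in index.tip_names])
    if values.all():
        logger.warning("all tips share state 1; shuffling cannot vary tau_d")
        return ConsenTraitResult(
            tau_d=observed.tau_d,
            clades=observed.clades,
            n_singletons=observed.n_singletons,
            cutoff=cutoff,
            count_singletons=count_singletons,
            p_value=1.0,
            n_permutations=n_permutations,
        )
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        tau_null, _, _ = index.score(
            rng.permutation(values), cutoff, count_singletons
        )
        if tau_null >= observed.tau_d - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return ConsenTraitResult(
        tau_d=observed.tau_d,
        clades=observed.clades,
        n_singletons=observed.n_singletons,
        cutoff=cutoff,
        count_singletons=count_singletons,
        p_value=p,
        n_permutations=n_permutations,
    )


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    n: int


def _condensed(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same ids.

    The statistic is the rank (Spearman) or product-moment (Pearson)
    correlation of off-diagonal entries; the null simultaneously permutes
    rows and columns of ``d2``; the p-value is one-sided for ``r >= r_obs``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    ids1, ids2 = set(d1.ids), set(d2.ids)
    if ids1 != ids2:
        diff = sorted(ids1 ^ ids2)
        raise ValueError(f"distance matrices disagree on ids: {diff[:10]}")
    d2 = d2.filter(d1.ids)
    x = _condensed(d1.data)
    m2 = d2.data
    n = len(d1.ids)

    def corr(y: np.ndarray) -> float:
        if method == "spearman":
            return float(stats.spearmanr(x, y).statistic)
        return float(stats.pearsonr(x, y).statistic)

    r_obs = corr(_condensed(m2))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(_condensed(m2[np.ix_(perm, perm)])) >= r_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return MantelResult(
        r=r_obs, p_value=p, n_permutations=n_permutations, method=method, n=n
    )
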