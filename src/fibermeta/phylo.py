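"""Sequence distances, neighbor joining, and phylogenetic trait conservation.

The conservation analysis asks at what phylogenetic depth a binary trait
(here: positive or negative response to a fiber intervention) is clustered
on a 16S tree. consenTRAIT finds the maximal clades in which at least a
cutoff fraction of tips share the trait and reports tau_D, the mean depth
of those clades (positive tips outside any clade count as singletons at
half their terminal branch). Significance comes from reshuffling trait
labels across tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import mantel as _skbio_mantel

from .io import ValidationError

__all__ = [
    "pairwise_distance",
    "neighbor_joining",
    "root_with_outgroup",
    "consentrait_depth",
    "mantel_test",
    "run_conservation",
    "CladeRecord",
    "ConsenTraitResult",
    "ConservationReport",
]


@dataclass(frozen=True)
class CladeRecord:
    node_id: str
    depth: float
    n_tips: int
    fraction_positive: float


@dataclass(frozen=True)
class ConsenTraitResult:
    """Trait-conservation depth tau_D and the clades that carry it."""

    tau_d: float
    clades: tuple[CladeRecord, ...]
    singleton_depths: tuple[float, ...]
    permutation_p: float | None
    n_perm: int
    cutoff: float

    @property
    def n_singletons(self) -> int:
        return len(self.singleton_depths)


@dataclass(frozen=True)
class ConservationReport:
    """Paired consenTRAIT runs: positive responders and negative responders."""

    positive: ConsenTraitResult
    negative: ConsenTraitResult
    n_positive_otus: int
    n_negative_otus: int


# ---------------------------------------------------------------------------
# distances

_UNAMBIG = set("ACGTU")


def pairwise_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """p-distances between aligned sequences.

    For each pair, sites where either sequence has a gap or an ambiguous
    base are excluded; the distance is the fraction of the remaining sites
    that differ. A pair with no comparable site is an error.
    """
    labels = list(alignment)
    if len(labels) < 3:
        raise ValidationError("need at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValidationError("sequences must be aligned to equal length")
    arr = np.array([list(alignment[l].upper()) for l in labels])
    ok = np.isin(arr, list(_UNAMBIG))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            m = int(comp.sum())
            if m == 0:
                raise ValidationError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no "
                    "comparable site"
                )
            d[i, j] = d[j, i] = float((arr[i, comp] != arr[j, comp]).sum()) / m
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive distances.

    Agglomerates by the Q-criterion (ties broken by smallest label pair for
    determinism). A negative estimated pendant length is clamped to zero
    and the deficit moved to its sibling edge so the pair still spans their
    distance. Returns an unrooted tree (trifurcating root).
    """
    n = dist.shape[0]
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    D = dist.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dist.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # row-major: smallest pair
        ai, aj = sorted((best[0], best[1]))
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.column_stack([D, np.append(new_row, 0.0)])
        nodes.append(parent)
        k = D.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [k]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.append(nodes[idx])
    return root


def root_with_outgroup(tree: TreeNode, tip_label: str) -> TreeNode:
    """Root an unrooted tree on the outgroup's pendant edge, at its midpoint."""
    try:
        tree.find(tip_label)
    except Exception:
        raise ValidationError(f"outgroup {tip_label!r} is not a tip of the tree")
    rooted = tree.root_at(tip_label, above=True, reset=True)
    if rooted.length is None:
        rooted.length = 0.0
    return rooted


# ---------------------------------------------------------------------------
# consenTRAIT


class _TreeIndex:
    """Flattened tree structure for repeated consenTRAIT evaluations."""

    def __init__(self, tree: TreeNode):
        self.tips = list(tree.tips())
        self.tip_labels = [t.name for t in self.tips]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValidationError("tree tip labels are not unique")
        tip_pos = {id(t): k for k, t in enumerate(self.tips)}
        self.nodes = list(tree.postorder(include_self=True))
        node_pos = {id(nd): k for k, nd in enumerate(self.nodes)}
        nn = len(self.nodes)
        self.is_tip = np.zeros(nn, dtype=bool)
        self.tip_index = np.full(nn, -1)
        self.children: list[list[int]] = [[] for _ in range(nn)]
        self.n_tips = np.zeros(nn, dtype=int)
        sum_depth = np.zeros(nn)
        self.terminal_half = np.zeros(len(self.tips))
        for k, nd in enumerate(self.nodes):
            if nd.is_tip():
                self.is_tip[k] = True
                ti = tip_pos[id(nd)]
                self.tip_index[k] = ti
                self.n_tips[k] = 1
                self.terminal_half[ti] = (nd.length or 0.0) / 2.0
            else:
                for c in nd.children:
                    ck = node_pos[id(c)]
                    self.children[k].append(ck)
                    self.n_tips[k] += self.n_tips[ck]
                    sum_depth[k] += sum_depth[ck] + (c.length or 0.0) * self.n_tips[ck]
        self.mean_depth = sum_depth / self.n_tips
        self.root = nn - 1
        # descendant tip lists per node, for maximality bookkeeping
        self._tips_under: list[np.ndarray] = [None] * nn
        for k in range(nn):
            if self.is_tip[k]:
                self._tips_under[k] = np.array([self.tip_index[k]])
            else:
                self._tips_under[k] = np.concatenate(
                    [self._tips_under[c] for c in self.children[k]]
                )

    def evaluate(self, trait: np.ndarray, cutoff: float):
        """One consenTRAIT pass: (tau_d, clade node indices, singleton tip indices)."""
        nn = len(self.nodes)
        pos = np.zeros(nn, dtype=int)
        for k in range(nn):
            if self.is_tip[k]:
                pos[k] = trait[self.tip_index[k]]
            else:
                pos[k] = sum(pos[c] for c in self.children[k])
        clades: list[int] = []
        covered = np.zeros(len(self.tips), dtype=bool)
        stack = [self.root]
        while stack:
            k = stack.pop()
            if pos[k] >= 2 and pos[k] / self.n_tips[k] >= cutoff:
                clades.append(k)
                covered[self._tips_under[k]] = True
            elif not self.is_tip[k]:
                stack.extend(self.children[k])
        singles = np.flatnonzero((trait > 0) & ~covered)
        depths = [self.mean_depth[k] for k in clades] + [
            self.terminal_half[t] for t in singles
        ]
        tau = float(np.mean(depths)) if depths else 0.0
        return tau, clades, singles


def consentrait_depth(
    tree: TreeNode,
    trait: dict[str, int],
    cutoff: float = 0.9,
    n_perm: int = 1000,
    seed=0,
) -> ConsenTraitResult:
    """Mean phylogenetic depth tau_D at which a binary trait is conserved.

    Every internal node whose descendant tips are at least ``cutoff``
    trait-positive, with at least 2 positive tips, qualifies; only maximal
    such nodes (no qualifying ancestor) are kept. A clade's depth is the
    mean path length from its root to *all* its descendant tips; positive
    tips outside every qualifying clade contribute half their terminal
    branch as singletons. tau_D is the unweighted mean over clades and
    singletons. The permutation p-value reshuffles trait values across tips
    (positive count preserved): p = (1 + #{tau_perm >= tau_obs})/(1 + n_perm).
    """
    if cutoff <= 0.5 or cutoff > 1.0:
        raise ValueError("cutoff must be in (0.5, 1]; maximality is ill-defined below")
    idx = _TreeIndex(tree)
    missing = [l for l in idx.tip_labels if l not in trait]
    if missing:
        raise ValidationError(f"tips without trait values: {missing[:5]}")
    tvec = np.array([1 if trait[l] else 0 for l in idx.tip_labels])
    if tvec.sum() == 0:
        raise ValidationError("no trait-positive tips")
    tau, clade_idx, singles = idx.evaluate(tvec, cutoff)
    clades = tuple(
        CladeRecord(
            node_id=idx.nodes[k].name or f"node{k}",
            depth=float(idx.mean_depth[k]),
            n_tips=int(idx.n_tips[k]),
            fraction_positive=float(
                tvec[idx._tips_under[k]].sum() / idx.n_tips[k]
            ),
        )
        for k in clade_idx
    )
    singleton_depths = tuple(float(idx.terminal_half[t]) for t in singles)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(tvec)
            tp, _, _ = idx.evaluate(perm, cutoff)
            if tp >= tau:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
    return ConsenTraitResult(
        tau_d=tau, clades=clades, singleton_depths=singleton_depths,
        permutation_p=p, n_perm=n_perm, cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Mantel


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed=0,
) -> tuple[float, float]:
    """One-sided Mantel test of correlation between two distance matrices.

    Rank (Spearman) correlation of the lower-triangle entries by default;
    p-value from simultaneous row/column permutations of the second matrix,
    counting permuted correlations >= the observed one.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices must share their label set")
    r, p, _ = _skbio_mantel(
        d1, d2, method=method, permutations=n_perm, alternative="greater",
        seed=np.random.default_rng(seed),
    )
    return float(r), float(p)


# ---------------------------------------------------------------------------
# paired runs


def run_conservation(
    tree: TreeNode,
    traits,
    n_perm: int = 1000,
    seed=0,
    cutoff: float = 0.9,
    outgroup: str | None = None,
) -> ConservationReport:
    """consenTRAIT for positive and for negative responders on one tree.

    ``traits`` is a :class:`fibermeta.cross_study.TraitAssignment` (or any
    object with ``positive_otus``/``negative_otus`` sets). The tree is
    sheared to the trait OTUs plus the optional outgroup, then
    consenTRAIT runs twice: once with positive responders coded 1, once
    with negative responders coded 1 — yielding separate positive and
    negative conservation depths.
    """
    pos = set(traits.positive_otus)
    neg = set(traits.negative_otus)
    wanted = pos | neg
    tip_names = {t.name for t in tree.tips()}
    present = wanted & tip_names
    if len(present) < 3:
        raise ValidationError(
            f"only {len(present)} trait OTUs are tips of the tree; need >= 3"
        )
    keep = present | ({outgroup} if outgroup else set())
    sheared = tree.shear(keep)
    labels = [t.name for t in sheared.tips()]
    trait_pos = {l: 1 if l in pos else 0 for l in labels}
    trait_neg = {l: 1 if l in neg else 0 for l in labels}
    rng = np.random.default_rng(seed)
    res_pos = consentrait_depth(
        sheared, trait_pos, cutoff=cutoff, n_perm=n_perm,
        seed=rng.integers(2 ** 31),
    )
    res_neg = consentrait_depth(
        sheared, trait_neg, cutoff=cutoff, n_perm=n_perm,
        seed=rng.integers(2 ** 31),
    )
    return ConservationReport(
        positive=res_pos, negative=res_neg,
        n_positive_otus=len(pos & set(labels)),
        n_negative_otus=len(neg & set(labels)),
    )
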