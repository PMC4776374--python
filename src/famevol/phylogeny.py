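"""Kinase-domain distance matrices, neighbor-joining trees with bootstrap
support, and transfer of group labels from reference-labelled leaves.

The tree container is :class:`skbio.TreeNode`; the agglomeration itself is
implemented here so the Q-criterion tie-break (lexicographically smallest
label pair) and negative-branch handling are fixed, and is cross-checked
against an independent NJ implementation in the test suite.
"""
from __future__ import annotations

import numpy as np
from skbio import TreeNode


class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over ordered labels."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(values), 0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (values < -1e-12).any():
            raise ValueError("negative distances")
        if not np.isfinite(values).all():
            raise ValueError("non-finite distances")
        self.labels = list(labels)
        self.values = np.maximum((values + values.T) / 2, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])


def _seq_array(aligned: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(aligned)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("aligned rows have unequal lengths")
    arr = np.frombuffer("".join(aligned.values()).encode(), dtype="S1")
    return labels, arr.reshape(len(labels), lengths.pop())


def _pairwise_p(arr: np.ndarray) -> np.ndarray:
    """p-distance matrix ignoring columns gapped in either row."""
    gap = (arr == b"-") | (arr == b".")
    n = arr.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & ok
        comp = ok.sum(axis=1)
        if (comp == 0).any():
            j = int(np.where(comp == 0)[0][0]) + i + 1
            raise ValueError(f"no comparable columns between rows {i} and {j}")
        p[i, i + 1 :] = diff.sum(axis=1) / comp
    return p + p.T


def kinase_distance_matrix(
    aligned: dict[str, str], model: str = "p-distance"
) -> DistanceMatrix:
    """Pairwise distances on an aligned domain set.

    ``model`` is "p-distance" (mismatches / compared columns) or "poisson"
    (-ln(1-p)); columns gapped in either row are ignored per pair.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    labels, arr = _seq_array(aligned)
    p = _pairwise_p(arr)
    if model == "p-distance":
        d = p
    elif model == "poisson":
        if (1 - p <= 1e-9).any():
            raise ValueError("saturated p-distance; poisson correction undefined")
        d = -np.log(1 - p)
    else:
        raise ValueError(f"unknown model {model!r}")
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    At each step the pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined (ties: lexicographically smallest pair of clade representative
    labels); branch lengths use the standard half-difference formula and
    negative raw lengths are clamped to 0 on output.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [TreeNode(name=lbl) for lbl in dm.labels]
    reps = list(dm.labels)  # lexicographic representative of each clade
    d = dm.values.copy()
    if n == 2:
        root = TreeNode()
        for node, length in zip(nodes, (dm.values[0, 1], 0.0)):
            node.length = max(float(length), 0.0)
            root.append(node)
        return root
    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        i, j = min(
            (t for t in map(tuple, ties) if t[0] < t[1]),
            key=lambda t: tuple(sorted((reps[t[0]], reps[t[1]]))),
        )
        li = d[i, j] / 2 + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        dnew = (d[i] + d[j] - d[i, j]) / 2
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
    root = TreeNode()
    # terminal 3-star: closed-form lengths
    (a, b, c) = (d[0, 1], d[0, 2], d[1, 2])
    lengths = ((a + b - c) / 2, (a + c - b) / 2, (b + c - a) / 2)
    for node, length in zip(nodes, lengths):
        node.length = float(length)
        root.append(node)
    _clamp_negative(root)
    return root


def _clamp_negative(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal bipartitions as the smaller-or-lexicographic side tip sets."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    aligned: dict[str, str],
    n_reps: int,
    seed: int,
    model: str = "p-distance",
) -> TreeNode:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each internal bipartition of
    the full-data tree, stored as ``node.support`` (and as the internal
    node name on newick output).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, arr = _seq_array(aligned)
    tree = neighbor_joining(kinase_distance_matrix(aligned, model))
    tips = frozenset(labels)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    n_cols = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        sample = dict(zip(labels, ("".join(row) for row in arr[:, cols].astype("U1"))))
        try:
            rep_tree = neighbor_joining(kinase_distance_matrix(sample, model))
        except ValueError:  # a pair with no comparable columns in this resample
            continue
        for bp in tree_bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(tips) - 1):
            continue
        key = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts.get(key, 0) / n_reps
        node.name = str(int(round(node.support)))
    return tree


def assign_groups(
    tree: TreeNode, reference_labels: dict[str, str]
) -> tuple[dict[str, str], dict[str, bool]]:
    """Label query leaves with the group of the nearest reference leaf.

    Distance is patristic (path length); ties break to the lexicographically
    smallest reference label.  Also reports, per group, whether its member
    leaves (references plus assignments) form a clade.
    """
    tip_names = [t.name for t in tree.tips()]
    refs = [r for r in reference_labels if r in tip_names]
    if not refs:
        raise ValueError("no reference leaves present in tree")
    dm = tree.tip_tip_distances()
    assignment: dict[str, str] = {}
    for leaf in tip_names:
        if leaf in reference_labels:
            continue
        best = min(refs, key=lambda r: (dm[leaf, r], r))
        assignment[leaf] = reference_labels[best]
    groups = sorted(set(reference_labels.values()))
    membership = {
        g: {r for r in refs if reference_labels[r] == g}
        | {q for q, gg in assignment.items() if gg == g}
        for g in groups
    }
    monophyly = {}
    all_tips = frozenset(tip_names)
    bps = tree_bipartitions(tree) | {
        frozenset({t}) for t in tip_names
    }
    for g, members in membership.items():
        side = frozenset(members)
        key = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        monophyly[g] = len(side) in (1, len(all_tips) - 1) or key in bps
    return assignment, monophyly
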