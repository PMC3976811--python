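"""Distance matrices, Neighbor-Joining, bootstrap supports and a simple
progressive aligner.

NJ follows the Saitou-Nei Q-criterion with two determinism policies: ties
break on the smallest (i, j) index pair, and a negative branch length is
clamped to zero with the deficit moved onto its sister branch, so total
path lengths are preserved.  Bootstrap supports (percent of replicates) are
attached to the bipartitions of the full-data tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import global_align, align_profiles, aligned_p_distance
from .tree import TreeNode

MSA = Sequence[tuple[str, str]]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch with taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def p_distance(msa: MSA, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an alignment, gaps removed pairwise.

    ``model="p"`` gives the raw proportion of differing sites;
    ``model="poisson"`` applies the multiple-hit correction -ln(1 - p).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    taxa = [name for name, _ in msa]
    seqs = [seq.upper() for _, seq in msa]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("aligned sequences must have equal length")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = diffs = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x != "-" and y != "-":
                    compared += 1
                    if x != y:
                        diffs += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]!r} and {taxa[j]!r}"
                )
            p = diffs / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance (p=1) between {taxa[i]!r} and {taxa[j]!r}"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei Neighbor-Joining; returns an unrooted tree with a
    trifurcating root."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) pair in current index order
        flat = np.argmin(q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the rest
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes on a trifurcating root
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.children.append(nodes[idx])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative pendant length to 0, moving the deficit to the sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_from_msa(msa: MSA, model: str = "poisson") -> TreeNode:
    return nj_tree(p_distance(msa, model=model))


def bootstrap_support(
    msa: MSA,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the full-data tree is the percentage of replicate
    trees containing the same bipartition, written as the internal node
    label (rounded to one decimal, trailing ``.0`` dropped).
    """
    rng = np.random.default_rng(seed)
    full = tree_from_msa(msa, model=model)
    names = [name for name, _ in msa]
    seq_mat = np.array([list(seq) for _, seq in msa])
    ncols = seq_mat.shape[1]
    counts: dict[frozenset, int] = {split: 0 for split in full.bipartitions()}
    effective_reps = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_msa = [
            (name, "".join(seq_mat[t, cols])) for t, name in enumerate(names)
        ]
        try:
            rep_tree = tree_from_msa(rep_msa, model=model)
        except ValueError:
            continue                      # saturated/incomparable replicate
        effective_reps += 1
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    all_leaves = frozenset(names)
    anchor = min(all_leaves)
    for node in full.walk():
        if node is full or node.is_leaf:
            continue
        below = frozenset(node.leaf_names())
        side = all_leaves - below if anchor in below else below
        if side in counts and effective_reps:
            pct = 100.0 * counts[side] / effective_reps
            label = f"{pct:.1f}".rstrip("0").rstrip(".")
            node.name = label
    return full


# ---------------------------------------------------------------------------
# Progressive alignment

def progressive_align(seqs: MSA) -> list[tuple[str, str]]:
    """Basic progressive multiple alignment of protein sequences.

    Guide tree: UPGMA on pairwise global-alignment p-distances.  Profiles
    are merged bottom-up with affine-gap NW on mean BLOSUM62 column scores.
    Output rows keep the input order.  Deterministic throughout.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("progressive_align requires at least 2 sequences")
    names = [name for name, _ in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(seqs[i][1], seqs[j][1], mode="aa")
            d[i, j] = d[j, i] = aligned_p_distance(res.aligned_a, res.aligned_b)

    # UPGMA merge order
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    profiles: dict[int, list[str]] = {i: [seqs[i][1]] for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (a, b), _ = min(dd.items(), key=lambda kv: (kv[1], kv[0]))
        rows_a, rows_b = profiles[a], profiles[b]
        merged_a, merged_b = align_profiles(rows_a, rows_b)
        profiles[next_id] = merged_a + merged_b
        members[next_id] = members[a] + members[b]
        size_a, size_b = len(members[a]), len(members[b])
        for c in clusters:
            if c in (a, b):
                continue
            da = dd[tuple(sorted((a, c)))]
            db = dd[tuple(sorted((b, c)))]
            dd[(c, next_id) if c < next_id else (next_id, c)] = (
                (size_a * da + size_b * db) / (size_a + size_b)
            )
        for key in list(dd):
            if a in key or b in key:
                del dd[key]
        del clusters[a], clusters[b], profiles[a], profiles[b]
        clusters[next_id] = [next_id]
        next_id += 1

    final_id = next(iter(clusters))
    rows = profiles[final_id]
    order = members[final_id]
    by_input = dict(zip(order, rows))
    return [(names[i], by_input[i]) for i in range(n)]
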