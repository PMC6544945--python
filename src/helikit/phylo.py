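"""Distance matrices, neighbor-joining trees and bootstrap support.

Copy-level phylogenies of an element family: pairwise distances under the
Kimura two-parameter model (or raw p-distance) with pairwise gap deletion,
the classical neighbor-joining agglomeration (exact on additive matrices),
and nonparametric bootstrap over alignment columns.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .quantify import SaturatedDistance, k2p_distance

GAP_COLUMN_MAX_FRACTION = 0.5  # columns gappier than this are dropped


def filter_gap_columns(rows: Sequence[str], max_gap_fraction: float = GAP_COLUMN_MAX_FRACTION) -> list[str]:
    """Drop alignment columns with more than max_gap_fraction gaps."""
    ncol = len(rows[0])
    keep = [
        c
        for c in range(ncol)
        if sum(r[c] == "-" for r in rows) / len(rows) <= max_gap_fraction
    ]
    return ["".join(r[c] for c in keep) for r in rows]


def p_distance(a: str, b: str) -> float:
    sites = diffs = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        diffs += x != y
    if sites == 0:
        raise ValueError("no comparable sites")
    return diffs / sites


def distance_matrix(
    rows: Sequence[str], labels: Sequence[str] | None = None, model: str = "K2P"
) -> np.ndarray:
    """Symmetric pairwise distance matrix with pairwise gap deletion.

    model: "K2P" or "p-distance". A saturated K2P pair raises
    SaturatedDistance naming the pair.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    labels = list(labels) if labels else [f"seq{i + 1}" for i in range(len(rows))]
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if model == "K2P":
                    d = k2p_distance(rows[i], rows[j])
                elif model in ("p", "p-distance"):
                    d = p_distance(rows[i], rows[j])
                else:
                    raise ValueError(f"unknown model {model!r}")
            except SaturatedDistance as exc:
                raise SaturatedDistance(
                    f"saturated pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
    return mat


def nj_tree(matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree as a Newick string (unrooted, trifurcating root).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. Ties in the NJ criterion are broken by label order,
    making the output deterministic.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")
    d = mat.copy()
    nodes = [f"'{lab}'" if _needs_quote(lab) else str(lab) for lab in labels]
    names = [str(lab) for lab in labels]  # for deterministic tie-breaks
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                tie = tuple(sorted((names[active[i]], names[active[j]])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        vi = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = sub[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in range(m):
            ak = active[k]
            if ak in (ai, aj):
                continue
            new_row[ak] = 0.5 * (d[ai, ak] + d[aj, ak] - d[ai, aj])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(f"({nodes[ai]}:{vi:.6f},{nodes[aj]}:{vj:.6f})")
        names.append(min(names[ai], names[aj]))
        active = [a for a in active if a not in (ai, aj)] + [d.shape[0] - 1]
    # final trifurcation
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    va, vb, vc = (max(0.0, v) for v in (va, vb, vc))
    return f"({nodes[a]}:{va:.6f},{nodes[b]}:{vb:.6f},{nodes[c]}:{vc:.6f});"


def _needs_quote(label) -> bool:
    s = str(label)
    return any(ch in s for ch in " (),:;'")


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi = max(0.0, vi + vj)
        vj = 0.0
    return vi, vj


def tree_bipartitions(newick: str, labels: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions of a Newick tree, canonicalised as the side
    not containing the alphabetically first label."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_labels = set(str(l) for l in labels)
    anchor = min(all_labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(below) < 2 or len(below) > len(all_labels) - 2:
            continue
        side = below if anchor not in below else frozenset(all_labels - below)
        out.add(side)
    return out


def bootstrap(
    rows: Sequence[str],
    labels: Sequence[str],
    n_replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    model: str = "K2P",
) -> dict[frozenset, float]:
    """Column-resampling bootstrap support for the NJ tree's bipartitions.

    Returns {bipartition: support fraction} for every bipartition of the
    tree built on the original alignment. Reproducible given the seed.
    """
    ncol = len(rows[0])
    if ncol < 10:
        raise ValueError("alignment too short to bootstrap (need >= 10 columns)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_tree = nj_tree(distance_matrix(rows, labels, model), labels)
    targets = tree_bipartitions(base_tree, labels)
    counts = {bp: 0 for bp in targets}
    arr = np.array([list(r) for r in rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, ncol)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = nj_tree(distance_matrix(rep_rows, labels, model), labels)
        except (SaturatedDistance, ValueError):
            continue
        rep_bps = tree_bipartitions(rep_tree, labels)
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    return {bp: counts[bp] / n_replicates for bp in targets}
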