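"""Alpha and beta diversity: rarefaction, Bray-Curtis, trees, UniFrac.

Richness is the analytic hypergeometric rarefaction expectation;
Shannon (nats) and Gini-Simpson are computed on one seeded rarefied
draw when a depth is imposed.  Sequence trees are built by pairwise
JC69 distances + canonical neighbor joining — a deterministic,
dependency-free stand-in for an aligner + approximate-ML tool that is
adequate for distance-based beta diversity at this scale.  UniFrac
follows the branch-set definitions: unweighted = unique/observed branch
length; weighted = sum_b l_b |A_b - B_b|, optionally normalized by
sum_b l_b (A_b + B_b) so both variants live on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from ._seeds import rng_for
from .align import pairwise_identity

__all__ = [
    "rarefy_counts",
    "expected_richness",
    "shannon",
    "simpson",
    "rarefaction_curve",
    "bray_curtis",
    "jc69",
    "nt_distance_matrix",
    "nj_tree",
    "unifrac",
    "unifrac_matrix",
]

JC69_CAP_P = 0.749  # p-distances at/above this are assigned max_distance


@dataclass
class RarefiedSample:
    counts: np.ndarray | None
    excluded: bool


def rarefy_counts(counts, depth: int = 10000, seed: int = 0) -> RarefiedSample:
    """Subsample counts without replacement to exactly ``depth`` reads.

    Samples whose total is below the depth are flagged excluded (a
    status, not an error), mirroring the exclusion of shallow samples
    before alpha-diversity comparison.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() < depth:
        return RarefiedSample(None, True)
    if counts.sum() == depth:
        return RarefiedSample(counts.copy(), False)
    rng = rng_for(seed, "rarefy")
    return RarefiedSample(rng.multivariate_hypergeometric(counts, depth), False)


def expected_richness(counts, depth: int) -> float:
    """Analytic rarefaction: E[S] = sum_i 1 - C(N-N_i, d) / C(N, d)."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if depth > N:
        raise ValueError(f"depth {depth} exceeds sample total {N}")

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    with np.errstate(invalid="ignore"):
        log_p_absent = logC(N - counts, depth) - logC(N, depth)
    # features with N - N_i < depth can never be absent from the draw
    log_p_absent = np.where(N - counts < depth, -np.inf, log_p_absent)
    return float(np.sum(1.0 - np.exp(log_p_absent)))


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats (0 ln 0 := 0)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one positive count required")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2, in [0, 1]."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one positive count required")
    p = counts / total
    return float(1.0 - (p**2).sum())


def rarefaction_curve(counts, depths) -> list[float]:
    """Expected richness at each depth of the grid (grid within [1, N])."""
    return [expected_richness(counts, int(d)) for d in depths]


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples of a features x samples table."""
    samples = list(table.columns)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    X = table.values.astype(float)
    if (X.sum(axis=0) == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = np.abs(X[:, i] - X[:, j]).sum()
            den = (X[:, i] + X[:, j]).sum()
            D[i, j] = D[j, i] = num / den
    return DistanceMatrix(D, ids=samples)


def jc69(p: float, max_distance: float = 5.0) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3), capped for p >= 0.749."""
    if p < 0:
        raise ValueError("p-distance must be >= 0")
    if p >= JC69_CAP_P:
        return max_distance
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def nt_distance_matrix(seqs: dict, model: str = "JC69",
                       max_distance: float = 5.0) -> DistanceMatrix:
    """Pairwise distances between sequences (p-distance or JC69-corrected)."""
    if model not in ("JC69", "p"):
        raise ValueError("model must be 'JC69' or 'p'")
    ids = list(seqs)
    if len(ids) < 3:
        raise ValueError("need at least three sequences")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - pairwise_identity(seqs[ids[i]], seqs[ids[j]])
            D[i, j] = D[j, i] = jc69(p, max_distance) if model == "JC69" else p
    return DistanceMatrix(D, ids=ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining.

    Deterministic: joins scan index pairs in order with a strict minimum,
    so ties resolve to the first pair.  Negative branch estimates are
    clamped to zero with the deficit transferred to the sibling branch of
    the same join.  Returns an unrooted tree (trifurcating root).
    """
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    if len(nodes) < 3:
        raise ValueError("need at least three labels")
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best, bi, bj = None, -1, -1
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-15:
                    best, bi, bj = q, i, j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (n - 2))
        lj = D[bi, bj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        a, b = nodes[bi], nodes[bj]
        a.length, b.length = float(li), float(lj)
        parent = TreeNode(children=[a, b])
        dnew = 0.5 * (D[bi, :] + D[bj, :] - D[bi, bj])
        keep = [k for k in range(n) if k not in (bi, bj)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = D2
    # resolve the final three branches in closed form
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    lens = [max(0.0, v) for v in (l0, l1, l2)]
    for node, ln in zip(nodes, lens):
        node.length = float(ln)
    return TreeNode(children=nodes)


def _branch_partial_sums(tree: TreeNode, counts_a: dict, counts_b: dict):
    present = {k for k, v in counts_a.items() if v > 0} | {
        k for k, v in counts_b.items() if v > 0
    }
    tips = {t.name for t in tree.tips()}
    missing = present - tips
    if missing:
        raise ValueError(f"feature(s) not in tree: {sorted(missing)[:5]}")
    sums: dict[int, tuple] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            sums[id(node)] = (float(counts_a.get(node.name, 0)),
                              float(counts_b.get(node.name, 0)))
        else:
            a = sum(sums[id(c)][0] for c in node.children)
            b = sum(sums[id(c)][1] for c in node.children)
            sums[id(node)] = (a, b)
    return sums


def unifrac(tree: TreeNode, counts_a: dict, counts_b: dict,
            weighted: bool = False, normalized: bool = True) -> float:
    """UniFrac distance between two samples over a shared tree.

    ``counts_a``/``counts_b`` map tip name -> count.  Unweighted: branch
    length unique to one sample / branch length observed in either.
    Weighted raw: sum_b l_b |A_b - B_b| with A_b the fraction of sample
    a's reads descending from branch b; normalized form divides by
    sum_b l_b (A_b + B_b).
    """
    sums = _branch_partial_sums(tree, counts_a, counts_b)
    total_a = sum(v for v in counts_a.values() if v > 0)
    total_b = sum(v for v in counts_b.values() if v > 0)
    if total_a <= 0 or total_b <= 0:
        raise ValueError("each sample needs at least one positive count")
    num = 0.0
    den = 0.0
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        a, b = sums[id(node)]
        if weighted:
            A, B = a / total_a, b / total_b
            num += length * abs(A - B)
            den += length * (A + B)
        else:
            if a > 0 or b > 0:
                den += length
                if (a > 0) != (b > 0):
                    num += length
    if not weighted:
        return num / den if den else 0.0
    if not normalized:
        return num
    return num / den if den else 0.0


def unifrac_matrix(tree: TreeNode, table, weighted: bool = False,
                   normalized: bool = True) -> DistanceMatrix:
    """Pairwise UniFrac over the samples of a features x samples table."""
    samples = list(table.columns)
    n = len(samples)
    D = np.zeros((n, n))
    counts = {s: table[s].to_dict() for s in samples}
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = unifrac(tree, counts[samples[i]],
                                        counts[samples[j]], weighted, normalized)
    return DistanceMatrix(D, ids=samples)
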