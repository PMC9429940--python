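"""Incremental tree-congruence comparison between two feature sets.

Two amplicon reconstruction methods give differently-labelled features,
so their trees can never share feature tips.  Congruence is therefore
measured on the induced topologies over a shared set of reference
sequences: at step i, a neighbor-joining tree is built over the
references plus the top-i features of each method, both trees are pruned
back to the reference tips, and the normalized Robinson-Foulds distance
between the induced topologies is recorded.  The resulting curve is
summarised by an ordinary least-squares fit rf = a * ln(n) + b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio.tree import TreeNode

from .diversity import nj_tree, nt_distance_matrix

__all__ = [
    "CongruenceCurve",
    "LogFit",
    "bipartitions",
    "robinson_foulds",
    "incremental_congruence",
    "fit_log_curve",
]


@dataclass
class CongruenceCurve:
    points: list  # [(n_added, rf_norm)], n_added strictly increasing from 1


@dataclass
class LogFit:
    a: float
    b: float
    rmse: float


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge splits the tips in two; a bipartition is canonical
    as the side not containing the lexicographically smallest tip.  Sides
    of size < 2 (or > n-2) are trivial and excluded.
    """
    tips = sorted(t.name for t in tree.tips())
    n = len(tips)
    anchor = tips[0]
    parts = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(tips) - side
        if 2 <= len(side) <= n - 2:
            parts.add(side)
    return parts


def _pruned_to(tree: TreeNode, names: set) -> TreeNode:
    sub = tree.shear(list(names))
    sub.prune()  # collapse single-child internals left by shearing
    return sub


def robinson_foulds(t1: TreeNode, t2: TreeNode,
                    mode: str = "strict") -> tuple[int, float]:
    """Robinson-Foulds distance between two unrooted trees.

    ``strict`` requires identical tip sets; ``prune-to-shared`` first
    restricts both trees to their shared tips (at least 4 required).
    rf is the size of the symmetric difference of non-trivial
    bipartitions; rf_norm divides by the total number of non-trivial
    bipartitions in both trees (0/0 -> 0), which lies in [0, 1] for
    binary or multifurcating trees alike.
    """
    names1 = {t.name for t in t1.tips()}
    names2 = {t.name for t in t2.tips()}
    if mode == "strict":
        if names1 != names2:
            raise ValueError("strict mode requires identical tip label sets")
    elif mode == "prune-to-shared":
        shared = names1 & names2
        if len(shared) < 4:
            raise ValueError(f"only {len(shared)} shared tips (need >= 4)")
        if shared != names1:
            t1 = _pruned_to(t1, shared)
        if shared != names2:
            t2 = _pruned_to(t2, shared)
    else:
        raise ValueError("mode must be 'strict' or 'prune-to-shared'")
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    rf = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return rf, (rf / denom if denom else 0.0)


def incremental_congruence(features_a, features_b, reference_seqs: dict,
                           max_iter: int | None = None) -> CongruenceCurve:
    """Add features one at a time (descending abundance) and track RF.

    ``features_a``/``features_b`` are [(feature id, sequence)] lists
    already sorted by descending abundance; ``reference_seqs`` maps
    reference id -> sequence (>= 4 required).  At step i both trees are
    rebuilt from scratch over references + top-i features, then compared
    on the induced reference topology.  The curve stops at
    min(|A|, |B|, max_iter) — the shorter feature list caps the number
    of comparable iterations.
    """
    if len(reference_seqs) < 4:
        raise ValueError("need at least 4 reference sequences")
    steps = min(len(features_a), len(features_b))
    if max_iter is not None:
        steps = min(steps, max_iter)
    ref_ids = list(reference_seqs)
    # pairwise distances are identical at every step, so compute each
    # method's full matrix once and slice; trees are rebuilt from scratch
    full = []
    for feats in (features_a, features_b):
        seqs = dict(reference_seqs)
        for fid, seq in feats[:steps]:
            seqs[f"feat_{fid}"] = seq
        full.append(nt_distance_matrix(seqs))
    points = []
    for i in range(1, steps + 1):
        induced = []
        for dm, feats in zip(full, (features_a, features_b)):
            ids = ref_ids + [f"feat_{fid}" for fid, _ in feats[:i]]
            tree = nj_tree(dm.filter(ids))
            induced.append(_pruned_to(tree, set(ref_ids)))
        _, rf_norm = robinson_foulds(induced[0], induced[1], mode="strict")
        points.append((i, rf_norm))
    return CongruenceCurve(points)


def fit_log_curve(curve: CongruenceCurve) -> LogFit:
    """OLS fit of rf_norm on ln(n_added): rf = a ln(n) + b."""
    pts = curve.points if isinstance(curve, CongruenceCurve) else list(curve)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    n = np.array([p[0] for p in pts], dtype=float)
    rf = np.array([p[1] for p in pts], dtype=float)
    if np.unique(n).size < 2:
        raise ValueError("need at least two distinct n values")
    x = np.log(n)
    a, b = np.polyfit(x, rf, 1)
    resid = rf - (a * x + b)
    return LogFit(float(a), float(b), float(np.sqrt((resid**2).mean())))
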