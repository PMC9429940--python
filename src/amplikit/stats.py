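"""Permutation inference and constrained ordination.

Mantel correlations between distance matrices, distance-based PERMANOVA
for the two-structure (ridge/runnel-style) contrast, and Hellinger +
canonical correspondence analysis with both-direction stepwise driver
selection.  All permutation p-values use the add-one convention
p = (1 + #{extreme}) / (n_perm + 1), so p is always in
[1/(n_perm+1), 1].  Mantel defaults to 9,999 two-sided permutations;
PERMANOVA to 999.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ._seeds import rng_for

__all__ = [
    "MantelResult",
    "PermanovaResult",
    "CCAModel",
    "mantel_test",
    "permanova",
    "hellinger",
    "cca_fit",
    "stepwise_select",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int


@dataclass
class CCAModel:
    eigenvalues: np.ndarray  # constrained eigenvalues, descending
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    selected: list = field(default_factory=list)  # [(variable, p)]


def _lower(D: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(D.shape[0], k=-1)
    return D[i, j]


def _as_matrix(D, other_ids=None):
    if isinstance(D, DistanceMatrix):
        return np.asarray(D.data, dtype=float), list(D.ids)
    D = np.asarray(D, dtype=float)
    return D, list(range(D.shape[0])) if other_ids is None else other_ids


def mantel_test(D1, D2, n_perm: int = 9999, alternative: str = "two-sided",
                seed: int = 0) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries;
    significance comes from permuting one matrix's label order.  The
    two-sided p counts permutations with |r_perm| >= |r_obs|.
    """
    M1, ids1 = _as_matrix(D1)
    M2, ids2 = _as_matrix(D2)
    if ids1 != ids2:
        raise ValueError("distance matrices must share labels in the same order")
    n = M1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 labels")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _lower(M1)
    y = _lower(M2)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance in a distance matrix")
    r_obs = float((xc * yc).sum() / denom)
    rng = rng_for(seed, "mantel")
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Mp = M1[perms[:, :, None], perms[:, None, :]]  # (P, n, n)
    i, j = np.tril_indices(n, k=-1)
    xp = Mp[:, i, j]
    xpc = xp - xp.mean(axis=1, keepdims=True)
    num = xpc @ yc
    den = np.sqrt((xpc**2).sum(axis=1) * (yc**2).sum())
    r_perm = num / den
    if alternative == "two-sided":
        extreme = np.abs(r_perm) >= abs(r_obs) - 1e-12
    elif alternative == "greater":
        extreme = r_perm >= r_obs - 1e-12
    else:
        extreme = r_perm <= r_obs + 1e-12
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, alternative)


def permanova(D, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the same quantity
    within each group (divided by the group size); the pseudo-F uses
    (g - 1, n - g) degrees of freedom and significance comes from
    permuting group labels.
    """
    M, ids = _as_matrix(D)
    groups = list(groups)
    if len(groups) != M.shape[0]:
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"groups with fewer than 2 samples: {list(small)}")
    n = M.shape[0]
    D2 = M**2
    ss_total = _lower(D2).sum() / n
    codes = np.searchsorted(labels, groups)
    masks = np.stack([(codes == k).astype(float) for k in range(g)])

    def ss_within(mask_rows):
        # sum_g (m_g D2 m_g^T) / (2 n_g)
        quad = np.einsum("gi,ij,gj->g", mask_rows, D2, mask_rows)
        sizes = mask_rows.sum(axis=1)
        return float((quad / (2.0 * sizes)).sum())

    if ss_total == 0:
        raise ValueError("all distances are zero")
    ssw = ss_within(masks)
    ssb = ss_total - ssw
    # perfect within-group homogeneity: pseudo-F degenerates to +inf
    F_obs = np.inf if ssw == 0 else (ssb / (g - 1)) / (ssw / (n - g))
    R2 = ssb / ss_total
    rng = rng_for(seed, "permanova")
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    pm = masks[:, perms]  # (g, P, n)
    quad = np.einsum("gpi,ij,gpj->gp", pm, D2, pm)
    sizes = masks.sum(axis=1)[:, None]
    ssw_perm = (quad / (2.0 * sizes)).sum(axis=0)
    ssb_perm = ss_total - ssw_perm
    with np.errstate(divide="ignore"):
        F_perm = np.where(
            ssw_perm == 0, np.inf,
            (ssb_perm / (g - 1)) / (np.where(ssw_perm == 0, 1.0, ssw_perm) / (n - g)),
        )
    p = (1 + int((F_perm >= F_obs - 1e-12).sum())) / (n_perm + 1)
    return PermanovaResult(float(F_obs), float(R2), p, n_perm)


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transformation: entry -> sqrt(count / row total).

    Rows are samples.  Zero rows are an error (the transform is
    undefined for empty samples).
    """
    X = table.values.astype(float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = X.sum(axis=1)
    if (row_sums == 0).any():
        zero = list(table.index[row_sums == 0])
        raise ValueError(f"all-zero rows: {zero}")
    return pd.DataFrame(np.sqrt(X / row_sums[:, None]),
                        index=table.index, columns=table.columns)


def _chi_square_standardize(Y: np.ndarray):
    total = Y.sum()
    if total <= 0:
        raise ValueError("response table must have positive total")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero row or column in response table")
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return Q, r, c


def _weighted_design(X: np.ndarray, r: np.ndarray):
    # weighted centering then sqrt(weight) scaling: columns of W live in
    # the row-weighted inner-product space of the chi-square standardization
    mean = (X * r[:, None]).sum(axis=0) / r.sum()
    Xc = X - mean
    return np.sqrt(r)[:, None] * Xc


def cca_fit(response: pd.DataFrame, constraints: pd.DataFrame,
            standardize: bool = True) -> CCAModel:
    """Canonical correspondence analysis.

    The response (samples x features) is chi-square standardized; the
    constraints (samples x variables, centered/scaled to unit variance)
    are projected in the row-weighted space; the SVD of the fitted matrix
    yields the constrained axes.  Total inertia = sum of squared
    standardized entries.
    """
    if list(response.index) != list(constraints.index):
        raise ValueError("response and constraint rows must align")
    if constraints.shape[1] >= response.shape[0]:
        raise ValueError("need fewer constraints than samples")
    Y = response.values.astype(float)
    X = constraints.values.astype(float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = list(constraints.columns[sd == 0])
            raise ValueError(f"constant constraint columns: {const}")
        X = (X - X.mean(axis=0)) / sd
    Q, r, c = _chi_square_standardize(Y)
    W = _weighted_design(X, r)
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        raise ValueError(
            f"rank-deficient constraints ({rank} < {W.shape[1]}); "
            f"columns: {list(constraints.columns)}"
        )
    B, *_ = np.linalg.lstsq(W, Q, rcond=None)
    fitted = W @ B
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2
    keep = eig > 1e-12
    eig = eig[keep]
    axes = [f"CCA{k + 1}" for k in range(keep.sum())]
    site = pd.DataFrame(U[:, keep] * s[keep], index=response.index, columns=axes)
    var_scores = pd.DataFrame(
        np.linalg.lstsq(W, U[:, keep], rcond=None)[0],
        index=constraints.columns, columns=axes,
    )
    return CCAModel(
        eigenvalues=eig,
        total_inertia=float((Q**2).sum()),
        constrained_inertia=float(eig.sum()),
        site_scores=site,
        variable_scores=var_scores,
        selected=[],
    )


def _added_inertia(Q, W_current, w_candidate):
    """Constrained inertia gained by adding one column to the model."""
    if W_current is None or W_current.shape[1] == 0:
        resid_Q = Q
        resid_w = w_candidate
    else:
        coef, *_ = np.linalg.lstsq(W_current, Q, rcond=None)
        resid_Q = Q - W_current @ coef
        cw, *_ = np.linalg.lstsq(W_current, w_candidate, rcond=None)
        resid_w = w_candidate - W_current @ cw
    norm2 = float((resid_w**2).sum())
    if norm2 <= 1e-12:
        return 0.0, resid_Q, resid_w
    proj = resid_w @ (resid_w.T @ resid_Q) / norm2
    return float((proj**2).sum()), resid_Q, resid_w


def stepwise_select(response: pd.DataFrame, constraints: pd.DataFrame,
                    p_in: float = 0.05, p_out: float = 0.10,
                    n_perm: int = 199, seed: int = 0) -> CCAModel:
    """Both-direction stepwise constraint selection for CCA.

    Forward step: each absent variable's added constrained inertia is
    tested by permuting the reduced-model residual rows of the response
    (add-one p-value); the smallest p at or below ``p_in`` enters.
    Backward step: each present variable is retested given the others and
    dropped if its p exceeds ``p_out``.  Iterates to a fixed point; the
    final model is refit on the selected variables.
    """
    if list(response.index) != list(constraints.index):
        raise ValueError("response and constraint rows must align")
    Y = response.values.astype(float)
    X = constraints.values.astype(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = list(constraints.columns[sd == 0])
        raise ValueError(f"constant constraint columns: {const}")
    X = (X - X.mean(axis=0)) / sd
    Q, r, c = _chi_square_standardize(Y)
    W_all = _weighted_design(X, r)
    names = list(constraints.columns)
    rng = rng_for(seed, "stepwise")
    n = Q.shape[0]

    def perm_p(current_idx, cand_idx):
        W_cur = W_all[:, current_idx] if current_idx else None
        w = W_all[:, [cand_idx]]
        stat, resid_Q, resid_w = _added_inertia(Q, W_cur, w)
        norm2 = float((resid_w**2).sum())
        if norm2 <= 1e-12:
            return 1.0, stat
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            proj = resid_w @ (resid_w.T @ resid_Q[perm]) / norm2
            if (proj**2).sum() >= stat - 1e-12:
                count += 1
        return (1 + count) / (n_perm + 1), stat

    selected: list[int] = []
    pvals: dict[int, float] = {}
    for _ in range(2 * len(names) + 1):
        changed = False
        # forward
        candidates = [k for k in range(len(names)) if k not in selected]
        results = []
        for k in candidates:
            p, stat = perm_p(selected, k)
            results.append((p, k))
        results.sort()
        if results and results[0][0] <= p_in:
            p, k = results[0]
            selected.append(k)
            pvals[k] = p
            changed = True
        # backward
        for k in list(selected):
            rest = [i for i in selected if i != k]
            p, _ = perm_p(rest, k)
            pvals[k] = p
            if p > p_out:
                selected.remove(k)
                changed = True
        if not changed:
            break
    if selected:
        model = cca_fit(response, constraints[[names[k] for k in selected]])
    else:
        model = CCAModel(
            eigenvalues=np.array([]),
            total_inertia=float((Q**2).sum()),
            constrained_inertia=0.0,
            site_scores=pd.DataFrame(index=response.index),
            variable_scores=pd.DataFrame(),
            selected=[],
        )
    model.selected = [(names[k], pvals[k]) for k in selected]
    return model
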