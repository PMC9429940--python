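"""Pairwise alignment primitives shared across the pipeline.

All identity values in the package flow through the two scoring schemes
fixed here so that cluster membership and QC verdicts are bit-reproducible:

* nucleotide: global alignment, match +2 / mismatch -3, gap open -5 /
  gap extend -2; identity = matching columns / alignment columns, with
  terminal-gap columns excluded from the denominator (the convention of
  threshold-clustering tools, where a short sequence nested in a longer
  one can still be 100% identical).
* protein: local Smith-Waterman, BLOSUM62, gap open -11 / extend -1.
"""

from __future__ import annotations

from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "pairwise_identity",
    "global_nt_alignment",
    "local_protein_alignment",
    "protein_alignment_stats",
    "query_match_vector",
    "identity_upper_bound",
    "edit_distance",
]

# "open" is the score of the first gapped column, "extend" of each further one.
NT_MATCH = 2
NT_MISMATCH = -3
NT_GAP_OPEN = -5
NT_GAP_EXTEND = -2

PROT_GAP_OPEN = -11
PROT_GAP_EXTEND = -1


@lru_cache(maxsize=None)
def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=NT_MATCH,
        mismatch_score=NT_MISMATCH,
        open_gap_score=NT_GAP_OPEN,
        extend_gap_score=NT_GAP_EXTEND,
    )
    return aligner


@lru_cache(maxsize=None)
def _prot_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=PROT_GAP_OPEN,
        extend_gap_score=PROT_GAP_EXTEND,
    )
    return aligner


def global_nt_alignment(a: str, b: str):
    """Best global nucleotide alignment under the package scoring scheme."""
    return _nt_aligner().align(a, b)[0]


def local_protein_alignment(query: str, ref: str):
    """Best local (Smith-Waterman) protein alignment, BLOSUM62."""
    return _prot_aligner().align(query, ref)[0]


def _segment_stats(alignment, a: str, b: str, skip_terminal_gaps: bool):
    """(matches, columns) over an alignment's diagonal/gap segments."""
    coords = alignment.coordinates
    nseg = coords.shape[1] - 1
    matches = 0
    columns = 0
    for s in range(nseg):
        a0, b0 = coords[0, s], coords[1, s]
        a1, b1 = coords[0, s + 1], coords[1, s + 1]
        da, db = a1 - a0, b1 - b0
        if da and db:  # diagonal segment
            m = sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
            matches += m
            columns += da
        else:  # gap segment
            if skip_terminal_gaps and (s == 0 or s == nseg - 1):
                continue
            columns += max(da, db)
    return matches, columns


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two nucleotide sequences.

    Global alignment (match +2, mismatch -3, gap open -5, extend -2);
    identity = matching columns / alignment columns excluding terminal
    gaps.  Symmetric by construction of the scoring scheme.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    aln = global_nt_alignment(a, b)
    matches, columns = _segment_stats(aln, a, b, skip_terminal_gaps=True)
    if columns == 0:
        return 0.0
    return matches / columns


def protein_alignment_stats(query: str, ref: str):
    """(identity, query_coverage, score) of the best local protein alignment.

    Identity is over all columns of the local alignment; coverage is the
    aligned fraction of the query.
    """
    aln = local_protein_alignment(query, ref)
    matches, columns = _segment_stats(aln, query, ref, skip_terminal_gaps=False)
    qstart = int(aln.coordinates[0, 0])
    qend = int(aln.coordinates[0, -1])
    coverage = (qend - qstart) / len(query) if query else 0.0
    identity = matches / columns if columns else 0.0
    return identity, coverage, aln.score


def query_match_vector(query: str, ref: str) -> list[bool]:
    """Per-position flags: query position aligns to an identical base in ref.

    Uses the global nucleotide alignment; gapped query positions are False.
    Used by the de novo chimera model builder.
    """
    aln = global_nt_alignment(query, ref)
    flags = [False] * len(query)
    coords = aln.coordinates
    for s in range(coords.shape[1] - 1):
        a0, b0 = coords[0, s], coords[1, s]
        a1, b1 = coords[0, s + 1], coords[1, s + 1]
        if a1 - a0 and b1 - b0:
            for i in range(a1 - a0):
                if query[a0 + i] == ref[b0 + i]:
                    flags[a0 + i] = True
    return flags


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (edlib)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def identity_upper_bound(a: str, b: str) -> float:
    """Cheap optimistic identity estimate used only to pre-screen candidates.

    1 - editdist/min(len); an over-estimate for substitution-dominated
    pairs.  Callers must confirm with :func:`pairwise_identity` before
    acting on it.
    """
    d = edit_distance(a, b)
    m = min(len(a), len(b))
    if m == 0:
        return 0.0
    return max(0.0, 1.0 - d / m)
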