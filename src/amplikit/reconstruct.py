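"""From reads to feature tables: the two routes under comparison.

* OTU route: quality trim -> pair merge -> pool -> dereplicate -> discard
  singletons -> greedy centroid clustering at an identity threshold ->
  de novo chimera flagging -> feature table.
* Variant route: same upstream steps, but exact variants are resolved by
  an abundance-skew denoiser (UNOISE-style rule) instead of a threshold.
  This preserves the contract that matters for the comparison — single-
  nucleotide resolution with no similarity threshold — without fitting a
  per-run sequencer error model.

Identity everywhere is the global-alignment identity of
:func:`amplikit.align.pairwise_identity` (terminal gaps excluded), so
cluster membership is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import edit_distance, identity_upper_bound, pairwise_identity

__all__ = [
    "UniqueSequence",
    "ClusterSet",
    "FeatureTable",
    "trim_reads",
    "merge_pairs",
    "dereplicate",
    "discard_singletons",
    "greedy_cluster",
    "denoise",
    "flag_chimeras_denovo",
    "build_feature_table",
]

# screening slack: candidates whose optimistic identity estimate falls this
# far below the threshold are skipped without a full alignment
_SCREEN_SLACK = 0.03


def _best_hit(seq: str, candidates: list, t: float):
    """(best identity, index) of the best candidate with identity >= t - slack.

    Candidates are visited in decreasing order of the cheap edit-distance
    identity estimate; once the estimate cannot exceed the best confirmed
    identity the scan stops.  The estimate is exact for the substitution-
    dominated divergence this pipeline produces, so the confirmed best is
    the true best; every returned identity is confirmed with the full
    package-standard alignment.
    """
    bounds = [identity_upper_bound(seq, c) for c in candidates]
    order = sorted(range(len(candidates)), key=lambda k: -bounds[k])
    best_id, best_k = -1.0, None
    for k in order:
        if bounds[k] < t - _SCREEN_SLACK or bounds[k] <= best_id:
            break
        ident = pairwise_identity(seq, candidates[k])
        if ident > best_id or (ident == best_id and best_k is not None
                               and k < best_k):
            best_id, best_k = ident, k
    return best_id, best_k


@dataclass
class UniqueSequence:
    """A dereplicated sequence with per-sample abundances."""

    sequence: str
    abundance: int
    per_sample: dict  # sample -> count

    def __post_init__(self):
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        if sum(self.per_sample.values()) != self.abundance:
            raise ValueError("per-sample counts must sum to total abundance")


@dataclass
class ClusterSet:
    """Greedy clustering result at threshold ``t``.

    ``membership`` maps member sequence -> centroid sequence; every
    member's identity to its centroid is >= t and centroids map to
    themselves.
    """

    threshold: float
    centroids: list  # sequences, in centroid creation order
    membership: dict  # member sequence -> centroid sequence
    identities: dict  # member sequence -> identity to its centroid


@dataclass
class FeatureTable:
    """Features x samples counts plus representative sequences."""

    counts: pd.DataFrame  # index: feature ids, columns: samples
    sequences: dict  # feature id -> representative sequence
    unassigned: dict = field(default_factory=dict)  # sample -> reads not mapped

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.sequences)
        if missing:
            raise ValueError(f"features without representatives: {sorted(missing)[:5]}")


def _phred(qual: str) -> np.ndarray:
    arr = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33
    if (arr < 0).any() or (arr > 60).any():
        raise ValueError("malformed Phred+33 quality string")
    return arr


def trim_reads(reads, q_threshold: int = 20, min_len: int = 10):
    """Sliding-window 3' quality trimming.

    Window width is 10% of the read length (minimum 1).  Scanning from
    the 5' end, the read is truncated at the start of the first window
    whose mean quality drops below ``q_threshold``; reads trimmed below
    ``min_len`` are dropped.  ``reads`` is a list of (seq, qual) pairs;
    returns (trimmed (seq, qual) list, number dropped).
    """
    out = []
    dropped = 0
    for seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError("sequence/quality length mismatch")
        q = _phred(qual)
        w = max(1, round(0.1 * len(seq)))
        cut = len(seq)
        if len(seq) >= w:
            means = np.convolve(q, np.ones(w) / w, mode="valid")
            below = np.nonzero(means < q_threshold)[0]
            if below.size:
                cut = int(below[0])
        if cut < min_len:
            dropped += 1
        else:
            out.append((seq[:cut], qual[:cut]))
    return out, dropped


def merge_pairs(fwd, rev, min_overlap: int = 20):
    """Merge forward/reverse pairs by their best ungapped overlap.

    ``fwd``/``rev`` are equal-length lists of (seq, qual); the reverse
    read is reverse-complemented before overlap search.  Overlaps of at
    least ``min_overlap`` bases are scored by matches - mismatches; the
    best positive-scoring overlap wins, mismatching positions take the
    higher-quality base (ties favour the forward read).  Returns
    (list of (merged seq, merged qual), number of discarded pairs).
    """
    if len(fwd) != len(rev):
        raise ValueError("unequal numbers of forward and reverse reads")
    comp = str.maketrans("ACGTN", "TGCAN")
    merged = []
    discarded = 0
    for (fs, fq), (rs, rq) in zip(fwd, rev):
        rrs = rs.translate(comp)[::-1]
        rrq = rq[::-1]
        best = None
        for o in range(min_overlap, min(len(fs), len(rrs)) + 1):
            a, b = fs[-o:], rrs[:o]
            m = sum(1 for x, y in zip(a, b) if x == y)
            score = 2 * m - o  # matches - mismatches
            if best is None or score > best[0]:
                best = (score, o)
        if best is None or best[0] <= 0:
            discarded += 1
            continue
        o = best[1]
        head_s, head_q = fs[:-o], fq[:-o]
        tail_s, tail_q = rrs[o:], rrq[o:]
        mid_s, mid_q = [], []
        for i in range(o):
            bf, bq = fs[len(fs) - o + i], fq[len(fs) - o + i]
            rf, rqc = rrs[i], rrq[i]
            if bf == rf:
                mid_s.append(bf)
                mid_q.append(max(bq, rqc))
            elif ord(rqc) > ord(bq):
                mid_s.append(rf)
                mid_q.append(rqc)
            else:
                mid_s.append(bf)
                mid_q.append(bq)
        merged.append((head_s + "".join(mid_s) + tail_s,
                       head_q + "".join(mid_q) + tail_q))
    return merged, discarded


def dereplicate(reads_per_sample: dict) -> list[UniqueSequence]:
    """Exact-string dereplication across samples.

    ``reads_per_sample`` maps sample -> iterable of sequences.  Output is
    sorted by decreasing total abundance, ties broken lexicographically
    by sequence, so ordering is deterministic across runs.
    """
    counts: dict[str, dict] = {}
    for sample, reads in reads_per_sample.items():
        for seq in reads:
            counts.setdefault(seq, {}).setdefault(sample, 0)
            counts[seq][sample] += 1
    uniques = [
        UniqueSequence(seq, sum(per.values()), per) for seq, per in counts.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def discard_singletons(uniques, min_abund: int = 2):
    """Keep uniques with total abundance >= min_abund, preserving order."""
    return [u for u in uniques if u.abundance >= min_abund]


def greedy_cluster(uniques, t: float) -> ClusterSet:
    """Abundance-ordered greedy centroid clustering.

    Scanning uniques in decreasing-abundance order, each sequence joins
    the existing centroid of maximal identity if that identity >= t
    (ties: earliest centroid); otherwise it founds a new centroid.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    centroids: list[str] = []
    membership: dict[str, str] = {}
    identities: dict[str, float] = {}
    for u in uniques:
        best_id, best_k = _best_hit(u.sequence, centroids, t)
        best_c = centroids[best_k] if best_k is not None else None
        if best_c is not None and best_id >= t:
            membership[u.sequence] = best_c
            identities[u.sequence] = best_id
        else:
            centroids.append(u.sequence)
            membership[u.sequence] = u.sequence
            identities[u.sequence] = 1.0
    return ClusterSet(t, centroids, membership, identities)


def denoise(uniques, alpha: float = 2.0, min_abund: int = 2):
    """Abundance-skew exact-variant denoiser.

    Scanning uniques in decreasing-abundance order, a candidate ``c`` is
    absorbed into the accepted variant ``v`` that minimises edit distance
    d >= 1 when abundance(c)/abundance(v) <= 2**-(alpha*d + 1) (the
    skew a read with d errors is expected to show relative to its true
    template); otherwise it becomes a new variant.  Absorbed abundances
    are added to the absorbing variant.  Returns (variants, absorbed_into)
    where variants is a list of UniqueSequence (original scan order) and
    absorbed_into maps absorbed sequence -> variant sequence.
    """
    variants: list[UniqueSequence] = []
    absorbed: dict[str, str] = {}
    for u in uniques:
        best = None  # (distance, order index)
        for i, v in enumerate(variants):
            d = edit_distance(u.sequence, v.sequence)
            if d < 1:
                continue
            if u.abundance / v.abundance <= 2.0 ** -(alpha * d + 1):
                if best is None or d < best[0]:
                    best = (d, i)
        if best is not None:
            v = variants[best[1]]
            v.abundance += u.abundance
            for s, n in u.per_sample.items():
                v.per_sample[s] = v.per_sample.get(s, 0) + n
            absorbed[u.sequence] = v.sequence
        else:
            variants.append(UniqueSequence(u.sequence, u.abundance,
                                           dict(u.per_sample)))
    variants = [v for v in variants if v.abundance >= min_abund]
    return variants, absorbed


def flag_chimeras_denovo(
    uniques,
    min_model_id: float = 0.99,
    min_gain: float = 0.02,
    abskew: float = 2.0,
    max_parents: int = 20,
):
    """De novo bimera flagging against more-abundant parents.

    For each candidate, eligible parents are uniques with >= abskew times
    its abundance (capped at the ``max_parents`` most abundant for
    tractability).  Over all ordered parent pairs and single breakpoints
    the best two-segment model identity (fraction of candidate positions
    matching the model) is compared with the best single-parent identity;
    the candidate is flagged iff model identity >= min_model_id and the
    gain over the best single parent is >= min_gain.  Returns
    {candidate sequence: flagged bool}.
    """
    from .align import query_match_vector

    flags: dict[str, bool] = {}
    for i, u in enumerate(uniques):
        parents = [v for v in uniques if v.abundance >= abskew * u.abundance
                   and v.sequence != u.sequence][:max_parents]
        if len(parents) < 2:
            flags[u.sequence] = False
            continue
        L = len(u.sequence)
        match = [np.array(query_match_vector(u.sequence, p.sequence), dtype=bool)
                 for p in parents]
        best_single = max(m.sum() / L for m in match)
        prefix = [np.concatenate([[0], np.cumsum(m)]) for m in match]
        best_two = 0.0
        for a in range(len(parents)):
            for b in range(len(parents)):
                if a == b:
                    continue
                # candidate positions 0..bp-1 scored on parent a, rest on b
                totals = prefix[a][1:-1] + (prefix[b][-1] - prefix[b][1:-1])
                if totals.size:
                    best_two = max(best_two, totals.max() / L)
        flags[u.sequence] = (best_two >= min_model_id
                             and best_two - best_single >= min_gain)
    return flags


def build_feature_table(
    features,
    reads_per_sample: dict,
    mode: str,
    t: float | None = None,
    cluster_set: ClusterSet | None = None,
    absorbed_into: dict | None = None,
) -> FeatureTable:
    """Map all reads onto features and count per sample.

    ``features`` is {feature id: representative sequence}.  In cluster
    mode a read maps to its best-identity feature if that identity >= t
    (an existing membership map is honoured first); in variant mode a
    read maps to its absorbing variant or exact match.  Unmapped reads
    are counted per sample in ``unassigned``.
    """
    if mode not in ("cluster", "variant"):
        raise ValueError("mode must be 'cluster' or 'variant'")
    if mode == "cluster" and t is None:
        raise ValueError("cluster mode requires a threshold t")
    seq_to_fid = {}
    for fid, seq in features.items():
        seq_to_fid[seq] = fid
    known: dict[str, str | None] = {}  # read sequence -> feature id or None
    if cluster_set is not None:
        for member, centroid in cluster_set.membership.items():
            if centroid in seq_to_fid:
                known[member] = seq_to_fid[centroid]
    if absorbed_into is not None:
        for member, variant in absorbed_into.items():
            if variant in seq_to_fid:
                known[member] = seq_to_fid[variant]
    samples = list(reads_per_sample)
    counts = pd.DataFrame(0, index=list(features), columns=samples, dtype=int)
    unassigned = {s: 0 for s in samples}
    feature_items = list(features.items())
    feature_seqs = [s for _, s in feature_items]
    for sample, reads in reads_per_sample.items():
        for seq in reads:
            fid = known.get(seq, "?")
            if fid == "?":
                if seq in seq_to_fid:
                    fid = seq_to_fid[seq]
                elif mode == "variant":
                    fid = None
                else:
                    best_id, best_k = _best_hit(seq, feature_seqs, t)
                    fid = (feature_items[best_k][0]
                           if best_k is not None and best_id >= t else None)
                known[seq] = fid
            if fid is None:
                unassigned[sample] += 1
            else:
                counts.loc[fid, sample] += 1
    return FeatureTable(counts, dict(features), unassigned)
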