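"""Protein-translation quality control for functional-gene features.

Amplicons of protein-coding genes are internal to an open reading frame,
so a correct feature must translate, in one of the six frames, to a
stop-free protein of a predictable length that matches the target enzyme.
The workflow implemented here:

1. determine the best reading frame against a reference protein panel;
2. translate and discard any feature whose translation contains a stop
   (anywhere — the amplicon is internal, so no terminal-stop exception);
3. gate the stop-free proteins by expected amino-acid length;
4. verify off-length proteins by local alignment against the panel
   (Smith-Waterman, BLOSUM62) with identity/coverage cutoffs — a
   network-free, deterministic stand-in for a protein database search;
5. curate the feature table down to the verified features.

Length gating alone is insufficient: correct and frameshifted proteins
can overlap in length, which is why step 4 exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import protein_alignment_stats, local_protein_alignment

__all__ = [
    "QCConfig",
    "TranslationVerdict",
    "QCEmptyOutputError",
    "CODON_TABLE",
    "detect_frame",
    "translate_frame",
    "partition_by_stop",
    "gate_by_length",
    "verify_by_alignment",
    "qc_feature_set",
    "qc_summary",
]

# Standard genetic code, written out so translation of N-containing and
# ambiguous codons is under this module's control ('X'), not a library's.
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    _BASES[i] + _BASES[j] + _BASES[k]: _AMINO[16 * i + 4 * j + k]
    for i in range(4) for j in range(4) for k in range(4)
}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class QCConfig:
    """Per-gene QC parameters.

    ``expected_nt_len`` is the amplicon length minus both primer lengths;
    ``expected_aa_len`` defaults to floor(expected_nt_len / 3).  The
    default length tolerance is 0 (only exact-length proteins skip
    alignment verification).
    """

    gene: str
    expected_nt_len: int
    reference_protein_panel: list
    expected_aa_len: int | None = None
    aa_len_tolerance: int = 0
    min_identity: float = 0.5
    min_coverage: float = 0.7

    def __post_init__(self):
        if self.expected_aa_len is None:
            self.expected_aa_len = self.expected_nt_len // 3
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.expected_aa_len < 1:
            raise ValueError("expected_aa_len must be >= 1")


@dataclass
class TranslationVerdict:
    """Per-feature QC outcome."""

    feature_id: str
    strand: str
    frame: int
    protein: str
    status: str  # pass_expected_length | pass_verified | fail_stop_codon | fail_unverified
    best_ref_identity: float

    @property
    def passed(self) -> bool:
        return self.status.startswith("pass")


class QCEmptyOutputError(RuntimeError):
    """Raised when no feature survives QC; carries the verdicts."""

    def __init__(self, verdicts):
        self.verdicts = verdicts
        counts = pd.Series([v.status for v in verdicts]).value_counts().to_dict()
        super().__init__(f"all {len(verdicts)} features failed QC: {counts}")


def translate_frame(nt: str, strand: str, offset: int, *, table=CODON_TABLE) -> str:
    """Translate one frame; '*' marks stops, codons containing N give 'X'.

    The trailing partial codon is dropped; the reverse strand is
    translated on the reverse complement.  Non-ACGTN symbols are errors.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1, or 2")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    seq = nt.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    if strand == "-":
        seq = seq.translate(_COMP)[::-1]
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else table[codon])
    return "".join(out)


def detect_frame(nt: str, panel: list) -> tuple[str, int, float]:
    """Pick the frame whose translation best matches the protein panel.

    All six frames are scored by the best local-alignment score against
    any panel member; ties break by fewest stops, then '+' strand, then
    smallest offset.
    """
    if not panel:
        raise ValueError("reference protein panel is empty")
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    best = None
    for strand in "+-":
        for offset in range(3):
            prot = translate_frame(nt, strand, offset)
            if not prot:
                continue
            score = max(
                local_protein_alignment(prot, ref).score for ref in panel
            )
            key = (-score, prot.count("*"), strand != "+", offset)
            if best is None or key < best[0]:
                best = (key, strand, offset, score)
    return best[1], best[2], best[3]


def partition_by_stop(proteins: dict) -> tuple[dict, dict]:
    """Split {id: protein} into (stop_free, containing_stop)."""
    stop_free, containing = {}, {}
    for fid, prot in proteins.items():
        (containing if "*" in prot else stop_free)[fid] = prot
    return stop_free, containing


def gate_by_length(protein: str, cfg: QCConfig) -> str:
    """'expected' iff |len - expected_aa_len| <= tolerance, else 'anomalous'."""
    if abs(len(protein) - cfg.expected_aa_len) <= cfg.aa_len_tolerance:
        return "expected"
    return "anomalous"


def verify_by_alignment(protein: str, cfg: QCConfig) -> tuple[bool, float]:
    """Smith-Waterman verification against the reference protein panel.

    Passes iff some panel member aligns with identity >= min_identity
    over >= min_coverage of the query (both bounds inclusive).  Returns
    (passed, best identity among qualifying-coverage alignments, falling
    back to the best identity overall).
    """
    if not cfg.reference_protein_panel:
        raise ValueError("reference protein panel is empty")
    best_identity = 0.0
    passed = False
    for ref in cfg.reference_protein_panel:
        identity, coverage, _ = protein_alignment_stats(protein, ref)
        if coverage >= cfg.min_coverage:
            best_identity = max(best_identity, identity)
            if identity >= cfg.min_identity:
                passed = True
    return passed, best_identity


def qc_feature_set(features: dict, table: pd.DataFrame, cfg: QCConfig):
    """Run the full decision tree and curate the feature table.

    ``features`` maps feature id -> nucleotide sequence; ``table`` is
    features x samples counts (index = feature ids).  Status assignment:
    stop codon -> fail_stop_codon; expected length -> pass_expected_length;
    anomalous but alignment-verified -> pass_verified; otherwise
    fail_unverified.  The curated table keeps only pass_* features.
    """
    missing = set(table.index) - set(features)
    if missing:
        raise ValueError(f"table features without sequences: {sorted(missing)[:5]}")
    verdicts = []
    for fid in table.index:
        strand, offset, _ = detect_frame(features[fid], cfg.reference_protein_panel)
        prot = translate_frame(features[fid], strand, offset)
        if "*" in prot:
            verdicts.append(TranslationVerdict(fid, strand, offset, prot,
                                               "fail_stop_codon", 0.0))
            continue
        verified, identity = verify_by_alignment(prot, cfg)
        if gate_by_length(prot, cfg) == "expected":
            status = "pass_expected_length"
        elif verified:
            status = "pass_verified"
        else:
            status = "fail_unverified"
        verdicts.append(TranslationVerdict(fid, strand, offset, prot, status, identity))
    keep = [v.feature_id for v in verdicts if v.passed]
    if not keep:
        raise QCEmptyOutputError(verdicts)
    curated = table.loc[keep]
    return verdicts, curated


def qc_summary(verdicts, table: pd.DataFrame, bin_width: int = 10) -> dict:
    """Report % failed features, % reads retained, and a size histogram.

    The histogram bins protein lengths into ``bin_width``-residue bins,
    split by pass/fail.
    """
    n = len(verdicts)
    failed = [v for v in verdicts if not v.passed]
    total_reads = float(table.values.sum())
    failed_reads = float(table.loc[[v.feature_id for v in failed]].values.sum()) \
        if failed else 0.0
    lengths = {"pass": [], "fail": []}
    for v in verdicts:
        lengths["pass" if v.passed else "fail"].append(len(v.protein))
    all_lengths = lengths["pass"] + lengths["fail"]
    top = (max(all_lengths) // bin_width + 1) * bin_width if all_lengths else bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    hist = {
        status: np.histogram(vals, bins=edges)[0].tolist()
        for status, vals in lengths.items()
    }
    return {
        "n_features": n,
        "pct_failed_features": 100.0 * len(failed) / n if n else 0.0,
        "pct_reads_retained": 100.0 * (1.0 - failed_reads / total_reads)
        if total_reads else 100.0,
        "histogram_bin_edges": edges.tolist(),
        "histogram": hist,
    }
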