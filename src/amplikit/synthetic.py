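"""Synthetic functional-gene amplicon communities with known ground truth.

The generator emulates the design of a two-structure sediment survey: a
panel of protein-coding marker genes (stop-free in frame), within-gene
taxa at controlled nucleotide identity, two sample groups with a planted
fold-change on a subset of taxa, per-base substitution/indel errors,
single-breakpoint chimeras, and (optionally) overlapping paired reads
with Phred+33 quality strings.  Every read is logged in a truth table so
downstream QC, denoising and chimera flagging can be scored against
ground truth.

What it deliberately does not model: PCR bias, polymerase error spectra,
flow-cell artifacts, or real error-rate profiles of a sequencer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .qc import translate_frame

__all__ = [
    "GeneModel",
    "CommunityDesign",
    "ErrorModel",
    "Read",
    "ReadPair",
    "make_reference_panel",
    "derive_taxa",
    "assign_abundances",
    "simulate_amplicons",
    "write_fixture",
    "read_fixture",
    "revcomp",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One marker gene: a stop-free coding amplicon plus its primer pair.

    ``coding_seq`` is the full amplicon (primer binding sites included);
    ``insert`` is the primer-trimmed region that gets sequenced.  Primer
    lengths are multiples of 3, so the insert shares the amplicon frame.
    """

    name: str
    coding_seq: str
    frame_offset: int
    primer_fwd: str
    primer_rev: str
    amplicon_len_nt: int

    def __post_init__(self):
        if self.amplicon_len_nt != len(self.coding_seq):
            raise ValueError("amplicon_len_nt must equal len(coding_seq)")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0-2")
        prot = translate_frame(self.coding_seq, "+", self.frame_offset)
        if "*" in prot:
            raise ValueError(f"{self.name}: coding_seq has an internal stop")

    @property
    def insert(self) -> str:
        """Amplicon with primer regions removed (what gets sequenced)."""
        return self.coding_seq[len(self.primer_fwd): len(self.coding_seq) - len(self.primer_rev)]

    @property
    def insert_frame_offset(self) -> int:
        return (self.frame_offset + (3 - len(self.primer_fwd) % 3)) % 3

    @property
    def protein(self) -> str:
        """Translation of the insert in its reading frame."""
        return translate_frame(self.insert, "+", self.insert_frame_offset)


@dataclass
class ErrorModel:
    """Per-base substitution/indel probabilities and chimera rate."""

    sub_rate: float = 0.0
    indel_rate: float = 0.0
    chimera_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.sub_rate, self.indel_rate, self.chimera_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class CommunityDesign:
    """Taxa, per-group relative-abundance profiles, and the planted effect."""

    taxa: list  # [(taxon_id, sequence)]
    group_profiles: np.ndarray  # (n_groups, n_taxa)
    n_groups: int
    n_replicates: int
    effect_taxa: set
    effect_fold: float

    def __post_init__(self):
        self.group_profiles = np.asarray(self.group_profiles, dtype=float)
        if self.group_profiles.shape != (self.n_groups, len(self.taxa)):
            raise ValueError("group_profiles shape mismatch")
        if (self.group_profiles < 0).any():
            raise ValueError("abundances must be non-negative")
        if not np.allclose(self.group_profiles.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("profiles must each sum to 1")

    @property
    def sample_names(self) -> list:
        return [
            f"g{g + 1}r{r + 1}"
            for g in range(self.n_groups)
            for r in range(self.n_replicates)
        ]

    def sample_group(self, sample: str) -> int:
        return int(sample.split("r")[0][1:]) - 1


@dataclass
class Read:
    id: str
    seq: str
    qual: str | None = None


@dataclass
class ReadPair:
    id: str
    fwd: str
    fwd_qual: str
    rev: str
    rev_qual: str


def make_reference_panel(n_genes: int, aa_length: int, seed: int) -> list[GeneModel]:
    """Generate ``n_genes`` stop-free coding amplicons with primer pairs.

    Each coding sequence is 3*aa_length nt of random sense codons; primers
    are the terminal segments of the amplicon (length 18 nt, shortened for
    very small genes), so the primer-trimmed insert stays in frame 0.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if aa_length < 10:
        raise ValueError("aa_length must be >= 10")
    rng = rng_for(seed, "reference_panel")
    primer_len = 18 if 3 * aa_length - 36 >= 60 else 3 * max(1, aa_length // 5)
    panel = []
    for i in range(n_genes):
        codons = rng.choice(len(SENSE_CODONS), size=aa_length)
        coding = "".join(SENSE_CODONS[c] for c in codons)
        panel.append(
            GeneModel(
                name=f"gene{i:02d}",
                coding_seq=coding,
                frame_offset=0,
                primer_fwd=coding[:primer_len],
                primer_rev=revcomp(coding[-primer_len:]),
                amplicon_len_nt=3 * aa_length,
            )
        )
    return panel


def _mutate_positions(seq: str, positions, rng, avoid_stops: bool, frame: int) -> str:
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        rng.shuffle(choices)
        for base in choices:
            out[pos] = base
            if not avoid_stops:
                break
            codon_start = pos - ((pos - frame) % 3)
            if codon_start < 0 or codon_start + 3 > len(out):
                break
            if "".join(out[codon_start:codon_start + 3]) not in STOP_CODONS:
                break
        else:  # every base made a stop (cannot happen for the standard code)
            out[pos] = seq[pos]
    return "".join(out)


def derive_taxa(
    gene: GeneModel,
    n_taxa: int,
    target_identity: float,
    seed: int,
    frame_preserving: bool = True,
) -> list[tuple[str, str]]:
    """Derive within-gene taxa at a controlled identity to the reference.

    Substitution-only divergence of the primer-trimmed insert.  In
    frame-preserving mode substitutions land on third codon positions and
    never create a stop; in frame-breaking mode positions are uniform and
    stops are allowed.  Realized identity to the reference is exactly
    1 - k/len where k = round((1 - target) * len).
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    insert = gene.insert
    L = len(insert)
    k = round((1.0 - target_identity) * L)
    frame = gene.insert_frame_offset
    if frame_preserving:
        candidates = [
            p for p in range(frame + 2, L, 3) if p + 1 <= L
        ]
    else:
        candidates = list(range(L))
    if k > len(candidates):
        raise ValueError(
            f"target identity {target_identity} unreachable: needs {k} "
            f"substitutions but only {len(candidates)} eligible positions"
        )
    rng = rng_for(seed, f"derive_taxa:{gene.name}")
    taxa = []
    for j in range(n_taxa):
        if k == 0:
            seq = insert
        else:
            positions = rng.choice(len(candidates), size=k, replace=False)
            seq = _mutate_positions(
                insert,
                [candidates[p] for p in positions],
                rng,
                avoid_stops=frame_preserving,
                frame=frame,
            )
        taxa.append((f"{gene.name}_t{j:03d}", seq))
    return taxa


def assign_abundances(
    taxa,
    n_groups: int,
    n_replicates: int,
    effect_fold: float,
    effect_frac: float,
    lognormal_sigma: float,
    seed: int,
) -> CommunityDesign:
    """Draw a lognormal base profile and plant a fold-change in group 2.

    A fraction ``effect_frac`` of taxa is multiplied by ``effect_fold`` in
    the second group, then the profile is renormalized.  Groups beyond the
    second reuse the base profile.
    """
    if effect_fold <= 0:
        raise ValueError("effect_fold must be > 0")
    if not 0.0 <= effect_frac <= 1.0:
        raise ValueError("effect_frac must be in [0, 1]")
    rng = rng_for(seed, "assign_abundances")
    n = len(taxa)
    base = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n)
    base /= base.sum()
    n_effect = round(effect_frac * n)
    effect_idx = rng.choice(n, size=n_effect, replace=False) if n_effect else np.array([], int)
    profiles = np.tile(base, (n_groups, 1))
    if n_groups >= 2 and n_effect:
        boosted = base.copy()
        boosted[effect_idx] *= effect_fold
        profiles[1] = boosted / boosted.sum()
    return CommunityDesign(
        taxa=list(taxa),
        group_profiles=profiles,
        n_groups=n_groups,
        n_replicates=n_replicates,
        effect_taxa={taxa[i][0] for i in effect_idx},
        effect_fold=effect_fold,
    )


def _quality_string(length: int, q: int = 37, decay: bool = False) -> str:
    if not decay:
        return chr(q + 33) * length
    # linear decay over the final third of the read, down to q - 20
    qs = np.full(length, q)
    tail = length // 3
    if tail:
        qs[-tail:] = np.maximum(2, np.round(np.linspace(q, q - 20, tail))).astype(int)
    return "".join(chr(int(v) + 33) for v in qs)


def simulate_amplicons(
    design: CommunityDesign,
    n_reads_per_sample: int,
    err: ErrorModel,
    paired: bool = False,
    read_length: int | None = None,
    quality_decay: bool = False,
):
    """Draw reads per sample and apply the error model.

    Reads are multinomial draws from the sample's group profile.  With
    probability ``chimera_fraction`` a read is a single-breakpoint join of
    two profile-sampled parents (breakpoint uniform in the middle 60% of
    the amplicon).  Substitution/indel counts per read are binomial in the
    template length.  Paired mode emits overlapping forward/reverse reads
    (default length 60% of the template) with Phred+33 qualities.

    Returns ``(reads, truth)`` where ``reads`` maps sample name to a list
    of :class:`Read` (or :class:`ReadPair`) and ``truth`` is a DataFrame
    with one row per emitted read.
    """
    if n_reads_per_sample < 1:
        raise ValueError("n_reads_per_sample must be >= 1")
    if not design.taxa:
        raise ValueError("empty community design")
    rng = rng_for(err.seed, "simulate_amplicons")
    taxon_ids = [t[0] for t in design.taxa]
    taxon_seqs = [t[1] for t in design.taxa]
    reads: dict[str, list] = {}
    truth_rows = {
        "read_id": [], "sample": [], "source": [], "parent1": [], "parent2": [],
        "breakpoint": [], "n_sub": [], "n_indel": [], "frame_intact": [],
    }
    for g in range(design.n_groups):
        profile = design.group_profiles[g]
        for r in range(design.n_replicates):
            sample = f"g{g + 1}r{r + 1}"
            idx = rng.choice(len(taxon_ids), size=n_reads_per_sample, p=profile)
            chim = rng.random(n_reads_per_sample) < err.chimera_fraction
            out = []
            for i in range(n_reads_per_sample):
                rid = f"{sample}_r{i:06d}"
                if chim[i] and len(taxon_ids) > 1:
                    p1 = int(rng.choice(len(taxon_ids), p=profile))
                    p2 = p1
                    while p2 == p1:  # a same-template join is not a chimera
                        p2 = int(rng.choice(len(taxon_ids), p=profile))
                    s1, s2 = taxon_seqs[p1], taxon_seqs[p2]
                    L = min(len(s1), len(s2))
                    bp = int(rng.integers(int(0.2 * L), int(0.8 * L)))
                    seq = s1[:bp] + s2[bp:]
                    source, par1, par2 = "chimera", taxon_ids[p1], taxon_ids[p2]
                else:
                    seq = taxon_seqs[idx[i]]
                    source, par1, par2, bp = taxon_ids[idx[i]], "", "", -1
                n_sub = int(rng.binomial(len(seq), err.sub_rate)) if err.sub_rate else 0
                n_ind = int(rng.binomial(len(seq), err.indel_rate)) if err.indel_rate else 0
                if n_sub:
                    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
                    seq = _mutate_positions(seq, pos, rng, avoid_stops=False, frame=0)
                for _ in range(n_ind):
                    p = int(rng.integers(0, len(seq)))
                    if rng.random() < 0.5:
                        seq = seq[:p] + "ACGT"[rng.integers(0, 4)] + seq[p:]
                    else:
                        seq = seq[:p] + seq[p + 1:]
                truth_rows["read_id"].append(rid)
                truth_rows["sample"].append(sample)
                truth_rows["source"].append(source)
                truth_rows["parent1"].append(par1)
                truth_rows["parent2"].append(par2)
                truth_rows["breakpoint"].append(bp)
                truth_rows["n_sub"].append(n_sub)
                truth_rows["n_indel"].append(n_ind)
                truth_rows["frame_intact"].append(n_ind == 0)
                if paired:
                    rl = read_length or max(20, int(0.6 * len(seq)))
                    fwd = seq[:rl]
                    rev = revcomp(seq)[:rl]
                    out.append(ReadPair(
                        rid, fwd, _quality_string(len(fwd), decay=quality_decay),
                        rev, _quality_string(len(rev), decay=quality_decay),
                    ))
                else:
                    out.append(Read(rid, seq))
            reads[sample] = out
    return reads, pd.DataFrame(truth_rows)


def write_fixture(outdir, design: CommunityDesign, reads, truth: pd.DataFrame) -> None:
    """Write per-sample FASTA/FASTQ, the truth TSV, and the design JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paired = bool(reads) and isinstance(next(iter(reads.values()))[0], ReadPair)
    for sample, rs in reads.items():
        if paired:
            with open(outdir / f"{sample}_R1.fastq", "w") as f1, \
                    open(outdir / f"{sample}_R2.fastq", "w") as f2:
                for rp in rs:
                    f1.write(f"@{rp.id}\n{rp.fwd}\n+\n{rp.fwd_qual}\n")
                    f2.write(f"@{rp.id}\n{rp.rev}\n+\n{rp.rev_qual}\n")
        else:
            with open(outdir / f"{sample}.fasta", "w") as f:
                for rd in rs:
                    f.write(f">{rd.id}\n{rd.seq}\n")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    meta = {
        "taxa": [[tid, seq] for tid, seq in design.taxa],
        "group_profiles": design.group_profiles.tolist(),
        "n_groups": design.n_groups,
        "n_replicates": design.n_replicates,
        "effect_taxa": sorted(design.effect_taxa),
        "effect_fold": design.effect_fold,
        "paired": paired,
    }
    with open(outdir / "design.json", "w") as f:
        json.dump(meta, f, indent=1, sort_keys=True)


def read_fixture(outdir):
    """Round-trip reader for :func:`write_fixture` output."""
    outdir = Path(outdir)
    with open(outdir / "design.json") as f:
        meta = json.load(f)
    design = CommunityDesign(
        taxa=[tuple(t) for t in meta["taxa"]],
        group_profiles=np.array(meta["group_profiles"]),
        n_groups=meta["n_groups"],
        n_replicates=meta["n_replicates"],
        effect_taxa=set(meta["effect_taxa"]),
        effect_fold=meta["effect_fold"],
    )
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t", keep_default_na=False)
    reads: dict[str, list] = {}
    for sample in design.sample_names:
        if meta["paired"]:
            pairs = []
            with open(outdir / f"{sample}_R1.fastq") as f1, \
                    open(outdir / f"{sample}_R2.fastq") as f2:
                l1, l2 = f1.readlines(), f2.readlines()
            for i in range(0, len(l1), 4):
                pairs.append(ReadPair(
                    l1[i][1:].strip(), l1[i + 1].strip(), l1[i + 3].strip(),
                    l2[i + 1].strip(), l2[i + 3].strip(),
                ))
            reads[sample] = pairs
        else:
            rs = []
            with open(outdir / f"{sample}.fasta") as f:
                lines = f.readlines()
            for i in range(0, len(lines), 2):
                rs.append(Read(lines[i][1:].strip(), lines[i + 1].strip()))
            reads[sample] = rs
    return design, reads, truth
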