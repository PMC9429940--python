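# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `amplikit`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
transcribed from external data.

## The question the package operationalizes

For protein-coding marker genes there is no agreed identity threshold
for OTU construction; values between 97% and 82% are all in use for
nitrogen-cycle genes.  Exact sequence variants (ASVs) avoid the
threshold entirely.  The package builds a fully synthetic but
structurally faithful version of a two-group amplicon survey so that
the downstream consequences of that choice — alpha diversity, beta
diversity inference, constrained ordination, representative-sequence
phylogeny and taxonomy — can be measured against planted ground truth.

## Synthetic communities

A *gene model* is a random stop-free coding amplicon (default 450 nt =
150 codons drawn from the 61 sense codons) with its primer pair taken
from the amplicon's termini (18 nt, a multiple of 3, so the
primer-trimmed insert stays in frame).  Reads represent primer-trimmed
inserts.

*Taxa* are derived from the insert by substitution-only divergence at a
controlled identity: k = round((1−t)·L) positions are substituted, by
default restricted to third codon positions with stop avoidance
(frame-preserving mode), so every taxon still passes protein QC.  A
frame-breaking mode (uniform positions, stops permitted) exists so
fixtures can control how many features *should* fail QC.  Realized
identity is exactly 1−k/L, which the alignment-based identity
reproduces to ±0.01.

*Abundances* are one lognormal base profile (σ = 1 by default),
normalized; in the second group a fraction of taxa (default 25%) is
multiplied by a fold-change (default 4×) and renormalized.  Reads are
multinomial draws per sample.  The *error model* applies per-base
substitutions and indels (binomial counts per read) and, with a
configurable probability, replaces a read by a single-breakpoint join
of two distinct profile-sampled parents, breakpoint uniform in the
middle 60% of the amplicon so both parents contribute detectable
segments.  Paired mode emits forward/reverse reads (60% of the template
each, so overlaps are generous) with constant Q37 qualities and an
optional 3' linear decay — enough to exercise trimming and merging
without modeling a sequencer.  Every read gets a truth row (source
taxon or chimera parents + breakpoint, error counts, frame-intact
flag).

Not modeled: PCR bias, polymerase error spectra, run-specific quality
profiles, flow-cell artifacts.  Consequences for interpretation: the
denoiser's job here is easier than on real data (errors are iid), so
passing tests demonstrate contract correctness, not real-data error
rates.

## Protein QC

The decision tree per feature: detect the best of the six reading
frames by local alignment (BLOSUM62, gap open −11 / extend −1) of each
frame's translation against a reference protein panel (ties: fewest
stops, then + strand, then smallest offset); translate; any stop
anywhere fails (`fail_stop_codon`) — the amplicon is internal to its
ORF, so no terminal-stop exception; stop-free proteins of expected
length pass (`pass_expected_length`); off-length proteins pass only if
a panel alignment reaches identity ≥ 0.5 over ≥ 0.7 of the query
(`pass_verified`, else `fail_unverified`).  The expected length is
floor((amplicon − primers)/3) with a configurable tolerance, default 0.
Alignment verification replaces an online protein-database search; it
is deterministic, offline, and carries the same contract ("matches the
expected enzyme").  Frame detection is per-feature rather than per-gene:
it reduces to the same answer on clean data and also handles
mixed-orientation input.

Translation is implemented from a literal standard-code table; codons
containing N give X and other non-nucleotide symbols are errors.  (A
general ambiguity-resolving translator would silently translate e.g.
GCN; the QC contract wants X there.)

Validation: on six genes with 10 clean, 3 frameshifted and 2
stop-substituted features each, fail-classification sensitivity and
specificity are both 1.0 (threshold: ≥ 0.95).  Frameshift positions are
rejection-sampled so all six frames of the damaged read contain a stop,
which keeps the truth labels unambiguous; a frameshift near a read's
end genuinely leaves most of the protein intact and is not a fair test
of the classifier.  A separate test shows the size gate alone is
insufficient: a stop-free random coding sequence of exactly the
expected length passes the gate and only alignment rejects it.

## Feature reconstruction

Identity is defined once for the whole package: global alignment with
match +2 / mismatch −3 / gap open −5 / extend −2 (open = first gap
column), identity = matching columns / alignment columns excluding
terminal gaps (the clustering-tool convention; it makes a nested
fragment 100% identical to its container).  Scores are cross-checked in
the tests against an independent affine-gap dynamic-programming
implementation, and substitution-only identities against the closed
form.

Pipeline order: trim (sliding window, width 10% of read length, cut at
the first window mean below Q20, drop reads under 10 nt) → merge pairs
(best ungapped overlap ≥ 20 by matches−mismatches; overlap conflicts
resolved by the higher-quality base) → pool and dereplicate (ties by
lexicographic sequence, so ordering is deterministic) → discard
singletons → cluster/denoise → flag chimeras → build tables → QC.

OTU route: greedy abundance-ordered clustering; each sequence joins the
existing centroid of *maximal* identity when that identity meets the
threshold, else founds a centroid.  (Assign-to-best rather than
first-above-threshold: order-stable and replayable; noted as a
deliberate deviation from first-match tools.)  A cheap edit-distance
screen (edlib, 0.03 identity slack, best-first with pruning) decides
which candidates get a full alignment; every assignment is confirmed by
the full alignment, so the membership invariant — identity(member,
centroid) ≥ t — holds by construction and is replayed wholesale in the
acceptance suite (4,000 member checks, 0 violations).

ASV route: an abundance-skew denoiser.  Scanning uniques by decreasing
abundance, a candidate is absorbed into the accepted variant at minimal
edit distance d ≥ 1 when abundance(c)/abundance(v) ≤ 2^−(α·d+1)
(α = 2), else it becomes a new variant.  This is a deliberate stand-in
for run-calibrated error-model denoisers: it preserves the contract the
comparison needs — single-nucleotide resolution without a similarity
threshold, low-abundance error reads absorbed — at desk scale, and the
tests verify exactly that contract (both rule boundaries, conservation,
resolution of planted single-nucleotide variants).

De novo chimera flagging: candidates are tested against parents with
≥ 2× their abundance (capped at the 20 most abundant); over ordered
parent pairs and all breakpoints, the best two-segment model identity
(fraction of candidate positions matching the model) must reach 0.99
and exceed the best single parent by 0.02.  Sensitivity ≥ 0.9 on
planted bimeras of sufficiently divergent parents and a false-flag rate
≤ 2% on chimera-free fixtures are both tested.  Chimeras of
nearly-identical parents are undetectable in principle (the model gain
vanishes); the fixtures use parents divergent enough that truth is
meaningful.

## Diversity

Richness uses the analytic hypergeometric rarefaction expectation
(log-gamma form); Shannon (natural log) and Gini-Simpson are computed
on one seeded draw without replacement at the rarefaction depth
(default 10,000 reads; shallower samples are excluded, a status rather
than an error).  One seeded draw mirrors common practice of computing
indices on a rarefied table; the analytic mean-vs-Monte-Carlo agreement
(0.003% at depth 1,000, tolerance 0.5%) is in the acceptance suite.
Group rarefaction curves are computed on group-averaged tables (rounded
to integers).

Sequence trees: pairwise JC69 distances (d = −¾ ln(1−4p/3), p ≥ 0.749
capped) over the package identity, then canonical neighbor joining with
deterministic first-minimum tie-breaking; negative branch estimates are
clamped to zero with the deficit moved to the sibling branch of the
same join.  This replaces an aligner + approximate-ML tree tool: for
distance-based beta diversity and topology comparison at this scale a
distance tree is adequate, and it is exactly reproducible.  NJ recovers
100/100 random additive matrices (5–12 tips) to 1e-9 patristic error.

UniFrac: unweighted = branch length unique to one sample / branch
length observed in either; weighted = Σ_b l_b |A_b − B_b| with A_b the
fraction of the sample's reads below branch b, normalized (default) by
Σ_b l_b (A_b + B_b) so both variants live on [0,1] and are comparable.
Whether to normalize the weighted form is genuinely open; both modes
exist, and the brute-force branch-enumeration oracle covers both
(max |Δ| ≈ 2e-16 over 50 random 10-tip trees, tolerance 1e-12).  The
unweighted form also matches scikit-bio's implementation.

## Inference

Permutation p-values use the add-one convention everywhere:
p = (1 + #extreme)/(n_perm + 1).  Mantel correlates strictly-lower-
triangle entries, permutes one matrix's labels, 9,999 permutations,
two-sided by default (one-sided by flag).  PERMANOVA partitions
Σ d²/n into within/between groups; 999 permutations by default (the
classical default; with small balanced designs the attainable minimum
p is limited by partition multiplicity, which the tests account for).
Null calibration over 500 exchangeable replicates lands inside the 99%
binomial band around α = 0.05 for both tests.

CCA follows the chi-square standardization: Q = (P − rcᵀ)/√(rcᵀ),
constraints centered/scaled and projected in the row-weighted space;
the SVD of the fitted matrix gives constrained eigenvalues; total
inertia = ΣQ².  With one binary constraint the first constrained
eigenvalue equals the correspondence-analysis inertia of the two-group
aggregated table (tested).  Stepwise selection is both-direction:
forward-add the smallest permutation p ≤ 0.05, backward-drop any
retained variable with p > 0.10, iterate to a fixed point; the test
statistic is added constrained inertia and the null permutes
reduced-model residual rows (a simple, reproducible surrogate for the
published selection heuristics, with the same contract: a table of
significant drivers).  Permutations default to 199 — selection needs
only a coarse p.

The package's headline phenomenon is tested directly: in a community
where the group-discriminating variants are mutually ≥ 97% identical
(six clade variants whose abundance ranking swaps between groups, plus
three distant background clades that keep the coarse table
non-degenerate), weighted-UniFrac PERMANOVA on exact variants detects
the effect (p ≤ 0.01) while the same test on the 85%-threshold table —
where the whole clade collapses into one feature of equal total
abundance — does not (p > 0.05), in ≥ 80% of 20 seeds (observed: 19–20
of 20).

## Tree congruence

Two methods' features never share labels, so Robinson-Foulds is
computed on the induced topologies over a shared reference set: at step
i, an NJ tree is built over the references plus the top-i features of
each method, both trees are pruned back to the reference tips, and
normalized RF (symmetric bipartition difference / total non-trivial
bipartitions of both trees, well-defined for multifurcations) is
recorded; the curve stops at min(|A|, |B|, max_iter).  Trees are rebuilt
from scratch each step (pairwise distances are cached — they are
identical across steps).  The curve is summarized by OLS of rf_norm on
ln(n); noiseless curves recover (a, b) to 1e-9.  Bipartition extraction
matches an independent edge-removal/graph-connectivity oracle and
dendropy's RF on all tested tree pairs.

## Taxonomy

NBC: word priors P(w) = (n(w)+0.5)/(N+1) over database sequences,
per-species conditionals P(w|s) = (m(w,s)+P(w))/(M_s+1), species scored
by Σ log P(w|s) over a bootstrap subsample of ⌈V/8⌉ of the query's V
distinct 8-mers; 100 bootstraps; per-rank confidence is the winning
lineage's vote share along the heaviest lineage chain; assignment stops
below confidence 0.8 and UNASSIGNED propagates downward.  Score ties
within a bootstrap break uniformly at random (seeded) so symmetric
fixtures split votes rather than defaulting to one species.

BLCA: hits are database entries within 0.02 of the best global-alignment
identity and above 0.80 absolute; each of 100 bootstraps resamples query
positions and distributes one unit of weight over hits proportionally to
their resampled match fraction; per-rank confidence is the accumulated
weight along the heaviest lineage chain, cutoff 0.8; no hits means fully
unassigned.  The two canonical outcomes — two same-species hits →
species; two congeneric species hits → genus with species unassigned —
are unit-tested exactly.

The synthetic reference databases share lineages but differ in distance
to the query-generating gene: genus anchors at 3% (near) or 30% (far)
divergence, ±30% per-genus jitter, species 2% within genus.  Against
the near database both classifiers assign genus and species; against
the far database BLCA's hits fall below the identity floor (fully
unassigned) while the k-mer classifier still commits at higher ranks —
so BLCA's species-level unassigned fraction is ≥ NBC's in 20/20 seeds.
The choice of 30% makes the contrast structural rather than borderline:
at ~25% divergence the jittered nearest genus occasionally crosses the
0.80 alignment floor and the contrast becomes seed-dependent.

## Orchestration and reproducibility

`run_pipeline` composes all stages and writes every intermediate as
TSV/FASTA/Newick/JSON; reports are byte-identical across reruns with
the same (config, seed).  One top-level seed expands into per-stage
seeds via BLAKE2("{seed}:{stage}") mod 2³¹, so stages are independently
re-runnable.  The sample covariate table uses the conventional sediment
covariate names (NH3, NO2, NO3, ChlA, pH, SGS, TOC, DOC, TDN), with
ammonia tracking the planted group contrast so driver selection has a
true positive.  The CLI is a thin wrapper (exit 0 success / 1 stage
failure / 2 usage error).

Problem sizes: the default experiment is 1 gene, 24 taxa, 2 groups × 6
replicates × 12,000 reads, thresholds {0.97, 0.95, 0.90, 0.85} plus the
variant route, rarefaction depth 10,000 — small enough to run end to
end in a few minutes on one CPU while keeping all stages non-trivial.
Validation experiments use smaller designs (stated in their
docstrings) chosen so each answer is unambiguous at that size.

## Known limitations

- The denoiser is a skew rule, not a fitted error model; on real data
  with structured errors it would over- or under-merge relative to
  run-calibrated tools.
- Distance trees (JC69+NJ) ignore alignment uncertainty and rate
  variation; congruence statements are about reproducible topology
  comparison, not phylogenetic accuracy.
- The edit-distance screen in clustering is exact only for
  substitution-dominated divergence; pathological indel-heavy pairs
  could be pre-screened out (the confirmed invariant still holds — a
  member is never assigned without a full-alignment check).
- PERMANOVA is one-way; the nested field structure (locations within
  groups) is not modeled as strata.
- Unweighted UniFrac on small, dense synthetic communities is often
  degenerate (every feature present everywhere); the pipeline records
  and skips those tests rather than failing.
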