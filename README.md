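# amplikit

Amplicon studies of protein-coding *functional* genes — nitrogen-cycle
markers such as *amoA*, *nxrB*, *nirS*, *nirK* and *nrfA* — face a choice
that 16S rRNA work has largely settled: group reads into OTUs at some
identity threshold (and which threshold? the literature uses anything
from 97% down to 82% for the same gene), or resolve exact sequence
variants (ASVs)?  The choice is not cosmetic: alpha-diversity ranks,
ordination results, PERMANOVA verdicts about a two-group field design,
and even the phylogeny of representative sequences can flip with it.

`amplikit` is a desk-scale, fully synthetic re-analysis framework for
studying exactly that sensitivity.  It provides:

- **a synthetic community generator** — protein-coding (stop-free,
  in-frame) marker genes, taxa at controlled pairwise identity, two
  sample groups with a planted abundance effect, per-base
  substitution/indel errors, single-breakpoint chimeras, paired reads
  with quality strings, and a per-read truth table;
- **protein-translation QC** — six-frame detection, translation,
  stop-codon rejection, amino-acid length gating, and Smith-Waterman
  verification against a reference enzyme panel, with table curation
  (the workflow that catches frameshifted and artifactual features that
  nucleotide-level filtering misses);
- **both reconstruction routes** — quality trimming, pair merging,
  dereplication, singleton discard, greedy centroid clustering at any
  threshold, an abundance-skew exact-variant denoiser, and de novo
  chimera flagging;
- **the downstream inference layer** — rarefaction (analytic expected
  richness + seeded subsampling), Shannon/Gini-Simpson, Bray-Curtis,
  JC69 + neighbor-joining trees, unweighted/weighted UniFrac, Mantel
  tests (9,999 permutations, two-sided), one-way PERMANOVA, Hellinger +
  CCA with both-direction stepwise driver selection;
- **tree congruence** — features added one at a time in descending
  abundance to reference-anchored trees from two methods, normalized
  Robinson-Foulds distance per step, and the fit RF = a·ln(n) + b;
- **two taxonomy classifiers** — an RDP-style naive Bayesian 8-mer
  classifier and a BLCA-style alignment + lowest-common-ancestor
  classifier, plus a near/far reference-database contrast.

Because every input is generated with known ground truth, every claim
the pipeline makes can be scored: QC sensitivity/specificity against
planted errors, cluster invariants replayed by alignment, UniFrac and
Robinson-Foulds against brute-force oracles, permutation tests against
exchangeable nulls.

## The core quantities

For a feature table `N` (features × samples) the package computes, per
reconstruction method:

- expected richness under rarefaction to depth *d*:
  E[S] = Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)];
- Shannon entropy H = −Σ pᵢ ln pᵢ (nats) and Gini-Simpson 1 − Σ pᵢ²
  on one seeded draw at depth *d* (samples under *d* are excluded);
- Bray-Curtis BC(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); unweighted UniFrac
  (unique/observed branch length) and weighted UniFrac
  Σ_b l_b|A_b−B_b|, normalized by Σ_b l_b(A_b+B_b), on a JC69+NJ tree
  of the representative sequences;
- PERMANOVA pseudo-F and R² with label-permutation p-values
  (add-one convention), and Mantel r between method-specific distance
  matrices;
- CCA constrained eigenvalues on the Hellinger-transformed table with
  permutation-tested stepwise selection of environmental drivers;
- normalized Robinson-Foulds congruence curves and their log fits;
- per-rank taxonomy assignments with bootstrap confidences.

## Worked example

```python
from amplikit.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=7, n_taxa=12, n_replicates=3, reads_per_sample=1500,
                rarefaction_depth=1000, thresholds=(0.97, 0.90),
                mantel_perms=999, permanova_perms=199, cca_perms=99)
report = run_pipeline(cfg, "out/")
print({k: round(v["p"], 3) for k, v in report["permanova"].items()})
```

prints (weighted UniFrac and Bray-Curtis PERMANOVA p-values per method)

```
{'ASV|BC': 0.115, 'ASV|WU': 0.07, 'OTU-97%|BC': 0.08, 'OTU-97%|WU': 0.095,
 'OTU-90%|BC': 0.085, 'OTU-90%|WU': 0.105}
```

— at this tiny scale (6 samples) the planted group effect is real but
the permutation floor (20 distinct label partitions) keeps p above
0.05.  At the default scale (12 samples, 12,000 reads each) the same
pipeline yields `ASV|WU` p = 0.002, while the 85%-threshold table
collapses to a single feature: its phylogenetic distances are
undefined and its Bray-Curtis test shows no effect (p = 0.195) — the
resolution sensitivity the package exists to study.

The same experiment is available from a shell:

```
amplikit run-all --seed 7 --outdir out/
amplikit simulate --seed 3 --outdir fixture/
amplikit cluster --reads-dir fixture/ -t 0.97 --outdir clusters/
amplikit --help   # all subcommands
```

Every output is a TSV/JSON/Newick/FASTA file regenerated bit-identically
from (config, seed).

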