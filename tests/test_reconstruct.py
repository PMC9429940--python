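"""Trimming, merging, dereplication, clustering, denoising, chimera flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from amplikit import reconstruct as rc
from amplikit import synthetic as syn
from amplikit.align import pairwise_identity

Q37 = chr(37 + 33)
Q2 = chr(2 + 33)


def gotoh_score(a, b, match=2, mismatch=-3, open_=-5, extend=-2):
    """Independent affine-gap global alignment score (first gap column
    costs `open_`, each further column `extend`)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend,
                          Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend,
                          X[i, j - 1] + open_)
    return max(M[n, m], X[n, m], Y[n, m])


class TestTrim:
    def test_high_quality_read_unchanged(self):
        reads = [("ACGT" * 25, Q37 * 100)]
        out, dropped = rc.trim_reads(reads)
        assert out == reads and dropped == 0

    def test_all_low_quality_read_removed(self):
        out, dropped = rc.trim_reads([("A" * 150, Q2 * 150)])
        assert out == [] and dropped == 1

    def test_truncation_near_quality_drop(self):
        seq = "A" * 150
        qual = Q37 * 100 + Q2 * 50
        out, dropped = rc.trim_reads([(seq, qual)])
        assert dropped == 0
        cut = len(out[0][0])
        assert abs(cut - 100) <= 15  # window width = 10% of read length

    def test_malformed_quality_errors(self):
        with pytest.raises(ValueError):
            rc.trim_reads([("ACGT", Q37 * 3)])


class TestMerge:
    def _pair_from(self, template, rl, qf=None, qr=None):
        fwd = template[:rl]
        rev = syn.revcomp(template)[:rl]
        return (fwd, qf or Q37 * len(fwd)), (rev, qr or Q37 * len(rev))

    def test_exact_overlap_reconstructs_template(self, gene):
        template = gene.insert  # 414 nt
        f, r = self._pair_from(template, 232)  # 50 nt overlap
        merged, discarded = rc.merge_pairs([f], [r])
        assert discarded == 0
        assert merged[0][0] == template

    def test_short_overlap_discarded(self, gene):
        template = gene.insert
        f, r = self._pair_from(template, 212)  # 10 nt true overlap
        merged, discarded = rc.merge_pairs([f], [r], min_overlap=20)
        assert merged == [] and discarded == 1

    def test_mismatch_resolved_by_quality(self):
        template = "ACGTTGCAATCGGATCCTAGGCATT"  # 25 nt, aperiodic
        rl = 15  # 5 nt overlap region: positions 10-14
        fwd = template[:rl]
        rev = syn.revcomp(template)[:rl]
        # corrupt the forward base at overlap position 12 with low quality
        fwd = fwd[:12] + ("A" if fwd[12] != "A" else "C") + fwd[13:]
        fq = Q37 * 12 + Q2 + Q37 * 2
        merged, _ = rc.merge_pairs([(fwd, fq)], [(rev, Q37 * rl)],
                                   min_overlap=5)
        assert merged[0][0] == template  # high-quality reverse base kept

    def test_unequal_pair_counts_error(self):
        with pytest.raises(ValueError):
            rc.merge_pairs([("A", Q37)], [])


class TestDereplicate:
    def test_counts_and_order(self):
        u = rc.dereplicate({"s1": ["AAA", "AAA", "CCC"], "s2": ["CCC", "TTT"]})
        assert [(x.sequence, x.abundance) for x in u] == [
            ("AAA", 2), ("CCC", 2), ("TTT", 1)]
        assert u[1].per_sample == {"s1": 1, "s2": 1}

    def test_conservation(self, community_seqs):
        u = rc.dereplicate(community_seqs)
        assert sum(x.abundance for x in u) == sum(
            len(v) for v in community_seqs.values())

    def test_singleton_discard(self):
        u = rc.dereplicate({"s": ["A", "A", "A", "C", "G", "G"]})
        kept = rc.discard_singletons(u)
        assert [(x.sequence, x.abundance) for x in kept] == [("A", 3), ("G", 2)]
        assert rc.discard_singletons(u, min_abund=1) == u
        dropped_mass = sum(x.abundance for x in u) - sum(
            x.abundance for x in kept)
        assert dropped_mass == 1


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_substitution_closed_form(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=100))
        pos = rng.choice(100, size=8, replace=False)
        other = list(base)
        for p in pos:
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        assert pairwise_identity(base, "".join(other)) == pytest.approx(0.92)

    def test_symmetry_and_score_oracle(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 45))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 45))))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a))
            from amplikit.align import global_nt_alignment
            assert global_nt_alignment(a, b).score == pytest.approx(
                gotoh_score(a, b))

    def test_nested_sequence_ignores_terminal_gaps(self):
        inner = "ACGTACGTACGTACGTACGT"
        outer = "TTTTT" + inner + "GGGGG"
        assert pairwise_identity(inner, outer) == 1.0


class TestGreedyCluster:
    def test_duplicates_form_one_cluster(self):
        u = [rc.UniqueSequence("ACGT" * 30, 5, {"s": 5}),
             rc.UniqueSequence("ACGT" * 30, 5, {"s": 5})]
        cs = rc.greedy_cluster(u, 0.97)
        assert len(cs.centroids) == 1

    def test_threshold_splits_and_merges(self, gene):
        a = gene.insert
        taxa = syn.derive_taxa(gene, 1, 0.92, seed=51)
        b = taxa[0][1]
        assert 0.91 <= pairwise_identity(a, b) <= 0.93
        u = [rc.UniqueSequence(a, 10, {"s": 10}),
             rc.UniqueSequence(b, 5, {"s": 5})]
        assert len(rc.greedy_cluster(u, 0.97).centroids) == 2
        assert len(rc.greedy_cluster(u, 0.90).centroids) == 1

    def test_centroid_identity_invariant(self, community_seqs):
        uniques = rc.discard_singletons(rc.dereplicate(community_seqs))
        for t in (0.97, 0.90):
            cs = rc.greedy_cluster(uniques, t)
            for member, centroid in cs.membership.items():
                assert pairwise_identity(member, centroid) >= t
                assert cs.identities[member] == pytest.approx(
                    pairwise_identity(member, centroid))
        assert all(cs.membership[c] == c for c in cs.centroids)


class TestDenoise:
    def _u(self, seq, n):
        return rc.UniqueSequence(seq, n, {"s": n})

    def test_low_abundance_child_absorbed(self):
        parent = "ACGT" * 30
        child = "T" + parent[1:]
        variants, absorbed = rc.denoise([self._u(parent, 1000),
                                         self._u(child, 2)], min_abund=1)
        assert len(variants) == 1
        assert variants[0].abundance == 1002
        assert absorbed == {child: parent}

    def test_balanced_abundances_kept_apart(self):
        a = "ACGT" * 30
        b = "T" + a[1:]
        variants, absorbed = rc.denoise([self._u(a, 500), self._u(b, 500)],
                                        min_abund=1)
        assert len(variants) == 2 and absorbed == {}

    def test_skew_rule_boundary(self):
        # d=1, alpha=2: merge iff child/parent <= 2^-3 = 1/8
        a = "ACGT" * 30
        b = "T" + a[1:]
        merged, _ = rc.denoise([self._u(a, 80), self._u(b, 10)], min_abund=1)
        assert len(merged) == 1  # 10/80 == 1/8, boundary merges
        kept, _ = rc.denoise([self._u(a, 79), self._u(b, 10)], min_abund=1)
        assert len(kept) == 2

    def test_abundance_conservation(self, community_seqs):
        uniques = rc.dereplicate(community_seqs)
        variants, _ = rc.denoise(uniques, min_abund=1)
        assert sum(v.abundance for v in variants) == sum(
            u.abundance for u in uniques)

    def test_resolves_single_nucleotide_variants(self, gene):
        # two genuine variants one substitution apart, both abundant
        a = gene.insert
        b = a[:-1] + ("A" if a[-1] != "A" else "C")
        variants, _ = rc.denoise([self._u(a, 300), self._u(b, 200)],
                                 min_abund=1)
        assert {v.sequence for v in variants} == {a, b}


class TestChimeraFlags:
    def test_perfect_bimera_flagged(self, gene):
        taxa = syn.derive_taxa(gene, 2, 0.90, seed=61)
        p1, p2 = taxa[0][1], taxa[1][1]
        bim = p1[:200] + p2[200:]
        uniques = [
            rc.UniqueSequence(p1, 1000, {"s": 1000}),
            rc.UniqueSequence(p2, 900, {"s": 900}),
            rc.UniqueSequence(bim, 10, {"s": 10}),
        ]
        flags = rc.flag_chimeras_denovo(uniques)
        assert flags[bim] is True or flags[bim] == True  # noqa: E712
        assert not flags[p1] and not flags[p2]

    def test_most_abundant_never_flagged(self, gene):
        taxa = syn.derive_taxa(gene, 3, 0.90, seed=62)
        uniques = [rc.UniqueSequence(s, 100 - 10 * i, {"s": 100 - 10 * i})
                   for i, (_, s) in enumerate(taxa)]
        flags = rc.flag_chimeras_denovo(uniques)
        assert not flags[uniques[0].sequence]

    def test_false_flag_rate_on_clean_fixtures(self, gene):
        flagged = total = 0
        for seed in range(20):
            taxa = syn.derive_taxa(gene, 10, 0.90, seed=700 + seed)
            d = syn.assign_abundances(taxa, 1, 1, 1.0, 0.0, 1.2,
                                      seed=800 + seed)
            reads, _ = syn.simulate_amplicons(
                d, 600, syn.ErrorModel(0.001, 0.0, 0.0, seed=900 + seed))
            uniques = rc.discard_singletons(rc.dereplicate(
                {s: [r.seq for r in rs] for s, rs in reads.items()}))
            flags = rc.flag_chimeras_denovo(uniques)
            flagged += sum(flags.values())
            total += len(flags)
        assert flagged / total <= 0.02

    def test_sensitivity_on_planted_chimeras(self, gene):
        hits = total = 0
        for seed in range(10):
            taxa = syn.derive_taxa(gene, 4, 0.85, seed=1000 + seed)
            d = syn.assign_abundances(taxa, 1, 1, 1.0, 0.0, 0.5,
                                      seed=1100 + seed)
            reads, truth = syn.simulate_amplicons(
                d, 800, syn.ErrorModel(0.0, 0.0, 0.02, seed=1200 + seed))
            chim_seqs = set()
            seqs = {s: [r.seq for r in rs] for s, rs in reads.items()}
            for (sample, rs) in reads.items():
                rows = truth[truth["sample"] == sample]
                for r, src in zip(rs, rows.source):
                    if src == "chimera":
                        chim_seqs.add(r.seq)
            uniques = rc.dereplicate(seqs)
            flags = rc.flag_chimeras_denovo(uniques)
            for u in uniques:
                if u.sequence in chim_seqs:
                    total += 1
                    hits += bool(flags[u.sequence])
        assert total >= 20
        assert hits / total >= 0.9

    @given(hst.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None)
    def test_flags_are_boolean_and_complete(self, abund):
        u = [rc.UniqueSequence("ACGTACGTACGTACGTACGT", abund + 1, {"s": abund + 1})]
        flags = rc.flag_chimeras_denovo(u)
        assert set(flags) == {u[0].sequence}
        assert flags[u[0].sequence] in (True, False)


class TestFeatureTable:
    def test_error_free_reads_reproduce_draws(self, gene):
        taxa = syn.derive_taxa(gene, 5, 0.92, seed=71)
        d = syn.assign_abundances(taxa, 2, 2, 3.0, 0.4, 1.0, seed=72)
        reads, truth = syn.simulate_amplicons(d, 200, syn.ErrorModel(seed=73))
        seqs = {s: [r.seq for r in rs] for s, rs in reads.items()}
        features = {tid: s for tid, s in taxa}
        ft = rc.build_feature_table(features, seqs, "variant")
        expected = truth.groupby(["source", "sample"]).size().unstack(
            fill_value=0)
        for tid in features:
            if tid in expected.index:
                assert (ft.counts.loc[tid] == expected.loc[tid]).all()
        assert sum(ft.unassigned.values()) == 0

    def test_total_conservation_with_unassigned(self, community_seqs):
        uniques = rc.discard_singletons(rc.dereplicate(community_seqs))
        variants, absorbed = rc.denoise(uniques)
        features = {f"v{i}": v.sequence for i, v in enumerate(variants)}
        ft = rc.build_feature_table(features, community_seqs, "variant",
                                    absorbed_into=absorbed)
        total_reads = sum(len(v) for v in community_seqs.values())
        assert ft.counts.values.sum() + sum(ft.unassigned.values()) == total_reads

    def test_read_equal_to_centroid_maps_there(self, gene):
        taxa = syn.derive_taxa(gene, 3, 0.90, seed=74)
        features = {tid: s for tid, s in taxa}
        reads = {"s1": [taxa[1][1]]}
        ft = rc.build_feature_table(features, reads, "cluster", t=0.97)
        assert ft.counts.loc[taxa[1][0], "s1"] == 1

    def test_cluster_mode_requires_threshold(self):
        with pytest.raises(ValueError):
            rc.build_feature_table({"f": "ACGT"}, {"s": []}, "cluster")

    def test_feature_count_ordering_across_resolutions(self, community_seqs):
        # variants >= OTU-97% >= OTU-85% features (resolution ordering)
        uniques = rc.discard_singletons(rc.dereplicate(community_seqs))
        variants, _ = rc.denoise(uniques)
        n_var = len(variants)
        n97 = len(rc.greedy_cluster(uniques, 0.97).centroids)
        n85 = len(rc.greedy_cluster(uniques, 0.85).centroids)
        assert n_var >= n97 >= n85
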