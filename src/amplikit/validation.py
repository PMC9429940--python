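"""Synthetic validation experiments with known ground truth.

Each function here builds a fixture whose correct answer is known by
construction (planted errors, additive distances, exchangeable nulls,
brute-force oracles) and measures how the pipeline's implementation
behaves on it.  The functions return plain dicts of measured quantities
so they can back both the test suite and reporting scripts.
"""

from __future__ import annotations

import math

import numpy as np
from skbio.tree import TreeNode

from . import congruence as cg
from . import diversity as dv
from . import qc as qcmod
from . import reconstruct as rc
from . import stats as st
from . import synthetic as syn
from . import taxonomy as tax
from ._seeds import derive_seed, rng_for

__all__ = [
    "qc_error_recovery",
    "cluster_invariant_check",
    "unifrac_brute_force",
    "unifrac_oracle_error",
    "permutation_calibration",
    "resolution_design",
    "resolution_experiment",
    "random_tree",
    "nj_exactness",
    "rf_bipartitions_oracle",
    "rf_oracle_check",
    "logfit_recovery",
    "rarefaction_consistency",
    "lca_scenarios",
    "classifier_contrast",
]


# ----------------------------------------------------------------- QC

def plant_errors(gene: syn.GeneModel, n_clean: int, n_frameshift: int,
                 n_stop: int, seed: int):
    """Features with planted frameshift/stop errors and their truth labels.

    Clean features are frame-preserving taxa of the gene.  Frameshifted
    features have one base deleted near mid-sequence; the deletion
    position is rejection-sampled until every one of the six reading
    frames of the damaged sequence contains a stop codon, so the truth
    label is unambiguous (the feature cannot translate cleanly in any
    frame).  Stop features have one codon substituted to TAA.  Returns
    (features dict, truth dict id -> 'clean'|'error').
    """
    rng = rng_for(seed, f"plant:{gene.name}")
    taxa = syn.derive_taxa(gene, n_clean + n_frameshift + n_stop, 0.97, seed)
    features, truth = {}, {}
    for i, (tid, s) in enumerate(taxa):
        if i < n_clean:
            features[tid] = s
            truth[tid] = "clean"
        elif i < n_clean + n_frameshift:
            for _ in range(100):
                pos = int(rng.integers(int(0.35 * len(s)), int(0.65 * len(s))))
                cand = s[:pos] + s[pos + 1:]
                if all("*" in qcmod.translate_frame(cand, strand, off)
                       for strand in "+-" for off in range(3)):
                    break
            else:  # pragma: no cover - rejection sampling essentially never fails
                raise RuntimeError("could not plant an unambiguous frameshift")
            features[f"{tid}_fs"] = cand
            truth[f"{tid}_fs"] = "error"
        else:
            frame = gene.insert_frame_offset
            codon_start = frame + 3 * int(rng.integers(5, (len(s) - frame) // 3 - 5))
            features[f"{tid}_stop"] = (
                s[:codon_start] + "TAA" + s[codon_start + 3:]
            )
            truth[f"{tid}_stop"] = "error"
    return features, truth


def qc_error_recovery(seed: int, n_genes: int = 6, aa_length: int = 150,
                      n_clean: int = 10, n_frameshift: int = 3,
                      n_stop: int = 2) -> dict:
    """Sensitivity/specificity of QC fail-classification on planted errors."""
    import pandas as pd

    panel = syn.make_reference_panel(n_genes, aa_length, seed)
    prot_panel = [g.protein for g in panel]
    tp = fn = tn = fp = 0
    for gene in panel:
        features, truth = plant_errors(gene, n_clean, n_frameshift, n_stop,
                                       derive_seed(seed, gene.name))
        table = pd.DataFrame(
            {"s1": np.full(len(features), 10)}, index=list(features))
        cfg = qcmod.QCConfig(
            gene=gene.name,
            expected_nt_len=len(gene.insert),
            reference_protein_panel=prot_panel,
        )
        verdicts, _ = qcmod.qc_feature_set(features, table, cfg)
        for v in verdicts:
            if truth[v.feature_id] == "error":
                tp += not v.passed
                fn += v.passed
            else:
                tn += v.passed
                fp += not v.passed
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_features": tp + fn + tn + fp,
    }


# ---------------------------------------------------------- clustering

def noisy_uniques(seed: int, n_taxa: int = 40, n_reads: int = 4000,
                  sub_rate: float = 0.004, max_uniques: int = 1000):
    """Dereplicated reads (singletons included) from an errorful community."""
    panel = syn.make_reference_panel(1, 150, seed)
    taxa = syn.derive_taxa(panel[0], n_taxa, 0.90, seed)
    design = syn.assign_abundances(taxa, 1, 1, 1.0, 0.0, 1.0, seed)
    reads, _ = syn.simulate_amplicons(
        design, n_reads, syn.ErrorModel(sub_rate, 0.0, 0.0, seed=seed))
    uniques = rc.dereplicate({s: [r.seq for r in rs] for s, rs in reads.items()})
    return uniques[:max_uniques]


def cluster_invariant_check(seed: int,
                            thresholds=(0.97, 0.95, 0.90, 0.85),
                            max_uniques: int = 1000) -> dict:
    """Replay the centroid-identity invariant over all thresholds."""
    uniques = noisy_uniques(seed, max_uniques=max_uniques)
    violations = 0
    checked = 0
    for t in thresholds:
        cs = rc.greedy_cluster(uniques, t)
        for member, centroid in cs.membership.items():
            checked += 1
            if member == centroid:
                continue
            if rc.pairwise_identity(member, centroid) < t:
                violations += 1
    return {"n_uniques": len(uniques), "n_checked": checked,
            "violations": violations}


# -------------------------------------------------------------- UniFrac

def unifrac_brute_force(tree: TreeNode, counts_a: dict, counts_b: dict,
                        weighted: bool, normalized: bool = True) -> float:
    """Branch-enumeration UniFrac oracle.

    Recomputes each branch's descendant tip set from scratch and sums
    the definitions directly — no shared traversal state with the
    implementation.
    """
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    num = den = 0.0
    for node in list(tree.traverse(include_self=True)):
        if node.parent is None:
            continue
        length = node.length or 0.0
        below = {t.name for t in node.tips()} or {node.name}
        a = sum(counts_a.get(n, 0) for n in below)
        b = sum(counts_b.get(n, 0) for n in below)
        if weighted:
            A, B = a / total_a, b / total_b
            num += length * abs(A - B)
            den += length * (A + B)
        else:
            if a > 0 or b > 0:
                den += length
                if (a > 0) != (b > 0):
                    num += length
    if weighted and not normalized:
        return num
    return num / den if den else 0.0


def random_tree(labels, rng, min_bl: float = 0.05, max_bl: float = 1.0,
                rooted: bool = False):
    """Random binary topology over ``labels`` with uniform branch lengths.

    Unrooted trees get a trifurcating root (the NJ convention); rooted
    trees a bifurcating one.
    """
    nodes = [TreeNode(name=str(x)) for x in labels]
    while len(nodes) > (2 if rooted else 3):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(min_bl, max_bl))
        b.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(TreeNode(children=[a, b]))
    for nd in nodes:
        nd.length = float(rng.uniform(min_bl, max_bl))
    return TreeNode(children=nodes)


def unifrac_oracle_error(seed: int, n_trees: int = 50, n_tips: int = 10) -> dict:
    """Max |implementation - oracle| over random trees and count vectors."""
    rng = rng_for(seed, "unifrac_oracle")
    worst = 0.0
    for _ in range(n_trees):
        labels = [f"t{i}" for i in range(n_tips)]
        tree = random_tree(labels, rng)
        ca = {l: int(rng.integers(0, 20)) for l in labels}
        cb = {l: int(rng.integers(0, 20)) for l in labels}
        ca[labels[0]] = max(1, ca[labels[0]])  # keep totals positive
        cb[labels[1]] = max(1, cb[labels[1]])
        for weighted, normalized in ((False, True), (True, True), (True, False)):
            mine = dv.unifrac(tree, ca, cb, weighted=weighted,
                              normalized=normalized)
            ref = unifrac_brute_force(tree, ca, cb, weighted=weighted,
                                      normalized=normalized)
            worst = max(worst, abs(mine - ref))
    return {"n_trees": n_trees, "max_abs_error": worst}


# ------------------------------------------------- permutation inference

def permutation_calibration(seed: int, n_reps: int = 500, n_samples: int = 12,
                            mantel_perms: int = 9999,
                            permanova_perms: int = 999,
                            alpha: float = 0.05) -> dict:
    """Type-I error of Mantel and PERMANOVA on exchangeable nulls."""
    rng = rng_for(seed, "calibration")
    groups = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)

    def euclid(X):
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    mantel_rej = permanova_rej = 0
    for rep in range(n_reps):
        X1 = rng.normal(size=(n_samples, 3))
        X2 = rng.normal(size=(n_samples, 3))
        D1, D2 = euclid(X1), euclid(X2)
        mres = st.mantel_test(D1, D2, n_perm=mantel_perms,
                              seed=derive_seed(seed, f"mantel{rep}"))
        mantel_rej += mres.p <= alpha
        pres = st.permanova(D1, groups, n_perm=permanova_perms,
                            seed=derive_seed(seed, f"perma{rep}"))
        permanova_rej += pres.p <= alpha
    return {
        "n_reps": n_reps,
        "mantel_rejection_rate": mantel_rej / n_reps,
        "permanova_rejection_rate": permanova_rej / n_reps,
    }


# -------------------------------------------------- resolution phenomenon

def resolution_design(seed: int, n_replicates: int = 6,
                      n_effect: int = 6, n_background_clades: int = 3):
    """Community where the group effect lives inside a >=97%-identity clade.

    Six effect variants are mutually >= 97% identical; groups differ only
    in which half of the clade carries the abundance.  Three distant
    background clades keep the low-threshold table non-degenerate but
    carry no group signal.  Clustering at 85% collapses the effect clade
    to one feature and erases the contrast that exact variants retain.
    """
    panel = syn.make_reference_panel(1, 150, seed)
    gene = panel[0]
    rng = rng_for(seed, "resolution")
    clade_anchor = syn.derive_taxa(gene, 1, 0.90, derive_seed(seed, "anchor"))[0][1]
    insert_frame = gene.insert_frame_offset
    third = [p for p in range(insert_frame + 2, len(clade_anchor), 3)]
    effect = []
    for v in range(n_effect):
        pos = rng.choice(len(third), size=4, replace=False)
        seq = syn._mutate_positions(clade_anchor, [third[p] for p in pos], rng,
                                    avoid_stops=True, frame=insert_frame)
        effect.append((f"eff{v}", seq))
    background = [
        (f"bg{i}", s)
        for i, (_, s) in enumerate(syn.derive_taxa(
            gene, n_background_clades, 0.75, derive_seed(seed, "background")))
    ]
    taxa = effect + background
    half = n_effect // 2
    base_bg = 0.3 / n_background_clades
    hi, lo = 0.66 / half, 0.04 / (n_effect - half)
    p1 = np.array([hi] * half + [lo] * (n_effect - half)
                  + [base_bg] * n_background_clades)
    p2 = np.array([lo] * half + [hi] * (n_effect - half)
                  + [base_bg] * n_background_clades)
    profiles = np.stack([p1 / p1.sum(), p2 / p2.sum()])
    return syn.CommunityDesign(
        taxa=taxa, group_profiles=profiles, n_groups=2,
        n_replicates=n_replicates, effect_taxa={t for t, _ in effect},
        effect_fold=hi / lo,
    )


def _resolution_one(seed: int, n_reads: int, permanova_perms: int):
    design = resolution_design(seed)
    reads, _ = syn.simulate_amplicons(
        design, n_reads, syn.ErrorModel(seed=seed))
    seqs = {s: [r.seq for r in rs] for s, rs in reads.items()}
    uniques = rc.discard_singletons(rc.dereplicate(seqs))
    groups = [s.split("r")[0] for s in design.sample_names]
    out = {}
    variants, absorbed = rc.denoise(uniques)
    cs = rc.greedy_cluster(uniques, 0.85)
    for tag, feats, mode, t, extra in (
        ("asv", variants, "variant", None, {"absorbed_into": absorbed}),
        ("otu85", None, "cluster", 0.85, {"cluster_set": cs}),
    ):
        if mode == "cluster":
            agg = {}
            for u in uniques:
                c = cs.membership[u.sequence]
                agg.setdefault(c, []).append(u)
            feats = [
                rc.UniqueSequence(c, sum(u.abundance for u in us),
                                  {"all": sum(u.abundance for u in us)})
                for c, us in agg.items()
            ]
        features = {f"{tag}{i}": f.sequence for i, f in enumerate(feats)}
        ft = rc.build_feature_table(features, seqs, mode, t=t, **extra)
        tree = dv.nj_tree(dv.nt_distance_matrix(ft.sequences))
        D = dv.unifrac_matrix(tree, ft.counts, weighted=True)
        res = st.permanova(D, groups, n_perm=permanova_perms,
                           seed=derive_seed(seed, f"res:{tag}"))
        out[tag] = res.p
    return out


def resolution_experiment(seed: int, n_seeds: int = 20, n_reads: int = 400,
                          permanova_perms: int = 999) -> dict:
    """Fraction of seeds where variants detect the effect and OTU-85% misses it."""
    success = 0
    asv_ps, otu_ps = [], []
    for i in range(n_seeds):
        ps = _resolution_one(derive_seed(seed, f"resolution{i}"), n_reads,
                             permanova_perms)
        asv_ps.append(ps["asv"])
        otu_ps.append(ps["otu85"])
        success += (ps["asv"] <= 0.01) and (ps["otu85"] > 0.05)
    return {
        "n_seeds": n_seeds,
        "success_fraction": success / n_seeds,
        "median_asv_p": float(np.median(asv_ps)),
        "median_otu85_p": float(np.median(otu_ps)),
    }


# ------------------------------------------------------------ NJ and RF

def nj_exactness(seed: int, n_trees: int = 100) -> dict:
    """Recovery of additive matrices: patristic distances to 1e-9."""
    rng = rng_for(seed, "nj_exact")
    from skbio import DistanceMatrix

    recovered = 0
    worst = 0.0
    for _ in range(n_trees):
        n = int(rng.integers(5, 13))
        labels = [f"t{i}" for i in range(n)]
        tree = random_tree(labels, rng)
        dm = tree.tip_tip_distances(labels)
        est = dv.nj_tree(DistanceMatrix(dm.data, ids=labels))
        dm2 = est.tip_tip_distances(labels)
        err = float(np.abs(dm.data - dm2.data).max())
        worst = max(worst, err)
        recovered += err <= 1e-9
    return {"n_trees": n_trees, "recovered_fraction": recovered / n_trees,
            "max_abs_error": worst}


def rf_bipartitions_oracle(tree: TreeNode) -> set:
    """Independent bipartition extraction by edge-removal connectivity.

    Builds the tree as a general graph and, for every edge, finds the
    connected component tip sets after removing it (networkx), rather
    than reading clades off the rooted traversal.
    """
    import networkx as nx

    G = nx.Graph()
    ids = {}
    for i, node in enumerate(tree.traverse(include_self=True)):
        ids[id(node)] = i
        if node.parent is not None:
            G.add_edge(ids[id(node.parent)], i)
    tipname = {ids[id(t)]: t.name for t in tree.tips()}
    tips = sorted(tipname.values())
    anchor = tips[0]
    n = len(tips)
    parts = set()
    for u, v in list(G.edges()):
        H = G.copy()
        H.remove_edge(u, v)
        comp = nx.node_connected_component(H, u)
        side = frozenset(tipname[x] for x in comp if x in tipname)
        if anchor in side:
            side = frozenset(tips) - side
        if 2 <= len(side) <= n - 2:
            parts.add(side)
    return parts


def rf_oracle_check(seed: int, n_pairs: int = 60) -> dict:
    """RF against the edge-removal oracle on random <=8-tip tree pairs."""
    rng = rng_for(seed, "rf_oracle")
    agree = 0
    norm_ok = 0
    for _ in range(n_pairs):
        n = int(rng.integers(4, 9))
        labels = [f"t{i}" for i in range(n)]
        t1 = random_tree(labels, rng)
        t2 = random_tree(labels, rng)
        rf, rf_norm = cg.robinson_foulds(t1, t2, mode="strict")
        o1 = rf_bipartitions_oracle(t1)
        o2 = rf_bipartitions_oracle(t2)
        agree += rf == len(o1 ^ o2)
        norm_ok += 0.0 <= rf_norm <= 1.0
    return {"n_pairs": n_pairs, "agreement_fraction": agree / n_pairs,
            "norm_in_bounds_fraction": norm_ok / n_pairs}


def logfit_recovery(a: float = 0.1, b: float = 0.05, n_points: int = 30) -> dict:
    """Exact recovery of a noiseless rf = a ln(n) + b curve."""
    pts = [(n, a * math.log(n) + b) for n in range(1, n_points + 1)]
    fit = cg.fit_log_curve(cg.CongruenceCurve(pts))
    return {
        "n_points": n_points,
        "max_param_error": max(abs(fit.a - a), abs(fit.b - b)),
        "rmse": fit.rmse,
    }


# ----------------------------------------------------------- rarefaction

def rarefaction_consistency(seed: int, depth: int = 1000,
                            n_draws: int = 10000) -> dict:
    """Analytic expected richness vs the mean of Monte-Carlo rarefactions."""
    rng = rng_for(seed, "rarefaction_fixture")
    counts = rng.integers(1, 200, size=40)
    while counts.sum() < depth:
        counts = counts * 2
    analytic = dv.expected_richness(counts, depth)
    mc_rng = rng_for(seed, "rarefaction_mc")
    richnesses = np.empty(n_draws)
    for i in range(n_draws):
        draw = mc_rng.multivariate_hypergeometric(counts, depth)
        richnesses[i] = (draw > 0).sum()
    mc = float(richnesses.mean())
    shallow = dv.rarefy_counts(np.array([3, 2]), depth=depth, seed=seed)
    return {
        "depth": depth,
        "analytic": analytic,
        "monte_carlo": mc,
        "relative_error_pct": 100.0 * abs(analytic - mc) / analytic,
        "shallow_excluded": bool(shallow.excluded),
    }


# -------------------------------------------------------------- taxonomy

def lca_scenarios(seed: int = 0) -> dict:
    """The two canonical LCA outcomes for congeneric reference hits.

    A query with near-perfect hits to two references of one species must
    be assigned to that species; with hits to two different species of
    one genus it must fall back to the genus.
    """
    rng = rng_for(seed, "lca")
    ancestor = "".join(
        syn.SENSE_CODONS[c] for c in rng.choice(len(syn.SENSE_CODONS), 100))
    base = ("Bacteria", "Proteobacteria", "Betaproteobacteria",
            "Nitrosomonadales", "Nitrosomonadaceae", "Nitrosomonas")
    e1 = _mut(ancestor, 3, rng)
    e2 = _mut(ancestor, 3, rng)
    olig = _mut(ancestor, 6, rng)
    same_db = tax.ReferenceDB(
        ["r1", "r2"], {"r1": e1, "r2": e2},
        {"r1": base + ("Nitrosomonas europaea",),
         "r2": base + ("Nitrosomonas europaea",)},
    )
    cross_db = tax.ReferenceDB(
        ["r1", "r2"], {"r1": e1, "r2": olig},
        {"r1": base + ("Nitrosomonas europaea",),
         "r2": base + ("Nitrosomonas oligotropha",)},
    )
    a_same = tax.blca_classify(ancestor, same_db, seed=seed)
    a_cross = tax.blca_classify(ancestor, cross_db, seed=seed)
    return {
        "same_species_assigned": a_same.at("species") == "Nitrosomonas europaea",
        "cross_species_genus": a_cross.at("genus") == "Nitrosomonas",
        "cross_species_unassigned": a_cross.at("species") == tax.UNASSIGNED,
    }


def _mut(seq: str, k: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def classifier_contrast(seed: int, n_seeds: int = 20) -> dict:
    """Distant-database contrast: BLCA loses species assignments first.

    Queries are light mutations of near-database species; against the
    far database the alignment hits evaporate while the k-mer classifier
    can still commit, so BLCA's species-level unassigned percentage
    should be at least NBC's.
    """
    wins = 0
    blca_vals, nbc_vals = [], []
    for i in range(n_seeds):
        s = derive_seed(seed, f"contrast{i}")
        panel = syn.make_reference_panel(1, 120, s)
        db_near, db_far = tax.build_synthetic_db(panel, 4, 3, 0.03, 0.30, s)
        rng = rng_for(s, "queries")
        queries = [_mut(db_near.sequences[rid], 3, rng)
                   for rid in db_near.ids[:10]]
        nbc_un = tax.summarize_unassigned(
            [tax.nbc_classify(q, db_far, seed=s) for q in queries])
        blca_un = tax.summarize_unassigned(
            [tax.blca_classify(q, db_far, seed=s) for q in queries])
        nbc_vals.append(nbc_un)
        blca_vals.append(blca_un)
        wins += blca_un >= nbc_un
    return {
        "n_seeds": n_seeds,
        "blca_ge_nbc_fraction": wins / n_seeds,
        "mean_blca_unassigned_pct": float(np.mean(blca_vals)),
        "mean_nbc_unassigned_pct": float(np.mean(nbc_vals)),
    }
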