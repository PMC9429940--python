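"""End-to-end "compare methods" experiment.

Strings every stage together the way the study design does: simulate a
functional-gene community -> (trim/merge when paired) -> dereplicate ->
discard singletons -> reconstruct features by every configured method
(greedy clustering at each threshold; the variant denoiser) -> flag de
novo chimeras -> protein QC -> feature tables -> alpha diversity and
rarefaction -> Bray-Curtis / UniFrac / weighted UniFrac -> PERMANOVA per
method, Mantel grid across methods -> Hellinger + CCA with stepwise
driver selection -> incremental tree congruence -> taxonomy contrast.

Everything is reproducible from (config, seed): one top-level seed
expands into stage seeds via a stable hash, and every table is written
as TSV (JSON for scalar results) so any report line can be traced to a
stage output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import congruence as cg
from . import diversity as dv
from . import qc as qcmod
from . import reconstruct as rc
from . import stats as st
from . import synthetic as syn
from . import taxonomy as tax
from ._seeds import derive_seed, rng_for

__all__ = ["RunConfig", "run_pipeline", "StageError"]

log = logging.getLogger("amplikit")

COVARIATES = ("NH3", "NO2", "NO3", "ChlA", "pH", "SGS", "TOC", "DOC", "TDN")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")


@dataclass
class RunConfig:
    """Configuration of one comparison experiment."""

    seed: int = 0
    n_genes: int = 1
    aa_length: int = 150
    n_taxa: int = 24
    taxon_identity: float = 0.92
    n_groups: int = 2
    n_replicates: int = 6
    reads_per_sample: int = 12000
    effect_fold: float = 4.0
    effect_frac: float = 0.25
    lognormal_sigma: float = 1.0
    sub_rate: float = 0.0002
    indel_rate: float = 0.00005
    chimera_fraction: float = 0.005
    paired: bool = False
    thresholds: tuple = (0.97, 0.95, 0.90, 0.85)
    variant_mode: bool = True
    rarefaction_depth: int = 10000
    mantel_perms: int = 9999
    permanova_perms: int = 999
    cca_perms: int = 199
    congruence_refs: int = 8
    congruence_max_iter: int = 8
    db_genera: int = 4
    db_species_per_genus: int = 3
    db_divergence_near: float = 0.05
    db_divergence_far: float = 0.30

    def __post_init__(self):
        ts = tuple(self.thresholds)
        if any(not 0 < t <= 1 for t in ts):
            raise ValueError("thresholds must lie in (0, 1]")
        if list(ts) != sorted(ts, reverse=True) or len(set(ts)) != len(ts):
            raise ValueError("thresholds must be strictly decreasing")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        self.thresholds = ts

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _write(df: pd.DataFrame, path: Path, **kwargs):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def _features_from_cluster(cs: rc.ClusterSet, uniques, prefix: str):
    """Aggregate member abundances onto centroids, keeping abundance order."""
    agg: dict[str, rc.UniqueSequence] = {}
    for u in uniques:
        cent = cs.membership[u.sequence]
        if cent not in agg:
            agg[cent] = rc.UniqueSequence(cent, u.abundance, dict(u.per_sample))
        else:
            a = agg[cent]
            a.abundance += u.abundance
            for s, n in u.per_sample.items():
                a.per_sample[s] = a.per_sample.get(s, 0) + n
    feats = sorted(agg.values(), key=lambda u: (-u.abundance, u.sequence))
    ids = {f.sequence: f"{prefix}_{i:04d}" for i, f in enumerate(feats)}
    return feats, ids


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full comparison experiment; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}
    log.info("run_pipeline parameters: %s", config.to_json())

    # --- simulate ----------------------------------------------------
    try:
        panel = syn.make_reference_panel(config.n_genes, config.aa_length,
                                         config.seed)
        gene = panel[0]
        taxa = syn.derive_taxa(gene, config.n_taxa, config.taxon_identity,
                               config.seed)
        design = syn.assign_abundances(
            taxa, config.n_groups, config.n_replicates, config.effect_fold,
            config.effect_frac, config.lognormal_sigma, config.seed,
        )
        err = syn.ErrorModel(config.sub_rate, config.indel_rate,
                             config.chimera_fraction, seed=config.seed)
        reads, truth = syn.simulate_amplicons(
            design, config.reads_per_sample, err, paired=config.paired)
        syn.write_fixture(outdir / "simulated", design, reads, truth)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    # --- trim / merge (paired) --------------------------------------
    try:
        if config.paired:
            seqs_per_sample = {}
            for sample, pairs in reads.items():
                # process distinct pairs once; multiply back by count
                groups: dict[tuple, int] = {}
                for p in pairs:
                    key = (p.fwd, p.fwd_qual, p.rev, p.rev_qual)
                    groups[key] = groups.get(key, 0) + 1
                out = []
                for (fs, fq, rs, rq), cnt in groups.items():
                    tf, df_ = rc.trim_reads([(fs, fq)])
                    tr, dr_ = rc.trim_reads([(rs, rq)])
                    if not tf or not tr:
                        continue
                    m, _ = rc.merge_pairs(tf, tr)
                    if m:
                        out.extend([m[0][0]] * cnt)
                seqs_per_sample[sample] = out
        else:
            seqs_per_sample = {s: [r.seq for r in rs] for s, rs in reads.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("trim_merge", str(e)) from e

    # --- dereplicate / reconstruct ----------------------------------
    try:
        uniques = rc.dereplicate(seqs_per_sample)
        kept = rc.discard_singletons(uniques)
        methods: dict[str, dict] = {}
        if config.variant_mode:
            variants, absorbed = rc.denoise(kept)
            feats = variants
            ids = {f.sequence: f"asv_{i:04d}" for i, f in enumerate(feats)}
            methods["ASV"] = {"feats": feats, "ids": ids, "mode": "variant",
                              "absorbed": absorbed, "cluster_set": None, "t": None}
        for t in config.thresholds:
            cs = rc.greedy_cluster(kept, t)
            prefix = f"otu{round(t * 100):02d}"
            feats, ids = _features_from_cluster(cs, kept, prefix)
            methods[f"OTU-{round(t * 100)}%"] = {
                "feats": feats, "ids": ids, "mode": "cluster",
                "absorbed": None, "cluster_set": cs, "t": t,
            }
        if not methods:
            raise ValueError("no reconstruction method enabled")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("reconstruct", str(e)) from e

    # --- chimera flag, QC, tables -----------------------------------
    qc_cfg = qcmod.QCConfig(
        gene=gene.name,
        expected_nt_len=gene.amplicon_len_nt - len(gene.primer_fwd)
        - len(gene.primer_rev),
        reference_protein_panel=[g.protein for g in panel],
    )
    total_reads = sum(len(v) for v in seqs_per_sample.values())
    summary_rows = {}
    tables: dict[str, rc.FeatureTable] = {}
    for name, m in methods.items():
        try:
            flags = rc.flag_chimeras_denovo(m["feats"])
            clean = [f for f in m["feats"] if not flags[f.sequence]]
            features = {m["ids"][f.sequence]: f.sequence for f in clean}
            ft = rc.build_feature_table(
                features, seqs_per_sample, m["mode"], t=m["t"],
                cluster_set=m["cluster_set"], absorbed_into=m["absorbed"],
            )
            verdicts, curated = qcmod.qc_feature_set(features, ft.counts, qc_cfg)
            qsum = qcmod.qc_summary(verdicts, ft.counts)
            curated_seqs = {fid: features[fid] for fid in curated.index}
            tables[name] = rc.FeatureTable(curated, curated_seqs, ft.unassigned)
            _write(curated, outdir / "tables" / f"{name}.tsv")
            with open(outdir / "tables" / f"{name}.fasta", "w") as fh:
                for fid, seq in curated_seqs.items():
                    fh.write(f">{fid}\n{seq}\n")
            summary_rows[name] = {
                "raw_reads": total_reads,
                "chimera_flagged": int(sum(flags.values())),
                "unique_features": len(features),
                "reads_in_features": int(ft.counts.values.sum()),
                "pct_reads_converted": 100.0 * ft.counts.values.sum() / total_reads,
                "pct_wrong_features": qsum["pct_failed_features"],
                "pct_reads_retained_after_qc": qsum["pct_reads_retained"],
                "final_unique_features": int(curated.shape[0]),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError(f"features:{name}", str(e)) from e
    feature_summary = pd.DataFrame(summary_rows).T
    _write(feature_summary, outdir / "feature_summary.tsv")
    report["feature_summary"] = summary_rows

    # --- alpha diversity / rarefaction curves -----------------------
    try:
        alpha_rows = []
        curve_rows = []
        for name, ft in tables.items():
            for sample in ft.counts.columns:
                counts = ft.counts[sample].values
                rar = dv.rarefy_counts(counts, config.rarefaction_depth,
                                       seed=derive_seed(config.seed, f"alpha:{name}:{sample}"))
                if rar.excluded:
                    alpha_rows.append({"method": name, "sample": sample,
                                       "excluded": True, "richness": np.nan,
                                       "shannon": np.nan, "simpson": np.nan})
                    continue
                depth = min(config.rarefaction_depth, int(counts.sum()))
                alpha_rows.append({
                    "method": name, "sample": sample, "excluded": False,
                    "richness": dv.expected_richness(counts, depth),
                    "shannon": dv.shannon(rar.counts),
                    "simpson": dv.simpson(rar.counts),
                })
            # group-averaged rarefaction curves
            for g in range(config.n_groups):
                cols = [s for s in ft.counts.columns
                        if design.sample_group(s) == g]
                avg = np.rint(ft.counts[cols].mean(axis=1).values).astype(int)
                total = int(avg.sum())
                if total < 2:
                    continue
                depths = np.unique(np.linspace(1, total, 20).astype(int))
                for d, richness in zip(depths,
                                       dv.rarefaction_curve(avg, depths)):
                    curve_rows.append({"method": name, "group": g + 1,
                                       "depth": int(d), "richness": richness})
        alpha = pd.DataFrame(alpha_rows)
        _write(alpha, outdir / "alpha_diversity.tsv", index=False)
        _write(pd.DataFrame(curve_rows), outdir / "rarefaction_curves.tsv",
               index=False)
        report["alpha"] = alpha.to_dict("records")
    except Exception as e:  # noqa: BLE001
        raise StageError("alpha", str(e)) from e

    # --- beta diversity: distances, PERMANOVA, Mantel ----------------
    try:
        groups = [str(design.sample_group(s) + 1)
                  for s in design.sample_names]
        distances: dict[tuple, object] = {}
        perma_rows = {}
        for name, ft in tables.items():
            tree = None
            if ft.counts.shape[0] >= 3:
                dm = dv.nt_distance_matrix(ft.sequences)
                tree = dv.nj_tree(dm)
                tree.write(str(outdir / "tables" / f"{name}.nwk"))
            for metric in ("BC", "U", "WU"):
                if metric == "BC":
                    D = dv.bray_curtis(ft.counts)
                elif tree is None:
                    continue
                else:
                    D = dv.unifrac_matrix(tree, ft.counts,
                                          weighted=(metric == "WU"))
                distances[(name, metric)] = D
                _write(pd.DataFrame(D.data, index=D.ids, columns=D.ids),
                       outdir / "distances" / f"{name}_{metric}.tsv")
                try:
                    res = st.permanova(
                        D, groups, n_perm=config.permanova_perms,
                        seed=derive_seed(config.seed,
                                         f"permanova:{name}:{metric}"))
                except ValueError as ve:
                    log.warning("permanova skipped for %s|%s: %s",
                                name, metric, ve)
                    continue
                perma_rows[f"{name}|{metric}"] = {
                    "pseudo_F": res.pseudo_F, "R2": res.R2, "p": res.p,
                }
        _write(pd.DataFrame(perma_rows).T, outdir / "permanova.tsv")
        report["permanova"] = perma_rows
        mantel_rows = {}
        names = list(tables)
        for metric in ("BC", "U", "WU"):
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    k1, k2 = (names[i], metric), (names[j], metric)
                    if k1 not in distances or k2 not in distances:
                        continue
                    try:
                        res = st.mantel_test(
                            distances[k1], distances[k2],
                            n_perm=config.mantel_perms,
                            seed=derive_seed(
                                config.seed,
                                f"mantel:{metric}:{names[i]}:{names[j]}"))
                    except ValueError as ve:
                        log.warning("mantel skipped for %s~%s|%s: %s",
                                    names[i], names[j], metric, ve)
                        continue
                    mantel_rows[f"{names[i]}~{names[j]}|{metric}"] = {
                        "r": res.r, "p": res.p,
                    }
        _write(pd.DataFrame(mantel_rows).T, outdir / "mantel.tsv")
        report["mantel"] = mantel_rows
    except Exception as e:  # noqa: BLE001
        raise StageError("beta", str(e)) from e

    # --- covariates + CCA -------------------------------------------
    try:
        rng = rng_for(config.seed, "covariates")
        n_samples = len(design.sample_names)
        cov = pd.DataFrame(
            rng.normal(size=(n_samples, len(COVARIATES))),
            index=design.sample_names, columns=list(COVARIATES),
        )
        # ammonia tracks the group contrast (the planted driver)
        grp = np.array([design.sample_group(s) for s in design.sample_names])
        cov["NH3"] = grp * 2.0 + rng.normal(scale=0.5, size=n_samples)
        _write(cov, outdir / "covariates.tsv")
        cca_rows = {}
        for name, ft in tables.items():
            resp = st.hellinger(ft.counts.T)  # samples x features
            model = st.stepwise_select(
                resp, cov, n_perm=config.cca_perms,
                seed=derive_seed(config.seed, f"cca:{name}"))
            cca_rows[name] = {v: p for v, p in model.selected}
        drivers = pd.DataFrame(cca_rows).T.reindex(columns=list(COVARIATES))
        _write(drivers, outdir / "cca_drivers.tsv")
        report["cca_drivers"] = {k: dict(v) for k, v in cca_rows.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("cca", str(e)) from e

    # --- tree congruence ---------------------------------------------
    try:
        refs = {
            f"ref_{tid}": seq
            for tid, seq in syn.derive_taxa(
                gene, config.congruence_refs, 0.85,
                derive_seed(config.seed, "congruence_refs"))
        }
        congr = {}
        if config.variant_mode and len(tables) > 1:
            asv = tables["ASV"]
            asv_feats = [(fid, asv.sequences[fid]) for fid in asv.counts.index]
            for name in tables:
                if name == "ASV":
                    continue
                ft = tables[name]
                feats = [(fid, ft.sequences[fid]) for fid in ft.counts.index]
                curve = cg.incremental_congruence(
                    asv_feats, feats, refs, max_iter=config.congruence_max_iter)
                fit = cg.fit_log_curve(curve) if len(curve.points) >= 2 else None
                congr[f"ASV~{name}"] = {
                    "curve": curve.points,
                    "fit": None if fit is None else
                    {"a": fit.a, "b": fit.b, "rmse": fit.rmse},
                }
        with open(outdir / "congruence.json", "w") as fh:
            json.dump(congr, fh, indent=1, sort_keys=True)
        report["congruence"] = congr
    except Exception as e:  # noqa: BLE001
        raise StageError("congruence", str(e)) from e

    # --- taxonomy contrast -------------------------------------------
    try:
        db_near, db_far = tax.build_synthetic_db(
            panel, config.db_genera, config.db_species_per_genus,
            config.db_divergence_near, config.db_divergence_far,
            derive_seed(config.seed, "taxonomy_db"))
        name0 = "ASV" if "ASV" in tables else next(iter(tables))
        queries = list(tables[name0].sequences.values())
        contrast = tax.compare_classifiers(
            queries, db_near, db_far,
            seed=derive_seed(config.seed, "taxonomy"))
        _write(contrast, outdir / "taxonomy_contrast.tsv")
        report["taxonomy"] = {
            f"{m}|{d}": dict(row) for (m, d), row in contrast.iterrows()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("taxonomy", str(e)) from e

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
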