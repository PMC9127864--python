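"""End-to-end orchestration of the repertoire comparison analysis.

``run_pipeline`` executes the full analysis sequence on either a simulated
cohort or user-supplied tables: ingest/collapse -> diversity profiling ->
pairwise similarity with group tests -> usage/RDI -> specificity clustering
-> antigen annotation with subsampled-evenness comparisons -> P_gen
coupling with its paired group test and the non-clustered top-rank
comparison -> clinical association with FDR.  Every stage writes a TSV/CSV
table into the output directory and a JSON manifest records seeds,
parameters and per-stage wall time, which suffices to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    assign_antigen_features,
    cluster_reference_db,
    subsampled_mean_evenness,
)
from .clustering import classify_and_merge, enriched_motifs, global_clusters, motif_clusters
from .core import (
    Clonotype,
    Cohort,
    GROUP_CASE,
    GROUP_CONTROL,
    Repertoire,
    collapse_by_cdr3aa,
    compute_frequencies,
)
from .diversity import (
    clone_size_spectrum,
    cumulative_top_fraction,
    diversity_profile,
    hill_number,
    pielou_evenness,
)
from .generation import GenerationModel, default_model, pgen_exact, sample_many
from .io import read_clonotype_table, read_reference_db, write_clonotype_table
from .similarity import pairwise_matrix
from .simulate import SimConfig, simulate_cohort
from .stats import (
    bh_fdr,
    clinical_association,
    freq_pgen_correlation,
    paired_wilcoxon,
    ranksum,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("tcrep")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulation`` (a :class:`tcrep.simulate.SimConfig`
    parameter mapping) or ``inputs`` (paths to clonotype tables, a subject
    metadata table, a reference DB, and optionally a clinical table /
    precomputed P_gen table) must be provided.
    """

    outdir: str | Path
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None
    subsample_n: int = 100
    top_fractions: tuple[float, float] = (0.1, 0.01)
    rdi_n_iter: int = 25
    clinical_features: tuple[str, ...] = ("PAC", "ARR", "PRA", "sodium")
    make_report: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


def _load_inputs(inputs: dict) -> tuple[Cohort, object, pd.DataFrame | None, dict]:
    meta = pd.read_csv(inputs["subjects"], sep=None, engine="python")
    reps = []
    pairs: dict[str, dict[str, str]] = {}
    for _, row in meta.iterrows():
        rep = read_clonotype_table(
            row["path"], dialect=inputs.get("dialect", "airr"),
            subject_id=row["subject_id"], group=row["group"], pair_id=row["pair_id"],
        )
        reps.append(rep)
        pairs.setdefault(row["pair_id"], {})[row["group"]] = row["subject_id"]
    pair_list = [
        (d[GROUP_CASE], d[GROUP_CONTROL])
        for d in pairs.values()
        if GROUP_CASE in d and GROUP_CONTROL in d
    ]
    cohort = Cohort(repertoires=reps, pairs=pair_list)
    db = read_reference_db(inputs["reference_db"])
    clinical = (
        pd.read_csv(inputs["clinical"], sep=None, engine="python")
        if inputs.get("clinical")
        else None
    )
    pgen_source: dict = {}
    if inputs.get("pgen_table"):
        tbl = pd.read_csv(inputs["pgen_table"], sep="\t")
        pgen_source = {"table": dict(zip(tbl["cdr3_aa"], tbl["pgen"]))}
    elif inputs.get("model"):
        pgen_source = {"model": GenerationModel.from_json(inputs["model"])}
    return cohort, db, clinical, pgen_source


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "parameters": {
            "subsample_n": config.subsample_n,
            "top_fractions": list(config.top_fractions),
            "rdi_n_iter": config.rdi_n_iter,
        },
    }
    t_all = time.time()

    def stage(name):
        t0 = time.time()

        def done(**extra):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **extra}
            log.info("stage %-22s %6.2fs %s", name, time.time() - t0, extra or "")

        return done

    model = default_model()
    # ---- ingest ----
    done = stage("ingest")
    if config.simulation is not None:
        sim = SimConfig(master_seed=config.seed, **config.simulation)
        cohort, db, clinical, truth = simulate_cohort(sim, model)
        truth.to_json(outdir / "truth.json")
        manifest["parameters"]["simulation"] = {
            k: getattr(sim, k) for k in sim.__dataclass_fields__
        }
        pgen_source = {"model": model}
    else:
        cohort, db, clinical, pgen_source = _load_inputs(config.inputs)
        if not pgen_source:
            pgen_source = {"model": model}
    cohort = Cohort(
        repertoires=[
            compute_frequencies(collapse_by_cdr3aa(r)) for r in cohort.repertoires
        ],
        pairs=cohort.pairs,
    )
    rep_dir = outdir / "repertoires"
    rep_dir.mkdir(exist_ok=True)
    for r in cohort.repertoires:
        write_clonotype_table(r, rep_dir / f"{r.subject_id}.tsv")
    done(n_subjects=len(cohort.repertoires), n_pairs=len(cohort.pairs))

    # ---- diversity (evenness, spectra, hyperexpanded comparison) ----
    done = stage("diversity")
    div_rows = []
    for r in cohort.repertoires:
        freqs = r.frequencies()
        spec = clone_size_spectrum(r)
        row = {
            "subject_id": r.subject_id, "group": r.group, "pair_id": r.pair_id,
            "richness": len(r), "shannon_exp": hill_number(freqs, 1.0),
            "pielou": pielou_evenness(freqs),
        }
        row.update({f"cumfreq_{k}": v for k, v in spec.cumulative_frequency.items()})
        div_rows.append(row)
    div = pd.DataFrame(div_rows)
    div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    profiles = []
    for r in cohort.repertoires:
        prof = diversity_profile(r)
        profiles.append(pd.DataFrame({
            "subject_id": r.subject_id, "group": r.group,
            "alpha": prof.alpha_grid, "hill": prof.hill_values,
            "renyi": prof.renyi_values,
        }))
    pd.concat(profiles, ignore_index=True).to_csv(
        outdir / "diversity_profile.tsv", sep="\t", index=False
    )
    idx = div.set_index("subject_id")
    tests = []
    for metric in ("pielou", "cumfreq_hyper"):
        cmp = paired_wilcoxon(
            idx[metric].to_dict(), idx[metric].to_dict(), cohort.pairs, metric=metric
        )
        tests.append({"metric": metric, "statistic": cmp.statistic, "p": cmp.pvalue,
                      "n": cmp.n_pairs})
    pd.DataFrame(tests).to_csv(outdir / "diversity_tests.tsv", sep="\t", index=False)
    done()

    # ---- similarity: MH matrix + intra/inter rank-sum tests ----
    done = stage("similarity")
    mh = pairwise_matrix(cohort, "MH")
    mh.to_long().to_csv(outdir / "similarity_mh.tsv", sep="\t", index=False)
    classes = [f"intra-{GROUP_CASE}", f"intra-{GROUP_CONTROL}", "inter"]
    comparisons = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    rows = []
    for a, b in comparisons:
        stat, p = ranksum(mh.by_class(a), mh.by_class(b))
        rows.append({"comparison": f"{a} vs {b}", "statistic": stat, "p": p})
    mh_tests = pd.DataFrame(rows)
    mh_tests["p_adjusted"] = bh_fdr(mh_tests["p"])
    mh_tests.to_csv(outdir / "similarity_tests.tsv", sep="\t", index=False)
    done()

    # ---- usage / RDI ----
    done = stage("usage_rdi")
    rdi_long = []
    for feature in ("V", "J", "VJpair", "CDR3length"):
        m = pairwise_matrix(
            cohort, "RDI", feature=feature, n_iter=config.rdi_n_iter,
            seed=config.seed + 17,
        )
        t = m.to_long()
        t["feature"] = feature
        rdi_long.append(t)
    rdi = pd.concat(rdi_long, ignore_index=True)
    rdi.to_csv(outdir / "usage_rdi.tsv", sep="\t", index=False)
    rows = []
    for feature in ("V", "J", "VJpair", "CDR3length"):
        sub = rdi[rdi["feature"] == feature]
        intra = sub[sub["pair_class"] != "inter"]["value"]
        inter = sub[sub["pair_class"] == "inter"]["value"]
        stat, p = ranksum(intra, inter)
        rows.append({"feature": feature, "comparison": "intra vs inter",
                     "statistic": stat, "p": p})
    rdi_tests = pd.DataFrame(rows)
    rdi_tests["p_adjusted"] = bh_fdr(rdi_tests["p"])
    rdi_tests.to_csv(outdir / "usage_rdi_tests.tsv", sep="\t", index=False)
    done()

    # ---- clustering + annotation ----
    done = stage("clustering_annotation")
    bg_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 999)))
    bg_seqs, bg_v, bg_j = sample_many(model, 2000, bg_rng)
    background = compute_frequencies(Repertoire(
        subject_id="background", group="", pair_id="",
        clonotypes=[
            Clonotype(cdr3_aa=s, v_allele=f"{v}*01", j_allele=f"{j}*01", count=1)
            for s, v, j in _dedupe(bg_seqs, bg_v, bg_j)
        ],
    ))
    clustered_ref = cluster_reference_db(db, background)
    ann_rows = []
    cluster_rows = []
    per_subject_features = {}
    for r in cohort.repertoires:
        gg = global_clusters(r)
        motifs = enriched_motifs(r, background)
        mg = motif_clusters(r, motifs)
        clusters, non_clustered = classify_and_merge(
            gg, mg, all_cdr3=r.cdr3_set(), id_prefix=f"{r.subject_id}_C"
        )
        feats = assign_antigen_features(r, clusters, non_clustered, db, clustered_ref)
        per_subject_features[r.subject_id] = feats
        for cl in clusters:
            cluster_rows.append({
                "subject_id": r.subject_id, "cluster_id": cl.cluster_id,
                "cluster_type": cl.cluster_type,
                "motifs": ";".join(cl.enriched_motifs),
                "members": ";".join(sorted(cl.members)),
            })
        vg = {c.cdr3_aa: c.v_gene for c in r.clonotypes}
        for f in feats:
            ann_rows.append({
                "subject_id": r.subject_id, "cdr3_aa": f.cdr3_aa,
                "v_gene": vg[f.cdr3_aa], "specificity": f.specificity,
                "cluster_status": f.cluster_status,
                "epitopes": ";".join(f.matched_epitopes),
            })
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(ann_rows).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    done(n_clusters=len(cluster_rows))

    # ---- annotation-stratified diversity + subsampled comparisons ----
    done = stage("annotation_diversity")
    rows = []
    for r in cohort.repertoires:
        feats = per_subject_features[r.subject_id]
        common = {f.cdr3_aa for f in feats if f.specificity == "common"}
        by_key = {c.cdr3_aa: c for c in r.clonotypes}
        common_cl = [by_key[a] for a in common]
        noncommon_cl = [c for c in r.clonotypes if c.cdr3_aa not in common]
        size = len(common_cl)
        row = {"subject_id": r.subject_id, "group": r.group, "n_common": size,
               "n_non_common": len(noncommon_cl)}
        for label, cl in (("common", common_cl), ("non_common", noncommon_cl)):
            if len(cl) >= 2:
                counts = np.array([c.count for c in cl], dtype=float)
                row[f"pielou_{label}"] = pielou_evenness(counts / counts.sum())
        if 2 <= size <= len(noncommon_cl):
            row["subsampled_non_common"] = subsampled_mean_evenness(
                noncommon_cl, size, config.subsample_n,
                rng=np.random.default_rng(np.random.SeedSequence((config.seed, 1, _stable_id(r.subject_id)))),
            )
            row["subsampled_all"] = subsampled_mean_evenness(
                list(r.clonotypes), size, config.subsample_n,
                rng=np.random.default_rng(np.random.SeedSequence((config.seed, 2, _stable_id(r.subject_id)))),
            )
        rows.append(row)
    ann_div = pd.DataFrame(rows)
    ann_div.to_csv(outdir / "annotation_diversity.tsv", sep="\t", index=False)
    idx = ann_div.set_index("subject_id")
    tests = []
    for metric in ("pielou_non_common", "pielou_common",
                   "subsampled_non_common", "subsampled_all"):
        if metric in idx.columns and idx[metric].notna().all():
            cmp = paired_wilcoxon(
                idx[metric].to_dict(), idx[metric].to_dict(), cohort.pairs, metric=metric
            )
            tests.append({"metric": metric, "statistic": cmp.statistic,
                          "p": cmp.pvalue, "n": cmp.n_pairs})
    pd.DataFrame(tests).to_csv(outdir / "annotation_tests.tsv", sep="\t", index=False)
    done()

    # ---- P_gen coupling + group test + non-clustered top fractions ----
    done = stage("pgen_coupling")
    coupling = []
    rows = []
    pgen_cache: dict[str, float] = {}
    for r in cohort.repertoires:
        if "table" in pgen_source:
            table = pgen_source["table"]
        else:
            mdl = pgen_source["model"]
            table = {}
            for c in r.clonotypes:
                if c.cdr3_aa not in pgen_cache:
                    pgen_cache[c.cdr3_aa] = pgen_exact(mdl, c.cdr3_aa).pgen
                table[c.cdr3_aa] = pgen_cache[c.cdr3_aa]
        res = freq_pgen_correlation(r, table)
        coupling.append(res)
        row = {"subject_id": r.subject_id, "group": r.group, "pair_id": r.pair_id,
               "r": res.r, "p": res.pvalue, "n_used": res.n_used,
               "n_excluded": res.n_excluded}
        feats = per_subject_features[r.subject_id]
        ncl = {f.cdr3_aa for f in feats if f.cluster_status == "non_clustered"}
        sub = [c for c in r.clonotypes if c.cdr3_aa in ncl]
        if sub:
            counts = np.array([c.count for c in sub], dtype=float)
            sub_rep = compute_frequencies(Repertoire(
                subject_id=r.subject_id, group=r.group, pair_id=r.pair_id,
                clonotypes=sub,
            ))
            for q in config.top_fractions:
                row[f"nonclustered_top_{q:g}"] = cumulative_top_fraction(sub_rep, q)
        rows.append(row)
    coup = pd.DataFrame(rows)
    coup.to_csv(outdir / "pgen_coupling.tsv", sep="\t", index=False)
    idx = coup.set_index("subject_id")
    tests = []
    metrics = ["r"] + [f"nonclustered_top_{q:g}" for q in config.top_fractions]
    for metric in metrics:
        if metric in idx.columns and idx[metric].notna().all():
            cmp = paired_wilcoxon(
                idx[metric].to_dict(), idx[metric].to_dict(), cohort.pairs, metric=metric
            )
            tests.append({"metric": metric, "statistic": cmp.statistic,
                          "p": cmp.pvalue, "n": cmp.n_pairs})
    pd.DataFrame(tests).to_csv(outdir / "pgen_tests.tsv", sep="\t", index=False)
    done()

    # ---- clinical association ----
    done = stage("clinical")
    if clinical is not None:
        features = [f for f in config.clinical_features if f in clinical.columns]
        blocks = []
        for scope in ("all", GROUP_CASE, GROUP_CONTROL):
            assoc = clinical_association(coupling, clinical, features, scope=scope)
            assoc["p_adjusted"] = bh_fdr(assoc["p"])
            blocks.append(assoc)
        pd.concat(blocks, ignore_index=True).to_csv(
            outdir / "clinical_association.tsv", sep="\t", index=False
        )
    done(skipped=clinical is None)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stable_id(s: str) -> int:
    import zlib

    return zlib.crc32(s.encode())


def _dedupe(seqs, vs, js):
    seen = set()
    for s, v, j in zip(seqs, vs, js):
        if s not in seen:
            seen.add(s)
            yield s, v, j


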