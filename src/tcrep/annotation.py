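"""Common-antigen annotation of clonotypes and clusters against a reference DB.

Two complementary strategies identify clonotypes with *common* (public,
database-documented) antigen specificity:

1. **exact** — the clonotype's V gene and CDR3 amino-acid sequence are
   identical to a reference entry;
2. **fuzzy / motif** — the reference is first grouped by epitope and each
   epitope group is clustered with the same machinery used for query
   repertoires.  A query clonotype matching a *global-clustered* reference
   entry on V gene, CDR3 length, and Hamming distance <= 1 (one
   substitution, no indels) is annotated; a query *motif* cluster whose
   enriched motif equals a reference motif annotates all its members.

Common status propagates to a whole cluster when at least one member
matches.  Everything else is non-common.  The diversity of the non-common
(or whole) compartment is compared across subjects via repeated fixed-size
subsampling of unique clonotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import (
    TCRCluster,
    classify_and_merge,
    enriched_motifs,
    global_clusters,
    motif_clusters,
)
from .core import (
    Clonotype,
    DegenerateInputError,
    ReferenceDB,
    Repertoire,
    normalize_gene,
)
from .diversity import pielou_evenness

__all__ = [
    "AntigenFeature",
    "ClusteredReference",
    "match_exact",
    "cluster_reference_db",
    "match_fuzzy",
    "match_motif",
    "assign_antigen_features",
    "subsampled_mean_evenness",
]


@dataclass
class AntigenFeature:
    """Per-clonotype annotation record (exactly one per clonotype)."""

    cdr3_aa: str
    specificity: str  # "common" | "non_common"
    cluster_status: str  # "clustered" | "non_clustered"
    matched_epitopes: tuple[str, ...] = ()


def match_exact(c: Clonotype, db: ReferenceDB) -> list[str]:
    """Epitope labels of reference entries identical in V gene and CDR3."""
    vg = c.v_gene
    return sorted({epi for v, cdr3, epi in db.entries if v == vg and cdr3 == c.cdr3_aa})


@dataclass
class ClusteredReference:
    """Reference DB after per-epitope clustering.

    ``global_entries`` are reference entries belonging to a global cluster
    within their epitope group; ``motifs`` maps an enriched motif of a
    reference motif cluster to the epitopes it tags.
    """

    global_entries: list[tuple[str, str, str]]
    motifs: dict[str, tuple[str, ...]] = field(default_factory=dict)


def cluster_reference_db(
    db: ReferenceDB,
    background: Repertoire | None = None,
    **motif_params,
) -> ClusteredReference:
    """Cluster the reference per epitope group.

    Global clusters need no background; motif enrichment requires a naive
    ``background`` repertoire and is skipped when none is given.
    """
    global_entries: list[tuple[str, str, str]] = []
    motifs: dict[str, set[str]] = {}
    for epitope in db.epitopes():
        entries = db.by_epitope(epitope)
        seqs = {cdr3 for _, cdr3, _ in entries}
        if len(seqs) < 2:
            continue
        clustered = set().union(*global_clusters(seqs)) if global_clusters(seqs) else set()
        global_entries.extend(e for e in entries if e[1] in clustered)
        if background is not None:
            pseudo = Repertoire(
                subject_id=f"db:{epitope}",
                group="",
                pair_id="",
                clonotypes=[
                    Clonotype(cdr3_aa=s, v_allele=v, j_allele="", count=1)
                    for v, s, _ in entries
                ],
            )
            table = enriched_motifs(pseudo, background, **motif_params)
            for motif, _members in motif_clusters(pseudo, table):
                motifs.setdefault(motif, set()).add(epitope)
    return ClusteredReference(
        global_entries=global_entries,
        motifs={m: tuple(sorted(es)) for m, es in motifs.items()},
    )


def match_fuzzy(c: Clonotype, ref: ClusteredReference) -> list[str]:
    """Epitopes of global-clustered reference entries with the same V gene,
    equal CDR3 length, and at most one substitution (no indels)."""
    vg = c.v_gene
    out: set[str] = set()
    for v, cdr3, epi in ref.global_entries:
        if v != vg or len(cdr3) != len(c.cdr3_aa):
            continue
        if sum(a != b for a, b in zip(cdr3, c.cdr3_aa)) <= 1:
            out.add(epi)
    return sorted(out)


def match_motif(
    query_clusters: list[TCRCluster], ref: ClusteredReference
) -> dict[str, tuple[str, ...]]:
    """Map cluster_id -> epitopes for motif/mixed clusters whose enriched
    motif string equals a reference motif."""
    out: dict[str, tuple[str, ...]] = {}
    for cl in query_clusters:
        if cl.cluster_type == "global":
            continue
        epis: set[str] = set()
        for motif in cl.enriched_motifs:
            epis.update(ref.motifs.get(motif, ()))
        if epis:
            out[cl.cluster_id] = tuple(sorted(epis))
    return out


def assign_antigen_features(
    rep: Repertoire,
    clusters: list[TCRCluster],
    non_clustered: set[str],
    db: ReferenceDB,
    clustered_ref: ClusteredReference | None = None,
) -> list[AntigenFeature]:
    """Annotate every clonotype exactly once.

    All three matchers run per clonotype/cluster; a cluster with at least
    one common member makes every member common.  The output covers each
    clonotype of ``rep`` with one record.
    """
    by_cdr3 = {c.cdr3_aa: c for c in rep.clonotypes}
    exact_index: dict[tuple[str, str], set[str]] = {}
    for v, cdr3, epi in db.entries:
        exact_index.setdefault((v, cdr3), set()).add(epi)

    epitopes: dict[str, set[str]] = {aa: set() for aa in by_cdr3}
    for aa, c in by_cdr3.items():
        epitopes[aa].update(exact_index.get((c.v_gene, aa), ()))
        if clustered_ref is not None:
            epitopes[aa].update(match_fuzzy(c, clustered_ref))
    motif_hits = match_motif(clusters, clustered_ref) if clustered_ref else {}

    cluster_of: dict[str, list[TCRCluster]] = {}
    for cl in clusters:
        for aa in cl.members:
            cluster_of.setdefault(aa, []).append(cl)

    common_clusters: set[str] = set()
    for cl in clusters:
        member_hit = any(epitopes.get(aa) for aa in cl.members if aa in epitopes)
        if member_hit or cl.cluster_id in motif_hits:
            common_clusters.add(cl.cluster_id)
            cluster_epis = set(motif_hits.get(cl.cluster_id, ()))
            for aa in cl.members:
                if aa in epitopes:
                    cluster_epis |= epitopes[aa]
            for aa in cl.members:
                if aa in epitopes:
                    epitopes[aa] |= cluster_epis

    out = []
    for aa in by_cdr3:
        in_cluster = aa in cluster_of
        is_common = bool(epitopes[aa]) or any(
            cl.cluster_id in common_clusters for cl in cluster_of.get(aa, [])
        )
        out.append(
            AntigenFeature(
                cdr3_aa=aa,
                specificity="common" if is_common else "non_common",
                cluster_status="clustered" if in_cluster else "non_clustered",
                matched_epitopes=tuple(sorted(epitopes[aa])),
            )
        )
    return out


def subsampled_mean_evenness(
    clonotypes: list[Clonotype],
    size: int,
    n_sub: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean Pielou evenness over repeated fixed-size clonotype subsamples.

    Each of ``n_sub`` subsamples draws ``size`` unique clonotypes without
    replacement, renormalizes their counts within the subsample, and scores
    Pielou's J'.  Deterministic given a seed.
    """
    n = len(clonotypes)
    if size > n:
        raise DegenerateInputError(f"subsample size {size} exceeds subset size {n}")
    if size < 2:
        raise DegenerateInputError("evenness undefined for subsample size < 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.array([c.count for c in clonotypes], dtype=float)
    vals = np.empty(n_sub)
    for i in range(n_sub):
        idx = rng.choice(n, size=size, replace=False)
        sub = counts[idx]
        vals[i] = pielou_evenness(sub / sub.sum())
    return float(vals.mean())
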