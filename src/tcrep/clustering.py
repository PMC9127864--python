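"""Specificity clustering of CDR3 sequences (simplified GLIPH-style).

Clonotypes likely to share antigen specificity are grouped by two criteria:

* **global similarity** — equal-length CDR3s differing at no more than one
  *interior* position, where the interior excludes the first three and last
  two residues (the conserved junction framework); connected components of
  size >= 2 form global clusters;
* **motif enrichment** — interior k-mers (k = 3, 4) significantly enriched
  in the query repertoire relative to a naive background repertoire
  (one-sided Fisher's exact test on clonotype-level presence counts);
  clonotypes sharing a retained motif form one cluster per motif.

A cluster satisfying both criteria (a global and a motif group sharing at
least one member) is merged and typed ``mixed``; otherwise clusters are
typed ``global`` or ``motif``.  Clonotypes in no cluster are non-clustered.
Clustering is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .core import DegenerateInputError, Repertoire

__all__ = [
    "TCRCluster",
    "interior",
    "global_clusters",
    "enriched_motifs",
    "motif_clusters",
    "classify_and_merge",
]

# interior = CDR3 minus the first INTERIOR_START and last INTERIOR_END residues
INTERIOR_START = 3
INTERIOR_END = 2


def interior(cdr3_aa: str) -> str:
    """Interior of a CDR3: residues 4 .. len-2 (empty if too short)."""
    if len(cdr3_aa) <= INTERIOR_START + INTERIOR_END:
        return ""
    return cdr3_aa[INTERIOR_START : len(cdr3_aa) - INTERIOR_END]


@dataclass
class TCRCluster:
    """A set of clonotypes (CDR3 keys) with predicted shared specificity."""

    cluster_id: str
    members: frozenset[str]
    cluster_type: str  # "global" | "motif" | "mixed"
    enriched_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")
        if self.cluster_type not in ("global", "motif", "mixed"):
            raise ValueError(f"bad cluster_type {self.cluster_type!r}")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def global_clusters(sequences) -> list[frozenset[str]]:
    """Connected components (size >= 2) under the global-similarity relation.

    Two CDR3s are adjacent iff they have equal length, identical first three
    and last two residues, and Hamming distance <= 1 over the interior.
    Accepts a :class:`Repertoire` or an iterable of CDR3 strings.  Pairs are
    found by wildcard hashing (each sequence keyed once per interior position
    with that position masked), so runtime is linear in total sequence length.
    """
    if isinstance(sequences, Repertoire):
        seqs = sorted({c.cdr3_aa for c in sequences.clonotypes})
    else:
        seqs = sorted(set(sequences))
    uf = _UnionFind(len(seqs))
    buckets: dict[tuple[int, int, str], int] = {}
    for idx, s in enumerate(seqs):
        if not interior(s):
            continue
        for pos in range(INTERIOR_START, len(s) - INTERIOR_END):
            key = (len(s), pos, s[:pos] + "\x00" + s[pos + 1 :])
            if key in buckets:
                uf.union(buckets[key], idx)
            else:
                buckets[key] = idx
    # a masked key collides for *all* sequences sharing it, and union() chains
    # them transitively, which matches connected components of Hamming-1 edges
    comps: dict[int, set[str]] = {}
    for idx, s in enumerate(seqs):
        comps.setdefault(uf.find(idx), set()).add(s)
    return [frozenset(m) for m in comps.values() if len(m) >= 2]


def _interior_kmers(cdr3_aa: str, k_set) -> set[str]:
    inner = interior(cdr3_aa)
    found: set[str] = set()
    for k in k_set:
        for i in range(len(inner) - k + 1):
            found.add(inner[i : i + k])
    return found


def enriched_motifs(
    rep: Repertoire,
    reference: Repertoire,
    k_set=(3, 4),
    min_fold: float = 10.0,
    max_p: float = 1e-3,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Interior k-mers enriched in ``rep`` relative to a naive background.

    Presence is counted per unique clonotype.  Each k-mer present in the
    query is tested with a one-sided Fisher's exact test against the
    reference; retained motifs need fold enrichment >= ``min_fold``
    (pseudocounted frequency ratio) and p <= ``max_p``.  Returns a table
    with columns motif, k, query_count, ref_count, fold, p, sorted by
    ascending p then motif.
    """
    if len(reference) == 0:
        raise DegenerateInputError("empty motif reference repertoire")
    q_sets = [_interior_kmers(c.cdr3_aa, k_set) for c in rep.clonotypes]
    r_sets = [_interior_kmers(c.cdr3_aa, k_set) for c in reference.clonotypes]
    n_q, n_r = len(q_sets), len(r_sets)
    q_counts: dict[str, int] = {}
    for s in q_sets:
        for m in s:
            q_counts[m] = q_counts.get(m, 0) + 1
    r_counts: dict[str, int] = {}
    for s in r_sets:
        for m in s:
            r_counts[m] = r_counts.get(m, 0) + 1

    rows = []
    for motif, qc in q_counts.items():
        rc = r_counts.get(motif, 0)
        fold = ((qc + pseudocount) / (n_q + pseudocount)) / (
            (rc + pseudocount) / (n_r + pseudocount)
        )
        if fold < min_fold:
            continue
        _, p = fisher_exact([[qc, n_q - qc], [rc, n_r - rc]], alternative="greater")
        if p <= max_p:
            rows.append(
                {"motif": motif, "k": len(motif), "query_count": qc,
                 "ref_count": rc, "fold": fold, "p": p}
            )
    out = pd.DataFrame(rows, columns=["motif", "k", "query_count", "ref_count", "fold", "p"])
    return out.sort_values(["p", "motif"], ignore_index=True)


def motif_clusters(rep: Repertoire, motifs: pd.DataFrame) -> list[tuple[str, frozenset[str]]]:
    """One cluster per retained motif: all clonotypes whose CDR3 interior
    contains the motif.  A clonotype may join several motif clusters."""
    out: list[tuple[str, frozenset[str]]] = []
    for motif in motifs["motif"]:
        members = frozenset(
            c.cdr3_aa for c in rep.clonotypes if motif in interior(c.cdr3_aa)
        )
        if len(members) >= 2:
            out.append((motif, members))
    return out


def classify_and_merge(
    global_groups: list[frozenset[str]],
    motif_groups: list[tuple[str, frozenset[str]]],
    all_cdr3: set[str] | None = None,
    id_prefix: str = "C",
) -> tuple[list[TCRCluster], set[str]]:
    """Type clusters and merge global/motif groups that share members.

    A global group overlapping (>= 1 shared member) one or more motif groups
    merges with them into a single ``mixed`` cluster carrying the union of
    members and motifs; remaining groups are typed ``global`` or ``motif``.
    If ``all_cdr3`` is given, the second return value is the set of
    clonotypes belonging to no cluster.  Cluster ids are assigned in a
    deterministic order (sorted smallest member).
    """
    n_g, n_m = len(global_groups), len(motif_groups)
    uf = _UnionFind(n_g + n_m)
    for gi, g in enumerate(global_groups):
        for mi, (_, m) in enumerate(motif_groups):
            if g & m:
                uf.union(gi, n_g + mi)

    comps: dict[int, dict] = {}
    for gi, g in enumerate(global_groups):
        c = comps.setdefault(uf.find(gi), {"members": set(), "motifs": [], "g": 0, "m": 0})
        c["members"] |= g
        c["g"] += 1
    for mi, (motif, m) in enumerate(motif_groups):
        c = comps.setdefault(uf.find(n_g + mi), {"members": set(), "motifs": [], "g": 0, "m": 0})
        c["members"] |= m
        c["motifs"].append(motif)
        c["m"] += 1

    drafts = []
    for c in comps.values():
        if c["g"] and c["m"]:
            ctype = "mixed"
        elif c["g"]:
            ctype = "global"
        else:
            ctype = "motif"
        drafts.append((min(c["members"]), ctype, c["members"], tuple(sorted(c["motifs"]))))
    drafts.sort(key=lambda t: t[0])
    clusters = [
        TCRCluster(
            cluster_id=f"{id_prefix}{i:04d}",
            members=frozenset(members),
            cluster_type=ctype,
            enriched_motifs=motifs,
        )
        for i, (_, ctype, members, motifs) in enumerate(drafts)
    ]
    clustered = set().union(*(c.members for c in clusters)) if clusters else set()
    non_clustered = (all_cdr3 - clustered) if all_cdr3 is not None else set()
    return clusters, non_clustered
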