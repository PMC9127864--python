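"""Core data model for TCR-beta clonotype repertoires.

A *clonotype* is keyed by its CDR3 amino-acid sequence together with
representative V/J gene-segment calls and an abundance (read or template
count).  A *repertoire* is one subject's collection of clonotypes plus
group/pair metadata; a *cohort* is a set of repertoires with an explicit
case/control pairing (age-matched design).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "AMINO_ACIDS",
    "GROUP_CASE",
    "GROUP_CONTROL",
    "Clonotype",
    "Repertoire",
    "Cohort",
    "ReferenceDB",
    "RepertoireFormatError",
    "DegenerateInputError",
    "collapse_by_cdr3aa",
    "compute_frequencies",
    "normalize_gene",
]

#: The 20 standard amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Group labels for the paired case/control design (APA-like vs EH-like).
GROUP_CASE = "APA"
GROUP_CONTROL = "EH"


class RepertoireFormatError(ValueError):
    """Malformed input table (missing column, empty file, bad dialect)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g. zero total count)."""


def normalize_gene(call: str) -> str:
    """Reduce a V/J allele call to gene level by stripping the ``*NN`` suffix.

    ``"TRBV19*01"`` -> ``"TRBV19"``.  Gene-level comparison is used for
    antigen annotation (reference databases record genes, aligners emit
    alleles); the full allele string is retained for usage profiling.
    """
    return call.split("*", 1)[0].strip()


@dataclass
class Clonotype:
    """One unique CDR3 amino-acid sequence with representative V/J calls.

    ``cdr3_nt_variants`` holds the underlying nucleotide-level variants as
    ``(nt_sequence, count)`` pairs when known (pre-/post-collapse); ``count``
    must equal their sum whenever variants are present.
    """

    cdr3_aa: str
    v_allele: str
    j_allele: str
    count: int
    frequency: float | None = None
    cdr3_nt_variants: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if not _AA_SET.issuperset(self.cdr3_aa):
            bad = sorted(set(self.cdr3_aa) - _AA_SET)
            raise ValueError(f"cdr3_aa contains non-standard residues: {bad}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.cdr3_nt_variants:
            total = sum(c for _, c in self.cdr3_nt_variants)
            if total != self.count:
                raise ValueError(
                    f"count ({self.count}) != sum of nt-variant counts ({total})"
                )
        if self.frequency is not None and self.frequency < 0:
            raise ValueError("frequency must be >= 0")

    @property
    def v_gene(self) -> str:
        return normalize_gene(self.v_allele)

    @property
    def j_gene(self) -> str:
        return normalize_gene(self.j_allele)


@dataclass
class Repertoire:
    """One subject's clonotype collection with group/pair metadata."""

    subject_id: str
    group: str
    pair_id: str
    clonotypes: list[Clonotype]
    #: free-form bookkeeping (e.g. number of non-productive rows dropped)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clonotypes:
            raise DegenerateInputError(
                f"repertoire {self.subject_id!r} has no clonotypes"
            )

    def __len__(self) -> int:
        return len(self.clonotypes)

    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def frequencies(self) -> list[float]:
        missing = [c.cdr3_aa for c in self.clonotypes if c.frequency is None]
        if missing:
            raise DegenerateInputError(
                "frequencies unset; call compute_frequencies first"
            )
        return [c.frequency for c in self.clonotypes]  # type: ignore[misc]

    def cdr3_set(self) -> set[str]:
        return {c.cdr3_aa for c in self.clonotypes}


@dataclass
class Cohort:
    """Paired case/control repertoire collection.

    ``pairs`` lists ``(case_subject_id, control_subject_id)`` tuples; every
    pair must reference existing subjects of opposite groups.
    """

    repertoires: list[Repertoire]
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        by_id = {r.subject_id: r for r in self.repertoires}
        if len(by_id) != len(self.repertoires):
            raise ValueError("duplicate subject_id in cohort")
        for case_id, ctrl_id in self.pairs:
            if case_id not in by_id or ctrl_id not in by_id:
                raise ValueError(f"pair ({case_id}, {ctrl_id}) references unknown subject")
            if by_id[case_id].group == by_id[ctrl_id].group:
                raise ValueError(f"pair ({case_id}, {ctrl_id}) not of opposite groups")
        pair_ids = [by_id[a].pair_id for a, _ in self.pairs]
        if len(set(pair_ids)) != len(pair_ids):
            raise ValueError("pair_ids not unique across pairs")

    def subject(self, subject_id: str) -> Repertoire:
        for r in self.repertoires:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    def by_group(self, group: str) -> list[Repertoire]:
        return [r for r in self.repertoires if r.group == group]


@dataclass
class ReferenceDB:
    """Reference of antigen-specific TCRs: ``(v_gene, cdr3_aa, epitope)`` rows.

    Entries are unique on the full triple; V genes are stored allele-free.
    """

    entries: list[tuple[str, str, str]]
    #: rows rejected at read time (empty epitope etc.)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("reference entries not unique")
        for v, cdr3, epi in self.entries:
            if not epi:
                raise ValueError("empty epitope label in reference entry")

    def __len__(self) -> int:
        return len(self.entries)

    def epitopes(self) -> list[str]:
        return sorted({e for _, _, e in self.entries})

    def by_epitope(self, epitope: str) -> list[tuple[str, str, str]]:
        return [t for t in self.entries if t[2] == epitope]


def collapse_by_cdr3aa(rep: Repertoire) -> Repertoire:
    """Merge clonotypes sharing a CDR3 amino-acid sequence.

    Counts of the distinct nucleotide variants are accumulated, and the V/J
    alleles of the dominant (highest-count) nucleotide variant become the
    representative calls.  Dominance ties break on the lexicographically
    smallest nucleotide sequence, so the result is deterministic.  Idempotent:
    collapsing a collapsed repertoire is the identity.
    """
    merged: dict[str, list[Clonotype]] = {}
    order: list[str] = []
    for c in rep.clonotypes:
        if c.cdr3_aa not in merged:
            merged[c.cdr3_aa] = []
            order.append(c.cdr3_aa)
        merged[c.cdr3_aa].append(c)

    out: list[Clonotype] = []
    for aa in order:
        group = merged[aa]
        if len(group) == 1:
            out.append(replace(group[0], frequency=None))
            continue
        # each input clonotype contributes its nt variants (or a synthetic
        # variant equal to itself when variants are absent)
        variants: list[tuple[str, int, str, str]] = []
        for c in group:
            if c.cdr3_nt_variants:
                variants.extend((nt, n, c.v_allele, c.j_allele) for nt, n in c.cdr3_nt_variants)
            else:
                variants.append(("", c.count, c.v_allele, c.j_allele))
        total = sum(n for _, n, _, _ in variants)
        # dominant nt variant; ties break on lexicographically smallest nt
        top = max(n for _, n, _, _ in variants)
        dominant = min((v for v in variants if v[1] == top), key=lambda t: t[0])
        out.append(
            Clonotype(
                cdr3_aa=aa,
                v_allele=dominant[2],
                j_allele=dominant[3],
                count=total,
                cdr3_nt_variants=[(nt, n) for nt, n, _, _ in variants if nt],
            )
        )
    return Repertoire(rep.subject_id, rep.group, rep.pair_id, out, dict(rep.meta))


def compute_frequencies(rep: Repertoire) -> Repertoire:
    """Set clonotype frequencies to count / total count (sums to 1)."""
    total = rep.total_count()
    if total <= 0:
        raise DegenerateInputError(
            f"repertoire {rep.subject_id!r} has zero total count"
        )
    clons = [replace(c, frequency=c.count / total) for c in rep.clonotypes]
    return Repertoire(rep.subject_id, rep.group, rep.pair_id, clons, dict(rep.meta))
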