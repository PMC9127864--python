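"""Readers and writers for clonotype tables and reference databases.

Two table dialects are supported:

* ``airr`` — AIRR Rearrangement TSV with columns ``duplicate_count``,
  ``junction``, ``junction_aa``, ``v_call``, ``j_call``;
* ``mixcr`` — MiXCR clone-table export with columns ``cloneCount``,
  ``nSeqCDR3``, ``aaSeqCDR3``, ``allVHitsWithScore``, ``allJHitsWithScore``
  (hit strings like ``"TRBV9*00(1200)"``; the best hit is kept and its
  alignment score stripped).

Rows whose CDR3 amino-acid sequence contains out-of-alphabet characters
(``*`` stop codons, ``_`` frameshifts) are non-productive and dropped; the
dropped-row count is recorded in ``Repertoire.meta["n_nonproductive"]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (
    Clonotype,
    ReferenceDB,
    Repertoire,
    RepertoireFormatError,
    normalize_gene,
)

__all__ = [
    "read_clonotype_table",
    "write_clonotype_table",
    "read_reference_db",
    "write_reference_db",
]

_DIALECT_COLUMNS = {
    "airr": ["duplicate_count", "junction", "junction_aa", "v_call", "j_call"],
    "mixcr": ["cloneCount", "nSeqCDR3", "aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore"],
}

_AA_OK = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _best_hit(hits: str) -> str:
    """First hit of a MiXCR hits-with-score string, score stripped."""
    first = hits.split(",", 1)[0].strip()
    return first.split("(", 1)[0].strip()


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    *,
    subject_id: str | None = None,
    group: str = "",
    pair_id: str = "",
) -> Repertoire:
    """Read one subject's clonotype table (one row per nucleotide clonotype).

    Counts are preserved exactly; frequencies are left unset until
    :func:`tcrep.core.compute_frequencies`.  Non-productive rows are dropped
    with a logged count (``meta["n_nonproductive"]``).
    """
    path = Path(path)
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'airr' or 'mixcr'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = _DIALECT_COLUMNS[dialect]
    for col in required:
        if col not in df.columns:
            raise RepertoireFormatError(
                f"{path.name}: missing required column {col!r} for dialect {dialect!r}"
            )
    if len(df) == 0:
        raise RepertoireFormatError(f"{path.name}: no clonotype rows")

    if dialect == "airr":
        count_col, nt_col, aa_col, v_col, j_col = required
        v_series = df[v_col]
        j_series = df[j_col]
    else:
        count_col, nt_col, aa_col, v_col, j_col = required
        v_series = df[v_col].map(_best_hit)
        j_series = df[j_col].map(_best_hit)

    n_dropped = 0
    clonotypes: list[Clonotype] = []
    for aa, nt, v, j, cnt in zip(df[aa_col], df[nt_col], v_series, j_series, df[count_col]):
        count = int(float(cnt))
        if not isinstance(aa, str) or not aa or not _AA_OK.issuperset(aa):
            n_dropped += 1
            continue
        nt = nt if isinstance(nt, str) else ""
        clonotypes.append(
            Clonotype(
                cdr3_aa=aa,
                v_allele=v,
                j_allele=j,
                count=count,
                cdr3_nt_variants=[(nt, count)] if nt else [],
            )
        )
    if not clonotypes:
        raise RepertoireFormatError(f"{path.name}: no productive clonotype rows")
    return Repertoire(
        subject_id=subject_id or path.stem,
        group=group,
        pair_id=pair_id,
        clonotypes=clonotypes,
        meta={"n_nonproductive": n_dropped, "dialect": dialect},
    )


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as AIRR-style TSV plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) records subject id, group, pair id and
    bookkeeping counters, so a read/write/read round trip is lossless.
    """
    path = Path(path)
    rows = []
    for c in rep.clonotypes:
        nt = max(c.cdr3_nt_variants, key=lambda t: (t[1], t[0]))[0] if c.cdr3_nt_variants else ""
        rows.append(
            {
                "duplicate_count": c.count,
                "junction": nt,
                "junction_aa": c.cdr3_aa,
                "v_call": c.v_allele,
                "j_call": c.j_allele,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    sidecar = {
        "subject_id": rep.subject_id,
        "group": rep.group,
        "pair_id": rep.pair_id,
        "meta": rep.meta,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_reference_db(path: str | Path) -> ReferenceDB:
    """Read a reference TSV of antigen-specific TCRs.

    Requires columns ``v_gene``, ``cdr3_aa``, ``epitope``.  V genes are
    normalized to allele-free form, rows are deduplicated, and rows with an
    empty epitope label are rejected (count kept in ``n_rejected``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("v_gene", "cdr3_aa", "epitope"):
        if col not in df.columns:
            raise RepertoireFormatError(f"{path.name}: missing required column {col!r}")
    entries: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    n_rejected = 0
    for v, cdr3, epi in zip(df["v_gene"], df["cdr3_aa"], df["epitope"]):
        if not isinstance(epi, str) or not epi.strip():
            n_rejected += 1
            continue
        key = (normalize_gene(str(v)), str(cdr3), epi.strip())
        if key in seen:
            continue
        seen.add(key)
        entries.append(key)
    return ReferenceDB(entries=entries, n_rejected=n_rejected)


def write_reference_db(db: ReferenceDB, path: str | Path) -> None:
    pd.DataFrame(db.entries, columns=["v_gene", "cdr3_aa", "epitope"]).to_csv(
        path, sep="\t", index=False
    )
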