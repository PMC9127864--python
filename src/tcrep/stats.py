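"""Inferential statistics for paired-cohort repertoire comparisons.

Paired group contrasts use the two-sided Wilcoxon signed-rank test (exact
null distribution for small samples, normal approximation with tie/zero
handling otherwise); unpaired contrasts of similarity metrics use the
two-sided Wilcoxon rank-sum (Mann-Whitney) test.  The coupling between
clonal abundance and generative likelihood is Pearson's r on
log10-transformed frequency versus log10-transformed P_gen, per subject.
Clinical features are related to the per-subject coupling coefficient by
simple linear regression; p-values within an analysis family are adjusted
by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import DegenerateInputError, Repertoire

__all__ = [
    "PairedComparison",
    "CouplingResult",
    "freq_pgen_correlation",
    "paired_wilcoxon",
    "ranksum",
    "clinical_association",
    "bh_fdr",
]


@dataclass
class PairedComparison:
    """Paired two-sided Wilcoxon signed-rank result for one metric."""

    metric: str
    statistic: float
    pvalue: float
    n_pairs: int
    n_zero_dropped: int
    values_case: np.ndarray
    values_control: np.ndarray
    adjusted_pvalue: float | None = None


@dataclass
class CouplingResult:
    """Per-subject Pearson coupling of log10 frequency and log10 P_gen."""

    subject_id: str
    r: float
    pvalue: float
    n_used: int
    n_excluded: int


def freq_pgen_correlation(rep: Repertoire, pgen_table) -> CouplingResult:
    """Pearson r between log10 clonal frequency and log10 P_gen.

    ``pgen_table`` maps cdr3_aa -> P_gen (dict or Series).  Clonotypes with
    P_gen = 0 (or absent from the table) cannot be log-transformed and are
    excluded; their count is reported.
    """
    if hasattr(pgen_table, "to_dict"):
        pgen_table = pgen_table.to_dict()
    freqs = rep.frequencies()
    logf, logp = [], []
    n_excluded = 0
    for c, f in zip(rep.clonotypes, freqs):
        pg = pgen_table.get(c.cdr3_aa, 0.0)
        if pg > 0 and f > 0:
            logf.append(np.log10(f))
            logp.append(np.log10(pg))
        else:
            n_excluded += 1
    if len(logf) < 3:
        raise DegenerateInputError(
            f"subject {rep.subject_id!r}: {len(logf)} clonotypes with positive "
            "P_gen; need >= 3 for a correlation"
        )
    r, p = sps.pearsonr(logp, logf)
    return CouplingResult(
        subject_id=rep.subject_id, r=float(r), pvalue=float(p),
        n_used=len(logf), n_excluded=n_excluded,
    )


def paired_wilcoxon(
    values_case,
    values_control,
    pairs=None,
    metric: str = "",
    zero_method: str = "wilcox",
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on matched case/control values.

    ``values_*`` are either aligned sequences or mappings from subject id,
    in which case ``pairs`` supplies ``(case_id, control_id)`` tuples.
    Zero differences are dropped (Wilcoxon's original treatment) by
    default.  The exact null distribution is used for n <= 25 (ties are
    handled by the exact conditional distribution); larger samples use the
    normal approximation with tie correction.
    """
    if pairs is not None and hasattr(values_case, "get"):
        x = np.array([values_case[a] for a, _ in pairs], dtype=float)
        y = np.array([values_control[b] for _, b in pairs], dtype=float)
    else:
        x = np.asarray(values_case, dtype=float)
        y = np.asarray(values_control, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired value vectors must have equal length")
    d = x - y
    n_zero = int((d == 0).sum())
    nz = d[d != 0] if zero_method == "wilcox" else d
    if nz.size < 2:
        raise DegenerateInputError(
            "signed-rank test undefined: fewer than 2 non-zero differences"
        )
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, zero_method=zero_method, method=method, alternative="two-sided")
    return PairedComparison(
        metric=metric,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_pairs=int(x.size),
        n_zero_dropped=n_zero,
        values_case=x,
        values_control=y,
    )


def ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U, midrank ties).

    Returns ``(U statistic, p)``; exact p when sample sizes allow.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("rank-sum test needs non-empty samples")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def clinical_association(
    coupling: list[CouplingResult],
    clinical: pd.DataFrame,
    features: list[str],
    scope: str = "all",
) -> pd.DataFrame:
    """Linear association of clinical features with per-subject coupling r.

    ``clinical`` needs a ``subject_id`` column (plus ``group`` when scoping
    to one group) and one numeric column per feature.  For each feature,
    Pearson's r with its two-sided p and the least-squares line are
    reported; missing values are dropped pairwise.  For simple regression
    the Pearson test and the slope t-test coincide, so both views carry the
    same p.
    """
    r_by_subject = {c.subject_id: c.r for c in coupling}
    df = clinical.copy()
    if scope != "all":
        if "group" not in df.columns:
            raise ValueError("clinical table lacks 'group' column for scoped analysis")
        df = df[df["group"] == scope]
    rows = []
    for feat in features:
        if feat not in df.columns:
            raise ValueError(f"clinical table lacks feature column {feat!r}")
        sub = df[df["subject_id"].isin(r_by_subject)]
        xy = [
            (r_by_subject[s], v)
            for s, v in zip(sub["subject_id"], pd.to_numeric(sub[feat], errors="coerce"))
            if np.isfinite(v)
        ]
        if len(xy) < 3:
            raise DegenerateInputError(
                f"feature {feat!r} in scope {scope!r}: {len(xy)} usable subjects (need >= 3)"
            )
        x = np.array([a for a, _ in xy])
        y = np.array([b for _, b in xy])
        fit = sps.linregress(x, y)
        rows.append(
            {"feature": feat, "scope": scope, "n": len(xy), "r": float(fit.rvalue),
             "p": float(fit.pvalue), "slope": float(fit.slope),
             "intercept": float(fit.intercept)}
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (position-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
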