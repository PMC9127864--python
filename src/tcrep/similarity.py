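"""Repertoire similarity and gene-usage comparison.

Morisita--Horn (MH) overlap between two repertoires X, Y with clonotype
frequencies ``x_i``, ``y_i`` indexed over the union of their unique CDR3
amino-acid sequences (absent = 0):

    ``MH = 2 * sum_i x_i * y_i / sum_i (x_i**2 + y_i**2)``,

ranging from 0 (disjoint) to 1 (identical).

The repertoire dissimilarity index (RDI) compares gene-usage vectors at a
fixed sampling depth: for each iteration a fixed number of unique clonotypes
is subsampled without replacement from each repertoire, per-category usage
counts are variance-stabilized as ``2*sqrt(count)``, and the Euclidean
distance between the transformed vectors is averaged over iterations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Cohort, DegenerateInputError, Repertoire

__all__ = [
    "UsageProfile",
    "PairwiseMatrix",
    "morisita_horn",
    "usage_profile",
    "rdi_distance",
    "pairwise_matrix",
]

USAGE_FEATURES = ("V", "J", "VJpair", "CDR3length")


def morisita_horn(rep_x: Repertoire, rep_y: Repertoire) -> float:
    """Morisita--Horn overlap of two repertoires on union-indexed frequencies."""
    fx = dict(zip((c.cdr3_aa for c in rep_x.clonotypes), rep_x.frequencies()))
    fy = dict(zip((c.cdr3_aa for c in rep_y.clonotypes), rep_y.frequencies()))
    if not fx or not fy:
        raise DegenerateInputError("empty repertoire")
    keys = fx.keys() | fy.keys()
    x = np.array([fx.get(k, 0.0) for k in keys])
    y = np.array([fy.get(k, 0.0) for k in keys])
    return float(2.0 * (x * y).sum() / ((x * x).sum() + (y * y).sum()))


@dataclass
class UsageProfile:
    """Occurrence counts of one feature over the unique clonotypes."""

    feature: str
    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())


def _category(clonotype, feature: str) -> str:
    if feature == "V":
        return clonotype.v_allele
    if feature == "J":
        return clonotype.j_allele
    if feature == "VJpair":
        return f"{clonotype.v_allele}|{clonotype.j_allele}"
    if feature == "CDR3length":
        return str(len(clonotype.cdr3_aa))
    raise ValueError(f"unknown usage feature {feature!r}; expected one of {USAGE_FEATURES}")


def usage_profile(rep: Repertoire, feature: str) -> UsageProfile:
    """Count occurrences of each V/J allele, V-J pair, or CDR3 length.

    Each unique clonotype contributes exactly 1 to one category, so counts
    sum to the number of unique clonotypes.
    """
    counts: dict[str, int] = {}
    for c in rep.clonotypes:
        cat = _category(c, feature)
        counts[cat] = counts.get(cat, 0) + 1
    return UsageProfile(feature=feature, counts=counts)


def rdi_distance(
    rep_x: Repertoire,
    rep_y: Repertoire,
    feature: str = "V",
    depth: int | None = None,
    n_iter: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Repertoire dissimilarity index between two usage profiles.

    Subsamples ``depth`` unique clonotypes without replacement from each
    repertoire per iteration (default: the smaller unique-clonotype count),
    builds usage-count vectors on the union category set, applies the
    variance-stabilizing transform ``2*sqrt(count)``, and returns the mean
    Euclidean distance over ``n_iter`` iterations.  Deterministic given a
    seed.  The raw mean distance is reported without null-distance
    calibration.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    nx, ny = len(rep_x), len(rep_y)
    if depth is None:
        depth = min(nx, ny)
    if depth < 1 or depth > min(nx, ny):
        raise DegenerateInputError(
            f"depth {depth} exceeds a repertoire (unique counts {nx}, {ny})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    cats_x = np.array([_category(c, feature) for c in rep_x.clonotypes])
    cats_y = np.array([_category(c, feature) for c in rep_y.clonotypes])
    categories = sorted(set(cats_x) | set(cats_y))
    index = {cat: i for i, cat in enumerate(categories)}
    ix = np.array([index[c] for c in cats_x])
    iy = np.array([index[c] for c in cats_y])
    k = len(categories)

    dists = np.empty(n_iter)
    for it in range(n_iter):
        sx = rng.choice(nx, size=depth, replace=False)
        sy = rng.choice(ny, size=depth, replace=False)
        vx = np.bincount(ix[sx], minlength=k)
        vy = np.bincount(iy[sy], minlength=k)
        dists[it] = np.linalg.norm(2.0 * np.sqrt(vx) - 2.0 * np.sqrt(vy))
    return float(dists.mean())


@dataclass
class PairwiseMatrix:
    """Symmetric subject-by-subject metric matrix with intra/inter labels."""

    subject_ids: list[str]
    metric: str
    values: np.ndarray
    pair_class: dict[tuple[str, str], str]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (a, b), cls in self.pair_class.items():
            i, j = self.subject_ids.index(a), self.subject_ids.index(b)
            rows.append(
                {"id1": a, "id2": b, "metric": self.metric,
                 "value": self.values[i, j], "pair_class": cls}
            )
        return pd.DataFrame(rows)

    def by_class(self, cls: str) -> np.ndarray:
        return np.array([
            self.values[self.subject_ids.index(a), self.subject_ids.index(b)]
            for (a, b), c in self.pair_class.items() if c == cls
        ])


def pairwise_matrix(
    cohort: Cohort,
    metric: str = "MH",
    **params,
) -> PairwiseMatrix:
    """All-pairs MH or RDI matrix with intra-/inter-group cell labels.

    Off-diagonal cells are labeled ``intra-<group>`` when both subjects share
    a group and ``inter`` otherwise.  RDI parameters (feature, depth, n_iter,
    seed) pass through ``params``.
    """
    groups = {r.group for r in cohort.repertoires}
    for g in groups:
        if len(cohort.by_group(g)) < 2:
            raise DegenerateInputError(f"group {g!r} has fewer than 2 subjects")
    reps = cohort.repertoires
    ids = [r.subject_id for r in reps]
    n = len(reps)
    values = np.zeros((n, n))
    if metric == "MH":
        np.fill_diagonal(values, 1.0)
    elif metric != "RDI":
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(params.pop("seed", None)) if metric == "RDI" else None

    pair_class: dict[tuple[str, str], str] = {}
    for i, j in itertools.combinations(range(n), 2):
        if metric == "MH":
            v = morisita_horn(reps[i], reps[j])
        else:
            v = rdi_distance(reps[i], reps[j], rng=rng, **params)
        values[i, j] = values[j, i] = v
        if reps[i].group == reps[j].group:
            cls = f"intra-{reps[i].group}"
        else:
            cls = "inter"
        pair_class[(ids[i], ids[j])] = cls
    return PairwiseMatrix(subject_ids=ids, metric=metric, values=values, pair_class=pair_class)
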