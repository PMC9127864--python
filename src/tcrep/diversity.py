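"""Repertoire diversity: Hill numbers, Rényi entropy, Pielou evenness,
clone-size spectra, and top-rank cumulative abundance.

The diversity profile of a repertoire with clonotype frequencies ``p_i`` is
the family of Hill numbers

    ``^aD = (sum_i p_i^a) ** (1 / (1 - a))``,

where the order ``a`` (alpha) weights abundant clonotypes more heavily as it
grows: ``a = 0`` gives richness (the number of unique clonotypes), and the
``a -> 1`` limit is the exponential of Shannon entropy, used directly at
``a = 1`` where the closed form is undefined.  The Rényi entropy is
``^aH = ln(^aD)``.  Pielou's evenness ``J' = H' / ln(N)`` normalizes Shannon
entropy by its maximum; 1 means a perfectly even repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateInputError, Repertoire

__all__ = [
    "DiversityProfile",
    "CloneSizeSpectrum",
    "CLONE_SIZE_BINS",
    "hill_number",
    "diversity_profile",
    "pielou_evenness",
    "shannon_entropy",
    "clone_size_spectrum",
    "cumulative_top_fraction",
]

#: Clone-size bins as (label, lower-exclusive, upper-inclusive) frequency
#: intervals: hyper-expanded > 1%, high 0.1–1%, medium 0.01–0.1%, low <= 0.01%.
CLONE_SIZE_BINS: list[tuple[str, float, float]] = [
    ("hyper", 0.01, 1.0),
    ("high", 0.001, 0.01),
    ("medium", 0.0001, 0.001),
    ("low", 0.0, 0.0001),
]


def _validated_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DegenerateInputError("frequency vector must be non-empty 1-D")
    if np.any(p < 0):
        raise DegenerateInputError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DegenerateInputError(f"frequencies sum to {p.sum():.12g}, not 1")
    # zero-frequency entries carry no abundance information; drop them so the
    # p*ln(p) and p**0 terms are never evaluated at 0
    return p[p > 0]


def shannon_entropy(freqs) -> float:
    """Shannon entropy H' = -sum p_i ln p_i (natural log)."""
    p = _validated_freqs(freqs)
    return float(-(p * np.log(p)).sum())


def hill_number(freqs, alpha: float) -> float:
    """Hill number ``^aD`` of order ``alpha`` for a frequency vector.

    ``alpha = 0`` returns richness; ``|alpha - 1| < 1e-9`` uses the exact
    Shannon branch ``exp(H')``; otherwise the closed form
    ``(sum p_i^alpha)^(1/(1-alpha))``.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    p = _validated_freqs(freqs)
    if abs(alpha - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**alpha).sum() ** (1.0 / (1.0 - alpha)))


@dataclass
class DiversityProfile:
    """Hill/Rényi values of one repertoire over an ordered alpha grid."""

    alpha_grid: np.ndarray
    hill_values: np.ndarray
    renyi_values: np.ndarray


def default_alpha_grid() -> np.ndarray:
    """Alpha from 0 to 10 in steps of 0.1."""
    return np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


def diversity_profile(rep: Repertoire, alpha_grid=None) -> DiversityProfile:
    """Hill-number profile of a repertoire; Rényi entropy is its natural log."""
    grid = default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid, float)
    if grid.size == 0:
        raise ValueError("alpha grid must be non-empty")
    freqs = rep.frequencies()
    hill = np.array([hill_number(freqs, a) for a in grid])
    return DiversityProfile(alpha_grid=grid, hill_values=hill, renyi_values=np.log(hill))


def pielou_evenness(freqs) -> float:
    """Pielou's evenness J' = H' / ln(N) over the positive frequencies.

    Undefined for a single clonotype (ln 1 = 0).
    """
    p = _validated_freqs(freqs)
    n = p.size
    if n < 2:
        raise DegenerateInputError("evenness undefined for a single clonotype")
    return float(-(p * np.log(p)).sum() / np.log(n))


@dataclass
class CloneSizeSpectrum:
    """Per-bin cumulative frequency and clonotype counts (bins partition 1)."""

    labels: list[str]
    cumulative_frequency: dict[str, float]
    clonotype_counts: dict[str, int]


def clone_size_spectrum(rep: Repertoire) -> CloneSizeSpectrum:
    """Partition clonal abundance into hyper/high/medium/low clone-size bins."""
    p = np.asarray(rep.frequencies(), dtype=float)
    cum: dict[str, float] = {}
    cnt: dict[str, int] = {}
    for label, lo, hi in CLONE_SIZE_BINS:
        mask = (p > lo) & (p <= hi) if lo > 0 else (p <= hi)
        cum[label] = float(p[mask].sum())
        cnt[label] = int(mask.sum())
    return CloneSizeSpectrum(
        labels=[b[0] for b in CLONE_SIZE_BINS],
        cumulative_frequency=cum,
        clonotype_counts=cnt,
    )


def cumulative_top_fraction(rep: Repertoire, q: float) -> float:
    """Cumulative frequency of clonotypes at or above the top-``q`` rank.

    Clonotypes are ranked by descending frequency; the threshold is the
    frequency at rank ``ceil(q * N)`` and all clonotypes with frequency
    greater than or equal to it are summed, so ties at the threshold are
    included.
    """
    if not (0 < q <= 1):
        raise ValueError(f"q must be in (0, 1], got {q}")
    p = np.sort(np.asarray(rep.frequencies(), dtype=float))[::-1]
    rank = int(np.ceil(q * p.size))
    threshold = p[rank - 1]
    return float(p[p >= threshold].sum())
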