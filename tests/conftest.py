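import numpy as np
import pytest

from tcrep.core import Clonotype, Repertoire, compute_frequencies
from tcrep.generation import GenerationModel, Segment


def make_repertoire(counts, cdr3s=None, v="TRBV9*01", j="TRBJ2-1*01",
                    subject_id="S1", group="APA", pair_id="p0"):
    """Repertoire with given counts (frequencies computed)."""
    if cdr3s is None:
        cdr3s = [f"CASS{_spell(i)}EQYF" for i in range(len(counts))]
    clons = [
        Clonotype(cdr3_aa=s, v_allele=v, j_allele=j, count=int(c))
        for s, c in zip(cdr3s, counts)
    ]
    return compute_frequencies(
        Repertoire(subject_id=subject_id, group=group, pair_id=pair_id, clonotypes=clons)
    )


def _spell(i):
    # distinct interior letters, avoiding non-amino characters
    letters = "ACDEFGHIKLMNPQRSTVWY"
    out = letters[i % 20]
    while i >= 20:
        i //= 20
        out += letters[i % 20]
    return out


@pytest.fixture
def tiny_rep():
    return make_repertoire([1, 1, 2])


@pytest.fixture
def random_rep():
    rng = np.random.default_rng(7)
    counts = rng.integers(1, 500, size=60)
    return make_repertoire(counts)


@pytest.fixture
def deterministic_model():
    """One V, one J, no trimming, no insertion: always emits CASSEQYF."""
    return GenerationModel(
        v_segments=[Segment("V1", "CASS", 1.0)],
        j_segments=[Segment("J1", "EQYF", 1.0)],
        trim_probs=np.array([1.0]),
        insert_len_probs=np.array([1.0]),
        insert_aa_probs=np.full(20, 0.05),
    )


@pytest.fixture
def enumerable_model():
    """2 V x 2 J, trims up to 1, inserts up to 2 over a 2-letter support."""
    aa = np.zeros(20)
    aa[0] = 0.7   # A
    aa[5] = 0.3   # G
    return GenerationModel(
        v_segments=[Segment("V1", "CASS", 0.6), Segment("V2", "CSAR", 0.4)],
        j_segments=[Segment("J1", "EQYF", 0.7), Segment("J2", "GYTF", 0.3)],
        trim_probs=np.array([0.8, 0.2]),
        insert_len_probs=np.array([0.5, 0.3, 0.2]),
        insert_aa_probs=aa,
    )
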