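"""An explicit amino-acid-level CDR3 generation model.

The model is a deliberately simple, fully specified stochastic stand-in for
a V(D)J recombination model: a CDR3 is generated by

1. drawing a V segment (an amino-acid *prefix*) and trimming 0..T residues
   from its end,
2. drawing an insertion length 0..L and that many i.i.d. residues from an
   insertion composition over the 20 amino acids,
3. drawing a J segment (an amino-acid *suffix*) and trimming 0..T residues
   from its start,

and concatenating trimmed-prefix + insert + trimmed-suffix.  Because every
component distribution is explicit, the generation probability P_gen of a
CDR3 string is an exact, finite sum over all (V, trimV, insert, trimJ, J)
decompositions that produce it — no training, no hidden state.  Externally
computed P_gen values can be supplied instead as a per-clonotype table;
downstream analyses consume either source identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AMINO_ACIDS

__all__ = [
    "Segment",
    "GenerationModel",
    "PgenResult",
    "default_model",
    "sample_cdr3",
    "sample_many",
    "pgen_exact",
    "pgen_montecarlo",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class Segment:
    """A germline segment: identifier, amino-acid sequence, usage probability."""

    id: str
    seq: str
    prob: float


def _check_dist(p: np.ndarray, name: str) -> None:
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name} must be a probability distribution summing to 1")


@dataclass
class GenerationModel:
    """Explicit V-insert-J generation process over amino-acid strings.

    ``trim_probs[d]`` is the probability of trimming ``d`` residues (applied
    independently to the V prefix end and the J suffix start);
    ``insert_len_probs[l]`` the probability of an ``l``-residue insertion;
    ``insert_aa_probs`` the per-residue insertion composition indexed like
    :data:`tcrep.core.AMINO_ACIDS`.
    """

    v_segments: list[Segment]
    j_segments: list[Segment]
    trim_probs: np.ndarray
    insert_len_probs: np.ndarray
    insert_aa_probs: np.ndarray

    def __post_init__(self) -> None:
        self.trim_probs = np.asarray(self.trim_probs, float)
        self.insert_len_probs = np.asarray(self.insert_len_probs, float)
        self.insert_aa_probs = np.asarray(self.insert_aa_probs, float)
        if not self.v_segments or not self.j_segments:
            raise ValueError("model needs at least one V and one J segment")
        for segs, name in ((self.v_segments, "V"), (self.j_segments, "J")):
            p = np.array([s.prob for s in segs])
            _check_dist(p, f"{name}-segment probabilities")
            if any(not s.seq for s in segs):
                raise ValueError(f"{name} segment sequences must be non-empty")
        _check_dist(self.trim_probs, "trim distribution")
        _check_dist(self.insert_len_probs, "insertion length distribution")
        if self.insert_aa_probs.size != len(AMINO_ACIDS):
            raise ValueError("insert_aa_probs must have 20 entries")
        _check_dist(self.insert_aa_probs, "insertion residue distribution")
        max_trim = self.trim_probs.size - 1
        min_seg = min(len(s.seq) for s in self.v_segments + self.j_segments)
        if max_trim >= min_seg:
            raise ValueError("maximum trim must be smaller than the shortest segment")
        self._tables: tuple[dict, dict] | None = None

    # -- cached (trimmed string -> summed probability / path count) tables --
    def _prefix_suffix_tables(self):
        if self._tables is None:
            pre: dict[str, list[float]] = {}
            for s in self.v_segments:
                for d, pt in enumerate(self.trim_probs):
                    tp = s.seq[: len(s.seq) - d]
                    prob = s.prob * pt
                    if prob > 0:
                        cur = pre.setdefault(tp, [0.0, 0])
                        cur[0] += prob
                        cur[1] += 1
            suf: dict[str, list[float]] = {}
            for s in self.j_segments:
                for d, pt in enumerate(self.trim_probs):
                    ts = s.seq[d:]
                    prob = s.prob * pt
                    if prob > 0:
                        cur = suf.setdefault(ts, [0.0, 0])
                        cur[0] += prob
                        cur[1] += 1
            self._tables = (pre, suf)
        return self._tables

    def to_json(self, path: str | Path) -> None:
        doc = {
            "v_segments": [[s.id, s.seq, s.prob] for s in self.v_segments],
            "j_segments": [[s.id, s.seq, s.prob] for s in self.j_segments],
            "trim_probs": self.trim_probs.tolist(),
            "insert_len_probs": self.insert_len_probs.tolist(),
            "insert_aa_probs": self.insert_aa_probs.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerationModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            v_segments=[Segment(*t) for t in doc["v_segments"]],
            j_segments=[Segment(*t) for t in doc["j_segments"]],
            trim_probs=np.array(doc["trim_probs"]),
            insert_len_probs=np.array(doc["insert_len_probs"]),
            insert_aa_probs=np.array(doc["insert_aa_probs"]),
        )


@dataclass
class PgenResult:
    """Exact generation probability of one CDR3 with its path count."""

    cdr3_aa: str
    pgen: float
    n_paths: int


def default_model() -> GenerationModel:
    """A human-TRB-flavoured default model.

    Segment identifiers and junction boundaries follow TRB naming
    conventions (V prefixes start with the conserved C, J suffixes end in
    F); usage probabilities are skewed rather than uniform, as real segment
    usage is.  Trims up to 2 residues, insertions up to 6.
    """
    v = [
        ("TRBV2", "CASSE", 0.13), ("TRBV4-1", "CASSQ", 0.06),
        ("TRBV5-1", "CASSL", 0.16), ("TRBV6-1", "CASSD", 0.08),
        ("TRBV7-2", "CASSH", 0.07), ("TRBV9", "CASSV", 0.12),
        ("TRBV11-2", "CASSG", 0.05), ("TRBV19", "CASSI", 0.11),
        ("TRBV20-1", "CSARD", 0.09), ("TRBV27", "CASSP", 0.05),
        ("TRBV28", "CASSF", 0.05), ("TRBV30", "CAWSM", 0.03),
    ]
    j = [
        ("TRBJ1-1", "NTEAFF", 0.14), ("TRBJ1-2", "NYGYTF", 0.10),
        ("TRBJ1-5", "SNQPQHF", 0.11), ("TRBJ2-1", "YNEQFF", 0.19),
        ("TRBJ2-2", "NTGELFF", 0.08), ("TRBJ2-3", "STDTQYF", 0.13),
        ("TRBJ2-5", "QETQYF", 0.12), ("TRBJ2-7", "SYEQYF", 0.13),
    ]
    # mildly non-uniform insertion composition (glycine/serine-rich junctions)
    w = np.ones(20)
    for aa, mult in (("G", 3.0), ("S", 2.0), ("L", 1.8), ("R", 1.6), ("A", 1.4),
                     ("P", 1.3), ("T", 1.2), ("W", 0.4), ("C", 0.3), ("M", 0.5)):
        w[_AA_INDEX[aa]] *= mult
    return GenerationModel(
        v_segments=[Segment(*t) for t in v],
        j_segments=[Segment(*t) for t in j],
        trim_probs=np.array([0.5, 0.3, 0.2]),
        insert_len_probs=np.array([0.08, 0.14, 0.2, 0.22, 0.18, 0.12, 0.06]),
        insert_aa_probs=w / w.sum(),
    )


def sample_cdr3(model: GenerationModel, rng: np.random.Generator,
                return_segments: bool = False):
    """Draw one CDR3 from the model (optionally with the V/J ids used)."""
    seq, v, j = _sample_one(model, rng)
    return (seq, v, j) if return_segments else seq


def _sample_one(model: GenerationModel, rng: np.random.Generator):
    vi = rng.choice(len(model.v_segments), p=[s.prob for s in model.v_segments])
    ji = rng.choice(len(model.j_segments), p=[s.prob for s in model.j_segments])
    dv = rng.choice(model.trim_probs.size, p=model.trim_probs)
    dj = rng.choice(model.trim_probs.size, p=model.trim_probs)
    il = rng.choice(model.insert_len_probs.size, p=model.insert_len_probs)
    ins = "".join(
        AMINO_ACIDS[k] for k in rng.choice(20, size=il, p=model.insert_aa_probs)
    )
    v, j = model.v_segments[vi], model.j_segments[ji]
    seq = v.seq[: len(v.seq) - dv] + ins + j.seq[dj:]
    return seq, v.id, j.id


def sample_many(model: GenerationModel, n: int, rng: np.random.Generator):
    """Vectorized draw of ``n`` CDR3s; returns (sequences, v_ids, j_ids)."""
    vp = np.array([s.prob for s in model.v_segments])
    jp = np.array([s.prob for s in model.j_segments])
    vi = rng.choice(vp.size, size=n, p=vp)
    ji = rng.choice(jp.size, size=n, p=jp)
    dv = rng.choice(model.trim_probs.size, size=n, p=model.trim_probs)
    dj = rng.choice(model.trim_probs.size, size=n, p=model.trim_probs)
    il = rng.choice(model.insert_len_probs.size, size=n, p=model.insert_len_probs)
    total_ins = int(il.sum())
    residues = rng.choice(20, size=total_ins, p=model.insert_aa_probs)
    seqs = []
    v_ids = []
    j_ids = []
    pos = 0
    for k in range(n):
        v = model.v_segments[vi[k]]
        j = model.j_segments[ji[k]]
        ins = "".join(AMINO_ACIDS[r] for r in residues[pos : pos + il[k]])
        pos += il[k]
        seqs.append(v.seq[: len(v.seq) - dv[k]] + ins + j.seq[dj[k] :])
        v_ids.append(v.id)
        j_ids.append(j.id)
    return seqs, v_ids, j_ids


def pgen_exact(model: GenerationModel, seq: str) -> PgenResult:
    """Exact P_gen of ``seq`` by exhaustive summation over decompositions.

    Sums ``P(v) P_trim(d_v) P_len(|mid|) prod_k P_aa(mid_k) P_trim(d_j) P(j)``
    over every (V, trimV, insert, trimJ, J) tuple whose trimmed prefix is a
    prefix of ``seq``, whose trimmed suffix is a non-overlapping suffix, and
    whose insertion fills the middle.  ``n_paths`` counts the contributing
    decompositions; pgen is 0 iff there are none.
    """
    if not seq or not set(seq) <= set(AMINO_ACIDS):
        raise ValueError(f"sequence must be over the 20-letter amino-acid alphabet: {seq!r}")
    pre, suf = model._prefix_suffix_tables()
    max_il = model.insert_len_probs.size - 1
    total = 0.0
    n_paths = 0
    for tp, (pp, np_pre) in pre.items():
        if not seq.startswith(tp):
            continue
        for ts, (ps, np_suf) in suf.items():
            mid_len = len(seq) - len(tp) - len(ts)
            if mid_len < 0 or mid_len > max_il or not seq.endswith(ts):
                continue
            mid = seq[len(tp) : len(seq) - len(ts)]
            p_mid = model.insert_len_probs[mid_len]
            for ch in mid:
                p_mid *= model.insert_aa_probs[_AA_INDEX[ch]]
            if p_mid > 0:
                total += pp * ps * p_mid
                n_paths += np_pre * np_suf
    return PgenResult(cdr3_aa=seq, pgen=float(total), n_paths=n_paths)


def pgen_montecarlo(
    model: GenerationModel, seq: str, n: int, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P_gen: fraction of ``n`` draws equal to ``seq``.

    Returns ``(estimate, standard_error)`` with
    ``SE = sqrt(p_hat (1 - p_hat) / n)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    seqs, _, _ = sample_many(model, n, rng)
    hits = sum(1 for s in seqs if s == seq)
    p_hat = hits / n
    return p_hat, float(np.sqrt(p_hat * (1.0 - p_hat) / n))
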