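"""Synthetic paired-cohort generator with ground truth.

Emulates a matched case/control TCR-beta study: each subject's repertoire
is drawn from the explicit CDR3 generation model, with

* **clonal evenness** controlled per group by a symmetric Dirichlet
  concentration over base clone weights (case-like subjects get a small
  concentration -> skewed, control-like a large one -> even);
* **abundance/generation coupling** injected multiplicatively on the log
  scale: ``log10 w_i = log10 base_i + beta * log10 pgen_i + eps_i``, the
  minimal mechanism producing a positive within-subject correlation between
  clonal frequency and P_gen (the signature of bystander expansion) without
  modelling T-cell dynamics; ``beta`` varies per subject around a group
  mean;
* **planted common-antigen clonotypes** copied verbatim (CDR3 + V gene)
  from a synthetic reference DB, so annotation recall is testable against
  ground truth;
* **clinical covariates** generated as linear functions of the subject's
  true coupling strength beta plus noise, positive slopes for
  aldosterone-like, aldosterone/renin-ratio-like and sodium-like features
  and a negative slope for the renin-like feature.

Every random stream derives from one master seed, so cohorts are
byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Clonotype,
    Cohort,
    GROUP_CASE,
    GROUP_CONTROL,
    ReferenceDB,
    Repertoire,
    compute_frequencies,
)
from .clustering import INTERIOR_END
from .core import AMINO_ACIDS
from .generation import GenerationModel, default_model, pgen_exact, sample_many

__all__ = [
    "SimConfig",
    "CohortTruth",
    "CLINICAL_FEATURES",
    "simulate_reference_db",
    "simulate_subject",
    "simulate_cohort",
]

#: clinical feature -> (baseline, slope per unit beta); signs mirror the
#: expected clinical picture: aldosterone (PAC), aldosterone/renin ratio
#: (ARR) and sodium rise with coupling strength, renin activity (PRA) falls.
CLINICAL_FEATURES: dict[str, tuple[float, float]] = {
    "PAC": (20.0, 160.0),
    "ARR": (10.0, 90.0),
    "sodium": (136.0, 8.0),
    "PRA": (3.0, -2.5),
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the matched 8 + 8 design: 8 pairs, 2,000 template
    clonotypes per subject sequenced to a depth of 100,000 counts (observed
    richness is lower where expansion crowds out rare clones), a skewed
    case group (Dirichlet concentration 5 vs 50) with strong
    frequency/P_gen coupling (beta 0.8 vs 0.2, per-subject SD 0.12), and a small planted minority
    (1.5%) of reference-documented clonotypes carrying a ~16x memory
    expansion factor.
    """

    n_pairs: int = 8
    n_clonotypes: int = 2000
    depth: int = 100_000
    alpha_case: float = 5.0
    alpha_control: float = 50.0
    beta_case: float = 0.8
    beta_control: float = 0.2
    beta_sd: float = 0.12
    coupling_noise_sd: float = 0.5
    planted_fraction: float = 0.015
    memory_log_boost: float = 1.2
    memory_log_sd: float = 0.2
    n_epitopes: int = 5
    clones_per_epitope: int = 10
    clinical_noise: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        if min(self.alpha_case, self.alpha_control) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be in [0, 1]")


@dataclass
class CohortTruth:
    """Ground-truth ledger of a simulated cohort.

    ``subjects`` maps subject_id -> {group, beta, alpha};
    ``clonotypes`` maps subject_id -> {cdr3_aa -> epitope or None (not
    planted)}; the ledger covers every generated clonotype.
    """

    subjects: dict[str, dict] = field(default_factory=dict)
    clonotypes: dict[str, dict[str, str | None]] = field(default_factory=dict)

    def n_clonotypes(self) -> int:
        return sum(len(v) for v in self.clonotypes.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def simulate_reference_db(
    model: GenerationModel,
    n_epitopes: int = 5,
    clones_per_epitope: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ReferenceDB:
    """Synthetic antigen-specificity reference (a VDJdb-like stand-in).

    Each epitope group seeds one CDR3 built as full V prefix + one
    insertion residue + full J suffix, then adds Hamming-1 neighbors
    substituted only at J-suffix positions outside the motif — positions a
    longer insertion plus J trimming can also produce, so every entry has
    positive generation probability under the model.  All group members
    share one V gene, differ from the seed at at most one interior
    position (a global cluster by construction), and share the interior
    4-mer spanning positions 4-7 (an enrichable motif).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    vp = np.array([s.prob for s in model.v_segments])
    jp = np.array([s.prob for s in model.j_segments])
    max_trim = model.trim_probs.size - 1
    entries: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for e in range(n_epitopes):
        epitope = f"EPITOPE_{e:02d}"
        while True:
            v = model.v_segments[rng.choice(vp.size, p=vp)]
            j = model.j_segments[rng.choice(jp.size, p=jp)]
            ins = AMINO_ACIDS[rng.choice(20, p=model.insert_aa_probs)]
            seed_seq = v.seq + ins + j.seq
            if seed_seq not in seen:
                break
        group = [seed_seq]
        # mutable positions: J-suffix offsets outside the shared motif
        # (interior positions 4-7) yet still reachable by trimming the J
        # deeper and extending the insertion (offset k needs trim k+1)
        j_start = len(v.seq) + len(ins)
        motif_end = 7  # seed[3:7] is the shared motif
        mutable = [
            j_start + k
            for k in range(min(max_trim, len(j.seq) - INTERIOR_END))
            if j_start + k >= motif_end
            and j_start + k < len(seed_seq) - INTERIOR_END
        ]
        candidates = [
            seed_seq[:p] + a + seed_seq[p + 1 :]
            for p in mutable
            for a in AMINO_ACIDS
            if a != seed_seq[p]
        ]
        for pick in rng.permutation(len(candidates)):
            if len(group) >= clones_per_epitope:
                break
            neighbor = candidates[pick]
            if neighbor not in group and neighbor not in seen:
                group.append(neighbor)
        for s in group:
            seen.add(s)
            entries.append((v.id, s, epitope))
    return ReferenceDB(entries=entries)


def _pgen_vector(model: GenerationModel, seqs: list[str],
                 cache: dict[str, float] | None = None) -> np.ndarray:
    out = np.empty(len(seqs))
    for i, s in enumerate(seqs):
        if cache is not None and s in cache:
            out[i] = cache[s]
        else:
            v = pgen_exact(model, s).pgen
            if cache is not None:
                cache[s] = v
            out[i] = v
    return out


def simulate_subject(
    model: GenerationModel,
    config: SimConfig,
    group: str,
    db: ReferenceDB,
    rng: np.random.Generator,
    subject_id: str = "S0",
    pair_id: str = "P0",
    beta: float | None = None,
    pgen_cache: dict[str, float] | None = None,
) -> tuple[Repertoire, dict]:
    """Draw one subject's repertoire plus its truth record.

    Returns ``(repertoire, truth)`` where ``truth`` holds the subject's
    group, true beta and Dirichlet concentration, and the planted-epitope
    label (or None) of every clonotype.
    """
    is_case = group == GROUP_CASE
    alpha = config.alpha_case if is_case else config.alpha_control
    if beta is None:
        mean_beta = config.beta_case if is_case else config.beta_control
        beta = float(rng.normal(mean_beta, config.beta_sd))

    n_planted = int(round(config.planted_fraction * config.n_clonotypes))
    n_planted = min(n_planted, len(db.entries))
    planted_idx = rng.choice(len(db.entries), size=n_planted, replace=False)
    planted = [db.entries[i] for i in planted_idx]
    planted_seqs = {cdr3 for _, cdr3, _ in planted}

    n_model = config.n_clonotypes - len(planted)
    seqs: list[str] = []
    vj: list[tuple[str, str]] = []
    seen = set(planted_seqs)
    while len(seqs) < n_model:
        draw, v_ids, j_ids = sample_many(model, int(1.6 * (n_model - len(seqs)) + 16), rng)
        for s, v, j in zip(draw, v_ids, j_ids):
            if s not in seen:
                seen.add(s)
                seqs.append(s)
                vj.append((v, j))
                if len(seqs) == n_model:
                    break

    all_seqs = [cdr3 for _, cdr3, _ in planted] + seqs
    all_v = [f"{v}*01" for v, _, _ in planted] + [f"{v}*01" for v, _ in vj]
    all_j = ["TRBJ2-1*01" for _ in planted] + [f"{j}*01" for _, j in vj]
    epitope_of = {cdr3: epi for _, cdr3, epi in planted}

    pgen = _pgen_vector(model, all_seqs, pgen_cache)
    # floor impossible sequences at the smallest positive pgen so the
    # coupling term stays finite (none arise when db and model agree)
    positive = pgen[pgen > 0]
    log_pgen = np.log10(np.where(pgen > 0, pgen, positive.min()))

    base = rng.dirichlet(np.full(len(all_seqs), alpha))
    eps = rng.normal(0.0, config.coupling_noise_sd, size=len(all_seqs))
    logw = np.log10(base) + beta * log_pgen + eps
    # planted clonotypes are antigen-experienced memory clones carrying a
    # multiplicative expansion factor (lognormal around ~30x); the bystander
    # coupling still applies to them, so they sit on the same
    # frequency/P_gen trend, just shifted upward and thereby detectable
    if planted:
        logw[: len(planted)] += rng.normal(
            config.memory_log_boost, config.memory_log_sd, size=len(planted)
        )
    w = 10 ** (logw - logw.max())
    w /= w.sum()
    # sequencing at the target depth: clonotypes drawing zero reads are
    # unobserved and drop out (so skewed subjects show reduced richness,
    # as real expansion does); planted reference clonotypes are kept
    # observable with a count floor of one read
    counts = rng.multinomial(config.depth, w)
    counts[: len(planted)] = np.maximum(counts[: len(planted)], 1)

    clonotypes = [
        Clonotype(cdr3_aa=s, v_allele=v, j_allele=j, count=int(c))
        for s, v, j, c in zip(all_seqs, all_v, all_j, counts)
        if c > 0
    ]
    rep = compute_frequencies(
        Repertoire(subject_id=subject_id, group=group, pair_id=pair_id,
                   clonotypes=clonotypes)
    )
    observed = {c.cdr3_aa for c in clonotypes}
    truth = {
        "group": group,
        "beta": beta,
        "alpha": alpha,
        "planted": {s: epitope_of.get(s) for s in all_seqs if s in observed},
    }
    return rep, truth


def simulate_cohort(
    config: SimConfig | None = None,
    model: GenerationModel | None = None,
) -> tuple[Cohort, ReferenceDB, pd.DataFrame, CohortTruth]:
    """Generate a full paired cohort: repertoires, reference DB, clinical
    table, and ground-truth ledger.  Deterministic given the master seed."""
    if config is None:
        config = SimConfig()
    if model is None:
        model = default_model()
    ss = np.random.SeedSequence(config.master_seed)
    db_seed, *subject_seeds = ss.spawn(1 + 2 * config.n_pairs)
    clin_seed = ss.spawn(1)[0]

    db = simulate_reference_db(
        model, config.n_epitopes, config.clones_per_epitope,
        rng=np.random.default_rng(db_seed),
    )

    truth = CohortTruth()
    repertoires: list[Repertoire] = []
    pairs: list[tuple[str, str]] = []
    pgen_cache: dict[str, float] = {}
    rows = []
    k = 0
    for p in range(config.n_pairs):
        pair_id = f"pair{p:02d}"
        for group, tag in ((GROUP_CASE, "APA"), (GROUP_CONTROL, "EH")):
            subject_id = f"{tag}{p:02d}"
            rng = np.random.default_rng(subject_seeds[k])
            k += 1
            rep, t = simulate_subject(
                model, config, group, db, rng,
                subject_id=subject_id, pair_id=pair_id, pgen_cache=pgen_cache,
            )
            repertoires.append(rep)
            truth.subjects[subject_id] = {
                "group": t["group"], "beta": t["beta"], "alpha": t["alpha"],
            }
            truth.clonotypes[subject_id] = t["planted"]
            rows.append({"subject_id": subject_id, "group": group, "pair_id": pair_id,
                         "beta": t["beta"]})
        pairs.append((f"APA{p:02d}", f"EH{p:02d}"))

    clin_rng = np.random.default_rng(clin_seed)
    clinical = pd.DataFrame(rows)
    for feat, (a, b) in CLINICAL_FEATURES.items():
        noise = clin_rng.normal(0.0, abs(b) * config.clinical_noise, size=len(clinical))
        clinical[feat] = a + b * clinical["beta"] + noise
    clinical = clinical.drop(columns=["beta"])

    cohort = Cohort(repertoires=repertoires, pairs=pairs)
    return cohort, db, clinical, truth
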