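"""Synthetic protein databases and simulated search results.

Everything downstream of a search engine — decoy construction, unique-peptide
ratios, corrected FDR, per-rank false-positive ratios — is testable without
real spectra if searches are simulated with known ground truth.  The
generator draws i.i.d. protein sequences from an average proteome residue
composition, then simulates a combined target+decoy search: each spectrum's
rank-1 match is correct with probability ``1 - pi0``; every incorrect match
(rank 1 with probability ``pi0``, ranks 2+ always) lands on a decoy peptide
with odds ``u : 1`` where ``u`` is the decoy/target unique-peptide ratio of
the databases searched — the core premise that decoy and target false
positives occur in proportion to the peptide candidates each side offers.

Correct scores stochastically dominate incorrect scores (by default a
normal correct-score family over a sharp Gumbel null; the estimators under
test are distribution-free, so the families only set test power).
Spectrum-level
correctness and scores are drawn from a stream keyed only by the seed, so
simulating the same spectra against two different decoy databases yields
comparable searches sharing their correct matches.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .digest import DigestParams, enumerate_unique_peptides
from .fdr import PSM
from .sequence_db import ProteinDatabase, ProteinRecord

#: Average residue composition of a well-annotated proteome (fractions).
DEFAULT_RESIDUE_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

MIN_PROTEIN_LENGTH = 20


@dataclass
class SimConfig:
    """Study conditions for one simulated search experiment."""

    n_proteins: int = 2000
    length_mean: float = 350.0
    length_sd: float = 120.0
    residue_frequencies: dict[str, float] | None = None
    n_spectra: int = 100_000
    pi0: float = 0.5                       # fraction of spectra w/o a correct match
    score_correct: tuple[float, float] = (4.0, 1.0)    # Normal (mean, sd)
    score_incorrect: tuple[float, float] = (0.0, 0.4)  # Gumbel (loc, scale)
    decoy_fraction: float = 0.125
    max_rank: int = 5
    seed: int = 0
    decoy_odds: float | None = None        # override of u, to model violations

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")

    def frequencies(self) -> tuple[list[str], np.ndarray]:
        freqs = self.residue_frequencies or DEFAULT_RESIDUE_FREQUENCIES
        letters = sorted(freqs)
        probs = np.array([freqs[aa] for aa in letters], dtype=float)
        if probs.sum() <= 0 or (probs < 0).any():
            raise ValueError("degenerate residue frequencies")
        return letters, probs / probs.sum()


@dataclass
class SimTruth:
    """Ground-truth labels aligned with the simulated PSM list."""

    is_correct: np.ndarray      # bool per PSM, same order as the list
    u: float                    # decoy/target odds used by the generator

    def __post_init__(self) -> None:
        self.is_correct = np.asarray(self.is_correct, dtype=bool)


def generate_protein_db(config: SimConfig,
                        accession_prefix: str = "SYN") -> ProteinDatabase:
    """Random protein database: normal lengths (truncated >= 20), i.i.d. residues."""
    rng = np.random.default_rng([config.seed, 11])
    letters, probs = config.frequencies()
    lengths = rng.normal(config.length_mean, config.length_sd,
                         size=config.n_proteins)
    lengths = np.maximum(np.rint(lengths).astype(int), MIN_PROTEIN_LENGTH)
    alphabet = np.array(letters)
    records = []
    width = len(str(config.n_proteins))
    for i, n in enumerate(lengths, start=1):
        seq = "".join(alphabet[rng.choice(len(alphabet), size=int(n), p=probs)])
        records.append(ProteinRecord(f"{accession_prefix}{i:0{width}d}",
                                     "synthetic protein", seq))
    return ProteinDatabase(records)


def _peptide_pool(db: ProteinDatabase, params: DigestParams) -> list[str]:
    return list(enumerate_unique_peptides(db, params).peptides)


def simulate_search(target: ProteinDatabase, decoy: ProteinDatabase,
                    config: SimConfig,
                    digest_params: DigestParams | None = None,
                    up_ratio: float | None = None,
                    target_pool: Sequence[str] | None = None,
                    decoy_pool: Sequence[str] | None = None,
                    ) -> tuple[list[PSM], SimTruth]:
    """Simulate a combined target+decoy search with ground-truth labels.

    Rank 1 of each spectrum is a correct target match with probability
    ``1 - pi0``; incorrect matches at any rank are decoys with probability
    ``u / (1 + u)``.  ``u`` defaults to the unique-peptide ratio of the two
    databases (``config.decoy_odds`` overrides it to model violations of
    that assumption).  Peptide pools may be passed in to avoid re-digesting
    when many simulations share the same databases.
    """
    params = digest_params or DigestParams()
    if target_pool is None:
        target_pool = _peptide_pool(target, params)
    if decoy_pool is None:
        decoy_pool = _peptide_pool(decoy, params)
    if not decoy_pool:
        raise ValueError("decoy database yields no unique peptides")
    if config.decoy_odds is not None:
        u = float(config.decoy_odds)
    elif up_ratio is not None:
        u = float(up_ratio)
    else:
        u = len(decoy_pool) / len(target_pool)

    n, n_ranks = config.n_spectra, config.max_rank
    # Stream A (spectrum randomness): identical across searches of the same
    # spectra, regardless of which decoy database is searched.
    rng_spec = np.random.default_rng([config.seed, 101])
    # Stream B (search randomness): decoy assignment and peptide identity.
    rng_search = np.random.default_rng([config.seed, 202])

    correct = rng_spec.random(n) < (1.0 - config.pi0)
    loc_c, scale_c = config.score_correct
    loc_i, scale_i = config.score_incorrect
    # Correct scores: normal, well separated; incorrect: Gumbel null with a
    # sharper exponential tail, so the score regions cross the way real
    # engine scores do and a fixed-FDR cutoff accepts most correct matches.
    scores_correct = rng_spec.normal(loc_c, scale_c, size=n)
    scores_incorrect = rng_spec.gumbel(loc_i, scale_i, size=(n, n_ranks))

    p_decoy = u / (1.0 + u)
    decoy_draw = rng_search.random((n, n_ranks)) < p_decoy
    is_decoy = decoy_draw.copy()
    is_decoy[correct, 0] = False

    t_idx = rng_search.integers(0, len(target_pool), size=(n, n_ranks))
    d_idx = rng_search.integers(0, len(decoy_pool), size=(n, n_ranks))
    t_acc = rng_search.integers(0, target.entry_count, size=(n, n_ranks))
    d_acc = rng_search.integers(0, decoy.entry_count, size=(n, n_ranks))

    scores = scores_incorrect
    scores[:, 0] = np.where(correct, scores_correct, scores_incorrect[:, 0])

    t_pool_arr = np.asarray(list(target_pool), dtype=object)
    d_pool_arr = np.asarray(list(decoy_pool), dtype=object)
    t_acc_arr = np.asarray(target.accessions, dtype=object)
    d_acc_arr = np.asarray(decoy.accessions, dtype=object)

    pep_arr = np.where(is_decoy, d_pool_arr[d_idx], t_pool_arr[t_idx]).ravel()
    prot_arr = np.where(is_decoy, d_acc_arr[d_acc], t_acc_arr[t_acc]).ravel()
    sids = np.repeat(np.array([f"spec{i + 1}" for i in range(n)],
                              dtype=object), n_ranks)
    ranks = np.tile(np.arange(1, n_ranks + 1), n).tolist()
    flat_scores = scores.ravel().tolist()
    flat_decoy = is_decoy.ravel().tolist()

    psms = [PSM(sid, r, pep, (prot,), sc, is_decoy=dec)
            for sid, r, pep, prot, sc, dec in zip(
                sids, ranks, pep_arr, prot_arr, flat_scores, flat_decoy)]

    is_correct = np.zeros((n, n_ranks), dtype=bool)
    is_correct[:, 0] = correct
    return psms, SimTruth(is_correct=is_correct.ravel(), u=u)


def true_fdr(psms: Sequence[PSM], truth: SimTruth, cutoff: float,
             higher_is_better: bool = True) -> float:
    """Exact fraction of incorrect matches among accepted rank-1 target PSMs."""
    sign = 1.0 if higher_is_better else -1.0
    accepted = incorrect = 0
    for p, ok in zip(psms, truth.is_correct):
        if p.rank == 1 and not p.is_decoy and sign * p.score >= sign * cutoff:
            accepted += 1
            incorrect += not ok
    if accepted == 0:
        raise ValueError("no accepted target PSMs at this cutoff")
    return incorrect / accepted


def cutoff_at_true_fdr(psms: Sequence[PSM], truth: SimTruth, alpha: float,
                       higher_is_better: bool = True) -> float:
    """Score of the largest accepted rank-1 target set with true FDR <= alpha."""
    sign = 1.0 if higher_is_better else -1.0
    pairs = [(sign * p.score, ok) for p, ok in zip(psms, truth.is_correct)
             if p.rank == 1 and not p.is_decoy]
    if not pairs:
        raise ValueError("no rank-1 target PSMs")
    pairs.sort(key=lambda t: -t[0])
    scores = np.array([s for s, _ in pairs])
    incorrect = np.cumsum([not ok for _, ok in pairs])
    accepted = np.arange(1, len(pairs) + 1)
    frac = incorrect / accepted
    ok_idx = np.flatnonzero(frac <= alpha)
    if ok_idx.size == 0:
        raise ValueError(f"no cutoff achieves true FDR <= {alpha}")
    return float(sign * scores[ok_idx[-1]])


def write_simulation(outdir: str | Path, target: ProteinDatabase,
                     decoy: ProteinDatabase, psms: Sequence[PSM],
                     truth: SimTruth, config: SimConfig) -> None:
    """Persist all simulated artifacts (FASTA, PSM TSV, truth TSV, config)."""
    from .fdr import write_psms
    from .sequence_db import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(target, outdir / "target.fasta")
    write_fasta(decoy, outdir / "decoy.fasta")
    write_psms(psms, outdir / "psms.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("spectrum_id\trank\tis_correct\n")
        for p, ok in zip(psms, truth.is_correct):
            fh.write(f"{p.spectrum_id}\t{p.rank}\t{int(ok)}\n")
    cfg = asdict(config)
    cfg["generator_u"] = truth.u
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
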