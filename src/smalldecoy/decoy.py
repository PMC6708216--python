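"""Decoy database construction and fractional subsampling.

Four sequence transformations are supported: plain reversal, pseudo-reversal
(reverse within each tryptic segment, keeping the C-terminal K/R of the
segment in place so the decoy stays tryptic-looking), uniform shuffling, and
pseudo-shuffling (shuffle within segments, K/R fixed).  A small decoy is a
simple random sample of the target, taken at a stated fraction of the
target's size and then transformed; sampling first is equivalent in
distribution because the transformation is per-protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Union

import numpy as np

from .digest import DigestParams, cleavage_sites
from .sequence_db import DEFAULT_DECOY_PREFIX, ProteinDatabase, ProteinRecord


class DecoyMethod(str, Enum):
    REVERSE = "reverse"
    PSEUDO_REVERSE = "pseudo_reverse"
    SHUFFLE = "shuffle"
    PSEUDO_SHUFFLE = "pseudo_shuffle"


FractionLike = Union[float, Fraction, str]


def _as_fraction(value: FractionLike) -> float:
    if isinstance(value, str):
        value = Fraction(value)
    return float(value)


@dataclass(frozen=True)
class DecoyBuildSpec:
    """How to build a small decoy: transformation, size fraction, seed."""

    method: DecoyMethod = DecoyMethod.REVERSE
    fraction: FractionLike = 1.0
    seed: int = 0
    sample_unit: str = "entries"  # "entries" | "residues"

    def __post_init__(self) -> None:
        frac = _as_fraction(self.fraction)
        if not 0.0 < frac <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.sample_unit not in ("entries", "residues"):
            raise ValueError("sample_unit must be 'entries' or 'residues'")


def _segments(seq: str, params: DigestParams) -> list[str]:
    bounds = [0] + cleavage_sites(seq, params) + [len(seq)]
    return [seq[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]


def reverse_sequence(seq: str) -> str:
    """Character-wise reversal of the whole protein."""
    if not seq:
        raise ValueError("cannot reverse an empty sequence")
    return seq[::-1]


def pseudo_reverse_sequence(seq: str,
                            params: DigestParams | None = None) -> str:
    """Reverse each tryptic segment, keeping its terminal K/R in place.

    The protein C-terminal segment, when it does not end in K/R, has no fixed
    terminus and is reversed whole.
    """
    if not seq:
        raise ValueError("cannot pseudo-reverse an empty sequence")
    params = params or DigestParams()
    out: list[str] = []
    for seg in _segments(seq, params):
        if seg[-1] in params.cleave_after:
            out.append(seg[-2::-1] + seg[-1])
        else:
            out.append(seg[::-1])
    return "".join(out)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of all residues."""
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def pseudo_shuffle_sequence(seq: str, rng: np.random.Generator,
                            params: DigestParams | None = None) -> str:
    """Shuffle within each tryptic segment, terminal K/R fixed in place."""
    if not seq:
        raise ValueError("cannot pseudo-shuffle an empty sequence")
    params = params or DigestParams()
    out: list[str] = []
    for seg in _segments(seq, params):
        if seg[-1] in params.cleave_after:
            body, term = seg[:-1], seg[-1]
        else:
            body, term = seg, ""
        if len(body) > 1:
            chars = np.array(list(body))
            rng.shuffle(chars)
            body = "".join(chars)
        out.append(body + term)
    return "".join(out)


def transform_sequence(seq: str, method: DecoyMethod,
                       rng: np.random.Generator | None = None,
                       params: DigestParams | None = None) -> str:
    method = DecoyMethod(method)
    if method is DecoyMethod.REVERSE:
        return reverse_sequence(seq)
    if method is DecoyMethod.PSEUDO_REVERSE:
        return pseudo_reverse_sequence(seq, params)
    if rng is None:
        raise ValueError(f"{method.value} requires a random generator")
    if method is DecoyMethod.SHUFFLE:
        return shuffle_sequence(seq, rng)
    return pseudo_shuffle_sequence(seq, rng, params)


def build_small_decoy(target: ProteinDatabase, spec: DecoyBuildSpec,
                      digest_params: DigestParams | None = None,
                      decoy_prefix: str = DEFAULT_DECOY_PREFIX,
                      ) -> tuple[ProteinDatabase, dict]:
    """Sample a fraction of the target and transform it into a decoy database.

    In ``entries`` mode the sample is exactly ``floor(fraction * entry_count)``
    records drawn without replacement; in ``residues`` mode records are taken
    from a random permutation until the residue budget
    ``floor(fraction * residue_count)`` would be exceeded.  One seed drives
    both sampling and any shuffling, so a fixed seed reproduces the decoy
    byte-for-byte.  Returns the decoy database and a build report with the
    achieved entry/residue ratios.
    """
    if not target.records:
        raise ValueError("target database is empty")
    frac = _as_fraction(spec.fraction)
    rng = np.random.default_rng(spec.seed)
    n = target.entry_count

    if spec.sample_unit == "entries":
        k = int(frac * n)
        if k < 1:
            raise ValueError(
                f"fraction {frac} of {n} entries yields an empty sample")
        idx = np.sort(rng.choice(n, size=k, replace=False))
    else:
        budget = int(frac * target.residue_count)
        order = rng.permutation(n)
        chosen: list[int] = []
        total = 0
        for i in order:
            length = len(target.records[i].sequence)
            if total + length > budget:
                continue
            chosen.append(int(i))
            total += length
            if total == budget:
                break
        if not chosen:
            raise ValueError(
                f"fraction {frac} of {target.residue_count} residues fits no protein")
        idx = np.sort(np.array(chosen))

    records = []
    for i in idx:
        rec = target.records[int(i)]
        decoy_seq = transform_sequence(rec.sequence, spec.method, rng,
                                       digest_params)
        records.append(ProteinRecord(decoy_prefix + rec.accession,
                                     rec.description, decoy_seq))
    db = ProteinDatabase(records, is_decoy=True, decoy_prefix=decoy_prefix)
    report = {
        "method": DecoyMethod(spec.method).value,
        "fraction_requested": frac,
        "sample_unit": spec.sample_unit,
        "seed": spec.seed,
        "decoy_entries": db.entry_count,
        "decoy_residues": db.residue_count,
        "achieved_entry_ratio": db.entry_count / target.entry_count,
        "achieved_residue_ratio": db.residue_count / target.residue_count,
        "order": "sample-then-transform",
    }
    return db, report
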