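"""In-silico tryptic digestion and unique-peptide enumeration.

The decoy/target unique-peptide ratio that corrects small-decoy FDR estimates
is defined over the peptides a search engine would actually consider, so the
digestion parameters here mirror a typical high-resolution search: trypsin
(cleave after K/R, optionally suppressed before proline), at most 2 missed
cleavages, fully tryptic termini, peptide length 6-45, and carbamidomethyl
as a fixed modification on cysteine.

Monoisotopic residue masses come from pyteomics; a peptide's neutral mass is
the residue sum plus one water plus any fixed-modification deltas.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from pyteomics import mass as _pmass

from .sequence_db import AMBIGUOUS_RESIDUES, ProteinDatabase

#: Monoisotopic mass of water, Da (peptide bond condensation complement).
WATER_MONO = 18.0105646837
#: Carbamidomethylation of cysteine (iodoacetamide), Da.
CARBAMIDOMETHYL = 57.021464

#: Monoisotopic residue (not amino-acid) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": CARBAMIDOMETHYL}


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings; defaults match a common high-resolution search."""

    max_missed_cleavages: int = 2
    ntt: int = 2
    min_length: int = 6
    max_length: int = 45
    cleave_after: frozenset[str] = frozenset("KR")
    suppress_before_proline: bool = True
    fixed_mods: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_MODS))
    clip_nterm_met: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if self.ntt not in (1, 2):
            raise ValueError("ntt must be 1 (semi-tryptic) or 2 (fully tryptic)")


@dataclass(frozen=True, slots=True)
class Peptide:
    sequence: str
    mass: float
    missed_cleavages: int
    ntt: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UniquePeptideSet:
    """Unique peptide sequences of one database, mapped to neutral mass."""

    peptides: dict[str, float]
    dropped_ambiguous: int = 0

    @property
    def count(self) -> int:
        return len(self.peptides)

    @property
    def n_max(self) -> float:
        """Largest precursor (neutral) mass present in the set."""
        if not self.peptides:
            raise ValueError("empty peptide set has no largest mass")
        return max(self.peptides.values())

    def masses(self) -> np.ndarray:
        return np.fromiter(self.peptides.values(), dtype=float,
                           count=len(self.peptides))

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)


def residue_mass_table(fixed_mods: Mapping[str, float] | None) -> dict[str, float]:
    """Residue masses with fixed-modification deltas folded in."""
    table = dict(RESIDUE_MASSES)
    for residue, delta in (fixed_mods or {}).items():
        if residue not in table:
            raise ValueError(f"fixed modification on unknown residue {residue!r}")
        table[residue] += delta
    return table


def peptide_mass(sequence: str,
                 fixed_mods: Mapping[str, float] | None = DEFAULT_FIXED_MODS) -> float:
    """Monoisotopic neutral mass of a peptide, Da.

    Sum of residue masses plus one water plus per-residue fixed-mod deltas.
    Raises for residues without a defined mass (including ambiguity letters).
    """
    if not sequence:
        raise ValueError("empty peptide has no mass")
    table = residue_mass_table(fixed_mods)
    try:
        return sum(map(table.__getitem__, sequence)) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"no mass defined for residue {exc.args[0]!r}") from None


def cleavage_sites(seq: str, params: DigestParams | None = None) -> list[int]:
    """0-based positions i (0 < i < len) where the backbone is cut before seq[i].

    A cut falls after K/R (configurable) and, with proline suppression on,
    never before P.
    """
    params = params or DigestParams()
    cleave = params.cleave_after
    noP = params.suppress_before_proline
    return [i for i in range(1, len(seq))
            if seq[i - 1] in cleave and not (noP and seq[i] == "P")]


def tryptic_segments(seq: str, params: DigestParams | None = None) -> list[str]:
    """Maximal zero-missed-cleavage segments of a protein, in order."""
    bounds = [0] + cleavage_sites(seq, params) + [len(seq)]
    return [seq[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]


def digest_sequence(seq: str, params: DigestParams | None = None) -> list[Peptide]:
    """Enumerate peptides of one protein under the digestion parameters.

    With ntt=2 both peptide ends coincide with protein termini or cleavage
    points; with ntt=1 one end may be non-tryptic.  Internal missed cleavage
    sites are bounded by ``max_missed_cleavages`` and length by
    ``[min_length, max_length]``.  Peptides containing ambiguity letters
    (B/J/O/U/X/Z) have no defined mass and are silently excluded.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    params = params or DigestParams()
    table = residue_mass_table(params.fixed_mods)
    sites = cleavage_sites(seq, params)
    starts = [0] + sites + [len(seq)]
    if params.clip_nterm_met and seq[0] == "M" and 1 not in starts:
        # Met excision exposes position 1 as an alternative N-terminal boundary.
        starts = sorted(starts + [1])
    has_ambiguous = bool(set(seq) & AMBIGUOUS_RESIDUES)

    peptides: list[Peptide] = []

    def emit(i: int, j: int, ntt: int) -> None:
        pep = seq[i:j]
        if has_ambiguous and set(pep) & AMBIGUOUS_RESIDUES:
            return
        lo = bisect.bisect_right(sites, i)
        hi = bisect.bisect_left(sites, j)
        missed = hi - lo
        mass = sum(map(table.__getitem__, pep)) + WATER_MONO
        peptides.append(Peptide(pep, mass, missed, ntt))

    n = len(seq)
    min_len, max_len = params.min_length, params.max_length
    mmc = params.max_missed_cleavages

    boundary = set(starts)
    for a_idx, i in enumerate(starts[:-1]):
        for j in starts[a_idx + 1:]:
            if j - i < min_len:
                continue
            if j - i > max_len:
                break
            lo = bisect.bisect_right(sites, i)
            hi = bisect.bisect_left(sites, j)
            if hi - lo > mmc:
                break
            emit(i, j, 2)

    if params.ntt == 1:
        semi: set[tuple[int, int]] = set()
        for i in starts[:-1]:  # tryptic N-terminus, free C-terminus
            for j in range(i + min_len, min(i + max_len, n) + 1):
                if j in boundary:
                    continue
                semi.add((i, j))
        for j in starts[1:]:  # free N-terminus, tryptic C-terminus
            for i in range(max(j - max_len, 0), j - min_len + 1):
                if i in boundary:
                    continue
                semi.add((i, j))
        for i, j in sorted(semi):
            lo = bisect.bisect_right(sites, i)
            hi = bisect.bisect_left(sites, j)
            if hi - lo > mmc:
                continue
            emit(i, j, 1)

    return peptides


def enumerate_unique_peptides(db: ProteinDatabase | Iterable[str],
                              params: DigestParams | None = None) -> UniquePeptideSet:
    """Union of per-protein digests, de-duplicated by exact sequence string.

    A peptide shared by several proteins is counted once; I and L are distinct
    characters.  The count of peptide occurrences dropped for containing
    ambiguity letters is tracked on the result.
    """
    params = params or DigestParams()
    table = residue_mass_table(params.fixed_mods)
    sequences = (r.sequence for r in db) if isinstance(db, ProteinDatabase) else db

    unique: dict[str, float] = {}
    dropped = 0
    for seq in sequences:
        sites = cleavage_sites(seq, params)
        starts = [0] + sites + [len(seq)]
        if params.clip_nterm_met and seq and seq[0] == "M" and 1 not in starts:
            starts = sorted(starts + [1])
        has_ambiguous = bool(set(seq) & AMBIGUOUS_RESIDUES)
        min_len, max_len, mmc = params.min_length, params.max_length, params.max_missed_cleavages
        if params.ntt == 2:
            m = len(starts)
            for a in range(m - 1):
                i = starts[a]
                for b in range(a + 1, m):
                    j = starts[b]
                    if j - i > max_len:
                        break
                    lo = bisect.bisect_right(sites, i)
                    hi = bisect.bisect_left(sites, j)
                    if hi - lo > mmc:
                        break
                    if j - i < min_len:
                        continue
                    pep = seq[i:j]
                    if pep in unique:
                        continue
                    if has_ambiguous and set(pep) & AMBIGUOUS_RESIDUES:
                        dropped += 1
                        continue
                    unique[pep] = sum(map(table.__getitem__, pep)) + WATER_MONO
        else:
            for pep_obj in digest_sequence(seq, params):
                unique.setdefault(pep_obj.sequence, pep_obj.mass)
    return UniquePeptideSet(unique, dropped_ambiguous=dropped)
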