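"""Entrapment validation via precursor-mass shifting.

Shifting every precursor's neutral mass by a fixed offset (default +10 Da)
makes every identification from a subsequent search a known false positive,
which allows the decoy/target false-positive ratio (FPRatio) to be measured
directly, rank by rank.  Under the small-decoy model this ratio is flat
across ranks and equals the unique-peptide ratio of the databases searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .fdr import PSM

PROTON_MASS = 1.00727646688  # Da, for completeness; shifts act on m/z directly


@dataclass
class ShiftStats:
    n_spectra: int = 0
    n_missing_charge: int = 0


@dataclass
class RankRatioReport:
    """Decoy/target counts and ratios per rank, plus the pooled FPRatio."""

    ranks: list[int]
    n_target: list[int]
    n_decoy: list[int]
    ratios: list[float | None]          # None where a rank has no targets
    pooled_ratio: float
    flatness: float | None              # max/min over defined ratios
    cv: float | None                    # coefficient of variation of ratios

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def shift_spectrum(spectrum: dict, delta_mass: float,
                   stats: ShiftStats | None = None) -> dict:
    """Shift one spectrum's neutral precursor mass by ``delta_mass`` Da.

    The precursor m/z moves by ``delta_mass / charge``; a record without a
    charge is treated as singly charged (counted in ``stats``).  Fragment
    peaks and all other fields pass through untouched.
    """
    params = dict(spectrum.get("params", {}))
    pepmass = params.get("pepmass")
    if pepmass is None:
        raise ValueError("spectrum has no PEPMASS")
    if isinstance(pepmass, (tuple, list)):
        mz, rest = float(pepmass[0]), tuple(pepmass[1:])
    else:
        mz, rest = float(pepmass), ()
    charge_field = params.get("charge")
    if charge_field:
        charge = abs(int(charge_field[0] if isinstance(charge_field, (list, tuple))
                         else charge_field))
    else:
        charge = 1
        if stats is not None:
            stats.n_missing_charge += 1
    new_mz = mz + delta_mass / charge
    if new_mz <= 0:
        raise ValueError(
            f"shift of {delta_mass} Da drives precursor m/z {mz} non-positive")
    params["pepmass"] = (new_mz, *rest) if rest else (new_mz,)
    out = dict(spectrum)
    out["params"] = params
    if stats is not None:
        stats.n_spectra += 1
    return out


def shift_precursor_masses(spectra: Iterable[dict], delta_mass: float,
                           stats: ShiftStats | None = None) -> Iterator[dict]:
    """Lazily shift a stream of spectra; see :func:`shift_spectrum`."""
    for spectrum in spectra:
        yield shift_spectrum(spectrum, delta_mass, stats)


def shift_mgf(in_path: str | Path, out_path: str | Path,
              delta_mass: float = 10.0) -> ShiftStats:
    """Shift every precursor in an MGF file; peak lists are preserved."""
    stats = ShiftStats()
    with _mgf.read(str(in_path), use_index=False) as reader:
        shifted = list(shift_precursor_masses(reader, delta_mass, stats))
    _mgf.write(shifted, str(out_path), file_mode="w")
    return stats


def compute_fp_ratio_by_rank(psms: Sequence[PSM],
                             max_rank: int = 5) -> RankRatioReport:
    """Tabulate decoy/target counts per rank on an all-incorrect search.

    Returns per-rank ratios, the pooled ratio (sum of decoys over sum of
    targets across ranks, the FPRatio estimate used to correct small-decoy
    FDR), a max/min flatness diagnostic and the coefficient of variation of
    the per-rank ratios.  A rank with zero targets gets a ``None`` ratio.
    """
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    n_target = [0] * max_rank
    n_decoy = [0] * max_rank
    for p in psms:
        if p.rank <= max_rank:
            if p.is_decoy:
                n_decoy[p.rank - 1] += 1
            else:
                n_target[p.rank - 1] += 1
    ratios: list[float | None] = [
        (d / t) if t > 0 else None for t, d in zip(n_target, n_decoy)
    ]
    total_t, total_d = sum(n_target), sum(n_decoy)
    if total_t == 0:
        raise ValueError("no target PSMs in any rank")
    pooled = total_d / total_t
    defined = [r for r in ratios if r is not None]
    flatness = (max(defined) / min(defined)
                if len(defined) >= 2 and min(defined) > 0 else None)
    cv = (float(np.std(defined) / np.mean(defined))
          if len(defined) >= 2 and np.mean(defined) > 0 else None)
    return RankRatioReport(ranks=list(range(1, max_rank + 1)),
                           n_target=n_target, n_decoy=n_decoy, ratios=ratios,
                           pooled_ratio=pooled, flatness=flatness, cv=cv)
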