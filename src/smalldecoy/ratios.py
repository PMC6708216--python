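"""Unique-peptide and database-size ratios.

The corrected small-decoy FDR divides the classical decoy/target PSM ratio by
the decoy/target *unique peptide* ratio (UPRatio), which tracks the ratio of
decoy to target false positives far better than the raw database-size ratio
(DBRatio).  This module computes both, plus a per-mass-window decomposition:
the mass axis is cut into bins of relative width twice the precursor
tolerance (one bin models the candidate set of one precursor), and the
through-origin slope of decoy versus target counts across bins recovers the
global UPRatio when the bins are well populated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest import DigestParams, UniquePeptideSet, enumerate_unique_peptides
from .sequence_db import ProteinDatabase

OVERLAP_POLICIES = ("keep", "drop-from-decoy", "drop-from-both")


@dataclass
class RatioReport:
    up_ratio: float
    db_ratio_entries: float
    db_ratio_residues: float
    overlap_count: int
    overlap_fraction: float
    n_target_unique: int
    n_decoy_unique: int
    overlap_policy: str = "drop-from-decoy"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class WindowSeries:
    """Per-mass-window unique-peptide counts at a given ppm tolerance."""

    low: np.ndarray        # window lower edges, Da
    high: np.ndarray       # window upper edges, Da
    target_count: np.ndarray
    decoy_count: np.ndarray
    tolerance_ppm: float

    def __len__(self) -> int:
        return len(self.low)

    def nonempty(self) -> np.ndarray:
        return (self.target_count > 0) | (self.decoy_count > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mass_low": self.low,
            "mass_high": self.high,
            "target_count": self.target_count,
            "decoy_count": self.decoy_count,
        })


def apply_overlap_policy(target_set: UniquePeptideSet,
                         decoy_set: UniquePeptideSet,
                         policy: str = "drop-from-decoy",
                         ) -> tuple[dict, dict, int]:
    """Resolve peptides present in both sets; returns (target, decoy, overlap).

    A decoy peptide that also occurs in the target would be credited to the
    target by a search engine, so the default removes it from the decoy side.
    """
    if policy not in OVERLAP_POLICIES:
        raise ValueError(f"unknown overlap policy {policy!r}")
    t, d = target_set.peptides, decoy_set.peptides
    shared = t.keys() & d.keys()
    if policy == "keep" or not shared:
        return dict(t), dict(d), len(shared)
    d2 = {k: v for k, v in d.items() if k not in shared}
    if policy == "drop-from-decoy":
        return dict(t), d2, len(shared)
    t2 = {k: v for k, v in t.items() if k not in shared}
    return t2, d2, len(shared)


def compute_up_ratio(target_set: UniquePeptideSet,
                     decoy_set: UniquePeptideSet,
                     overlap_policy: str = "drop-from-decoy",
                     statistic: str = "count") -> float:
    """Decoy/target unique-peptide ratio.

    Evaluating the cumulative unique-peptide count of each database at its own
    largest peptide mass, this is the total decoy count over the total target
    count across the digest-constrained mass range.  ``statistic="mass"``
    replaces counts by summed masses (a diagnostic alternative, not the
    default reading).
    """
    if target_set.count == 0:
        raise ValueError("target peptide set is empty")
    if statistic not in ("count", "mass"):
        raise ValueError("statistic must be 'count' or 'mass'")
    t, d, _ = apply_overlap_policy(target_set, decoy_set, overlap_policy)
    if not t:
        raise ValueError("target peptide set empty after overlap policy")
    if statistic == "count":
        return len(d) / len(t)
    return (sum(d.values()) / sum(t.values())) if d else 0.0


def compute_db_ratio(target: ProteinDatabase,
                     decoy: ProteinDatabase) -> tuple[float, float]:
    """Decoy/target database-size ratio in (entries, residues)."""
    if not target.records:
        raise ValueError("target database is empty")
    return (decoy.entry_count / target.entry_count,
            decoy.residue_count / target.residue_count)


def ratio_report(target: ProteinDatabase, decoy: ProteinDatabase,
                 params: DigestParams | None = None,
                 overlap_policy: str = "drop-from-decoy") -> RatioReport:
    """Full UPRatio/DBRatio report for a target/decoy database pair."""
    params = params or DigestParams()
    tset = enumerate_unique_peptides(target, params)
    dset = enumerate_unique_peptides(decoy, params)
    _, _, overlap = apply_overlap_policy(tset, dset, overlap_policy)
    up = compute_up_ratio(tset, dset, overlap_policy)
    dbe, dbr = compute_db_ratio(target, decoy)
    return RatioReport(
        up_ratio=up, db_ratio_entries=dbe, db_ratio_residues=dbr,
        overlap_count=overlap,
        overlap_fraction=overlap / tset.count,
        n_target_unique=tset.count, n_decoy_unique=dset.count,
        overlap_policy=overlap_policy)


def mass_window_scan(target_set: UniquePeptideSet,
                     decoy_set: UniquePeptideSet,
                     tolerance_ppm: float = 10.0) -> WindowSeries:
    """Partition the union mass range into log-spaced precursor-tolerance bins.

    Each window spans a relative width of ``2 * tolerance_ppm`` (the candidate
    interval of one precursor at that tolerance); windows tile the range
    contiguously, so per-window target counts sum to the target set size.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if target_set.count == 0:
        raise ValueError("target peptide set is empty")
    tm = target_set.masses()
    dm = decoy_set.masses() if decoy_set.count else np.empty(0)
    lo = min(tm.min(), dm.min() if dm.size else np.inf)
    hi = max(tm.max(), dm.max() if dm.size else -np.inf)
    width = 2.0 * tolerance_ppm * 1e-6
    log_step = math.log1p(width)
    n_win = int(math.floor(math.log(hi / lo) / log_step)) + 1

    def index(masses: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            k = np.floor(np.log(masses / lo) / log_step).astype(int)
        return np.clip(k, 0, n_win - 1)

    t_counts = np.bincount(index(tm), minlength=n_win)
    d_counts = (np.bincount(index(dm), minlength=n_win)
                if dm.size else np.zeros(n_win, dtype=int))
    edges = lo * np.exp(log_step * np.arange(n_win + 1))
    return WindowSeries(low=edges[:-1], high=edges[1:],
                        target_count=t_counts, decoy_count=d_counts,
                        tolerance_ppm=tolerance_ppm)


def window_slope(series: WindowSeries) -> float:
    """Through-origin least-squares slope of decoy vs target window counts.

    Empty windows are excluded; a window with zero targets must have expected
    zero decoys, so the fit is ``sum(x*y) / sum(x^2)`` with no intercept.
    """
    mask = series.nonempty()
    if mask.sum() < 2:
        raise ValueError("need at least 2 non-empty windows for a slope")
    x = series.target_count[mask].astype(float)
    y = series.decoy_count[mask].astype(float)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("all non-empty windows have zero target peptides")
    return float(np.dot(x, y) / denom)
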