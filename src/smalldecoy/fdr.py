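"""PSM-level FDR estimation with the small-decoy correction.

The classical target-decoy estimate at a score cutoff is
``FDR_TDS = #Decoy / #Target``.  When the decoy database is a fraction of the
target's size, decoy false positives are scarcer than target false positives
by the decoy/target unique-peptide ratio, so the estimate is rescaled:
``FDR_small = (#Decoy / #Target) / correction`` with the correction equal to
the UPRatio (or a directly measured false-positive ratio).  Reported
q-values are the running minimum of the raw FDR from the loosest cutoff
inward, which makes "PSMs at 1% FDR" well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_db import DEFAULT_DECOY_PREFIX

PSM_DIALECTS = ("generic_tsv", "comet_txt")


@dataclass(slots=True)
class PSM:
    """One candidate peptide-spectrum match."""

    spectrum_id: str
    rank: int
    peptide: str
    proteins: tuple[str, ...]
    score: float
    charge: int | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not self.proteins:
            raise ValueError("a PSM must map to at least one protein")


@dataclass
class FDRCurve:
    """Per-score-cutoff counts and FDR estimates, tightest cutoff first."""

    scores: np.ndarray          # distinct cutoffs, best score first
    n_target: np.ndarray        # targets at or above each cutoff
    n_decoy: np.ndarray
    fdr_tds: np.ndarray
    fdr_small: np.ndarray
    q_value_tds: np.ndarray
    q_value_small: np.ndarray
    correction: float
    higher_is_better: bool = True

    def __len__(self) -> int:
        return len(self.scores)

    def _index_for_score(self, score: float) -> int:
        oriented = self.scores if self.higher_is_better else -self.scores
        key = score if self.higher_is_better else -score
        # oriented is descending; find the loosest cutoff still >= `score`
        pos = np.searchsorted(-oriented, -key, side="right") - 1
        if pos < 0:
            raise ValueError(f"no cutoff at or above score {score}")
        return int(pos)

    def at_score(self, score: float) -> dict:
        """Counts and estimates at the loosest cutoff not looser than `score`."""
        i = self._index_for_score(score)
        return {
            "score": float(self.scores[i]),
            "n_target": int(self.n_target[i]),
            "n_decoy": int(self.n_decoy[i]),
            "fdr_tds": float(self.fdr_tds[i]),
            "fdr_small": float(self.fdr_small[i]),
            "q_value_tds": float(self.q_value_tds[i]),
            "q_value_small": float(self.q_value_small[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "score": self.scores,
            "n_target": self.n_target,
            "n_decoy": self.n_decoy,
            "fdr_tds": self.fdr_tds,
            "fdr_small": self.fdr_small,
            "q_value_tds": self.q_value_tds,
            "q_value_small": self.q_value_small,
        })


def read_psms(path: str | Path, dialect: str = "generic_tsv",
              score_column: str | None = None,
              higher_is_better: bool | None = None) -> list[PSM]:
    """Read a tab-separated PSM list.

    ``generic_tsv`` expects columns spectrum_id, rank, peptide, proteins
    (semicolon-separated), score.  ``comet_txt`` maps Comet's text export
    (scan, num, plain_peptide, protein, xcorr/e-value); a leading
    "CometVersion" revision line is skipped when present.
    """
    path = Path(path)
    if dialect not in PSM_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "generic_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
        required = {"spectrum_id", "rank", "peptide", "proteins", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        cols = dict(spectrum_id="spectrum_id", rank="rank", peptide="peptide",
                    proteins="proteins", score="score", charge="charge")
        sep = ";"
    else:
        with open(path) as fh:
            first = fh.readline()
        skip = 1 if first.startswith("CometVersion") else 0
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        score_col = score_column or ("xcorr" if "xcorr" in df.columns else "e-value")
        required = {"scan", "num", "plain_peptide", "protein", score_col}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        cols = dict(spectrum_id="scan", rank="num", peptide="plain_peptide",
                    proteins="protein", score=score_col, charge="charge")
        sep = ","

    psms: list[PSM] = []
    has_charge = cols["charge"] in df.columns
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            proteins = tuple(p.strip() for p in str(row[cols["proteins"]]).split(sep)
                             if p.strip())
            psms.append(PSM(
                spectrum_id=str(row[cols["spectrum_id"]]),
                rank=int(row[cols["rank"]]),
                peptide=str(row[cols["peptide"]]),
                proteins=proteins,
                score=float(row[cols["score"]]),
                charge=int(row[cols["charge"]]) if has_charge and pd.notna(row[cols["charge"]]) else None,
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: unparseable row {row_no}: {exc}") from None
    return psms


def annotate_decoy(psms: Iterable[PSM],
                   decoy_prefix: str = DEFAULT_DECOY_PREFIX,
                   shared_as_target: bool = True) -> list[PSM]:
    """Set ``is_decoy`` from protein accessions.

    A PSM is a decoy only when *all* of its mapped proteins carry the decoy
    prefix; a peptide shared between target and decoy proteins counts as
    target (configurable via ``shared_as_target``; with it off, any decoy
    protein makes the PSM a decoy).
    """
    if not decoy_prefix:
        raise ValueError("decoy_prefix must be non-empty")
    out: list[PSM] = []
    for psm in psms:
        flags = [p.startswith(decoy_prefix) for p in psm.proteins]
        is_decoy = all(flags) if shared_as_target else any(flags)
        out.append(replace_is_decoy(psm, is_decoy))
    return out


def replace_is_decoy(psm: PSM, is_decoy: bool) -> PSM:
    return PSM(psm.spectrum_id, psm.rank, psm.peptide, psm.proteins,
               psm.score, psm.charge, is_decoy)


def _rank1_arrays(psms: Sequence[PSM], rank_filter: int,
                  higher_is_better: bool) -> tuple[np.ndarray, np.ndarray]:
    scores = np.fromiter((p.score for p in psms if p.rank <= rank_filter),
                         dtype=float)
    decoy = np.fromiter((p.is_decoy for p in psms if p.rank <= rank_filter),
                        dtype=bool)
    if scores.size == 0:
        raise ValueError(f"no PSMs at rank <= {rank_filter}")
    return scores, decoy


def estimate_fdr_curve(psms: Sequence[PSM], correction: float = 1.0,
                       rank_filter: int = 1,
                       higher_is_better: bool = True) -> FDRCurve:
    """Build the FDR curve over all distinct score cutoffs.

    At each cutoff, targets and decoys at or above it are counted;
    ``fdr_tds = n_decoy / n_target`` (0 when no decoys, 1 when no targets),
    ``fdr_small = fdr_tds / correction`` capped at 1, and q-values are the
    running minimum of each FDR series from the loosest cutoff inward.
    """
    if correction <= 0:
        raise ValueError("correction must be positive")
    scores, decoy = _rank1_arrays(psms, rank_filter, higher_is_better)
    oriented = scores if higher_is_better else -scores
    order = np.argsort(-oriented, kind="stable")
    s_sorted = oriented[order]
    d_sorted = decoy[order]

    cum_decoy = np.cumsum(d_sorted)
    cum_target = np.arange(1, len(s_sorted) + 1) - cum_decoy

    # last occurrence of each distinct score = counts at that cutoff
    is_last = np.ones(len(s_sorted), dtype=bool)
    is_last[:-1] = s_sorted[:-1] != s_sorted[1:]
    cut = np.flatnonzero(is_last)
    n_target = cum_target[cut]
    n_decoy = cum_decoy[cut]
    cut_scores = s_sorted[cut] if higher_is_better else -s_sorted[cut]

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_tds = np.where(n_target > 0, n_decoy / np.maximum(n_target, 1),
                           np.where(n_decoy > 0, 1.0, 0.0))
    fdr_small = np.minimum(fdr_tds / correction, 1.0)

    def qvals(f: np.ndarray) -> np.ndarray:
        return np.minimum.accumulate(f[::-1])[::-1]

    return FDRCurve(scores=cut_scores, n_target=n_target, n_decoy=n_decoy,
                    fdr_tds=fdr_tds, fdr_small=fdr_small,
                    q_value_tds=qvals(fdr_tds), q_value_small=qvals(fdr_small),
                    correction=correction, higher_is_better=higher_is_better)


def filter_at_fdr(curve: FDRCurve, psms: Sequence[PSM], alpha: float,
                  estimator: str = "small", rank_filter: int = 1) -> list[PSM]:
    """Target PSMs accepted at the loosest cutoff whose q-value is <= alpha.

    Returns the target (non-decoy) PSMs at rank <= ``rank_filter`` scoring at
    or above that cutoff, ordered by score then spectrum id; an empty list
    when no cutoff qualifies.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if estimator not in ("tds", "small"):
        raise ValueError("estimator must be 'tds' or 'small'")
    q = curve.q_value_small if estimator == "small" else curve.q_value_tds
    ok = np.flatnonzero(q <= alpha)
    if ok.size == 0:
        return []
    cutoff = curve.scores[ok[-1]]  # q monotone: last index is the loosest
    sign = 1.0 if curve.higher_is_better else -1.0
    accepted = [p for p in psms
                if p.rank <= rank_filter and not p.is_decoy
                and sign * p.score >= sign * cutoff]
    accepted.sort(key=lambda p: (-sign * p.score, p.spectrum_id))
    return accepted


def write_psms(psms: Sequence[PSM], path: str | Path) -> None:
    """Write PSMs as a generic TSV (inverse of ``read_psms`` generic dialect)."""
    df = pd.DataFrame({
        "spectrum_id": [p.spectrum_id for p in psms],
        "rank": [p.rank for p in psms],
        "peptide": [p.peptide for p in psms],
        "proteins": [";".join(p.proteins) for p in psms],
        "score": [p.score for p in psms],
        "charge": [p.charge if p.charge is not None else "" for p in psms],
    })
    df.to_csv(path, sep="\t", index=False)
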