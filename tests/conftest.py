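"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from smalldecoy import DigestParams, ProteinDatabase, ProteinRecord, SimConfig
from smalldecoy.synthetic import generate_protein_db

STANDARD_20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(seq: str, params: DigestParams) -> Counter:
    """Independent digestion oracle: test every substring against the rules.

    Returns a multiset of (peptide, missed_cleavages) pairs over all substring
    positions satisfying the cleavage/length/missed-cleavage predicates.
    Deliberately naive (O(n^2) substrings) and shares no code with the
    implementation under test.
    """
    n = len(seq)
    sites = [i for i in range(1, n)
             if seq[i - 1] in params.cleave_after
             and not (params.suppress_before_proline and seq[i] == "P")]
    termini = {0, n} | set(sites)
    out: Counter = Counter()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not params.min_length <= j - i <= params.max_length:
                continue
            ntt = (i in termini) + (j in termini)
            if ntt < params.ntt:
                continue
            missed = sum(1 for s in sites if i < s < j)
            if missed > params.max_missed_cleavages:
                continue
            out[(seq[i:j], missed)] += 1
    return out


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_20), size=length))


@pytest.fixture(scope="session")
def tiny_db() -> ProteinDatabase:
    return ProteinDatabase([
        ProteinRecord("P1", "first protein", "MKTAYIAKQRPEPTIDEK"),
        ProteinRecord("P2", "", "AAAGGGKCCDDEEFFRKLMNPQR"),
        ProteinRecord("P3", "third", "PEPTIDEKPEPTIDER"),
    ])


@pytest.fixture(scope="session")
def synthetic_db_500() -> ProteinDatabase:
    return generate_protein_db(SimConfig(n_proteins=500, seed=1))
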