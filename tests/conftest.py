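"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
Fisher oracle enumerates margin-preserving tables in exact rational
arithmetic, and the projection oracle is a brute-force double loop over
all disease pairs.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import pytest

from diseasome import (
    DiseaseGeneAssociation,
    GeneSymbol,
    HgncRecord,
    IcdCode,
    SyntheticConfig,
    generate_study,
)


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive margin-preserving enumeration.

    Point probabilities are exact rationals, so ties are exact and no
    floating slack is needed on the oracle side.
    """
    r1, k, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, k)
    lo, hi = max(0, k - (n - r1)), min(k, r1)
    probs = [Fraction(comb(r1, x) * comb(n - r1, k - x), denom) for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return float(sum(p for p in probs if p <= p_obs))


def brute_force_pairs(profiles: dict) -> dict[tuple, frozenset]:
    """All unordered disease pairs with non-empty intersection, by double loop."""
    out = {}
    for x, y in itertools.combinations(sorted(profiles), 2):
        shared = set(profiles[x]) & set(profiles[y])
        if shared:
            out[(x, y)] = frozenset(shared)
    return out


@pytest.fixture(scope="session")
def tiny_authority() -> list[HgncRecord]:
    g = GeneSymbol
    return [
        HgncRecord(approved=g("EGFR"), previous=frozenset({g("ERBB1")}),
                   aliases=frozenset({g("HER1")})),
        HgncRecord(approved=g("TP53"), aliases=frozenset({g("P53")})),
        HgncRecord(approved=g("KRAS"), previous=frozenset({g("KRAS2")})),
        HgncRecord(approved=g("GONE"), status="withdrawn",
                   previous=frozenset({g("OLDGONE")})),
    ]


@pytest.fixture(scope="session")
def tiny_assocs() -> list[DiseaseGeneAssociation]:
    return [
        DiseaseGeneAssociation(IcdCode("C34"), GeneSymbol("ERBB1")),
        DiseaseGeneAssociation(IcdCode("C34"), GeneSymbol("TP53")),
        DiseaseGeneAssociation(IcdCode("J45"), GeneSymbol("P53")),
        DiseaseGeneAssociation(IcdCode("J45"), GeneSymbol("UNKNOWN1")),
    ]


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured synthetic study shared across tests."""
    return generate_study(SyntheticConfig(seed=42, codes_per_chapter=5, n_genes=300,
                                          n_pathways=120, n_background_candidates=100,
                                          n_planted_enriched=10, n_subset_pairs=5))
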