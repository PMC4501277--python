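"""Gene-disease prediction by pathway-overlap enrichment.

Candidate genes — genes with at least one pathway membership but no known
phenotype-causing mutation — are scored against every disease whose
pathway profile they intersect, using a two-tailed Fisher exact test on a
2x2 pathway-count table.  Pairs at or below a raw p-value threshold
(default 0.001) are kept and ranked.

Two table constructions are supported (see :class:`ContingencyTable`):
``paper_literal`` (the default; the disease column counts all of the
disease's pathways, so shared ones are counted on both sides) and
``conventional`` (the standard partition of the pathway universe).

The two-sided p-value is the sum of hypergeometric point probabilities,
over all tables with the observed margins, that do not exceed the
observed table's point probability (with 1e-7 relative slack for
floating-point ties) — the same definition ``scipy.stats.fisher_exact``
implements.  Point probabilities come from ``scipy.stats.hypergeom``,
vectorized over the support and cached per margin set so that studies
with hundreds of thousands of pairs stay fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.stats import hypergeom

from .errors import ContractViolationError
from .model import ContingencyTable, GeneSymbol, IcdCode, Prediction

_TIE_SLACK = 1e-7


def candidate_gene_set(
    gene_profiles: Mapping[GeneSymbol, frozenset],
    disease_genes: frozenset[GeneSymbol],
) -> set[GeneSymbol]:
    """Genes with >= 1 pathway membership and no disease-gene association."""
    return {g for g, paths in gene_profiles.items() if paths and g not in disease_genes}


def contingency_table(
    gene_pathways: frozenset,
    disease_pathways: frozenset,
    N: int,
    mode: str = "paper_literal",
) -> ContingencyTable:
    """Build the 2x2 table for one gene-disease pair.

    ``a`` = |N_g ∩ N_d|, ``b`` = N_g − a; ``c`` and ``d`` follow the
    construction mode.  ``N`` is the pathway universe size and must cover
    the union of both sets.
    """
    gene_pathways = frozenset(gene_pathways)
    disease_pathways = frozenset(disease_pathways)
    n_g, n_d = len(gene_pathways), len(disease_pathways)
    if N < len(gene_pathways | disease_pathways):
        raise ContractViolationError(
            f"universe N={N} smaller than |gene ∪ disease| = "
            f"{len(gene_pathways | disease_pathways)}"
        )
    a = len(gene_pathways & disease_pathways)
    b = n_g - a
    if mode == "paper_literal":
        c, d = n_d, N - n_d
    elif mode == "conventional":
        c, d = n_d - a, N - n_g - n_d + a
    else:
        raise ValueError(f"unknown construction mode {mode!r}")
    return ContingencyTable(a=a, b=b, c=c, d=d, N_g=n_g, N_d=n_d, N=N, mode=mode)


@lru_cache(maxsize=100_000)
def _margin_pmf(n: int, r1: int, k: int) -> tuple[int, tuple[float, ...]]:
    """Hypergeometric pmf over the support of tables with margins (r1, n-r1; k, n-k).

    Returns (lowest feasible a, pmf values across the support).
    """
    lo = max(0, k - (n - r1))
    hi = min(k, r1)
    x = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(x, n, r1, k)
    return lo, tuple(float(v) for v in pmf)


def fisher_two_tailed(
    table: Union[ContingencyTable, Sequence[Sequence[int]]],
) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Sums the point probabilities of every margin-preserving table whose
    probability does not exceed the observed one (1e-7 relative tie
    slack).  Accepts a :class:`ContingencyTable` or a raw [[a,b],[c,d]].
    """
    if isinstance(table, ContingencyTable):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ContractViolationError("negative cell in contingency table")
    n = a + b + c + d
    if n < 1:
        raise ContractViolationError("empty contingency table")
    lo, pmf = _margin_pmf(n, a + b, a + c)
    p_obs = pmf[a - lo]
    p = sum(v for v in pmf if v <= p_obs * (1.0 + _TIE_SLACK))
    return min(1.0, float(p))


@dataclass
class EnrichmentResult:
    """Full outcome of an enrichment run.

    ``evaluated`` holds every scored pair ranked 1..M over the whole run;
    ``predictions`` is the kept subset (p <= alpha), re-ranked 1..K.
    """

    predictions: list[Prediction]
    evaluated: list[Prediction]
    n_evaluated: int
    universe_size: int
    alpha: float
    mode: str
    universe: str

    def summary(self) -> dict:
        return {
            "pairs_evaluated": self.n_evaluated,
            "pairs_kept": len(self.predictions),
            "universe_size": self.universe_size,
            "alpha": self.alpha,
            "mode": self.mode,
            "universe": self.universe,
        }


def enrich_predictions(
    candidates: Mapping[GeneSymbol, frozenset],
    diseases: Mapping[IcdCode, frozenset],
    N: int | None = None,
    alpha: float = 0.001,
    mode: str = "paper_literal",
    universe: str = "disease_linked",
    bh: bool = False,
) -> EnrichmentResult:
    """Score every candidate-gene x disease pair sharing >= 1 pathway.

    ``universe`` chooses the pathway universe N when not given explicitly:
    ``disease_linked`` (default) is the union of pathways over disease
    profiles — candidate pathways outside it are ignored so the table
    stays consistent with N — while ``all`` adds candidate-only pathways.
    With ``bh=True`` the p <= alpha filter is applied to
    Benjamini-Hochberg adjusted p-values instead of raw ones (reported
    p-values stay raw).

    Ties are broken by ascending p, then descending shared-pathway count,
    then (gene, code) lexicographically, making output deterministic.
    """
    if not (0.0 < alpha <= 1.0):
        raise ContractViolationError(f"alpha {alpha} outside (0, 1]")
    if universe not in ("disease_linked", "all"):
        raise ValueError(f"unknown universe {universe!r}")
    diseases = {c: frozenset(p) for c, p in diseases.items() if p}
    disease_universe = frozenset().union(*diseases.values()) if diseases else frozenset()
    if universe == "disease_linked":
        universe_set = disease_universe
        cand_profiles = {g: frozenset(p) & universe_set for g, p in candidates.items()}
    else:
        universe_set = disease_universe.union(*(candidates.values() or [frozenset()]))
        cand_profiles = {g: frozenset(p) for g, p in candidates.items()}
    n_universe = len(universe_set) if N is None else int(N)

    codes_by_pathway: dict[object, list] = {}
    for code in sorted(diseases):
        for p in diseases[code]:
            codes_by_pathway.setdefault(p, []).append(code)

    scored: list[tuple[float, int, GeneSymbol, IcdCode]] = []
    for gene in sorted(cand_profiles):
        gpaths = cand_profiles[gene]
        if not gpaths:
            continue
        hit_codes: set = set()
        for p in gpaths:
            hit_codes.update(codes_by_pathway.get(p, ()))
        for code in sorted(hit_codes):
            tab = contingency_table(gpaths, diseases[code], n_universe, mode=mode)
            scored.append((fisher_two_tailed(tab), -tab.a, gene, code))

    scored.sort()
    evaluated = [
        Prediction(gene=g, code=c, shared_pathways=-neg_a, p_value=p, rank=i + 1)
        for i, (p, neg_a, g, c) in enumerate(scored)
    ]
    if bh and evaluated:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [pr.p_value for pr in evaluated], alpha=alpha, method="fdr_bh"
        )
        kept_src = [pr for pr, rej in zip(evaluated, reject) if rej]
    else:
        kept_src = [pr for pr in evaluated if pr.p_value <= alpha]
    predictions = [
        Prediction(
            gene=pr.gene,
            code=pr.code,
            shared_pathways=pr.shared_pathways,
            p_value=pr.p_value,
            rank=i + 1,
        )
        for i, pr in enumerate(kept_src)
    ]
    return EnrichmentResult(
        predictions=predictions,
        evaluated=evaluated,
        n_evaluated=len(evaluated),
        universe_size=n_universe,
        alpha=alpha,
        mode=mode,
        universe=universe,
    )


def write_predictions(
    result: EnrichmentResult,
    tsv_path: Union[str, Path],
    summary_json_path: Union[str, Path, None] = None,
) -> None:
    """Ranked TSV (gene, code, shared_pathways, p_value, rank) + JSON summary."""
    import pandas as pd

    df = pd.DataFrame(
        [
            (str(p.gene), str(p.code), p.shared_pathways, repr(p.p_value), p.rank)
            for p in result.predictions
        ],
        columns=["gene", "code", "shared_pathways", "p_value", "rank"],
    )
    df.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if summary_json_path is not None:
        Path(summary_json_path).write_text(json.dumps(result.summary(), indent=2) + "\n")
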