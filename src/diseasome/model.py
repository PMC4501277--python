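"""Domain types for disease-gene-pathway association analysis.

The atoms of the analysis are standardized identifiers: HGNC-style gene
symbols, ICD-10-CM disease codes, and KEGG-style pathway identifiers
(pathway maps ``ko``, modules ``M``, disease entries ``H``).  All three are
thin validated ``str`` subclasses so they hash, sort and serialize like
plain strings while rejecting malformed input at construction time.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from fractions import Fraction
from typing import NamedTuple

from .errors import ContractViolationError

_GENE_RE = re.compile(r"^[A-Z0-9][A-Z0-9-]*$")
_ICD_RE = re.compile(r"^[A-Z][0-9A-Z]{2}(\.[0-9A-Z]{1,4})?$")
_PATHWAY_RE = re.compile(r"^(ko|M|H)[0-9A-Za-z]+$")

#: The three KEGG identifier classes pooled as "pathways" in this analysis.
PATHWAY_CLASSES = ("ko", "M", "H")


class GeneSymbol(str):
    """An HGNC-style gene symbol: uppercase alphanumerics and hyphens.

    Input is case-normalized to uppercase so comparison is effectively
    case-insensitive; whitespace-bearing or empty strings are rejected.
    """

    __slots__ = ()

    def __new__(cls, symbol: str) -> "GeneSymbol":
        s = str(symbol).strip().upper()
        if not _GENE_RE.match(s):
            raise ValueError(f"invalid gene symbol: {symbol!r}")
        return super().__new__(cls, s)


class IcdCode(str):
    """An ICD-10-CM code: letter + 2 alphanumerics, optional '.' sub-code.

    Examples: ``C34``, ``O9A``, ``E11.9``.  Case-normalized to uppercase.
    """

    __slots__ = ()

    def __new__(cls, code: str) -> "IcdCode":
        s = str(code).strip().upper()
        if not _ICD_RE.match(s):
            raise ValueError(f"invalid ICD-10-CM code: {code!r}")
        return super().__new__(cls, s)

    @property
    def root(self) -> str:
        """The 3-character category prefix used for chapter assignment."""
        return str(self)[:3]


class PathwayId(str):
    """A KEGG-style pathway identifier with its class prefix (ko/M/H)."""

    __slots__ = ()

    def __new__(cls, pid: str) -> "PathwayId":
        s = str(pid).strip()
        if not _PATHWAY_RE.match(s):
            raise ValueError(
                f"invalid pathway id {pid!r}: expected prefix one of {PATHWAY_CLASSES}"
            )
        return super().__new__(cls, s)

    @property
    def cls(self) -> str:
        """Identifier class: ``ko`` (pathway map), ``M`` (module) or ``H`` (disease)."""
        return "ko" if str(self).startswith("ko") else str(self)[0]


@dataclass(frozen=True)
class HgncRecord:
    """One row of a gene-symbol authority table.

    ``previous`` are formerly-approved symbols, ``aliases`` informal
    synonyms; both map onto ``approved``.  Withdrawn records never receive
    mappings during normalization.
    """

    approved: GeneSymbol
    previous: frozenset[GeneSymbol] = frozenset()
    aliases: frozenset[GeneSymbol] = frozenset()
    status: str = "approved"

    def __post_init__(self) -> None:
        if self.status not in ("approved", "withdrawn"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.approved in self.previous or self.approved in self.aliases:
            raise ValueError(
                f"approved symbol {self.approved} also listed as previous/alias"
            )


class DiseaseGeneAssociation(NamedTuple):
    """One (ICD-10-CM code, gene symbol) edge of the bipartite network."""

    code: IcdCode
    gene: GeneSymbol


class GenePathwayAssociation(NamedTuple):
    """One (gene symbol, pathway id) membership edge."""

    gene: GeneSymbol
    pathway: PathwayId


class TripartiteTriple(NamedTuple):
    """One (code, gene, pathway) interaction of the tripartite network."""

    code: IcdCode
    gene: GeneSymbol
    pathway: PathwayId


@dataclass(frozen=True)
class NormalizationReport:
    """Bookkeeping from rewriting raw gene symbols to approved ones."""

    n_input_rows: int
    n_already_approved: int
    n_mapped_via_previous_or_alias: int
    n_dropped_unmatched: int
    n_deduplicated: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


@dataclass(frozen=True)
class ElementProfile:
    """The element set (genes or pathways) attached to one disease code.

    Houses n_x / n_y of the inclusion index: ``len(profile.elements)`` is
    the number of genes or pathways in the disease.
    """

    entity: str
    elements: frozenset
    mode: str  # "gene" | "pathway"

    def __post_init__(self) -> None:
        if self.mode not in ("gene", "pathway"):
            raise ValueError(f"invalid profile mode {self.mode!r}")
        if not self.elements:
            raise ContractViolationError(f"empty element profile for {self.entity}")


@dataclass(frozen=True)
class DiseasePair:
    """An unordered disease pair sharing at least one element.

    Canonically stored with the lexicographically smaller code as ``x``.
    """

    x: IcdCode
    y: IcdCode
    shared: frozenset
    mode: str

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ContractViolationError(f"self-pair {self.x}")
        if not self.shared:
            raise ContractViolationError(f"pair ({self.x},{self.y}) shares nothing")
        if self.x > self.y:
            object.__setattr__(self, "x", self.y)
            object.__setattr__(self, "y", self.x)


@dataclass(frozen=True)
class InclusionRecord:
    """One directed disease pair with its inclusion index.

    tau = shared / n_x exactly (kept as a Fraction); tau = 1 iff disease
    x's element set is a subset of disease y's.
    """

    x: IcdCode
    y: IcdCode
    mode: str
    n_x: int
    n_y: int
    shared: int
    tau: Fraction

    def __post_init__(self) -> None:
        if not (1 <= self.shared <= min(self.n_x, self.n_y)):
            raise ContractViolationError(
                f"({self.x}->{self.y}): shared={self.shared} outside "
                f"[1, min({self.n_x},{self.n_y})]"
            )
        if self.tau != Fraction(self.shared, self.n_x):
            raise ContractViolationError(
                f"({self.x}->{self.y}): tau {self.tau} != {self.shared}/{self.n_x}"
            )

    @property
    def tau_float(self) -> float:
        return float(self.tau)


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary of a group of inclusion-index values."""

    group: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("empty distribution summary")
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError(f"non-monotone quartiles in group {self.group}")


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 table behind the Fisher test of one gene-disease pair.

    a = pathways shared between gene and disease (|N_g ∩ N_d|)
    b = pathways in the gene not in the disease (N_g − a)
    c, d depend on the construction mode:

    * ``paper_literal`` — c = N_d and d = N − N_d, i.e. shared pathways are
      counted in both the gene column and the disease column.
    * ``conventional`` — the standard partition of the universe:
      c = N_d − a, d = N − N_g − N_d + a.
    """

    a: int
    b: int
    c: int
    d: int
    N_g: int
    N_d: int
    N: int
    mode: str = "paper_literal"

    def __post_init__(self) -> None:
        if self.mode not in ("paper_literal", "conventional"):
            raise ValueError(f"invalid construction mode {self.mode!r}")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractViolationError(
                f"negative cell in table a={self.a} b={self.b} c={self.c} d={self.d} "
                f"(N_g={self.N_g}, N_d={self.N_d}, N={self.N}, mode={self.mode})"
            )
        if self.a + self.b != self.N_g:
            raise ContractViolationError("a + b must equal N_g")
        if self.a > min(self.N_g, self.N_d):
            raise ContractViolationError("a exceeds min(N_g, N_d)")
        if self.mode == "paper_literal":
            ok = self.c == self.N_d and self.d == self.N - self.N_d
        else:
            ok = (
                self.c == self.N_d - self.a
                and self.d == self.N - self.N_g - self.N_d + self.a
            )
        if not ok:
            raise ContractViolationError(f"cells inconsistent with mode {self.mode}")

    def cells(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class Prediction:
    """One predicted gene-disease association with its enrichment p-value."""

    gene: GeneSymbol
    code: IcdCode
    shared_pathways: int
    p_value: float
    rank: int

    def __post_init__(self) -> None:
        if self.shared_pathways < 1:
            raise ValueError("a prediction requires >= 1 shared pathway")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")
        if self.rank < 1:
            raise ValueError("ranks start at 1")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic study.

    ``subset_pairs`` lists (x, y) with profile(x) a strict subset of
    profile(y); ``enriched_pairs`` lists planted candidate (gene, code)
    pairs; ``alias_map`` maps each raw symbol written into the
    disease-gene table to its approved form.
    """

    subset_pairs: list[tuple[IcdCode, IcdCode]]
    enriched_pairs: list[tuple[GeneSymbol, IcdCode]]
    alias_map: dict[GeneSymbol, GeneSymbol]

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "subset_pairs": [[str(x), str(y)] for x, y in self.subset_pairs],
                "enriched_pairs": [[str(g), str(c)] for g, c in self.enriched_pairs],
                "alias_map": {str(k): str(v) for k, v in self.alias_map.items()},
            },
            **kwargs,
        )
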