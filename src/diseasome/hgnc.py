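"""Gene-symbol normalization against an HGNC-like authority table.

Raw symbols found in disease-gene tables drift behind the nomenclature:
a symbol may already be the approved one, may be a previous symbol or an
alias of an approved record, or may match nothing.  Normalization rewrites
every association to approved symbols, drops unmatched rows, merges
duplicates created by rewriting, and reports the bookkeeping.

Matching precedence is approved > previous > alias: a hit at a higher
tier suppresses lower tiers, mirroring HGNC's own disambiguation
convention.  Withdrawn records contribute nothing (their symbols are
treated as unmatched).  A raw symbol matching two approved records at the
same tier raises :class:`AmbiguousSymbolError` rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmbiguousSymbolError, ContractViolationError
from .model import (
    DiseaseGeneAssociation,
    GeneSymbol,
    HgncRecord,
    NormalizationReport,
)


@dataclass
class SymbolIndex:
    """Lookup maps built once from an authority table."""

    approved: frozenset[GeneSymbol]
    previous: dict[GeneSymbol, list[GeneSymbol]] = field(default_factory=dict)
    aliases: dict[GeneSymbol, list[GeneSymbol]] = field(default_factory=dict)

    def resolve(self, raw: GeneSymbol) -> GeneSymbol | None:
        """Map a raw symbol to its approved form, or None if unmatched."""
        if raw in self.approved:
            return raw
        for tier in (self.previous, self.aliases):
            if raw in tier:
                candidates = tier[raw]
                if len(candidates) > 1:
                    raise AmbiguousSymbolError(raw, candidates)
                return candidates[0]
        return None


def build_symbol_index(authority: list[HgncRecord]) -> SymbolIndex:
    """Index an authority table, excluding withdrawn records entirely."""
    live = [r for r in authority if r.status == "approved"]
    approved = [r.approved for r in live]
    if len(set(approved)) != len(approved):
        raise ContractViolationError("authority table has duplicate approved symbols")
    previous: dict[GeneSymbol, list[GeneSymbol]] = {}
    aliases: dict[GeneSymbol, list[GeneSymbol]] = {}
    for rec in live:
        for sym in rec.previous:
            previous.setdefault(sym, []).append(rec.approved)
        for sym in rec.aliases:
            aliases.setdefault(sym, []).append(rec.approved)
    for tier in (previous, aliases):
        for sym in tier:
            tier[sym] = sorted(set(tier[sym]))
    return SymbolIndex(approved=frozenset(approved), previous=previous, aliases=aliases)


def normalize_symbols(
    assocs: list[DiseaseGeneAssociation],
    authority: list[HgncRecord],
) -> tuple[list[DiseaseGeneAssociation], NormalizationReport]:
    """Rewrite disease-gene associations to approved gene symbols.

    Returns the deduplicated rewritten associations (first-seen order) and
    a :class:`NormalizationReport`.  Idempotent: a second pass over the
    output is the identity.
    """
    index = build_symbol_index(authority)
    n_already = n_mapped = n_dropped = 0
    seen: set[DiseaseGeneAssociation] = set()
    out: list[DiseaseGeneAssociation] = []
    kept_rows = 0
    for assoc in assocs:
        resolved = index.resolve(assoc.gene)
        if resolved is None:
            n_dropped += 1
            continue
        if resolved == assoc.gene:
            n_already += 1
        else:
            n_mapped += 1
        kept_rows += 1
        rewritten = DiseaseGeneAssociation(assoc.code, resolved)
        if rewritten not in seen:
            seen.add(rewritten)
            out.append(rewritten)
    report = NormalizationReport(
        n_input_rows=len(assocs),
        n_already_approved=n_already,
        n_mapped_via_previous_or_alias=n_mapped,
        n_dropped_unmatched=n_dropped,
        n_deduplicated=kept_rows - len(out),
    )
    return out, report
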