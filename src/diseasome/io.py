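"""Readers and writers for the four tab-separated mapping tables.

Schemas (all TSV with a header row):

* ``disease_gene`` — columns ``icd10cm_code``, ``gene_symbol``
* ``gene_pathway`` — columns ``gene_symbol``, ``pathway_id``
* ``hgnc`` — columns ``approved_symbol``, ``previous_symbols``,
  ``alias_symbols``, ``status``; multi-symbol cells are '|'-separated
* ``chapters`` — columns ``range``, ``name``

Association tables use set semantics: duplicate rows are merged and
counted.  Malformed rows are collected with their 1-based file line
numbers and raised together as a single :class:`TableParseError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .chapters import Chapter, icd_sort_key
from .errors import TableParseError
from .model import (
    DiseaseGeneAssociation,
    GenePathwayAssociation,
    GeneSymbol,
    HgncRecord,
    IcdCode,
    PathwayId,
)

_COLUMNS = {
    "disease_gene": ("icd10cm_code", "gene_symbol"),
    "gene_pathway": ("gene_symbol", "pathway_id"),
    "hgnc": ("approved_symbol", "previous_symbols", "alias_symbols", "status"),
    "chapters": ("range", "name"),
}


@dataclass
class TableReadResult:
    """Parsed records plus row-level bookkeeping."""

    records: list
    n_rows: int
    n_duplicates: int


def _split_multi(cell: str) -> frozenset[GeneSymbol]:
    return frozenset(GeneSymbol(s) for s in str(cell).split("|") if s.strip())


def read_table(path: Union[str, Path], schema: str) -> TableReadResult:
    """Parse one mapping table into typed records.

    Association schemas are deduplicated (first occurrence kept, merges
    counted in ``n_duplicates``).  Any malformed row raises
    :class:`TableParseError` listing every offending line.
    """
    if schema not in _COLUMNS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_COLUMNS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[schema] if c not in df.columns]
    if missing:
        raise TableParseError(str(path), [(1, f"missing required column(s) {missing}")])

    problems: list[tuple[int, str]] = []
    parsed = []
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        try:
            if schema == "disease_gene":
                rec = DiseaseGeneAssociation(
                    IcdCode(getattr(row, "icd10cm_code")),
                    GeneSymbol(getattr(row, "gene_symbol")),
                )
            elif schema == "gene_pathway":
                rec = GenePathwayAssociation(
                    GeneSymbol(getattr(row, "gene_symbol")),
                    PathwayId(getattr(row, "pathway_id")),
                )
            elif schema == "hgnc":
                rec = HgncRecord(
                    approved=GeneSymbol(getattr(row, "approved_symbol")),
                    previous=_split_multi(getattr(row, "previous_symbols")),
                    aliases=_split_multi(getattr(row, "alias_symbols")),
                    status=str(getattr(row, "status")).strip().lower(),
                )
            else:
                rec = Chapter.from_range(getattr(row, "range"), getattr(row, "name"))
        except ValueError as exc:
            problems.append((lineno, str(exc)))
            continue
        parsed.append(rec)

    if schema == "hgnc":
        seen_appr: dict[GeneSymbol, int] = {}
        for idx, rec in enumerate(parsed):
            if rec.approved in seen_appr:
                problems.append(
                    (idx + 2, f"duplicate approved symbol {rec.approved}")
                )
            else:
                seen_appr[rec.approved] = idx
    if problems:
        raise TableParseError(str(path), sorted(problems))

    if schema in ("disease_gene", "gene_pathway"):
        seen = set()
        unique = []
        for rec in parsed:
            if rec not in seen:
                seen.add(rec)
                unique.append(rec)
        return TableReadResult(unique, n_rows=len(parsed), n_duplicates=len(parsed) - len(unique))
    return TableReadResult(parsed, n_rows=len(parsed), n_duplicates=0)


def write_table(records: list, path: Union[str, Path], schema: str) -> None:
    """Write records back in the same dialect, deterministically sorted."""
    if schema not in _COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    cols = _COLUMNS[schema]
    if schema == "disease_gene":
        rows = sorted({(str(r.code), str(r.gene)) for r in records})
    elif schema == "gene_pathway":
        rows = sorted({(str(r.gene), str(r.pathway)) for r in records})
    elif schema == "hgnc":
        rows = sorted(
            (
                str(r.approved),
                "|".join(sorted(r.previous)),
                "|".join(sorted(r.aliases)),
                r.status,
            )
            for r in records
        )
    else:
        rows = [
            (c.id, c.name)
            for c in sorted(records, key=lambda c: icd_sort_key(c.start))
        ]
    df = pd.DataFrame(rows, columns=list(cols))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
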