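"""Directional inclusion analysis between disease pairs.

For diseases X and Y with element sets (genes or pathways), the inclusion
index is

    tau_{x->y} = |X ∩ Y| / |X|,        0 <= tau <= 1,

a *directional* statistic: tau_{x->y} = 1 means X's elements are a subset
of Y's, while the reverse direction divides the same intersection by |Y|.
Unlike the symmetric Szymkiewicz-Simpson overlap coefficient (which
divides by min(|X|,|Y|)), tau distinguishes which disease includes which.

tau is kept as an exact :class:`fractions.Fraction` so the identity
tau_{x->y}·n_x = tau_{y->x}·n_y = |X∩Y| holds bit-exactly; floats appear
only in summaries and serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .chapters import ChapterTable
from .errors import ContractViolationError, IntegrityError
from .model import DiseasePair, DistributionSummary, ElementProfile, InclusionRecord

QUARTILE_METHOD = "linear"  # numpy interpolation; the common "type 7" convention


def inclusion_index(x_elements: frozenset, y_elements: frozenset) -> Fraction:
    """tau_{x->y} = |X ∩ Y| / |X| as an exact rational."""
    if not x_elements:
        raise ContractViolationError("inclusion index undefined for empty X set")
    return Fraction(len(set(x_elements) & set(y_elements)), len(x_elements))


def all_directed_inclusions(
    profiles: Sequence[ElementProfile],
    pairs: Sequence[DiseasePair],
) -> list[InclusionRecord]:
    """Materialize both directed records (x->y and y->x) for every pair."""
    by_entity = {p.entity: p.elements for p in profiles}
    records: list[InclusionRecord] = []
    for pair in pairs:
        for entity in (pair.x, pair.y):
            if entity not in by_entity:
                raise IntegrityError(f"pair references missing profile {entity}")
        ex, ey = by_entity[pair.x], by_entity[pair.y]
        shared = len(ex & ey)
        if shared != len(pair.shared):
            raise IntegrityError(
                f"pair ({pair.x},{pair.y}) shared set inconsistent with profiles"
            )
        for (a, b, ea, eb) in ((pair.x, pair.y, ex, ey), (pair.y, pair.x, ey, ex)):
            records.append(
                InclusionRecord(
                    x=a,
                    y=b,
                    mode=pair.mode,
                    n_x=len(ea),
                    n_y=len(eb),
                    shared=shared,
                    tau=Fraction(shared, len(ea)),
                )
            )
    return records


def summarize_distribution(values: Sequence[float], group: str) -> DistributionSummary:
    """Five-number summary with linear-interpolation (type 7) quartiles."""
    arr = np.asarray([float(v) for v in values], dtype=float)
    if arr.size == 0:
        raise ValueError(f"no values to summarize for group {group!r}")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=QUARTILE_METHOD)
    return DistributionSummary(
        group=group,
        n=int(arr.size),
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(arr.max()),
    )


ChapterOf = Union[ChapterTable, Mapping, Callable]


def _chapter_fn(chapter_of: ChapterOf) -> Callable:
    if isinstance(chapter_of, ChapterTable):
        return chapter_of.id_of
    if callable(chapter_of):
        return chapter_of
    return lambda code: chapter_of[code]


def same_category_summary(
    records: Sequence[InclusionRecord],
    chapter_of: ChapterOf,
) -> list[DistributionSummary]:
    """Distribution of tau per chapter, over records whose two codes share it.

    Directed records are pooled (both directions contribute); records whose
    codes lie in different chapters contribute to no summary, and chapters
    with no same-category record are omitted.
    """
    ch = _chapter_fn(chapter_of)
    groups: dict[str, list[float]] = {}
    for rec in records:
        cx, cy = ch(rec.x), ch(rec.y)
        if cx == cy:
            groups.setdefault(cx, []).append(rec.tau_float)
    return [summarize_distribution(vals, grp) for grp, vals in sorted(groups.items())]


def focal_role_values(
    records: Sequence[InclusionRecord],
    focal: str,
    chapter_of: ChapterOf,
) -> tuple[dict[str, list[float]], dict[str, list[float]]]:
    """Raw tau values for a focal chapter by role, grouped by partner chapter.

    ``as_X`` collects records whose x-code lies in the focal chapter and
    whose y-code does not; ``as_Y`` is symmetric.  Pairs entirely inside
    the focal chapter belong to the same-category view and are excluded.
    """
    ch = _chapter_fn(chapter_of)
    as_x: dict[str, list[float]] = {}
    as_y: dict[str, list[float]] = {}
    for rec in records:
        cx, cy = ch(rec.x), ch(rec.y)
        if cx == focal and cy != focal:
            as_x.setdefault(cy, []).append(rec.tau_float)
        elif cy == focal and cx != focal:
            as_y.setdefault(cx, []).append(rec.tau_float)
    return as_x, as_y


@dataclass(frozen=True)
class FocalDirectionality:
    """Focal-chapter inclusion distributions by role (overall or per partner)."""

    focal: str
    as_X: Union[DistributionSummary, list[DistributionSummary], None]
    as_Y: Union[DistributionSummary, list[DistributionSummary], None]


def focal_directionality(
    records: Sequence[InclusionRecord],
    focal: str,
    chapter_of: ChapterOf,
    split_by_partner: bool = False,
) -> FocalDirectionality:
    """Summaries of tau for one chapter acting as disease X vs as disease Y."""
    as_x, as_y = focal_role_values(records, focal, chapter_of)

    def _summ(groups: dict[str, list[float]], role: str):
        if not groups:
            return [] if split_by_partner else None
        if split_by_partner:
            return [
                summarize_distribution(vals, grp) for grp, vals in sorted(groups.items())
            ]
        pooled = [v for vals in groups.values() for v in vals]
        return summarize_distribution(pooled, f"{focal}:{role}")

    return FocalDirectionality(
        focal=focal, as_X=_summ(as_x, "as_X"), as_Y=_summ(as_y, "as_Y")
    )


def write_inclusion_records(
    records: Sequence[InclusionRecord], path: Union[str, Path]
) -> None:
    """TSV dump: columns x, y, mode, n_x, n_y, shared, tau (float)."""
    rows = sorted(
        (str(r.x), str(r.y), r.mode, r.n_x, r.n_y, r.shared, r.tau_float)
        for r in records
    )
    df = pd.DataFrame(rows, columns=["x", "y", "mode", "n_x", "n_y", "shared", "tau"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_summaries(
    summaries: Sequence[DistributionSummary], path: Union[str, Path]
) -> None:
    """TSV dump of distribution summaries, with the quartile method noted."""
    rows = [
        (s.group, s.n, s.min, s.q1, s.median, s.q3, s.max, QUARTILE_METHOD)
        for s in summaries
    ]
    df = pd.DataFrame(
        rows,
        columns=["group", "n", "min", "q1", "median", "q3", "max", "quartile_method"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
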