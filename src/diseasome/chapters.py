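"""ICD-10-CM chapter table and chapter assignment.

ICD-10-CM organizes codes into 21 chapters identified by 3-character code
ranges (e.g. C00-D49 "Neoplasms").  Range membership uses ICD tabular
ordering, which is character-wise with digits sorting before letters at
positions 2-3 — this places O9A after O99 and hence inside O00-O9A, where
plain lexicographic comparison would not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator, Union

from .errors import UnassignableCodeError
from .model import IcdCode

_RANGE_RE = re.compile(r"^([A-Z][0-9A-Z]{2})-([A-Z][0-9A-Z]{2})$")
_ALPHANUM = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def icd_sort_key(root: str) -> tuple[str, int, int]:
    """Ordering key for a 3-character code under ICD tabular order.

    Position 1 is a letter; positions 2-3 rank digits 0-9 before letters
    A-Z, so "O99" < "O9A" and "T88" < "T8A".
    """
    root = str(root)[:3].upper()
    return (root[0], _ALPHANUM.index(root[1]), _ALPHANUM.index(root[2]))


@dataclass(frozen=True)
class Chapter:
    """One chapter: an inclusive [start, end] range of 3-character codes."""

    id: str
    name: str
    start: str
    end: str

    def __post_init__(self) -> None:
        m = _RANGE_RE.match(self.id)
        if m is None:
            raise ValueError(f"invalid chapter range label {self.id!r}")
        if (self.start, self.end) != m.groups():
            raise ValueError(f"chapter {self.id}: start/end do not match label")
        if icd_sort_key(self.start) > icd_sort_key(self.end):
            raise ValueError(f"chapter {self.id}: start after end")

    @classmethod
    def from_range(cls, range_label: str, name: str) -> "Chapter":
        m = _RANGE_RE.match(str(range_label).strip().upper())
        if m is None:
            raise ValueError(f"invalid chapter range label {range_label!r}")
        start, end = m.groups()
        return cls(id=f"{start}-{end}", name=str(name).strip(), start=start, end=end)

    def contains(self, code: Union[IcdCode, str]) -> bool:
        key = icd_sort_key(IcdCode(code).root)
        return icd_sort_key(self.start) <= key <= icd_sort_key(self.end)


class ChapterTable:
    """A validated, non-overlapping collection of chapters."""

    def __init__(self, chapters: list[Chapter]):
        self.chapters = sorted(chapters, key=lambda c: icd_sort_key(c.start))
        if len({c.id for c in self.chapters}) != len(self.chapters):
            raise ValueError("duplicate chapter ranges")
        for prev, cur in zip(self.chapters, self.chapters[1:]):
            if icd_sort_key(prev.end) >= icd_sort_key(cur.start):
                raise ValueError(f"overlapping chapters {prev.id} and {cur.id}")

    def __len__(self) -> int:
        return len(self.chapters)

    def __iter__(self) -> Iterator[Chapter]:
        return iter(self.chapters)

    def assign(self, code: Union[IcdCode, str]) -> Chapter:
        """Return the unique chapter containing ``code``, or raise."""
        code = IcdCode(code)
        for ch in self.chapters:
            if ch.contains(code):
                return ch
        raise UnassignableCodeError(
            f"code {code} falls outside every chapter range in the table"
        )

    def id_of(self, code: Union[IcdCode, str]) -> str:
        return self.assign(code).id


def assign_chapter(code: Union[IcdCode, str], chapters: ChapterTable) -> Chapter:
    """Functional alias for :meth:`ChapterTable.assign`."""
    return chapters.assign(code)


@lru_cache(maxsize=1)
def load_default_chapters() -> ChapterTable:
    """Load the packaged 21-chapter ICD-10-CM table (A00-B99 … Z00-Z99)."""
    text = (
        resources.files("diseasome").joinpath("data/icd10cm_chapters.tsv").read_text()
    )
    chapters = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        rng, name = line.split("\t")
        chapters.append(Chapter.from_range(rng, name))
    table = ChapterTable(chapters)
    assert len(table) == 21
    return table


def codes_in_chapter(chapter: Chapter, extended: bool = False) -> list[str]:
    """Enumerate 3-character codes inside a chapter range in ICD order.

    By default returns the letter+2-digit codes within [start, end], plus
    the range's end code when it has a letter suffix (e.g. O9A) so the
    alphanumeric tail of a range stays reachable.  With ``extended=True``
    the full alphanumeric suffix space (digits before letters) is
    enumerated instead.
    """
    lo, hi = icd_sort_key(chapter.start), icd_sort_key(chapter.end)
    suffixes = _ALPHANUM if extended else _ALPHANUM[:10]
    out = []
    for letter in (chr(o) for o in range(ord(chapter.start[0]), ord(chapter.end[0]) + 1)):
        for c2 in suffixes:
            for c3 in suffixes:
                code = f"{letter}{c2}{c3}"
                if lo <= icd_sort_key(code) <= hi:
                    out.append(code)
    if chapter.end not in out:
        out.append(chapter.end)
    return out
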