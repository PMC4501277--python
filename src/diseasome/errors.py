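"""Exception hierarchy for the diseasome package."""

from __future__ import annotations


class DiseasomeError(Exception):
    """Base class for all package-specific errors."""


class TableParseError(DiseasomeError):
    """A mapping table contained malformed rows.

    Carries ``problems``, a list of ``(line_number, message)`` tuples with
    1-based line numbers counted in the file (header is line 1).
    """

    def __init__(self, path: str, problems: list[tuple[int, str]]):
        self.path = str(path)
        self.problems = list(problems)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems[:20])
        extra = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{self.path}: {len(self.problems)} malformed row(s): {lines}{extra}")


class AmbiguousSymbolError(DiseasomeError):
    """A raw gene symbol matches more than one approved record at the same tier."""

    def __init__(self, symbol: str, candidates: list[str]):
        self.symbol = str(symbol)
        self.candidates = sorted(str(c) for c in candidates)
        super().__init__(
            f"symbol {self.symbol!r} ambiguously maps to approved symbols "
            f"{self.candidates}; refusing to guess"
        )


class UnassignableCodeError(DiseasomeError):
    """An ICD-10-CM code falls outside every chapter range in the table."""


class ContractViolationError(DiseasomeError):
    """An operation was called with inputs violating its stated contract."""


class IntegrityError(DiseasomeError):
    """Cross-referenced inputs do not belong together (missing profile, foreign truth)."""


class ConfigError(DiseasomeError):
    """A synthetic-study configuration is infeasible."""
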