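"""Molecular formulas as exact atom multisets.

A :class:`Formula` is an immutable element -> count mapping with the
arithmetic the rest of the pipeline is built on: count-wise addition and
subtraction, monoisotopic and nominal mass, and ring-plus-double-bond
equivalents (RDB).  Charge is *not* part of a formula; ion bookkeeping
(adducts, electron mass) lives in :mod:`forcedeg.ions`.

RDB is evaluated on whatever multiset is passed in.  Applied to an anion
composition such as C42H71O13 (a deprotonated even-electron molecule) it
yields a half-integer value -- this is deliberate and matches the RDB
convention of vendor formula-assignment software for ion compositions.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "ElementMassTable",
    "Formula",
    "FormulaError",
    "default_element_table",
    "ELECTRON_MASS",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 5.48579909e-4


class FormulaError(ValueError):
    """Raised for unparsable formula strings or infeasible arithmetic."""


@dataclass(frozen=True)
class ElementRecord:
    symbol: str
    monoisotopic: float
    nominal: int
    valence: int


class ElementMassTable:
    """Element -> (monoisotopic mass, nominal mass, valence) lookup.

    Loaded from a tab-separated text file so the atomic-mass provenance is
    inspectable and overridable.  The special symbol ``e-`` carries the
    electron rest mass and is excluded from formula parsing.
    """

    def __init__(self, records: Mapping[str, ElementRecord], electron_mass: float = ELECTRON_MASS):
        self._records = dict(records)
        self.electron_mass = electron_mass
        for sym, rec in self._records.items():
            if rec.monoisotopic <= 0:
                raise ValueError(f"non-positive monoisotopic mass for {sym!r}")
        if "C" in self._records and self._records["C"].monoisotopic != 12.0:
            raise ValueError("carbon monoisotopic mass must be exactly 12")

    @classmethod
    def from_file(cls, path: str | Path) -> "ElementMassTable":
        records: dict[str, ElementRecord] = {}
        electron_mass = ELECTRON_MASS
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
                sym, mono, nominal, valence = parts
                if sym == "e-":
                    electron_mass = float(mono)
                    continue
                records[sym] = ElementRecord(sym, float(mono), int(nominal), int(valence))
        return cls(records, electron_mass=electron_mass)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._records

    def __getitem__(self, symbol: str) -> ElementRecord:
        try:
            return self._records[symbol]
        except KeyError:
            raise FormulaError(f"element {symbol!r} not in mass table") from None

    def symbols(self) -> list[str]:
        return sorted(self._records)


_DEFAULT_TABLE: ElementMassTable | None = None


def default_element_table() -> ElementMassTable:
    """The packaged element table (cached singleton)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(resources.files("forcedeg.data") / "elements.tsv") as p:
            _DEFAULT_TABLE = ElementMassTable.from_file(p)
    return _DEFAULT_TABLE


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An immutable multiset of atoms.

    Supports ``+`` and ``-`` (count-wise, subtraction must stay
    non-negative), hashing, and Hill-order printing (C first, H second,
    remaining elements alphabetical).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if n < 0:
                    raise FormulaError(f"negative count for {el!r}")
                if n:
                    merged[el] = merged.get(el, 0) + n
        self._counts = merged
        self._hash = hash(frozenset(merged.items()))

    # -- parsing / printing -------------------------------------------------

    @classmethod
    def parse(cls, text: str, table: ElementMassTable | None = None) -> "Formula":
        """Parse ``"C48H82O18"``-style strings into a Formula.

        Rejects empty strings, unknown element symbols, explicit zero
        counts, charge signs and anything else outside ``Symbol[count]``
        tokens, naming the offending token in the error.
        """
        table = table or default_element_table()
        if not isinstance(text, str) or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or m.start() != pos or not m.group(1):
                raise FormulaError(f"unparsable token at {text[pos:]!r}")
            sym, digits = m.groups()
            if sym not in table:
                raise FormulaError(f"unknown element symbol {sym!r}")
            n = int(digits) if digits else 1
            if n <= 0:
                raise FormulaError(f"zero count for element {sym!r}")
            counts[sym] = counts.get(sym, 0) + n
            pos = m.end()
        return cls(counts)

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        rest = dict(self._counts)
        for el in ("C", "H"):
            if el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    # -- mapping protocol ---------------------------------------------------

    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __bool__(self) -> bool:
        return bool(self._counts)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        out = dict(self._counts)
        for el, n in other._counts.items():
            out[el] = out.get(el, 0) + n
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        out = dict(self._counts)
        for el, n in other._counts.items():
            left = out.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"infeasible loss: removing {other.hill()} from {self.hill()} "
                    f"drives {el} negative"
                )
            if left:
                out[el] = left
            else:
                out.pop(el, None)
        return Formula(out)

    def contains(self, other: "Formula") -> bool:
        """True when ``other`` can be subtracted without going negative."""
        return all(self._counts.get(el, 0) >= n for el, n in other._counts.items())

    # -- derived quantities -------------------------------------------------

    def monoisotopic_mass(self, table: ElementMassTable | None = None) -> float:
        """Sum of monoisotopic atomic masses in Da (0.0 for the empty formula)."""
        table = table or default_element_table()
        return sum(n * table[el].monoisotopic for el, n in self._counts.items())

    def nominal_mass(self, table: ElementMassTable | None = None) -> int:
        table = table or default_element_table()
        return sum(n * table[el].nominal for el, n in self._counts.items())

    def rdb(self, table: ElementMassTable | None = None) -> float:
        """Ring-plus-double-bond equivalents: 1 + sum n_i (v_i - 2) / 2.

        For CHNO this is C - H/2 + N/2 + 1.  No electron or charge
        correction is applied: passed an ion composition, the value is a
        half-integer, which is the convention used in formula-assignment
        report tables.
        """
        table = table or default_element_table()
        return 1.0 + sum(n * (table[el].valence - 2) for el, n in self._counts.items()) / 2.0
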