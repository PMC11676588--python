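"""Candidate molecular-formula enumeration for an observed m/z.

Given an accurate mass, a set of adducts, per-element count bounds and a
ppm tolerance, enumerate every elemental composition whose theoretical
m/z falls inside the window, screen it for chemical plausibility (RDB
range, H/C ratio), and rank the survivors.  The heavy elements are
enumerated on a nested grid; the hydrogen count is solved directly from
the residual mass window, which prunes the search from O(prod bounds) to
the heavy-element grid only.

Ranking: |ppm error| ascending, ties by |RDB - centre of the allowed RDB
range|, then Hill string -- a deterministic total order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

from .formula import ElementMassTable, Formula, default_element_table
from .ions import Adduct, DEPROTONATED, ion_mz, ppm_error

__all__ = ["ElementBounds", "CandidateAssignment", "enumerate_candidates", "assign_best"]

#: Default bounds for CHO glycoside work: triterpenoid saponins and their
#: degradants contain no nitrogen, so N is excluded by default; the engine
#: itself is element-generic.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {"C": (0, 60), "H": (0, 120), "O": (0, 30)}

#: H/C plausibility window ("golden rules"-style screen).
DEFAULT_HC_RANGE: tuple[float, float] = (0.2, 3.1)


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) count bounds defining the search grid."""

    bounds: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, tuple[int, int]]) -> "ElementBounds":
        items = []
        for el, (lo, hi) in d.items():
            if lo < 0 or lo > hi:
                raise ValueError(f"infeasible bounds for {el}: ({lo}, {hi})")
            items.append((el, lo, hi))
        return cls(tuple(sorted(items)))

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {el: (lo, hi) for el, lo, hi in self.bounds}

    def grid_size(self) -> int:
        n = 1
        for _, lo, hi in self.bounds:
            n *= hi - lo + 1
        return n


@dataclass(frozen=True)
class CandidateAssignment:
    """One formula candidate for an observed m/z."""

    ion: Formula
    neutral: Formula
    adduct: Adduct
    theoretical_mz: float
    error_ppm: float
    rdb: float

    def sort_key(self, rdb_centre: float) -> tuple:
        return (abs(self.error_ppm), abs(self.rdb - rdb_centre), self.ion.hill())


def _hc_ok(f: Formula, hc_range: tuple[float, float] | None) -> bool:
    if hc_range is None:
        return True
    c = f["C"]
    if c == 0:
        return True
    return hc_range[0] <= f["H"] / c <= hc_range[1]


def enumerate_candidates(
    mz: float,
    adducts: list[Adduct] | tuple[Adduct, ...] = (DEPROTONATED,),
    bounds: ElementBounds | dict[str, tuple[int, int]] | None = None,
    tol_ppm: float = 5.0,
    rdb_range: tuple[float, float] = (0.0, 25.0),
    convention: str = "report_table",
    hc_range: tuple[float, float] | None = DEFAULT_HC_RANGE,
    table: ElementMassTable | None = None,
) -> list[CandidateAssignment]:
    """All formula candidates for ``mz`` within tolerance, ranked.

    ``rdb_range`` constrains the RDB of the *neutral* candidate; the ion
    composition of a deprotonated species sits 0.5 higher.  The result is
    exhaustive over the bounds grid: heavy elements are enumerated
    explicitly and the hydrogen count interval is derived from the mass
    window, so no in-window composition can be skipped.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    table = table or default_element_table()
    if bounds is None:
        bounds = ElementBounds.from_dict(DEFAULT_BOUNDS)
    elif isinstance(bounds, dict):
        bounds = ElementBounds.from_dict(bounds)

    bdict = bounds.as_dict()
    h_lo, h_hi = bdict.pop("H", (0, 0))
    heavy = sorted(bdict)
    mh = table["H"].monoisotopic
    rdb_centre = (rdb_range[0] + rdb_range[1]) / 2.0

    out: list[CandidateAssignment] = []
    for adduct in adducts:
        # atom-sum mass the ion composition must hit for this convention
        if adduct.charge < 0:
            delta_me = -table.electron_mass if convention == "report_table" else table.electron_mass
        else:
            delta_me = -table.electron_mass
        adduct_mass = adduct.added.monoisotopic_mass(table) - adduct.removed.monoisotopic_mass(table)
        # neutral atom-sum target; slightly inflated window so the exact
        # ppm filter below is the only arbiter at the boundary
        target = mz - delta_me - adduct_mass
        half_width = mz * tol_ppm * 1e-6 * (1 + 1e-6) + 1e-9
        for counts in product(*(range(bdict[el][0], bdict[el][1] + 1) for el in heavy)):
            heavy_mass = sum(n * table[el].monoisotopic for el, n in zip(heavy, counts))
            # solve the neutral H-count window from the residual mass
            lo = math.ceil((target - half_width - heavy_mass) / mh - 1e-12)
            hi = math.floor((target + half_width - heavy_mass) / mh + 1e-12)
            for h in range(max(lo, h_lo), min(hi, h_hi) + 1):
                neutral_counts = {el: n for el, n in zip(heavy, counts) if n}
                if h:
                    neutral_counts["H"] = h
                neutral = Formula(neutral_counts)
                try:
                    ion = (neutral + adduct.added) - adduct.removed
                except Exception:
                    continue
                theo = ion_mz(ion, charge=adduct.charge, convention=convention, table=table)
                if theo <= 0:
                    continue
                err = ppm_error(mz, theo)
                if abs(err) > tol_ppm:
                    continue
                neutral_rdb = neutral.rdb(table)
                if not (rdb_range[0] <= neutral_rdb <= rdb_range[1]):
                    continue
                if not _hc_ok(neutral, hc_range):
                    continue
                out.append(CandidateAssignment(
                    ion=ion, neutral=neutral, adduct=adduct,
                    theoretical_mz=theo, error_ppm=err, rdb=ion.rdb(table),
                ))
    out.sort(key=lambda c: c.sort_key(rdb_centre))
    return out


def assign_best(mz: float, **kwargs) -> CandidateAssignment | None:
    """Head of the ranked candidate list, or None when nothing matches."""
    cands = enumerate_candidates(mz, **kwargs)
    return cands[0] if cands else None
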