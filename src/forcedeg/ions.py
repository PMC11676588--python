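"""Ion compositions, theoretical m/z and ppm mass errors.

Negative-mode electrospray of glycosides produces two singly charged
species per neutral molecule: the deprotonated molecule [M-H]- and the
formate adduct [M+HCOO]-.  An :class:`Adduct` turns a neutral formula into
an ion composition (plain atom multiset; charge is carried separately) and
:func:`ion_mz` turns that composition into a theoretical m/z.

Two electron-mass conventions are supported for anions:

``physical``
    m/z = atom-sum + m_e: a singly charged anion carries one extra
    electron, so its physical mass exceeds the atom sum.

``report_table``
    m/z = atom-sum - m_e.  Several vendor formula-assignment tools print
    "theoretical mass" this way for negative ions (the sign of the
    electron correction follows the charge sign rather than the electron
    count).  It is the default because published annotation tables for
    this class of study round-trip exactly under it; the two conventions
    differ by exactly 2 m_e ~ 0.0011 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formula import ELECTRON_MASS, ElementMassTable, Formula, FormulaError, default_element_table

__all__ = [
    "Adduct",
    "IonSpecies",
    "MassMatch",
    "DEPROTONATED",
    "FORMATE",
    "DEFAULT_ADDUCTS",
    "ion_composition",
    "ion_mz",
    "ppm_error",
    "within_tolerance",
]

#: Conventions accepted by :func:`ion_mz`.
CONVENTIONS = ("report_table", "physical")


@dataclass(frozen=True)
class Adduct:
    """An ionization rule: atoms added, atoms removed, resulting charge."""

    name: str
    added: Formula = field(default_factory=Formula)
    removed: Formula = field(default_factory=Formula)
    charge: int = -1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    def ion_composition(self, neutral: Formula) -> Formula:
        return ion_composition(neutral, self)


DEPROTONATED = Adduct("[M-H]-", removed=Formula(H=1), charge=-1)
FORMATE = Adduct("[M+HCOO]-", added=Formula(C=1, H=1, O=2), charge=-1)
DEFAULT_ADDUCTS: tuple[Adduct, ...] = (DEPROTONATED, FORMATE)


def ion_composition(neutral: Formula, adduct: Adduct) -> Formula:
    """Atom multiset of the ion: neutral + added - removed.

    Raises :class:`FormulaError` when removal is infeasible (for example
    deprotonating a hydrogen-free composition).
    """
    try:
        return (neutral + adduct.added) - adduct.removed
    except FormulaError as exc:
        raise FormulaError(f"cannot form {adduct.name} from {neutral.hill()}: {exc}") from exc


@dataclass(frozen=True)
class IonSpecies:
    """A neutral formula ionized by an adduct under a named convention."""

    neutral: Formula
    adduct: Adduct = DEPROTONATED
    convention: str = "report_table"

    @property
    def composition(self) -> Formula:
        return ion_composition(self.neutral, self.adduct)

    def mz(self, table: ElementMassTable | None = None) -> float:
        return ion_mz(self.composition, charge=self.adduct.charge,
                      convention=self.convention, table=table)


def ion_mz(
    ion: Formula,
    charge: int = -1,
    convention: str = "report_table",
    table: ElementMassTable | None = None,
) -> float:
    """Theoretical m/z of an ion composition.

    Only |charge| = 1 is supported; the forced-degradation studies this
    package targets are acquired in negative mode where glycosides appear
    singly charged.
    """
    if abs(charge) != 1:
        raise ValueError(f"only singly charged ions supported, got charge {charge}")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")
    table = table or default_element_table()
    atoms = ion.monoisotopic_mass(table)
    me = table.electron_mass
    if charge < 0:
        return atoms + me if convention == "physical" else atoms - me
    # cations: both conventions subtract the missing electron
    return atoms - me


def ppm_error(observed: float, theoretical: float) -> float:
    """(observed - theoretical) / theoretical * 1e6.

    The theoretical mass must be the full-precision value; rounding it to
    report precision first shifts the ppm error visibly at the third
    decimal.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def within_tolerance(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True when |ppm error| <= tol_ppm."""
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    return abs(ppm_error(observed, theoretical)) <= tol_ppm


@dataclass(frozen=True)
class MassMatch:
    """An observed/theoretical m/z pair with its ppm error."""

    observed: float
    theoretical: float

    @property
    def error_ppm(self) -> float:
        return ppm_error(self.observed, self.theoretical)
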