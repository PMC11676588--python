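"""Packaged reference dataset: the ginsenoside Re forced-degradation study.

Ginsenoside Re (C48H82O18, a protopanaxatriol-type saponin carrying one
rhamnosyl and two glucosyl groups) degrades under acidic, basic and
oxidative stress into thirteen products spanning seven molecular
formulas; the remaining stress conditions (neutral hydrolysis, heat,
humidity, light) leave it intact.  The shipped files transcribe the
published negative-mode Orbitrap observations of that study: one MS1
peak list per productive stress condition ([M-H]- and [M+HCOO]- observed
masses) and one MS2 fragment list per [M-H]- precursor.
"""

from __future__ import annotations

from importlib import resources

from .formula import Formula
from .io import PeakList, read_peaklist

__all__ = ["RE_PARENT", "REFERENCE_CONDITIONS", "load_reference_ms1", "load_reference_ms2"]

#: Neutral formula of ginsenoside Re.
RE_PARENT = Formula(C=48, H=82, O=18)

#: Stress conditions under which the reference study observed degradation.
REFERENCE_CONDITIONS = (
    "acidic_methanolic", "acidic_aqueous", "basic", "oxidative",
)


def _data_path(name: str):
    return resources.as_file(resources.files("forcedeg.data") / name)


def load_reference_ms1() -> dict[str, PeakList]:
    """MS1 observed-mass lists keyed by stress condition."""
    out: dict[str, PeakList] = {}
    for condition in REFERENCE_CONDITIONS:
        with _data_path(f"ginsenoside_re_ms1_{condition}.csv") as p:
            pl = read_peaklist(p, format="csv", level="MS1", condition=condition)
        out[condition] = pl
    return out


def load_reference_ms2() -> list[PeakList]:
    """MS2 fragment lists, one per [M-H]- degradant precursor."""
    with _data_path("ginsenoside_re_ms2.mgf") as p:
        return read_peaklist(p, format="mgf")
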