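"""Annotation reports and the end-to-end annotation pipeline.

An :class:`AnnotationReport` holds one row per assigned MS1 peak in the
layout of a published degradation-product table: observed m/z, adduct,
theoretical m/z, ppm error, ion formula, RDB, transformation chain and
the annotated MS2 fragments.  All rounding (theoretical masses to 4
decimals, ppm to 3) happens at serialization only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .formula import Formula, default_element_table
from .fragments import FragmentationTree, NeutralLoss, build_tree
from .ions import Adduct, DEFAULT_ADDUCTS, ion_composition
from .io import PeakList
from .transforms import Transformation, match_ms1

__all__ = ["AnnotationRow", "AnnotationReport", "annotate_study"]

_COLUMNS = [
    "group", "condition", "observed_mz", "adduct", "theoretical_mz",
    "error_ppm", "ion_formula", "rdb", "chain", "fragments",
]


@dataclass
class AnnotationRow:
    group: str
    condition: str | None
    observed_mz: float
    adduct: str
    theoretical_mz: float
    error_ppm: float
    ion_formula: str
    rdb: float
    chain: str
    fragments: list[tuple[float, str]] = field(default_factory=list)

    def fragments_str(self) -> str:
        return "; ".join(f"{mz:.4f} ({f}-)" for mz, f in self.fragments)


@dataclass
class AnnotationReport:
    rows: list[AnnotationRow]
    trees: dict[str, FragmentationTree] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = []
        for r in self.rows:
            data.append({
                "group": r.group,
                "condition": r.condition,
                "observed_mz": r.observed_mz,
                "adduct": r.adduct,
                "theoretical_mz": round(r.theoretical_mz, 4),
                "error_ppm": round(r.error_ppm, 3),
                "ion_formula": r.ion_formula,
                "rdb": r.rdb,
                "chain": r.chain,
                "fragments": r.fragments_str(),
            })
        return pd.DataFrame(data, columns=_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["observed_mz"] = df["observed_mz"].map(lambda v: f"{v:.4f}")
        df["theoretical_mz"] = df["theoretical_mz"].map(lambda v: f"{v:.4f}")
        df["error_ppm"] = df["error_ppm"].map(lambda v: f"{v:.3f}")
        df.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "rows": [
                {
                    "group": r.group, "condition": r.condition,
                    "observed_mz": r.observed_mz, "adduct": r.adduct,
                    "theoretical_mz": r.theoretical_mz, "error_ppm": r.error_ppm,
                    "ion_formula": r.ion_formula, "rdb": r.rdb, "chain": r.chain,
                    "fragments": [[mz, f] for mz, f in r.fragments],
                }
                for r in self.rows
            ],
            "trees": {k: t.to_dict() for k, t in self.trees.items()},
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationReport":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        rows = [
            AnnotationRow(
                group=r["group"], condition=r["condition"],
                observed_mz=r["observed_mz"], adduct=r["adduct"],
                theoretical_mz=r["theoretical_mz"], error_ppm=r["error_ppm"],
                ion_formula=r["ion_formula"], rdb=r["rdb"], chain=r["chain"],
                fragments=[(mz, f) for mz, f in r["fragments"]],
            )
            for r in payload["rows"]
        ]
        return cls(rows)


def annotate_study(
    parent: Formula,
    ms1_lists: list[PeakList],
    ms2_lists: list[PeakList] | None = None,
    library: list[Transformation] | None = None,
    losses: list[NeutralLoss] | None = None,
    adducts: tuple[Adduct, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
    ms2_tol_ppm: float = 10.0,
    max_steps: int = 3,
    convention: str = "report_table",
    residue_caps: dict[str, int] | None = None,
) -> AnnotationReport:
    """MS1 hypothesis matching plus MS2 tree building in one pass.

    MS2 lists are associated to MS1 assignments by precursor m/z within
    ``tol_ppm``.  Peaks sharing one neutral formula form an isomer group
    labelled ``G1, G2, ...`` in descending first-observed order.
    """
    table = default_element_table()
    ms2_lists = ms2_lists or []
    rows: list[AnnotationRow] = []
    trees: dict[str, FragmentationTree] = {}
    group_of: dict[Formula, str] = {}

    for pl in ms1_lists:
        matches = [m for m in match_ms1(
            parent, pl.mzs, library, adducts=adducts, tol_ppm=tol_ppm,
            max_steps=max_steps, condition=pl.condition,
            convention=convention, residue_caps=residue_caps,
        ) if m.best]
        for m in matches:
            neutral = m.hypothesis.neutral
            if neutral not in group_of:
                group_of[neutral] = f"G{len(group_of) + 1}"
            ion = ion_composition(neutral, m.adduct)
            fragments: list[tuple[float, str]] = []
            if m.adduct.name == "[M-H]-":
                for ms2 in ms2_lists:
                    if ms2.precursor_mz is None:
                        continue
                    if abs(ms2.precursor_mz - m.peak_mz) / m.peak_mz * 1e6 > tol_ppm:
                        continue
                    tree = build_tree(
                        ion, ms2.mzs, losses, tol_ppm=ms2_tol_ppm,
                        convention=convention, precursor_mz=ms2.precursor_mz)
                    key = f"{group_of[neutral]}@{ms2.precursor_mz:.4f}"
                    trees[key] = tree
                    fragments = [
                        (n.mz, n.ion.hill()) for n in tree.nodes[1:] if n.mz is not None
                    ]
            rows.append(AnnotationRow(
                group=group_of[neutral],
                condition=pl.condition,
                observed_mz=m.peak_mz,
                adduct=m.adduct.name,
                theoretical_mz=m.match.theoretical,
                error_ppm=m.match.error_ppm,
                ion_formula=ion.hill(),
                rdb=ion.rdb(table),
                chain=m.hypothesis.describe(),
                fragments=fragments,
            ))
    rows.sort(key=lambda r: (r.group, -r.observed_mz))
    return AnnotationReport(rows, trees)
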