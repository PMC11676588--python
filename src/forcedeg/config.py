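"""YAML configuration loaders for adducts, transformations and losses.

Example library file::

    adducts:
      - name: "[M-H]-"
        removed: H
        charge: -1
    transformations:
      - name: "-Glc"
        removed: C6H10O5
        tags: [acidic, basic]
      - name: isomerization
        identity: true
    losses:
      - name: Glc
        composition: C6H10O5
    residue_caps:
      "-Glc": 2
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .formula import Formula
from .fragments import NeutralLoss
from .ions import Adduct
from .transforms import Transformation, _ALL_TAGS

__all__ = ["load_config", "parse_transformations", "parse_losses", "parse_adducts"]


def _formula(value: str | None) -> Formula:
    return Formula.parse(value) if value else Formula()


def parse_adducts(entries: list[dict]) -> list[Adduct]:
    return [
        Adduct(
            name=e["name"],
            added=_formula(e.get("added")),
            removed=_formula(e.get("removed")),
            charge=int(e.get("charge", -1)),
        )
        for e in entries
    ]


def parse_transformations(entries: list[dict]) -> list[Transformation]:
    out = []
    for e in entries:
        tags = frozenset(e["tags"]) if "tags" in e else _ALL_TAGS
        out.append(Transformation(
            name=e["name"],
            added=_formula(e.get("added")),
            removed=_formula(e.get("removed")),
            tags=tags,
            identity=bool(e.get("identity", False)),
        ))
    return out


def parse_losses(entries: list[dict]) -> list[NeutralLoss]:
    return [NeutralLoss(e["name"], Formula.parse(e["composition"])) for e in entries]


def load_config(path: str | Path) -> dict:
    """Load a YAML library file into typed objects.

    Returns a dict with any of the keys ``adducts``, ``transformations``,
    ``losses``, ``residue_caps`` that the file defines.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "adducts" in raw:
        out["adducts"] = parse_adducts(raw["adducts"])
    if "transformations" in raw:
        out["transformations"] = parse_transformations(raw["transformations"])
    if "losses" in raw:
        out["losses"] = parse_losses(raw["losses"])
    if "residue_caps" in raw:
        out["residue_caps"] = {str(k): int(v) for k, v in raw["residue_caps"].items()}
    return out
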