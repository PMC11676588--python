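"""Peak-list reading and writing (two-column CSV and MGF)."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mgf as _mgf

__all__ = ["PeakList", "read_peaklist", "write_peaklist_csv", "write_peaklists_mgf"]


class PeakListError(ValueError):
    """Malformed peak-list input."""


@dataclass
class PeakList:
    """A centroided peak list: (m/z, optional intensity) pairs.

    ``level`` is "MS1" or "MS2"; MS2 lists carry the precursor m/z.
    ``condition`` tags the stress condition the sample came from.
    """

    peaks: list[tuple[float, float | None]]
    level: str = "MS1"
    precursor_mz: float | None = None
    condition: str | None = None
    source_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("MS1", "MS2"):
            raise PeakListError(f"level must be MS1 or MS2, got {self.level!r}")
        if self.level == "MS2" and self.precursor_mz is None:
            raise PeakListError("MS2 peak list requires a precursor m/z")
        for mz, inten in self.peaks:
            if mz <= 0:
                raise PeakListError(f"non-positive m/z {mz}")
            if inten is not None and inten < 0:
                raise PeakListError(f"negative intensity {inten}")

    @property
    def mzs(self) -> list[float]:
        return [mz for mz, _ in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


def _read_csv(path: Path, level: str, precursor_mz: float | None,
              condition: str | None) -> PeakList:
    peaks: list[tuple[float, float | None]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PeakListError(f"{path}: empty file") from None
        header = [h.strip().lower() for h in header]
        if not header or header[0] != "mz":
            raise PeakListError(f"{path}:1: header must start with 'mz'")
        has_intensity = len(header) > 1 and header[1] == "intensity"
        for lineno, row in enumerate(reader, 2):
            if not row or not row[0].strip():
                continue
            try:
                mz = float(row[0])
            except ValueError:
                raise PeakListError(f"{path}:{lineno}: bad m/z {row[0]!r}") from None
            if mz <= 0:
                raise PeakListError(f"{path}:{lineno}: non-positive m/z {mz}")
            inten: float | None = None
            if has_intensity and len(row) > 1 and row[1].strip():
                try:
                    inten = float(row[1])
                except ValueError:
                    raise PeakListError(
                        f"{path}:{lineno}: bad intensity {row[1]!r}") from None
            peaks.append((mz, inten))
    return PeakList(peaks, level=level, precursor_mz=precursor_mz,
                    condition=condition, source_id=str(path))


def read_peaklist(
    path: str | Path,
    format: str | None = None,
    level: str = "MS1",
    precursor_mz: float | None = None,
    condition: str | None = None,
) -> PeakList | list[PeakList]:
    """Read a peak list from CSV (header ``mz[,intensity]``) or MGF.

    CSV yields a single :class:`PeakList`; an MGF file yields one MS2
    :class:`PeakList` per BEGIN/END IONS block (PEPMASS as precursor).
    Format is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "mgf" if path.suffix.lower() == ".mgf" else "csv"
    if format == "csv":
        return _read_csv(path, level, precursor_mz, condition)
    if format == "mgf":
        out: list[PeakList] = []
        with _mgf.read(str(path)) as reader:
            for i, spectrum in enumerate(reader):
                params = spectrum.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise PeakListError(f"{path}: spectrum {i} lacks PEPMASS")
                prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                mzs = spectrum.get("m/z array")
                intens = spectrum.get("intensity array")
                peaks = [
                    (float(mz), float(it) if intens is not None and len(intens) else None)
                    for mz, it in zip(mzs, intens if intens is not None and len(intens)
                                      else [None] * len(mzs))
                ]
                out.append(PeakList(
                    peaks, level="MS2", precursor_mz=prec,
                    condition=condition or params.get("condition"),
                    source_id=params.get("title", f"{path}#{i}"),
                ))
        return out
    raise ValueError(f"unknown peak-list format {format!r}")


def write_peaklist_csv(peaklist: PeakList, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        has_intensity = any(i is not None for _, i in peaklist.peaks)
        writer.writerow(["mz", "intensity"] if has_intensity else ["mz"])
        for mz, inten in peaklist.peaks:
            row = [f"{mz:.6f}"]
            if has_intensity:
                row.append("" if inten is None else f"{inten:.6g}")
            writer.writerow(row)


def write_peaklists_mgf(peaklists: list[PeakList], path: str | Path) -> None:
    """Write MS2 peak lists as MGF (one IONS block per list)."""
    spectra = []
    for pl in peaklists:
        if pl.level != "MS2":
            raise PeakListError("MGF output requires MS2 peak lists")
        params = {"title": pl.source_id or "", "pepmass": pl.precursor_mz,
                  "charge": "1-"}
        if pl.condition:
            params["condition"] = pl.condition
        spectra.append({
            "params": params,
            "m/z array": [mz for mz, _ in pl.peaks],
            "intensity array": [1.0 if i is None else i for _, i in pl.peaks],
        })
    _mgf.write(spectra, str(path), file_mode="w")
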