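"""Ground-truthed synthetic forced-degradation studies.

The generator emulates the statistical structure of a negative-mode
LC-HRMS stress study of a glycosylated parent compound:

* per stress condition, each degradation chain emits its [M-H]- and
  [M+HCOO]- adduct peaks (isomer multiplicity = repeated chromatographic
  peaks of one formula);
* mass errors are Gaussian in ppm (default sigma 1.5 ppm, bracketing the
  1-4 ppm deviations Orbitrap annotation tables report);
* MS2 ladders follow the sequential neutral-loss grammar of glycoside
  fragmentation: 1-3 feasible losses drawn without replacement per path;
* decoy peaks are uniform over the observed m/z range, rejected within
  3 sigma of any true mass so they can never be correct answers.

Everything is reproducible from the spec's integer seed.  Retention
times, intensities and detector response are deliberately not modelled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .formula import Formula, FormulaError
from .fragments import NeutralLoss, default_loss_library
from .ions import Adduct, DEFAULT_ADDUCTS, DEPROTONATED, ion_composition, ion_mz
from .io import PeakList
from .transforms import Transformation, TransformationChain, default_library

__all__ = [
    "SyntheticStudySpec",
    "TruePeak",
    "GroundTruth",
    "SimulatedStudy",
    "default_study_chains",
    "simulate_study",
    "corrupt_with_decoys",
]

#: Parent compound of the reference study: ginsenoside Re.
RE_PARENT = Formula(C=48, H=82, O=18)


def _lib_by_name() -> dict[str, Transformation]:
    return {t.name: t for t in default_library()}


def default_study_chains() -> dict[str, list[TransformationChain]]:
    """Condition -> degradation chains of the reference stress study.

    Acidic hydrolysis with methanol co-solvent gives deglycosylation,
    deglycosylation+dehydration, and the methanol adduct of the latter;
    aqueous acid swaps the methanol adduct for hydration; base stops at
    deglycosylation(+dehydration); oxidation adds one to three oxygens.
    """
    t = _lib_by_name()
    c = TransformationChain.of
    return {
        "acidic_methanolic": [
            c(t["-Glc"]),
            c(t["-Glc"], t["-H2O"]),
            c(t["-Glc"], t["-H2O"], t["+CH4O"]),
        ],
        "acidic_aqueous": [
            c(t["-Glc"]),
            c(t["-Glc"], t["-H2O"]),
            c(t["-Glc"], t["+H2O"]),
        ],
        "basic": [
            c(t["-Glc"]),
            c(t["-Glc"], t["-H2O"]),
        ],
        "oxidative": [
            c(t["+O"]),
            c(t["+H2O2"]),
            c(t["+H2O3"]),
        ],
    }


@dataclass
class SyntheticStudySpec:
    """Parameters of one synthetic study."""

    parent: Formula = field(default_factory=lambda: RE_PARENT)
    conditions: dict[str, list[TransformationChain]] = field(
        default_factory=default_study_chains)
    adducts: tuple[Adduct, ...] = DEFAULT_ADDUCTS
    sigma_ppm: float = 1.5
    decoy_rate: float = 0.0
    isomer_multiplicity: int = 1
    ms2_paths: int = 2
    ms2_max_depth: int = 3
    convention: str = "report_table"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ppm < 0:
            raise ValueError("sigma_ppm must be >= 0")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be >= 0")
        if self.isomer_multiplicity < 1:
            raise ValueError("isomer_multiplicity must be >= 1")


@dataclass(frozen=True)
class TruePeak:
    """Ground-truth record for one emitted (non-decoy) peak."""

    condition: str
    level: str  # MS1 | MS2
    precursor_key: str | None
    formula: Formula  # ion composition
    neutral: Formula | None  # neutral formula (MS1 peaks)
    chain: tuple[str, ...]
    adduct: str
    mz_true: float
    mz_emitted: float


@dataclass
class GroundTruth:
    records: list[TruePeak]
    decoys: dict[str, list[float]] = field(default_factory=dict)

    def ms1_records(self, condition: str) -> list[TruePeak]:
        return [r for r in self.records
                if r.level == "MS1" and r.condition == condition]


@dataclass
class SimulatedStudy:
    ms1: dict[str, PeakList]
    ms2: dict[str, PeakList]
    truth: GroundTruth
    spec: SyntheticStudySpec


def _perturb(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6) if sigma_ppm > 0 else mz


def simulate_study(spec: SyntheticStudySpec,
                   losses: list[NeutralLoss] | None = None) -> SimulatedStudy:
    """Emit MS1 peak lists per condition and MS2 ladders per precursor."""
    rng = np.random.default_rng(spec.seed)
    losses = default_loss_library() if losses is None else losses
    records: list[TruePeak] = []
    ms1: dict[str, PeakList] = {}
    ms2: dict[str, PeakList] = {}

    for condition in sorted(spec.conditions):
        chains = spec.conditions[condition]
        cond_peaks: list[tuple[float, float | None]] = []
        for chain in chains:
            try:
                neutral = chain.apply(spec.parent)
            except FormulaError as exc:
                raise ValueError(f"infeasible chain {chain.describe()!r} "
                                 f"under {condition}: {exc}") from exc
            for adduct in spec.adducts:
                ion = ion_composition(neutral, adduct)
                true_mz = ion_mz(ion, charge=adduct.charge,
                                 convention=spec.convention)
                for _ in range(spec.isomer_multiplicity):
                    emitted = _perturb(rng, true_mz, spec.sigma_ppm)
                    cond_peaks.append((emitted, None))
                    records.append(TruePeak(
                        condition, "MS1", None, ion, neutral,
                        chain.name_multiset(), adduct.name, true_mz, emitted))
            # MS2 on the deprotonated precursor
            prec_ion = ion_composition(neutral, DEPROTONATED)
            prec_true = ion_mz(prec_ion, charge=-1, convention=spec.convention)
            prec_key = f"{condition}/{chain.describe()}"
            frag_peaks: list[tuple[float, float | None]] = []
            seen_frags: set[Formula] = set()
            for _ in range(spec.ms2_paths):
                depth = int(rng.integers(1, spec.ms2_max_depth + 1))
                current = prec_ion
                available = list(losses)
                for _ in range(depth):
                    feasible = [
                        l for l in available
                        if current.contains(l.composition) and current != l.composition
                    ]
                    if not feasible:
                        break
                    pick = feasible[int(rng.integers(len(feasible)))]
                    available.remove(pick)
                    current = current - pick.composition
                    if current in seen_frags:
                        continue
                    seen_frags.add(current)
                    f_true = ion_mz(current, charge=-1, convention=spec.convention)
                    f_emit = _perturb(rng, f_true, spec.sigma_ppm)
                    frag_peaks.append((f_emit, None))
                    records.append(TruePeak(
                        condition, "MS2", prec_key, current, None,
                        chain.name_multiset(), DEPROTONATED.name, f_true, f_emit))
            ms2[prec_key] = PeakList(
                sorted(frag_peaks, reverse=True), level="MS2",
                precursor_mz=prec_true, condition=condition, source_id=prec_key)
        ms1[condition] = PeakList(
            sorted(cond_peaks, reverse=True), level="MS1",
            condition=condition, source_id=f"synthetic/{condition}")

    truth = GroundTruth(records)
    if spec.decoy_rate > 0:
        for condition in sorted(ms1):
            pl = ms1[condition]
            true_mzs = [r.mz_true for r in truth.ms1_records(condition)]
            decoy_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, zlib.crc32(condition.encode())]))
            corrupted, decoys = corrupt_with_decoys(
                pl.mzs, spec.decoy_rate, decoy_rng, true_mzs,
                sigma_ppm=max(spec.sigma_ppm, 1.0))
            truth.decoys[condition] = decoys
            ms1[condition] = PeakList(
                [(mz, None) for mz in corrupted], level="MS1",
                condition=condition, source_id=pl.source_id)
    return SimulatedStudy(ms1, ms2, truth, spec)


def corrupt_with_decoys(
    peaks: list[float],
    rate: float,
    rng: np.random.Generator | int,
    true_mzs: list[float] | None = None,
    sigma_ppm: float = 1.5,
) -> tuple[list[float], list[float]]:
    """Insert ``round(rate * n)`` decoy masses into a peak list.

    Decoys are uniform over the observed m/z range and re-drawn while
    within 3 sigma (in ppm) of any true mass, so a decoy is never a
    near-duplicate of a real signal.  Returns (corrupted peaks sorted
    descending, decoy masses).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if rate == 0 or not peaks:
        return list(peaks), []
    true_mzs = list(peaks) if true_mzs is None else true_mzs
    lo, hi = min(peaks), max(peaks)
    if lo == hi:
        lo, hi = lo * 0.9, hi * 1.1
    n_decoys = int(round(rate * len(peaks)))
    decoys: list[float] = []
    margin = 3.0 * sigma_ppm * 1e-6
    while len(decoys) < n_decoys:
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - t) > margin * t for t in true_mzs):
            decoys.append(cand)
    return sorted(list(peaks) + decoys, reverse=True), decoys
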