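"""Degradation-transformation algebra and MS1 hypothesis matching.

A :class:`Transformation` is a net composition delta (atoms added, atoms
removed) tagged with the stress conditions under which it is chemically
admissible.  Chains of transformations applied to a parent formula give
degradant hypotheses; matching their theoretical adduct m/z values
against an observed MS1 peak list annotates a stress sample.

The shipped default library encodes the degradation chemistry of
glycosylated triterpenoids under forced-degradation (ICH-style stress)
conditions: hydrolytic loss of glycosyl residues (glucosyl C6H10O5,
rhamnosyl C6H10O4), dehydration, water or methanol addition at a side
chain double bond (methanol only when it is the co-solvent), and one- to
three-oxygen oxidative additions, plus mass-preserving isomerization.

Deglycosylation counts are capped per parent (a parent carrying two
glucosyl and one rhamnosyl group cannot lose a third Glc); the caps are
configuration, defaulting to the ginsenoside Re pattern (2 Glc, 1 Rha).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .formula import Formula, FormulaError
from .ions import Adduct, DEFAULT_ADDUCTS, MassMatch, ion_composition, ion_mz, ppm_error

__all__ = [
    "Transformation",
    "TransformationChain",
    "DegradantHypothesis",
    "MS1Match",
    "default_library",
    "default_residue_caps",
    "apply_chain",
    "enumerate_degradants",
    "match_ms1",
    "group_isomers",
    "CONDITION_TAGS",
]

#: Stress-condition vocabulary.  The two acidic sub-tags distinguish the
#: aqueous-acid and methanolic-acid variants of acidic hydrolysis; the
#: bare "acidic" condition activates both.
CONDITION_TAGS = {
    "acidic": frozenset({"acidic", "acidic_aqueous", "acidic_methanolic"}),
    "acidic_aqueous": frozenset({"acidic", "acidic_aqueous"}),
    "acidic_methanolic": frozenset({"acidic", "acidic_methanolic"}),
    "basic": frozenset({"basic"}),
    "neutral": frozenset({"neutral"}),
    "oxidative": frozenset({"oxidative"}),
    "thermal": frozenset({"thermal"}),
    "humidity": frozenset({"humidity"}),
    "photolytic": frozenset({"photolytic"}),
}

_ALL_TAGS = frozenset(
    {"acidic", "acidic_aqueous", "acidic_methanolic", "basic", "neutral",
     "oxidative", "thermal", "humidity", "photolytic"}
)


@dataclass(frozen=True)
class Transformation:
    """A named composition delta with stress-condition tags."""

    name: str
    added: Formula = field(default_factory=Formula)
    removed: Formula = field(default_factory=Formula)
    tags: frozenset[str] = field(default_factory=lambda: _ALL_TAGS)
    identity: bool = False  # mass-preserving (isomerization)

    def __post_init__(self) -> None:
        if not self.added and not self.removed and not self.identity:
            raise ValueError(f"transformation {self.name!r} has an empty delta")

    def admissible(self, active_tags: frozenset[str]) -> bool:
        return bool(self.tags & active_tags)

    def apply(self, f: Formula) -> Formula:
        return (f + self.added) - self.removed


def default_library() -> list[Transformation]:
    """The shipped degradation-transformation library."""
    glc = Formula(C=6, H=10, O=5)
    rha = Formula(C=6, H=10, O=4)
    h2o = Formula(H=2, O=1)
    return [
        Transformation("-Glc", removed=glc, tags=frozenset({"acidic", "basic"})),
        Transformation("-Rha", removed=rha, tags=frozenset({"acidic", "basic"})),
        Transformation("-H2O", removed=h2o, tags=frozenset({"acidic", "basic"})),
        Transformation("+H2O", added=h2o, tags=frozenset({"acidic_aqueous"})),
        Transformation("+CH4O", added=Formula(C=1, H=4, O=1),
                       tags=frozenset({"acidic_methanolic"})),
        Transformation("+O", added=Formula(O=1), tags=frozenset({"oxidative"})),
        Transformation("+H2O2", added=Formula(H=2, O=2), tags=frozenset({"oxidative"})),
        Transformation("+H2O3", added=Formula(H=2, O=3), tags=frozenset({"oxidative"})),
        Transformation("isomerization", identity=True),
    ]


def default_residue_caps() -> dict[str, int]:
    """Per-chain deglycosylation caps for a 2-Glc/1-Rha parent."""
    return {"-Glc": 2, "-Rha": 1}


@dataclass(frozen=True)
class TransformationChain:
    """An ordered sequence of transformations.

    The net composition delta is order-independent; feasibility is not,
    so chains are canonicalized as name-sorted multisets and feasibility
    is assessed additions-first (a multiset is feasible in *some* order
    iff it is feasible with all additions applied before any removal).
    """

    steps: tuple[Transformation, ...]

    @classmethod
    def of(cls, *steps: Transformation) -> "TransformationChain":
        return cls(tuple(sorted(steps, key=lambda t: t.name)))

    @property
    def net_added(self) -> Formula:
        out = Formula()
        for t in self.steps:
            out = out + t.added
        return out

    @property
    def net_removed(self) -> Formula:
        out = Formula()
        for t in self.steps:
            out = out + t.removed
        return out

    def name_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(t.name for t in self.steps))

    def describe(self) -> str:
        counts = Counter(t.name for t in self.steps)
        return " ".join(
            name if n == 1 else f"{n}x{name}" for name, n in sorted(counts.items())
        ) or "(parent)"

    def apply(self, parent: Formula) -> Formula:
        return apply_chain(parent, self)

    def is_net_identity(self) -> bool:
        return self.net_added == self.net_removed


def apply_chain(parent: Formula, chain: TransformationChain) -> Formula:
    """Apply a chain stepwise, naming the failing step on infeasibility."""
    current = parent
    # additions first so any order-feasible multiset passes
    ordered = sorted(chain.steps, key=lambda t: bool(t.removed))
    for i, step in enumerate(ordered):
        try:
            current = step.apply(current)
        except FormulaError as exc:
            raise FormulaError(f"step {i} ({step.name}) infeasible: {exc}") from exc
    return current


@dataclass(frozen=True)
class DegradantHypothesis:
    """A candidate degradant: parent composed with a transformation chain."""

    chain: TransformationChain
    neutral: Formula
    tags: frozenset[str]

    def describe(self) -> str:
        return self.chain.describe()


def _caps_ok(names: Counter, caps: dict[str, int] | None) -> bool:
    if not caps:
        return True
    return all(names[k] <= v for k, v in caps.items())


def enumerate_degradants(
    parent: Formula,
    library: list[Transformation] | None = None,
    max_steps: int = 3,
    condition: str | None = None,
    residue_caps: dict[str, int] | None = None,
    include_identity: bool = False,
) -> list[DegradantHypothesis]:
    """All feasible degradant hypotheses up to ``max_steps`` transformations.

    Chains are deduplicated as transformation multisets; chains whose net
    delta is zero (including lone isomerization) are dropped unless
    ``include_identity`` is set, in which case a single parent-mass
    hypothesis is emitted for them.  ``condition`` filters the library to
    transformations admissible under that stress condition.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    library = default_library() if library is None else library
    if residue_caps is None:
        residue_caps = default_residue_caps()
    if condition is not None:
        if condition not in CONDITION_TAGS:
            raise ValueError(f"unknown condition {condition!r}")
        active = CONDITION_TAGS[condition]
        library = [t for t in library if t.admissible(active)]

    seen: set[tuple[str, ...]] = set()
    out: list[DegradantHypothesis] = []
    identity_emitted = False
    for size in range(1, max_steps + 1):
        for combo in combinations_with_replacement(
            sorted(library, key=lambda t: t.name), size
        ):
            chain = TransformationChain.of(*combo)
            key = chain.name_multiset()
            if key in seen:
                continue
            seen.add(key)
            if not _caps_ok(Counter(key), residue_caps):
                continue
            if chain.is_net_identity():
                if include_identity and not identity_emitted:
                    tags = frozenset.intersection(*(t.tags for t in chain.steps))
                    out.append(DegradantHypothesis(chain, parent, tags))
                    identity_emitted = True
                continue
            try:
                net = apply_chain(parent, chain)
            except FormulaError:
                continue
            tags = frozenset.intersection(*(t.tags for t in chain.steps))
            out.append(DegradantHypothesis(chain, net, tags))
    return out


@dataclass(frozen=True)
class MS1Match:
    """One within-tolerance (peak, hypothesis, adduct) assignment."""

    peak_mz: float
    hypothesis: DegradantHypothesis
    adduct: Adduct
    match: MassMatch
    best: bool  # smallest |ppm| among this peak's matches


def match_ms1(
    parent: Formula,
    peaks: list[float],
    library: list[Transformation] | None = None,
    adducts: tuple[Adduct, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
    max_steps: int = 3,
    condition: str | None = None,
    convention: str = "report_table",
    residue_caps: dict[str, int] | None = None,
    include_identity: bool = False,
) -> list[MS1Match]:
    """Match observed MS1 peaks against every hypothesis x adduct.

    Every within-tolerance match is returned; per peak, the smallest-|ppm|
    match carries ``best=True``.  Use :func:`group_isomers` to collapse
    peaks explained by the same formula into isomer sets.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    hypotheses = enumerate_degradants(
        parent, library, max_steps=max_steps, condition=condition,
        residue_caps=residue_caps, include_identity=include_identity,
    )
    # precompute theoretical m/z per (hypothesis, adduct)
    theo: list[tuple[DegradantHypothesis, Adduct, float]] = []
    for hyp in hypotheses:
        for adduct in adducts:
            try:
                ion = ion_composition(hyp.neutral, adduct)
            except FormulaError:
                continue
            theo.append((hyp, adduct, ion_mz(ion, charge=adduct.charge,
                                             convention=convention)))
    out: list[MS1Match] = []
    for mz in peaks:
        hits = []
        for hyp, adduct, t in theo:
            err = ppm_error(mz, t)
            if abs(err) <= tol_ppm:
                hits.append(MS1Match(mz, hyp, adduct, MassMatch(mz, t), best=False))
        if hits:
            best_i = min(range(len(hits)),
                         key=lambda i: (abs(hits[i].match.error_ppm),
                                        hits[i].hypothesis.neutral.hill()))
            hits = [
                MS1Match(h.peak_mz, h.hypothesis, h.adduct, h.match, best=(i == best_i))
                for i, h in enumerate(hits)
            ]
        out.extend(hits)
    return out


def group_isomers(matches: list[MS1Match]) -> dict[Formula, list[float]]:
    """Group matched peaks by neutral formula (isomer multiplicity).

    Only best-flagged matches contribute; peaks sharing one formula are
    chromatographic isomer candidates (identical mass, distinct peaks).
    """
    groups: dict[Formula, list[float]] = {}
    for m in matches:
        if not m.best:
            continue
        groups.setdefault(m.hypothesis.neutral, []).append(m.peak_mz)
    return {f: sorted(set(mzs)) for f, mzs in groups.items()}
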