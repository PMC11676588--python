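"""Formula-conserving neutral-loss fragmentation trees.

MS2 peaks of glycoside anions are explained almost entirely by sequential
neutral losses: glycosyl residues (Glc C6H10O5, Rha C6H10O4), water,
methanol, the C17 side chain (C6H12), formic acid (formate-adduct to
[M-H]- transition) and small polyol fragments.  :func:`build_tree`
assembles a rooted DAG over the MS2 peak list in which every edge's loss
multiset balances the parent and child ion formulas *exactly* -- only the
peak-to-formula matching step is mass-tolerance based, never the atom
bookkeeping.

Peaks are attached greedily in descending m/z order: each peak joins the
already-placed node that explains it with the fewest loss terms (ties:
smallest |ppm|, then the heaviest feasible parent).  All other
within-tolerance parent edges that agree on the fragment formula are
retained as secondary edges, so ions the data support from two precursors
keep both parents while a tree rendering stays possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .formula import Formula, FormulaError, default_element_table
from .ions import MassMatch, ion_mz, ppm_error

__all__ = [
    "NeutralLoss",
    "LossDecomposition",
    "FragmentNode",
    "FragmentEdge",
    "FragmentationTree",
    "default_loss_library",
    "decompose_loss",
    "build_tree",
    "validate_tree",
]


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral fragment lost during collision-induced dissociation."""

    name: str
    composition: Formula

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError(f"neutral loss {self.name!r} has empty composition")


def default_loss_library() -> list[NeutralLoss]:
    """Neutral losses of deglycosylation-type MS2 chemistry.

    CH4O appears both as a solvent adduct gained in solution and as a
    collision-cell loss; CH2O2 (formic acid) covers the formate-adduct to
    deprotonated-molecule transition.
    """
    return [
        NeutralLoss("Glc", Formula(C=6, H=10, O=5)),
        NeutralLoss("Rha", Formula(C=6, H=10, O=4)),
        NeutralLoss("H2O", Formula(H=2, O=1)),
        NeutralLoss("CH4O", Formula(C=1, H=4, O=1)),
        NeutralLoss("C6H12", Formula(C=6, H=12)),
        NeutralLoss("C3H8O2", Formula(C=3, H=8, O=2)),
        NeutralLoss("CH2O2", Formula(C=1, H=2, O=2)),
    ]


@dataclass(frozen=True)
class LossDecomposition:
    """A loss multiset explaining one fragment peak from one precursor."""

    fragment: Formula
    losses: tuple[NeutralLoss, ...]
    match: MassMatch

    @property
    def n_terms(self) -> int:
        return len(self.losses)


def decompose_loss(
    parent_ion: Formula,
    fragment_mz: float,
    losses: list[NeutralLoss] | None = None,
    max_terms: int = 2,
    tol_ppm: float = 10.0,
    convention: str = "report_table",
    charge: int = -1,
    min_terms: int = 1,
) -> list[LossDecomposition]:
    """All loss multisets of ``min_terms..max_terms`` losses explaining a peak.

    A decomposition is returned when subtracting the multiset from the
    parent ion composition is feasible and the resulting theoretical m/z
    (fragment keeps the precursor's charge) matches ``fragment_mz`` within
    ``tol_ppm``.  Sorted by (fewest terms, |ppm|, fragment Hill string).
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    losses = default_loss_library() if losses is None else losses
    out: list[LossDecomposition] = []
    seen: set[tuple[str, ...]] = set()
    for n in range(min_terms, max_terms + 1):
        for combo in combinations_with_replacement(
            sorted(losses, key=lambda l: l.name), n
        ):
            key = tuple(l.name for l in combo)
            if key in seen:
                continue
            seen.add(key)
            frag = parent_ion
            try:
                for loss in combo:
                    frag = frag - loss.composition
            except FormulaError:
                continue
            if not frag:
                continue
            theo = ion_mz(frag, charge=charge, convention=convention)
            err = ppm_error(fragment_mz, theo)
            if abs(err) <= tol_ppm:
                out.append(LossDecomposition(frag, combo, MassMatch(fragment_mz, theo)))
    out.sort(key=lambda d: (d.n_terms, abs(d.match.error_ppm), d.fragment.hill()))
    return out


@dataclass
class FragmentNode:
    """One ion in the tree: formula, matched peak m/z, theoretical m/z."""

    ion: Formula
    mz: float | None  # observed peak m/z; None for an unobserved root
    theoretical_mz: float

    @property
    def error_ppm(self) -> float | None:
        if self.mz is None:
            return None
        return ppm_error(self.mz, self.theoretical_mz)


@dataclass
class FragmentEdge:
    parent: int  # node indices
    child: int
    losses: tuple[NeutralLoss, ...]
    primary: bool


@dataclass
class FragmentationTree:
    """Rooted DAG of ion formulas connected by exact neutral-loss edges."""

    nodes: list[FragmentNode]
    edges: list[FragmentEdge]
    unassigned: list[float] = field(default_factory=list)

    @property
    def root(self) -> FragmentNode:
        return self.nodes[0]

    def primary_children(self, idx: int) -> list[tuple[FragmentEdge, int]]:
        return [(e, e.child) for e in self.edges if e.parent == idx and e.primary]

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"formula": n.ion.hill(), "mz": n.mz,
                 "theoretical_mz": n.theoretical_mz, "error_ppm": n.error_ppm}
                for n in self.nodes
            ],
            "edges": [
                {"parent": e.parent, "child": e.child,
                 "losses": [l.name for l in e.losses], "primary": e.primary}
                for e in self.edges
            ],
            "unassigned": list(self.unassigned),
        }

    def render(self) -> str:
        """Indented text rendering of the primary tree."""
        lines: list[str] = []

        def walk(idx: int, depth: int, via: str) -> None:
            n = self.nodes[idx]
            mz = f"{n.mz:.4f}" if n.mz is not None else f"({n.theoretical_mz:.4f})"
            label = f"{mz} {n.ion.hill()}-"
            if via:
                label += f"  [-{via}]"
            lines.append("  " * depth + label)
            for e, child in sorted(self.primary_children(idx),
                                   key=lambda ec: -self.nodes[ec[1]].theoretical_mz):
                walk(child, depth + 1, "+".join(l.name for l in e.losses))

        walk(0, 0, "")
        if self.unassigned:
            lines.append("unassigned: " + ", ".join(f"{m:.4f}" for m in self.unassigned))
        return "\n".join(lines)


def build_tree(
    precursor_ion: Formula,
    ms2_peaks: list[float],
    losses: list[NeutralLoss] | None = None,
    tol_ppm: float = 10.0,
    max_terms: int = 2,
    convention: str = "report_table",
    charge: int = -1,
    precursor_mz: float | None = None,
) -> FragmentationTree:
    """Assemble the neutral-loss DAG for one precursor's MS2 peak list.

    Unexplainable peaks are collected in ``tree.unassigned`` rather than
    force-fitted.  Deterministic: all orderings and tie-breaks are total.
    """
    if not ms2_peaks:
        raise ValueError("MS2 peak list is empty")
    losses = default_loss_library() if losses is None else losses
    root_theo = ion_mz(precursor_ion, charge=charge, convention=convention)
    if precursor_mz is not None and abs(ppm_error(precursor_mz, root_theo)) > tol_ppm:
        raise ValueError(
            f"precursor m/z {precursor_mz} does not match {precursor_ion.hill()} "
            f"within {tol_ppm} ppm"
        )
    nodes = [FragmentNode(precursor_ion, precursor_mz, root_theo)]
    edges: list[FragmentEdge] = []
    unassigned: list[float] = []

    for mz in sorted(ms2_peaks, reverse=True):
        # candidate attachments to every already-placed heavier node
        candidates: list[tuple[int, LossDecomposition]] = []
        for idx, node in enumerate(nodes):
            if node.theoretical_mz <= mz:
                continue
            for dec in decompose_loss(node.ion, mz, losses, max_terms=max_terms,
                                      tol_ppm=tol_ppm, convention=convention,
                                      charge=charge):
                candidates.append((idx, dec))
        if not candidates:
            unassigned.append(mz)
            continue
        # fewest terms, then |ppm|, then heaviest parent, then Hill string
        best_idx, best = min(
            candidates,
            key=lambda c: (c[1].n_terms, abs(c[1].match.error_ppm),
                           -nodes[c[0]].theoretical_mz, c[1].fragment.hill()),
        )
        child = len(nodes)
        nodes.append(FragmentNode(best.fragment, mz, best.match.theoretical))
        for idx, dec in candidates:
            if dec.fragment != best.fragment:
                continue  # conflicting formula: keep only the winner's
            primary = idx == best_idx and dec.losses == best.losses
            # one edge per (parent, loss multiset)
            if any(e.parent == idx and e.child == child and
                   tuple(l.name for l in e.losses) == tuple(l.name for l in dec.losses)
                   for e in edges):
                continue
            edges.append(FragmentEdge(idx, child, dec.losses, primary))
        # guarantee exactly one primary edge
        assert sum(e.primary for e in edges if e.child == child) == 1
    unassigned.sort(reverse=True)
    return FragmentationTree(nodes, edges, unassigned)


def validate_tree(tree: FragmentationTree) -> list[str]:
    """Check exact atom balance and RDB additivity on every edge.

    Returns human-readable violation messages; an empty list means the
    tree satisfies parent = child + sum(losses) exactly and
    rdb(parent) = rdb(child) + sum(rdb(loss)) - n_losses on each edge,
    with a single root and no cycles.
    """
    table = default_element_table()
    violations: list[str] = []
    for e in tree.edges:
        parent, child = tree.nodes[e.parent], tree.nodes[e.child]
        total = child.ion
        for loss in e.losses:
            total = total + loss.composition
        lossdesc = "+".join(l.name for l in e.losses)
        if total != parent.ion:
            violations.append(
                f"edge {parent.ion.hill()} -> {child.ion.hill()} [{lossdesc}]: "
                f"atoms do not balance (child+losses = {total.hill()})"
            )
            continue
        lhs = parent.ion.rdb(table)
        rhs = child.ion.rdb(table) + sum(l.composition.rdb(table) for l in e.losses) \
            - len(e.losses)
        if abs(lhs - rhs) > 1e-9:
            violations.append(
                f"edge {parent.ion.hill()} -> {child.ion.hill()} [{lossdesc}]: "
                f"RDB additivity fails ({lhs} vs {rhs})"
            )
    # structural checks: children always appended after parents, so an
    # edge with child <= parent index would be the only way to cycle
    for e in tree.edges:
        if e.child <= e.parent and not (e.parent == 0 and e.child == 0):
            violations.append(f"edge {e.parent} -> {e.child}: not topologically ordered")
    for idx in range(1, len(tree.nodes)):
        if not any(e.child == idx for e in tree.edges):
            violations.append(f"node {idx} ({tree.nodes[idx].ion.hill()}) is unreachable")
    return violations
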