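# Methods

## Problem setting

A forced-degradation (stress) study exposes a drug substance to acid,
base, oxidant, heat, humidity and light, then identifies the degradation
products (DPs) by LC-HRMS. For glycosylated natural products the
identification is almost entirely mass arithmetic: every observed
negative-mode ion is (i) assigned an elemental composition from its
accurate mass, (ii) explained as the parent formula plus a short chain of
composition-changing reactions admissible under that stress condition,
and (iii) corroborated by an MS2 spectrum whose peaks form ladders of
neutral losses. `forcedeg` makes each of those steps an explicit,
testable computation.

## Formula layer

Formulas are immutable atom multisets. Monoisotopic masses come from a
versioned TSV table (CODATA/IUPAC values to ≥ 8 decimals; C is exactly
12) shipped with the package and overridable by configuration.
Ring-plus-double-bond equivalents use the linear valence form

    RDB = 1 + Σ n_i (v_i − 2) / 2

with no charge or electron correction. This is a deliberate convention
choice: annotation tables print RDB for *ion* compositions, where an
even-electron anion such as C42H71O13⁻ evaluates to 7.5. Two useful exact
identities follow from linearity and are enforced as properties:
mass(a+b) = mass(a)+mass(b), and RDB(a+b) = RDB(a)+RDB(b)−1 — the latter
is the conservation law fragmentation trees rely on.

## Ion m/z conventions

For singly charged anions two conventions are implemented. `physical`
adds one electron mass to the atom sum, which is the physically correct
mass of an anion. `report_table` (default) *subtracts* one electron
mass; the sign of the correction follows the charge sign rather than the
electron count. The second convention is what several vendor
formula-assignment tools print as "theoretical mass" in negative mode,
and it is the one that round-trips the reference study's annotation
table to all four printed decimals, so it is the reproducibility
default; the gap between the conventions is exactly 2mₑ ≈ 0.0011 Da
(≈ 1.4 ppm at m/z 800 — well above the instrument's precision, which is
why the choice must be explicit). ppm errors are always computed against
the full-precision theoretical mass; rounding it to 4 decimals first
shifts ppm values at the third decimal, visibly disagreeing with
printed tables. Only |z| = 1 is supported: the target studies are
negative-mode analyses of saponins, which do not multiply charge.
Positive mode and isotope patterns are out of scope.

## Formula search

Candidates for an observed m/z are enumerated exhaustively over
per-element count bounds. Heavy elements are iterated on a nested grid;
the hydrogen count interval is solved directly from the residual mass
window, which removes the largest dimension of the grid without
sacrificing completeness (the window is inflated by a relative 1e-6 so
the exact ppm filter is the only arbiter at the boundary). Survivors are
screened by neutral RDB range (default 0–25) and an H/C ratio window
(0.2–3.1, a "golden rules"-style plausibility screen, configurable off),
then ranked by |ppm error| with deterministic tie-breaks (RDB distance
to the range centre, then Hill string). Defaults exclude nitrogen
because the target chemistry is CHO; the engine itself is
element-generic. Equivalence with a brute-force triple-loop oracle is
asserted in tests on small grids.

## Transformation engine

Transformations are net composition deltas with condition tags; no
mechanism or regiochemistry is encoded (the +H2O2 / +H2O3 products are
handled purely as composition, leaving hydroperoxide-vs-diol open, which
is all accurate mass can support). The default library: −Glc (C6H10O5)
and −Rha (C6H10O4) residues and dehydration under acidic and basic
hydrolysis; hydration under aqueous acid; methanol addition only when
methanol is the co-solvent (tag `acidic_methanolic` — alcohols add
across the side-chain double bond during acidic heating, so the product
spectrum depends on when the co-solvent is introduced); +O, +H2O2, +H2O3
under oxidation; and a mass-preserving isomerization carrying an
explicit identity flag. The generic `acidic` condition activates both
acidic sub-variants.

Chains up to `max_steps` (default 3, the deepest chain needed:
deglycosylation + dehydration + methanol addition) are enumerated as
transformation multisets — the net formula is order-independent, and a
multiset is feasible in some order iff it is feasible with additions
applied first, which is how feasibility is checked. Net-identity chains
are discarded; an opt-in flag emits a single parent-mass hypothesis so
control samples can match the intact parent. Deglycosylation is capped
per parent (default 2 Glc, 1 Rha, the glycosylation pattern of
ginsenoside Re) because an uncapped engine proposes chemically
impossible multi-deglycosylations. Isomer pairs are *not* inferred from
mass: peaks sharing one formula are grouped as an isomer set, and
multiplicity remains input metadata.

MS1 matching scores every hypothesis × adduct against every peak,
returns all within-tolerance matches (default 5 ppm) and flags the
minimum-|ppm| match per peak as best.

## Fragmentation trees

MS2 peaks are attached greedily in descending m/z order. For each peak,
every already-placed heavier node is asked for loss multisets (≤
`max_terms`, default 2 — the deepest combined loss needed is
glycosyl + water) whose subtraction is formula-feasible and whose
theoretical m/z matches within the MS2 tolerance (default 10 ppm, looser
than MS1 because fragment masses in published tables scatter more than
precursors). The winning attachment minimizes (loss terms, |ppm|,
−parent mass, fragment Hill string); all other within-tolerance parents
that agree on the fragment formula are kept as secondary edges, so ions
supported from two precursors stay a DAG while the primary edges form a
renderable tree. Unexplainable peaks go to an `unassigned` set — they
are never force-fitted. Because decompositions operate in formula space,
every edge conserves atoms exactly and satisfies
RDB(parent) = RDB(child) + Σ RDB(loss) − #losses; `validate_tree`
re-checks both plus topological ordering. A globally optimal
(minimum-total-terms) forest is deliberately not attempted; the greedy
rule with total tie-breaks keeps the output deterministic.

## Synthetic studies

The generator emulates the observable structure of the reference study:
per condition, each degradation chain emits both adduct peaks, with
isomer multiplicity as repeated peaks of one formula; mass error is
Gaussian in ppm (σ default 1.5 ppm, bracketing the ±3.9 ppm deviations
of the reference table at ≈ 2.6σ); MS2 ladders apply 1–3 losses
sequentially, sampled without replacement per path to keep chains
finite; decoys are uniform over the observed m/z range and rejected
within 3σ of any true mass so they can never be accidentally correct.
All randomness derives from one integer seed. The generator does *not*
model retention time, intensity, detector response or isotope clusters —
so passing recovery tests demonstrates correctness of the mass-inference
logic under calibrated mass error, not robustness to chromatographic
artefacts or co-elution.

At σ = 1 ppm and 5 ppm tolerance the per-peak miss probability is
P(|N(0,1)| > 5) ≈ 6×10⁻⁷, so the analytic expectation is total recovery;
the suite asserts 100 % formula-and-chain recovery across 50 seeded
replicates and near-total (≥ 99 %) recovery in a separate Monte-Carlo
run. Decoy false-assignment has no sharp analytic value (it depends on
hypothesis density); it is reported empirically and bounded below 50 %
with a normal-approximation confidence interval.

## Numerical and interface choices

* All rounding (masses to 4 decimals, ppm to 3) happens at
  serialization; internal computation is double precision throughout.
* The reference dataset ships as plain CSV/MGF transcriptions of the
  published observed masses; readers reject malformed rows with line
  numbers rather than coercing.
* Problem sizes throughout the suite are desk-scale: the largest search
  grid the default bounds induce has ~1,900 heavy-element points per
  adduct, and a full synthetic replicate is ~150 peaks, so tests and
  the acceptance script complete in seconds.
* Known limitations: no positive mode, no multiply charged ions, no
  isotope-pattern scoring, no MS2-informed formula ranking, no
  stereochemistry — isomer pairs sharing a formula are reported as one
  group with multiplicity, which is as far as accurate mass goes.
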