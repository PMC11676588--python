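# forcedeg

Exact-mass annotation of forced-degradation products in LC-HRMS stress
studies.

When a drug substance is stressed (acid, base, peroxide, heat, humidity,
light) its degradation products (DPs) are usually characterized from
accurate negative-mode masses alone: each observed ion is assigned a
molecular formula, explained as the parent compound plus a short chain of
chemical transformations, and its MS2 spectrum is rationalized as a
cascade of neutral losses. `forcedeg` implements that whole inference as
a reusable pipeline, aimed at analysts characterizing glycosylated
natural products — the shipped reference dataset is the forced
degradation of ginsenoside Re (C48H82O18), a protopanaxatriol saponin
bearing one rhamnosyl and two glucosyl groups.

## What it computes

* **Formula arithmetic** — formulas as atom multisets with monoisotopic
  mass and ring-plus-double-bond equivalents,
  RDB = 1 + Σᵢ nᵢ(vᵢ − 2)/2 (C − H/2 + N/2 + 1 for CHNO). Applied to an
  anion composition this is deliberately half-integer (7.5, 8.5, …), the
  convention of vendor annotation tables.
* **Ion m/z** — [M−H]⁻ and [M+HCOO]⁻ compositions and theoretical m/z
  under two electron-mass conventions: `physical`
  (m/z = atom sum + mₑ for an anion) and the default `report_table`
  (atom sum − mₑ), which round-trips published annotation tables; the two
  differ by exactly 2mₑ ≈ 0.0011 Da. Mass errors are
  ppm = (obs − theo)/theo × 10⁶ on the full-precision theoretical mass.
* **Formula search** — exhaustive candidate enumeration over element
  bounds with the hydrogen count solved from the mass window, RDB and
  H/C plausibility screens, ranked by |ppm|.
* **Transformation algebra** — degradation chemistry as composition
  deltas (−Glc C6H10O5, −Rha C6H10O4, ±H2O, +CH4O, +O, +H2O2, +H2O3,
  isomerization) tagged by stress condition, with per-parent
  deglycosylation caps; chains are enumerated, deduplicated as
  multisets, and matched to MS1 peaks within a ppm tolerance.
* **Fragmentation trees** — per precursor, a rooted DAG whose edges are
  neutral-loss multisets balancing parent and child formulas *exactly*;
  only peak-to-formula matching is tolerance-based. Shared fragments
  keep all supported parents; one primary edge makes tree rendering
  possible.
* **Synthetic studies** — a seeded generator emitting ground-truthed MS1
  peak lists per condition and MS2 ladders per precursor with Gaussian
  ppm mass error, isomer multiplicity and decoy peaks, for end-to-end
  validation.

## Worked example

Assign the deglycosylated degradant of ginsenoside Re and build its
fragmentation tree from the four observed MS2 peaks:

```python
from forcedeg import Formula, build_tree, ion_mz, ppm_error

ion = Formula.parse("C42H71O13")          # [M-H]- of Re minus one Glc
theo = ion_mz(ion)                        # report_table convention
print(f"theoretical m/z {theo:.4f}   ppm error "
      f"{ppm_error(783.4897, theo):+.3f}   RDB {ion.rdb()}")

tree = build_tree(ion, [637.4297, 619.4189, 475.3777, 391.2837],
                  precursor_mz=783.4897)
print(tree.render())
```

```
theoretical m/z 783.4889   ppm error +0.997   RDB 7.5
783.4897 C42H71O13-
  637.4297 C36H61O9-  [-Rha]
    619.4189 C36H59O8-  [-H2O]
    475.3777 C30H51O4-  [-Glc]
      391.2837 C24H39O4-  [-C6H12]
```

The precursor at m/z 783.4897 deviates +0.997 ppm from theory; it loses
its rhamnosyl residue, then water or the second glucosyl residue, and
finally the C6H12 side chain — each edge conserving atoms exactly.

The same pipeline runs from the shell:

```sh
forcedeg annotate --parent C48H82O18 \
    --ms1 src/forcedeg/data/ginsenoside_re_ms1_oxidative.csv \
    --ms2 src/forcedeg/data/ginsenoside_re_ms2.mgf \
    --condition oxidative --out report.csv
forcedeg simulate --seed 7 --decoy-rate 0.5 --out-dir study/
```

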