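"""Synthetic-study generator: determinism, noise calibration, recovery."""

import numpy as np
import pytest

from forcedeg import (
    Formula,
    build_tree,
    corrupt_with_decoys,
    group_isomers,
    match_ms1,
    simulate_study,
    validate_tree,
)
from forcedeg.simulate import RE_PARENT, SyntheticStudySpec, default_study_chains


class TestDeterminismAndNoise:
    def test_zero_noise_emits_exact_theoretical_masses(self):
        spec = SyntheticStudySpec(sigma_ppm=0.0, seed=7)
        study = simulate_study(spec)
        for r in study.truth.records:
            assert r.mz_emitted == r.mz_true

    def test_same_seed_same_output(self):
        a = simulate_study(SyntheticStudySpec(sigma_ppm=1.0, seed=42))
        b = simulate_study(SyntheticStudySpec(sigma_ppm=1.0, seed=42))
        assert [r.mz_emitted for r in a.truth.records] == \
            [r.mz_emitted for r in b.truth.records]
        assert {k: pl.mzs for k, pl in a.ms1.items()} == \
            {k: pl.mzs for k, pl in b.ms1.items()}

    def test_different_seeds_differ(self):
        a = simulate_study(SyntheticStudySpec(sigma_ppm=1.0, seed=1))
        b = simulate_study(SyntheticStudySpec(sigma_ppm=1.0, seed=2))
        assert [r.mz_emitted for r in a.truth.records] != \
            [r.mz_emitted for r in b.truth.records]

    def test_ppm_noise_calibration(self):
        """Emitted deviations have mean ~0 and s.d. ~sigma."""
        sigma = 1.5
        devs = []
        for seed in range(60):
            spec = SyntheticStudySpec(sigma_ppm=sigma, isomer_multiplicity=6,
                                      ms2_paths=3, seed=seed)
            study = simulate_study(spec)
            devs.extend((r.mz_emitted - r.mz_true) / r.mz_true * 1e6
                        for r in study.truth.records)
        devs = np.asarray(devs)
        assert len(devs) >= 10_000
        assert abs(devs.mean()) < 4 * sigma / np.sqrt(len(devs))
        assert devs.std() == pytest.approx(sigma, rel=0.05)

    def test_ground_truth_bijective_with_ms1_peaks(self):
        spec = SyntheticStudySpec(sigma_ppm=1.0, seed=3)
        study = simulate_study(spec)
        for condition, pl in study.ms1.items():
            emitted = sorted(r.mz_emitted for r in study.truth.ms1_records(condition))
            assert emitted == sorted(pl.mzs)


class TestDecoys:
    def test_rate_zero_is_identity(self):
        peaks = [500.0, 600.0]
        out, decoys = corrupt_with_decoys(peaks, 0.0, 5)
        assert out == peaks and decoys == []

    def test_fixed_seed_deterministic(self):
        peaks = [400.0, 500.0, 600.0, 700.0]
        a = corrupt_with_decoys(peaks, 1.0, 11)
        b = corrupt_with_decoys(peaks, 1.0, 11)
        assert a == b
        assert len(a[1]) == 4

    def test_decoys_respect_exclusion_margin(self):
        peaks = sorted(np.linspace(400, 1000, 50))
        sigma = 2.0
        _, decoys = corrupt_with_decoys(peaks, 2.0, 13, sigma_ppm=sigma)
        for d in decoys:
            assert all(abs(d - t) > 3 * sigma * 1e-6 * t for t in peaks)


class TestPipelineRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_full_roundtrip_recovers_ground_truth(self, seed):
        """At sigma <= 1 ppm and 5 ppm tolerance the pipeline recovers every
        true formula, chain multiset and fragment formula."""
        spec = SyntheticStudySpec(sigma_ppm=1.0, seed=seed)
        study = simulate_study(spec)
        for condition, pl in study.ms1.items():
            truth = {round(r.mz_emitted, 6): r
                     for r in study.truth.ms1_records(condition)}
            matches = [m for m in match_ms1(RE_PARENT, pl.mzs, tol_ppm=5.0,
                                            condition=condition) if m.best]
            assert len(matches) == len(pl)
            for m in matches:
                r = truth[round(m.peak_mz, 6)]
                assert m.hypothesis.neutral == r.neutral
                assert m.hypothesis.chain.name_multiset() == r.chain
                assert m.adduct.name == r.adduct
        for key, pl in study.ms2.items():
            truth_frags = {r.formula for r in study.truth.records
                           if r.level == "MS2" and r.precursor_key == key}
            condition, chain_desc = key.split("/", 1)
            chain = next(c for c in study.spec.conditions[condition]
                         if c.describe() == chain_desc)
            prec_ion = chain.apply(RE_PARENT) - Formula(H=1)
            tree = build_tree(prec_ion, pl.mzs, tol_ppm=10.0)
            assert tree.unassigned == []
            assert validate_tree(tree) == []
            assert {n.ion for n in tree.nodes[1:]} == truth_frags

    def test_recovery_rate_with_noise_near_total(self):
        """Monte-Carlo across seeds: >= 99% of true MS1 peaks recovered."""
        total = hits = 0
        for seed in range(25):
            spec = SyntheticStudySpec(sigma_ppm=1.0, isomer_multiplicity=2,
                                      seed=seed)
            study = simulate_study(spec)
            for condition, pl in study.ms1.items():
                truth = {round(r.mz_emitted, 6): r
                         for r in study.truth.ms1_records(condition)}
                matches = [m for m in match_ms1(RE_PARENT, pl.mzs, tol_ppm=5.0,
                                                condition=condition) if m.best]
                got = {round(m.peak_mz, 6): m.hypothesis.neutral for m in matches}
                for mz, r in truth.items():
                    total += 1
                    if got.get(mz) == r.neutral:
                        hits += 1
        assert total > 500
        assert hits / total >= 0.99

    def test_decoy_false_assignment_rate_bounded(self):
        """Unconstrained decoy masses are assigned well under half the time."""
        assigned = total = 0
        for seed in range(20):
            spec = SyntheticStudySpec(sigma_ppm=1.0, decoy_rate=1.0, seed=seed)
            study = simulate_study(spec)
            for condition, pl in study.ms1.items():
                decoys = set(study.truth.decoys.get(condition, []))
                matches = [m for m in match_ms1(RE_PARENT, pl.mzs, tol_ppm=5.0,
                                                condition=condition) if m.best]
                matched = {m.peak_mz for m in matches}
                for d in decoys:
                    total += 1
                    if d in matched:
                        assigned += 1
        assert total >= 100
        rate = assigned / total
        # Wilson-style upper bound must stay below 0.5
        upper = rate + 1.96 * np.sqrt(max(rate * (1 - rate), 1e-9) / total)
        assert upper < 0.5

    def test_infeasible_chain_rejected(self):
        from forcedeg.transforms import TransformationChain, default_library
        t = {x.name: x for x in default_library()}
        bad = TransformationChain.of(t["-Glc"], t["-Glc"], t["-Rha"])
        spec = SyntheticStudySpec(
            parent=Formula(C=12, H=22, O=11),
            conditions={"acidic_aqueous": [bad]}, seed=0)
        with pytest.raises(ValueError):
            simulate_study(spec)

    def test_isomer_multiplicity_repeats_formula_peaks(self):
        spec = SyntheticStudySpec(sigma_ppm=1.0, isomer_multiplicity=3, seed=5)
        study = simulate_study(spec)
        recs = study.truth.ms1_records("basic")
        per_ion = {}
        for r in recs:
            per_ion.setdefault((r.formula.hill(), r.adduct), []).append(r)
        assert all(len(v) == 3 for v in per_ion.values())


def test_default_chains_match_condition_vocabulary():
    chains = default_study_chains()
    assert set(chains) == {"acidic_methanolic", "acidic_aqueous",
                           "basic", "oxidative"}
    assert all(chains.values())
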