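"""Degradation-transformation algebra and MS1 hypothesis matching."""

import pytest

from forcedeg import (
    Formula,
    FormulaError,
    TransformationChain,
    apply_chain,
    default_library,
    enumerate_degradants,
    group_isomers,
    match_ms1,
)
from forcedeg.transforms import default_residue_caps
from _reference import CONDITION_FORMULAS, MH_NEUTRALS, UNIQUE_MH_PEAKS, ION_ROWS


def lib():
    return {t.name: t for t in default_library()}


@pytest.fixture
def parent():
    return Formula(C=48, H=82, O=18)


class TestDefaultLibrary:
    def test_oxidative_additions_present(self):
        by_name = lib()
        for name in ("+O", "+H2O2", "+H2O3"):
            assert "oxidative" in by_name[name].tags

    def test_methanol_addition_is_cosolvent_dependent(self):
        t = lib()["+CH4O"]
        assert t.tags == {"acidic_methanolic"}

    def test_glycosidic_losses_hydrolytic(self):
        by_name = lib()
        assert by_name["-Glc"].removed == Formula(C=6, H=10, O=5)
        assert by_name["-Rha"].removed == Formula(C=6, H=10, O=4)
        assert by_name["-Glc"].tags == {"acidic", "basic"}

    def test_isomerization_is_identity_mass(self):
        t = lib()["isomerization"]
        assert t.identity and not t.added and not t.removed


class TestApplyChain:
    def test_deglycosylation(self, parent):
        chain = TransformationChain.of(lib()["-Glc"])
        assert apply_chain(parent, chain) == Formula(C=42, H=72, O=13)

    def test_three_step_methanolic_chain(self, parent):
        t = lib()
        chain = TransformationChain.of(t["-Glc"], t["-H2O"], t["+CH4O"])
        assert apply_chain(parent, chain) == Formula(C=43, H=74, O=13)

    def test_monooxygenation(self, parent):
        chain = TransformationChain.of(lib()["+O"])
        assert apply_chain(parent, chain) == Formula(C=48, H=82, O=19)

    def test_net_delta_order_independent(self, parent):
        t = lib()
        a = apply_chain(parent, TransformationChain((t["-Glc"], t["+H2O"])))
        b = apply_chain(parent, TransformationChain((t["+H2O"], t["-Glc"])))
        assert a == b

    def test_infeasible_step_reports_index(self):
        t = lib()
        tiny = Formula(C=6, H=12, O=6)
        chain = TransformationChain.of(t["-Glc"], t["-Glc"])
        with pytest.raises(FormulaError, match="step"):
            apply_chain(tiny, chain)


class TestEnumerateDegradants:
    def test_acidic_three_steps_covers_reported_products(self, parent):
        hyps = enumerate_degradants(parent, max_steps=3, condition="acidic")
        formulas = {h.neutral.hill() for h in hyps}
        assert {"C42H72O13", "C42H70O12", "C43H74O13", "C42H74O14"} <= formulas

    def test_oxidative_single_step_formulas(self, parent):
        hyps = enumerate_degradants(parent, max_steps=1, condition="oxidative")
        assert {h.neutral.hill() for h in hyps} == {
            "C48H82O19", "C48H84O20", "C48H84O21"}

    def test_empty_library_yields_nothing(self, parent):
        assert enumerate_degradants(parent, library=[], max_steps=3) == []

    def test_residue_caps_forbid_excess_deglycosylation(self, parent):
        hyps = enumerate_degradants(parent, max_steps=3, condition="basic")
        for h in hyps:
            names = list(h.chain.name_multiset())
            assert names.count("-Glc") <= 2
            assert names.count("-Rha") <= 1
        # without caps a 3x Glc loss appears
        uncapped = enumerate_degradants(parent, max_steps=3, condition="basic",
                                        residue_caps={})
        assert any(list(h.chain.name_multiset()).count("-Glc") == 3
                   for h in uncapped)

    def test_condition_filter_is_monotone(self, parent):
        all_h = {h.chain.name_multiset()
                 for h in enumerate_degradants(parent, max_steps=2)}
        for condition in CONDITION_FORMULAS:
            sub = {h.chain.name_multiset()
                   for h in enumerate_degradants(parent, max_steps=2,
                                                 condition=condition)}
            assert sub <= all_h

    def test_net_identity_chains_removed(self, parent):
        hyps = enumerate_degradants(parent, max_steps=2, condition="acidic_aqueous")
        assert all(h.neutral != parent for h in hyps)

    def test_identity_hypothesis_on_request(self, parent):
        hyps = enumerate_degradants(parent, max_steps=1, include_identity=True)
        assert sum(h.neutral == parent for h in hyps) == 1

    def test_multiset_deduplication(self, parent):
        hyps = enumerate_degradants(parent, max_steps=3)
        keys = [h.chain.name_multiset() for h in hyps]
        assert len(keys) == len(set(keys))


class TestConditionReproduction:
    @pytest.mark.parametrize("condition", sorted(CONDITION_FORMULAS))
    def test_hypotheses_cover_reported_degradants(self, parent, condition):
        hyps = enumerate_degradants(parent, max_steps=3, condition=condition)
        assert CONDITION_FORMULAS[condition] <= {h.neutral.hill() for h in hyps}

    def test_methanol_adduct_absent_without_cosolvent(self, parent):
        for condition in ("acidic_aqueous", "basic", "oxidative"):
            hyps = enumerate_degradants(parent, max_steps=3, condition=condition)
            assert "C43H74O13" not in {h.neutral.hill() for h in hyps}

    @pytest.mark.parametrize("condition", sorted(CONDITION_FORMULAS))
    def test_matched_peaks_recover_exactly_reported_groups(self, parent, condition):
        """Matching all observed masses under each condition's chemistry
        assigns exactly that condition's degradant formulas."""
        matches = match_ms1(parent, UNIQUE_MH_PEAKS, tol_ppm=5,
                            condition=condition)
        got = {f.hill() for f in group_isomers(matches)}
        assert got == CONDITION_FORMULAS[condition]


class TestMatchMs1:
    def test_all_reference_peaks_uniquely_assigned(self, parent):
        matches = match_ms1(parent, UNIQUE_MH_PEAKS, tol_ppm=5)
        best = {m.peak_mz: m for m in matches if m.best}
        assert set(best) == set(UNIQUE_MH_PEAKS)
        printed_ppm = {obs: ppm for _, ad, obs, _, ppm, _, _ in ION_ROWS
                       if ad == "[M-H]-"}
        for mz, m in best.items():
            assert m.hypothesis.neutral.hill() == MH_NEUTRALS[mz]
            assert m.adduct.name == "[M-H]-"
            assert m.match.error_ppm == pytest.approx(printed_ppm[mz], abs=0.005)

    def test_parent_peak_matches_identity_hypothesis(self, parent):
        from forcedeg import DEPROTONATED, ion_composition, ion_mz
        mz = ion_mz(ion_composition(parent, DEPROTONATED))
        matches = match_ms1(parent, [mz], tol_ppm=5, include_identity=True)
        best = [m for m in matches if m.best]
        assert best and best[0].hypothesis.neutral == parent

    def test_formate_adducts_assigned_to_same_degradants(self, parent):
        adduct_peaks = [obs for _, ad, obs, _, _, _, _ in ION_ROWS
                        if ad == "[M+HCOO]-"]
        matches = match_ms1(parent, adduct_peaks, tol_ppm=5)
        best = {m.peak_mz: m for m in matches if m.best}
        assert set(best) == set(adduct_peaks)
        assert all(m.adduct.name == "[M+HCOO]-" for m in best.values())
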