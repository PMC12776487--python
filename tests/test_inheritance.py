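"""Inheritance classification against an exhaustive decision-table oracle."""

from __future__ import annotations

from itertools import product

import pytest

from trioprio.errors import UsageError
from trioprio.inheritance import (
    InheritanceConfig,
    Mode,
    classify,
    classify_cohort,
    find_compound_hets,
)
from trioprio.types import Role, Sex, Zygosity

from conftest import make_family, make_variant, set_trio

# ---------------------------------------------------------------------------
# Independent oracle: a literal decision table over symbolic genotype states.
# States: R = hom_ref, H = het, A = hom_alt; "uncalled" and "absent" both mean
# no usable parental genotype.

_CARRIER = {"H", "A"}


def _dominant(parent_affected: bool) -> str:
    return "ad_inherited_affected_parent" if parent_affected else "ad_incomplete_penetrance"


def oracle_mode(proband, mother, father, mother_aff, father_aff) -> str:
    both = mother is not None and father is not None
    if proband == "H":
        if both:
            mc, fc = mother in _CARRIER, father in _CARRIER
            if not mc and not fc:
                return "de_novo"
            if mc and fc:
                return _dominant(mother_aff or father_aff)
            return _dominant(mother_aff if mc else father_aff)
        if mother is None and father is None:
            return "unknown_missing_parent"
        present, aff = (mother, mother_aff) if mother is not None else (father, father_aff)
        if present in _CARRIER:
            return _dominant(aff)
        return "unknown_missing_parent"
    # proband == "A"
    if both:
        mc, fc = mother in _CARRIER, father in _CARRIER
        if mc and fc:
            return "ar_homozygous"
        if not mc and not fc:
            return "de_novo_homozygous_flagged"
        return "mendelian_inconsistent"
    if mother is None and father is None:
        return "unknown_missing_parent"
    present = mother if mother is not None else father
    if present in _CARRIER:
        return "unknown_missing_parent"
    return "mendelian_inconsistent"


def oracle_mode_x_xy(proband, mother) -> str:
    if proband == "H":
        return "mendelian_inconsistent"
    if mother is None:
        return "unknown_missing_parent"
    if mother in _CARRIER:
        return "x_linked"
    return "de_novo"


_ZYG = {"R": Zygosity.hom_ref, "H": Zygosity.het, "A": Zygosity.hom_alt}
_PARENT_STATES = ("R", "H", "A", "uncalled", "absent")


def _build_case(proband_state, mother_state, father_state, m_aff, f_aff, chrom="chr1",
                proband_sex=Sex.XX):
    fam = make_family(
        proband_sex=proband_sex,
        mother_affected=m_aff,
        father_affected=f_aff,
        mother_present=mother_state != "absent",
        father_present=father_state != "absent",
    )
    v = make_variant(family_id="FAM1", chrom=chrom)
    fam.set_genotype(v.key, Role.proband, _ZYG[proband_state])
    for state, role in ((mother_state, Role.mother), (father_state, Role.father)):
        zyg = _ZYG.get(state, Zygosity.missing)
        fam.set_genotype(v.key, role, zyg)
    return v, fam


def _symbolic(state):
    return None if state in ("uncalled", "absent") else state


class TestDecisionTableEquivalence:
    def test_all_autosomal_cases_match_oracle(self):
        """Every carrier-proband genotype/parent-presence/affection combination
        agrees with the independently written decision table."""
        checked = 0
        for proband, mother, father, m_aff, f_aff in product(
            "HA", _PARENT_STATES, _PARENT_STATES, (False, True), (False, True)
        ):
            v, fam = _build_case(proband, mother, father, m_aff, f_aff)
            call = classify(v, fam)
            expected = oracle_mode(
                proband, _symbolic(mother), _symbolic(father), m_aff, f_aff
            )
            assert call.mode.value == expected, (
                proband, mother, father, m_aff, f_aff, call.mode)
            checked += 1
        assert checked == 2 * 5 * 5 * 4

    def test_all_x_hemizygous_cases_match_oracle(self):
        for proband, mother, father in product("HA", _PARENT_STATES, _PARENT_STATES):
            v, fam = _build_case(proband, mother, father, False, False,
                                 chrom="chrX", proband_sex=Sex.XY)
            call = classify(v, fam)
            assert call.mode.value == oracle_mode_x_xy(proband, _symbolic(mother))

    def test_x_in_xx_proband_follows_autosomal_rules(self):
        v, fam = _build_case("H", "R", "R", False, False, chrom="chrX", proband_sex=Sex.XX)
        assert classify(v, fam).mode is Mode.de_novo

    def test_classification_is_exhaustive_and_single_valued(self):
        modes = set()
        for proband, mother, father in product("HA", "RHA", "RHA"):
            v, fam = _build_case(proband, mother, father, False, False)
            modes.add(classify(v, fam).mode)
        assert modes <= set(Mode)


class TestWorkedExamples:
    def test_de_novo_het_trio(self):
        fam = make_family()
        v = make_variant(gene="TP63")
        set_trio(fam, v.key, Zygosity.het)
        call = classify(v, fam)
        assert call.mode is Mode.de_novo and call.carrier_parent.value == "none"

    def test_maternal_dominant_from_affected_mother(self):
        fam = make_family(mother_affected=True)
        v = make_variant(gene="TP63")
        set_trio(fam, v.key, Zygosity.het, mother=Zygosity.het)
        call = classify(v, fam)
        assert call.mode is Mode.ad_inherited_affected_parent
        assert call.carrier_parent.value == "mother"

    def test_dyad_with_hom_ref_mother_is_unknown(self):
        fam = make_family(father_present=False)
        v = make_variant(gene="NIPBL")
        fam.set_genotype(v.key, Role.proband, Zygosity.het)
        fam.set_genotype(v.key, Role.mother, Zygosity.hom_ref)
        assert classify(v, fam).mode is Mode.unknown_missing_parent

    def test_homozygous_with_hom_ref_parents_is_flagged_not_silent(self):
        fam = make_family()
        v = make_variant(gene="FAM90A26")
        set_trio(fam, v.key, Zygosity.hom_alt)
        call = classify(v, fam)
        assert call.mode is Mode.de_novo_homozygous_flagged
        assert any("artefact" in n for n in call.notes)

    def test_unaffected_carrier_father_is_incomplete_penetrance(self):
        fam = make_family()
        v = make_variant()
        set_trio(fam, v.key, Zygosity.het, father=Zygosity.het)
        call = classify(v, fam)
        assert call.mode is Mode.ad_incomplete_penetrance
        assert call.carrier_parent.value == "father"

    def test_hom_ref_proband_rejected(self):
        fam = make_family()
        v = make_variant()
        set_trio(fam, v.key, Zygosity.hom_ref)
        with pytest.raises(UsageError):
            classify(v, fam)

    def test_miscall_tolerance_demotes_inconsistency_to_unclassified(self):
        fam = make_family()
        v = make_variant()
        set_trio(fam, v.key, Zygosity.hom_alt, mother=Zygosity.het,
                 father=Zygosity.hom_ref)
        assert classify(v, fam).mode is Mode.mendelian_inconsistent
        tolerant = classify(v, fam, InheritanceConfig(max_parent_miscalls=1))
        assert tolerant.mode is Mode.unclassified


class TestCompoundHets:
    def _pair(self, fam, origins):
        v1 = make_variant(gene="G", family_id="FAM1")
        v2 = make_variant(gene="G", family_id="FAM1")
        for v, origin in ((v1, origins[0]), (v2, origins[1])):
            mother = Zygosity.het if origin == "maternal" else Zygosity.hom_ref
            father = Zygosity.het if origin == "paternal" else Zygosity.hom_ref
            set_trio(fam, v.key, Zygosity.het, mother, father)
        return [v1, v2]

    def test_trans_pair_detected(self):
        fam = make_family()
        pairs = find_compound_hets(self._pair(fam, ("maternal", "paternal")), fam)
        assert len(pairs) == 1
        assert pairs[0].mode is Mode.compound_het
        assert pairs[0].carrier_parent.value == "both"

    def test_cis_pair_excluded(self):
        fam = make_family()
        assert find_compound_hets(self._pair(fam, ("maternal", "maternal")), fam) == []

    def test_dyad_pair_reported_phase_unknown(self):
        fam = make_family(father_present=False)
        vs = self._pair(fam, ("maternal", "paternal"))
        pairs = find_compound_hets(vs, fam)
        assert len(pairs) == 1
        assert pairs[0].carrier_parent.value == "unknown"
        assert any("phase-unknown" in n for n in pairs[0].notes)

    def test_single_het_variant_yields_no_pair(self):
        fam = make_family()
        v = make_variant(gene="G", family_id="FAM1")
        set_trio(fam, v.key, Zygosity.het, Zygosity.het, Zygosity.hom_ref)
        assert find_compound_hets([v], fam) == []


class TestCohort:
    def test_table1_modes_match_printed_labels(self, table1):
        from trioprio.fixtures import table1_expected_modes

        variants, families = table1
        calls, counts = classify_cohort(variants, {f.family_id: f for f in families})
        expected = table1_expected_modes()
        single = [c for c in calls if "|" not in c.key]
        assert len(single) == 14
        for c in single:
            assert c.mode is expected[c.key], (c.key, c.mode)
        assert counts[Mode.de_novo] == 9
        assert counts[Mode.de_novo_homozygous_flagged] == 2
        assert counts[Mode.unknown_missing_parent] == 2
        assert counts[Mode.ad_inherited_affected_parent] == 1

    def test_empty_cohort_yields_empty_output(self):
        calls, counts = classify_cohort([], {})
        assert calls == [] and not counts
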