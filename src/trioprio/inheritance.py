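"""Mendelian inheritance classification within trios and dyads.

Given a proband who carries a variant (het or hom-alt) and the parental
genotypes, assign one segregation mode.  The rules, for an autosomal variant
with both parents present and called:

========= ================= ===========================================
proband    parents           mode
========= ================= ===========================================
het        hom_ref×hom_ref   de_novo
het        one carrier       ad_inherited_affected_parent if that parent
                             is affected, else ad_incomplete_penetrance
het        both carriers     dominant from either side; affected parent
                             preferred, carrier_parent = both
hom_alt    het×het           ar_homozygous
hom_alt    het×hom_alt or    ar_homozygous
           hom_alt×hom_alt
hom_alt    hom_ref×hom_ref   de_novo_homozygous_flagged (two independent
                             de novo hits are implausible — flagged, not
                             silently accepted)
hom_alt    hom_ref×carrier   mendelian_inconsistent (one parent cannot
                             have transmitted an ALT allele)
========= ================= ===========================================

A de novo call requires both parents present with non-missing hom-ref
calls; any absent parent or missing parental call demotes the variant to
``unknown_missing_parent`` unless the present parent's genotype forces a
classification (a carrier parent still supports the dominant sub-modes; a
hom-ref single parent of a hom-alt proband forces inconsistency).

On the X chromosome an XY proband cannot be het (``mendelian_inconsistent``)
and a hom-alt (hemizygous) call with a carrier mother is ``x_linked``.

Compound heterozygotes are paired per gene: two proband-het variants, one
carried by the mother only and the other by the father only (trans by
parental origin).  With a parent absent the pair is reported phase-unknown,
never asserted.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .errors import UsageError
from .types import AnnotatedVariant, FamilyGenotypes, Role, Sex, Zygosity


class Mode(str, enum.Enum):
    de_novo = "de_novo"
    de_novo_homozygous_flagged = "de_novo_homozygous_flagged"
    ad_inherited_affected_parent = "ad_inherited_affected_parent"
    ad_incomplete_penetrance = "ad_incomplete_penetrance"
    ar_homozygous = "ar_homozygous"
    compound_het = "compound_het"
    x_linked = "x_linked"
    unknown_missing_parent = "unknown_missing_parent"
    mendelian_inconsistent = "mendelian_inconsistent"
    unclassified = "unclassified"


class CarrierParent(str, enum.Enum):
    mother = "mother"
    father = "father"
    both = "both"
    none = "none"
    unknown = "unknown"


@dataclass
class InheritanceCall:
    key: str
    family_id: str
    gene: str
    mode: Mode
    carrier_parent: CarrierParent
    notes: list[str] = field(default_factory=list)


@dataclass
class InheritanceConfig:
    """``max_parent_miscalls``: number of parental genotype conflicts
    tolerated (as possible genotyping error) before a variant is declared
    Mendelian-inconsistent.  Default 0: every conflict is reported."""

    max_parent_miscalls: int = 0


def _parent_state(fam: FamilyGenotypes, key: str, role: Role) -> Optional[Zygosity]:
    """Genotype of a parent, or None when the parent is absent/uncalled."""
    member = fam.member(role)
    if member is None or not member.present:
        return None
    zyg = fam.genotype(key, role)
    return None if zyg is Zygosity.missing else zyg


def classify(
    v: AnnotatedVariant,
    fam: FamilyGenotypes,
    cfg: Optional[InheritanceConfig] = None,
) -> InheritanceCall:
    """Classify one carrier variant's segregation pattern in one family."""
    cfg = cfg or InheritanceConfig()
    key = v.key
    proband = fam.genotype(key, Role.proband)
    if not proband.is_carrier:
        raise UsageError(f"{key}: proband is {proband.value}; nothing to classify")

    mother = _parent_state(fam, key, Role.mother)
    father = _parent_state(fam, key, Role.father)
    notes: list[str] = []

    def call(mode: Mode, carrier: CarrierParent) -> InheritanceCall:
        return InheritanceCall(key, fam.family_id, v.gene, mode, carrier, notes)

    def inconsistent(carrier: CarrierParent, n_conflicts: int) -> InheritanceCall:
        if n_conflicts <= cfg.max_parent_miscalls:
            notes.append(
                f"{n_conflicts} parental conflict(s) within genotyping-error tolerance"
            )
            return call(Mode.unclassified, carrier)
        return call(Mode.mendelian_inconsistent, carrier)

    # --- X chromosome, XY proband (hemizygous) ---------------------------
    if v.on_x and fam.proband.sex is Sex.XY:
        if proband is Zygosity.het:
            notes.append("heterozygous call on X in an XY proband is invalid")
            return inconsistent(CarrierParent.unknown, 1)
        # hom_alt == hemizygous; only the maternal allele is informative
        if mother is None:
            return call(Mode.unknown_missing_parent, CarrierParent.unknown)
        if mother.is_carrier:
            return call(Mode.x_linked, CarrierParent.mother)
        notes.append("hemizygous variant absent in the mother")
        return call(Mode.de_novo, CarrierParent.none)

    # --- autosomal (and X in XX probands, treated identically) -----------
    both_called = mother is not None and father is not None

    if proband is Zygosity.het:
        if both_called:
            m_car, f_car = mother.is_carrier, father.is_carrier
            if not m_car and not f_car:
                return call(Mode.de_novo, CarrierParent.none)
            if m_car and f_car:
                m_aff = bool(fam.member(Role.mother) and fam.member(Role.mother).affected)
                f_aff = bool(fam.member(Role.father) and fam.member(Role.father).affected)
                mode = (
                    Mode.ad_inherited_affected_parent
                    if (m_aff or f_aff)
                    else Mode.ad_incomplete_penetrance
                )
                return call(mode, CarrierParent.both)
            role = Role.mother if m_car else Role.father
            carrier = CarrierParent.mother if m_car else CarrierParent.father
            parent = fam.member(role)
            mode = (
                Mode.ad_inherited_affected_parent
                if parent is not None and parent.affected
                else Mode.ad_incomplete_penetrance
            )
            return call(mode, carrier)
        # one (or both) parents unavailable: de novo cannot be asserted
        present = mother if mother is not None else father
        if present is not None and present.is_carrier:
            role = Role.mother if mother is not None else Role.father
            carrier = CarrierParent.mother if mother is not None else CarrierParent.father
            parent = fam.member(role)
            mode = (
                Mode.ad_inherited_affected_parent
                if parent is not None and parent.affected
                else Mode.ad_incomplete_penetrance
            )
            return call(mode, carrier)
        notes.append("variant absent in the available parent; de novo cannot be asserted")
        return call(Mode.unknown_missing_parent, CarrierParent.unknown)

    # proband hom_alt
    if both_called:
        m_car, f_car = mother.is_carrier, father.is_carrier
        if m_car and f_car:
            return call(Mode.ar_homozygous, CarrierParent.both)
        if not m_car and not f_car:
            notes.append("possible hemizygosity/CNV or genotyping artefact")
            return call(Mode.de_novo_homozygous_flagged, CarrierParent.none)
        # exactly one carrier: the hom_ref parent cannot have transmitted ALT
        carrier = CarrierParent.mother if m_car else CarrierParent.father
        return inconsistent(carrier, 1)
    # single available parent
    present = mother if mother is not None else father
    if present is None:
        return call(Mode.unknown_missing_parent, CarrierParent.unknown)
    if present.is_carrier:
        notes.append("second parental allele unverifiable (parent unavailable)")
        return call(Mode.unknown_missing_parent, CarrierParent.unknown)
    notes.append("available parent is hom_ref yet proband is hom_alt")
    return inconsistent(CarrierParent.unknown, 1)


def _parental_origin(fam: FamilyGenotypes, key: str) -> str:
    mother = _parent_state(fam, key, Role.mother)
    father = _parent_state(fam, key, Role.father)
    if mother is None or father is None:
        return "unknown"
    m, f = mother.is_carrier, father.is_carrier
    if m and not f:
        return "maternal"
    if f and not m:
        return "paternal"
    if m and f:
        return "both"
    return "neither"


def find_compound_hets(
    variants: Iterable[AnnotatedVariant], fam: FamilyGenotypes
) -> list[InheritanceCall]:
    """Pair proband-het variants per gene into trans compound heterozygotes.

    With both parents present a pair qualifies iff one variant is maternal-
    only and the other paternal-only; cis pairs are excluded.  With a parent
    unavailable, candidate pairs are emitted with a phase-unknown note.
    """
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if v.family_id != fam.family_id:
            continue
        if fam.genotype(v.key, Role.proband) is Zygosity.het:
            by_gene.setdefault(v.gene, []).append(v)

    full_trio = fam.parent_present(Role.mother) and fam.parent_present(Role.father)
    calls: list[InheritanceCall] = []
    for gene, vs in by_gene.items():
        for v1, v2 in combinations(sorted(vs, key=lambda v: v.key), 2):
            pair_key = f"{v1.key}|{v2.key}"
            if full_trio:
                o1, o2 = _parental_origin(fam, v1.key), _parental_origin(fam, v2.key)
                if {o1, o2} == {"maternal", "paternal"}:
                    calls.append(
                        InheritanceCall(
                            pair_key, fam.family_id, gene, Mode.compound_het,
                            CarrierParent.both,
                            ["trans configuration by parental origin"],
                        )
                    )
            else:
                calls.append(
                    InheritanceCall(
                        pair_key, fam.family_id, gene, Mode.compound_het,
                        CarrierParent.unknown,
                        ["phase-unknown: parent unavailable, trans configuration not asserted"],
                    )
                )
    return calls


def classify_cohort(
    variants: Iterable[AnnotatedVariant],
    families: dict[str, FamilyGenotypes],
    cfg: Optional[InheritanceConfig] = None,
) -> tuple[list[InheritanceCall], Counter]:
    """Classify every carrier variant in every family, plus compound-het
    pairing; returns the calls and per-mode summary counts."""
    cfg = cfg or InheritanceConfig()
    variants = list(variants)
    calls: list[InheritanceCall] = []
    for fid, fam in families.items():
        fam_variants = [v for v in variants if v.family_id == fid]
        for v in fam_variants:
            if fam.genotype(v.key, Role.proband).is_carrier:
                calls.append(classify(v, fam, cfg))
        calls.extend(find_compound_hets(fam_variants, fam))
    return calls, Counter(c.mode for c in calls)


def calls_to_frame(calls: Iterable[InheritanceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": c.family_id,
                "gene": c.gene,
                "key": c.key,
                "mode": c.mode.value,
                "carrier_parent": c.carrier_parent.value,
                "notes": "; ".join(c.notes),
            }
            for c in calls
        ],
        columns=["family_id", "gene", "key", "mode", "carrier_parent", "notes"],
    )
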