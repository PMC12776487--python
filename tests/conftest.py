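from __future__ import annotations

from typing import Optional

import pytest
from hypothesis import HealthCheck, settings

from trioprio.types import (
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    AnnotationPanel,
    Consequence,
    FamilyGenotypes,
    FamilyMember,
    Role,
    Sex,
    Verdict,
    Zygosity,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_panel(
    votes: Optional[int] = None,
    mafs: Optional[dict[str, Optional[float]]] = None,
    cadd: Optional[float] = None,
    splice: Optional[float] = None,
) -> AnnotationPanel:
    """Panel with the first ``votes`` tools voting pathogenic, rest benign;
    ``votes=None`` leaves all verdicts missing."""
    verdicts: dict[str, Verdict] = {}
    if votes is not None:
        for i, tool in enumerate(PREDICTOR_TOOLS):
            verdicts[tool] = Verdict.pathogenic if i < votes else Verdict.benign
    return AnnotationPanel(
        maf_by_source=dict(mafs or {}),
        predictor_verdicts=verdicts,
        cadd_phred=cadd,
        splice_delta=splice,
    )


_COUNTER = [0]


def make_variant(
    consequence: Consequence | str = Consequence.missense,
    panel: Optional[AnnotationPanel] = None,
    gene: str = "GENE1",
    family_id: str = "FAM1",
    chrom: str = "chr1",
    pos: Optional[int] = None,
    ref: str = "A",
    alt: str = "G",
    dbsnp_id: str = "rs1",
    **panel_kwargs,
) -> AnnotatedVariant:
    if pos is None:
        _COUNTER[0] += 1
        pos = 1000 + _COUNTER[0]
    return AnnotatedVariant(
        family_id=family_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        hgvs_c=f"c.{pos}{ref}>{alt}",
        hgvs_p="",
        consequence=Consequence(consequence),
        dbsnp_id=dbsnp_id,
        panel=panel if panel is not None else make_panel(**panel_kwargs),
    )


def make_family(
    family_id: str = "FAM1",
    proband_sex: Sex = Sex.XX,
    mother_affected: bool = False,
    father_affected: bool = False,
    father_present: bool = True,
    mother_present: bool = True,
) -> FamilyGenotypes:
    members = [
        FamilyMember(f"{family_id}.p", Role.proband, proband_sex, affected=True),
        FamilyMember(
            f"{family_id}.m", Role.mother, Sex.XX, mother_affected, mother_present
        ),
        FamilyMember(
            f"{family_id}.f", Role.father, Sex.XY, father_affected, father_present
        ),
    ]
    return FamilyGenotypes(family_id=family_id, members=members)


def set_trio(
    fam: FamilyGenotypes,
    key: str,
    proband: Zygosity,
    mother: Zygosity = Zygosity.hom_ref,
    father: Zygosity = Zygosity.hom_ref,
) -> None:
    fam.set_genotype(key, Role.proband, proband)
    fam.set_genotype(key, Role.mother, mother)
    fam.set_genotype(key, Role.father, father)


@pytest.fixture
def table1():
    from trioprio.fixtures import load_table1_fixture

    return load_table1_fixture()
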