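"""Packaged worked-example fixtures.

``load_table1_fixture`` transcribes the published 14-variant table for the
nine-family orofacial-cleft/limb-anomaly cohort: genomic coordinates, rsIDs,
zygosity, HGVS nomenclature, per-variant predictor-support counts, and the
printed inheritance labels.  Two caveats, both cosmetic for the analyses this
package performs:

* the publication prints coordinates but not REF/ALT alleles — SNV alleles
  are taken from the HGVSc nucleotides (a strand simplification) and indel
  alleles are minimal placeholder representations consistent with the HGVSc;
* family genotypes are reconstructed from the printed zygosity and
  inheritance labels (de novo ⇒ both parents hom-ref; maternal dominant ⇒
  mother het and affected; unknown ⇒ dyad with the variant absent in the
  mother), which is exactly the information the table asserts.

The packaged interaction edge list and GMT collection are *synthetic*
stand-ins (the originals are exports of external databases and are not
printed); they are shaped to match the published count-level network numbers
(13 nodes, 5 edges, one edge at confidence ≥ 0.4).
"""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import as_file, files

import pandas as pd

from .inheritance import Mode
from .io import read_edges, read_gmt
from .types import (
    NOVEL,
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    AnnotationPanel,
    Consequence,
    EdgeList,
    FamilyGenotypes,
    FamilyMember,
    GeneSetCollection,
    Role,
    Sex,
    Verdict,
    Zygosity,
)

_DATA = files("trioprio.data")

#: Printed label → inheritance mode expected from the classifier.
_LABEL_TO_MODE = {
    ("de_novo", Zygosity.het): Mode.de_novo,
    ("de_novo", Zygosity.hom_alt): Mode.de_novo_homozygous_flagged,
    ("unknown", Zygosity.het): Mode.unknown_missing_parent,
    ("maternal", Zygosity.het): Mode.ad_inherited_affected_parent,
}


def _panel(row: pd.Series) -> AnnotationPanel:
    verdicts: dict[str, Verdict] = {}
    if row["consequence"] == "missense":
        support = int(row["support"])
        for i, tool in enumerate(PREDICTOR_TOOLS):
            verdicts[tool] = Verdict.pathogenic if i < support else Verdict.benign
    cadd = None if row["cadd_phred"] == "." else float(row["cadd_phred"])
    gnomad = None if row["maf_gnomad"] == "." else float(row["maf_gnomad"])
    return AnnotationPanel(
        maf_by_source={"KG1000": None, "ESP": None, "GNOMAD": gnomad},
        predictor_verdicts=verdicts,
        cadd_phred=cadd,
    )


@lru_cache(maxsize=1)
def _table() -> pd.DataFrame:
    with (_DATA / "table1_variants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_table1_fixture() -> tuple[list[AnnotatedVariant], list[FamilyGenotypes]]:
    """The published 14-variant, 9-family worked example.

    Returns the annotated variants and one :class:`FamilyGenotypes` per
    family with genotypes reconstructed from the printed zygosity and
    inheritance labels.  Families F4 and F6 are dyads (father absent).
    """
    df = _table()
    variants: list[AnnotatedVariant] = []
    families: dict[str, FamilyGenotypes] = {}

    for fid, rows in df.groupby("family_id", sort=False):
        sex = Sex(rows.iloc[0]["sex"])
        dyad = (rows["inheritance"] == "unknown").any()
        mother_affected = (rows["inheritance"] == "maternal").any()
        members = [
            FamilyMember(f"{fid}.proband", Role.proband, sex, affected=True),
            FamilyMember(f"{fid}.mother", Role.mother, Sex.XX, affected=mother_affected),
            FamilyMember(f"{fid}.father", Role.father, Sex.XY, affected=False, present=not dyad),
        ]
        families[fid] = FamilyGenotypes(family_id=fid, members=members)

    for row in df.to_dict(orient="records"):
        v = AnnotatedVariant(
            family_id=row["family_id"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            hgvs_c=row["hgvs_c"],
            hgvs_p=row["hgvs_p"],
            consequence=Consequence(row["consequence"]),
            dbsnp_id=row["dbsnp_id"],
            panel=_panel(pd.Series(row)),
        )
        variants.append(v)
        fam = families[row["family_id"]]
        proband_zyg = Zygosity(row["zygosity"])
        label = row["inheritance"]
        fam.set_genotype(v.key, Role.proband, proband_zyg)
        fam.set_genotype(
            v.key, Role.mother, Zygosity.het if label == "maternal" else Zygosity.hom_ref
        )
        fam.set_genotype(
            v.key,
            Role.father,
            Zygosity.missing if not fam.parent_present(Role.father) else Zygosity.hom_ref,
        )
    return variants, list(families.values())


def table1_expected_modes() -> dict[str, Mode]:
    """Variant key → inheritance mode implied by the printed labels."""
    expected = {}
    for row in _table().to_dict(orient="records"):
        key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
        expected[key] = _LABEL_TO_MODE[(row["inheritance"], Zygosity(row["zygosity"]))]
    return expected


def table1_genes() -> list[str]:
    """The distinct gene symbols of the worked example, sorted."""
    return sorted(set(_table()["gene"]))


def load_ppi_edges() -> EdgeList:
    """Synthetic five-interaction confidence-scored edge list (0–1000 dialect
    rescaled to [0, 1]) over the worked-example genes."""
    with as_file(_DATA / "string_edges_synthetic.tsv") as path:
        return read_edges(path, score_scale="milli")


def load_demo_genesets() -> GeneSetCollection:
    """Synthetic GMT collection used by tests and the demo pipeline run."""
    with as_file(_DATA / "genesets_synthetic.gmt") as path:
        return read_gmt(path)
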