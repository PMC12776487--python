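"""Readers and writers for the external formats the pipeline touches.

Formats: VCF v4.x (via pysam), 6-column PED, the annotation sidecar TSV
(schema below), STRING-dialect interaction edge lists, and GMT gene sets.

Sidecar TSV schema (tab-separated, one header line; ``.`` denotes missing)::

    chrom  pos  ref  alt  gene  consequence  hgvs_c  hgvs_p  dbsnp_id
    maf_kg1000  maf_esp  maf_gnomad  cadd_phred  splice_delta
    verdict_<tool>            # one column per tool in PREDICTOR_TOOLS,
                              # values P (pathogenic) / B (benign) / .

Rows are keyed by ``chrom:pos:ref:alt`` and must cover every biallelic VCF
record.  Multiallelic records are rejected: inputs are assumed normalized
(split and left-aligned) upstream.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pysam

from .errors import (
    FormatError,
    MissingAnnotationError,
    NormalizationError,
    PedigreeMismatchError,
)
from .types import (
    MAF_SOURCES,
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    AnnotationPanel,
    Consequence,
    EdgeList,
    FamilyGenotypes,
    FamilyMember,
    GeneSet,
    GeneSetCollection,
    PedigreeTable,
    Role,
    Sex,
    Verdict,
    Zygosity,
    variant_key,
)

log = logging.getLogger(__name__)

_MAF_COLUMNS = {"KG1000": "maf_kg1000", "ESP": "maf_esp", "GNOMAD": "maf_gnomad"}
_VERDICT_CODES = {"P": Verdict.pathogenic, "B": Verdict.benign, ".": Verdict.missing}
_VERDICT_CODES_INV = {v: k for k, v in _VERDICT_CODES.items()}

SIDECAR_COLUMNS: tuple[str, ...] = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "hgvs_c",
    "hgvs_p",
    "dbsnp_id",
    "maf_kg1000",
    "maf_esp",
    "maf_gnomad",
    "cadd_phred",
    "splice_delta",
) + tuple(f"verdict_{t}" for t in PREDICTOR_TOOLS)


# ---------------------------------------------------------------------------
# PED


def read_ped(path: Union[str, Path]) -> PedigreeTable:
    """Parse a whitespace-delimited 6-column PED file.

    Roles are inferred from parent pointers: an individual with a non-zero
    parent pointer is the proband; individuals named as its parents take the
    mother/father roles.  Sex codes 1/2 map to XY/XX; phenotype 2 means
    affected, 1 unaffected, 0 unknown (treated as unaffected with a logged
    warning).  Two probands in one family is an error: multiplex families
    are encoded as proband plus affected parent.
    """
    rows: list[tuple[str, str, str, str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        rows.append(tuple(parts))  # type: ignore[arg-type]

    families: dict[str, list[FamilyMember]] = {}
    by_family: dict[str, list[tuple[str, ...]]] = {}
    for row in rows:
        by_family.setdefault(row[0], []).append(row)

    for fid, frows in by_family.items():
        ids = {r[1] for r in frows}
        children = [r for r in frows if r[2] != "0" or r[3] != "0"]
        if len(children) != 1:
            raise FormatError(
                f"family {fid}: expected exactly one individual with parent "
                f"pointers (the proband), got {len(children)}"
            )
        child = children[0]
        father_id, mother_id = child[2], child[3]
        for pid, label in ((father_id, "father"), (mother_id, "mother")):
            if pid != "0" and pid not in ids:
                raise FormatError(f"family {fid}: {label} {pid!r} has no PED row")
        members: list[FamilyMember] = []
        for r in frows:
            _, iid, _, _, sex_code, pheno_code = r
            if sex_code == "1":
                sex = Sex.XY
            elif sex_code == "2":
                sex = Sex.XX
            else:
                raise FormatError(f"family {fid}: unknown sex code {sex_code!r}")
            if pheno_code == "2":
                affected = True
            elif pheno_code == "1":
                affected = False
            elif pheno_code == "0":
                affected = False
                log.warning("family %s individual %s: unknown affected status", fid, iid)
            else:
                raise FormatError(f"family {fid}: unknown phenotype code {pheno_code!r}")
            if iid == child[1]:
                role = Role.proband
            elif iid == mother_id:
                role = Role.mother
            elif iid == father_id:
                role = Role.father
            else:
                raise FormatError(
                    f"family {fid}: individual {iid!r} is neither proband nor a "
                    "named parent"
                )
            members.append(FamilyMember(iid, role, sex, affected))
        families[fid] = members
    return PedigreeTable(families)


def write_ped(pedigree: PedigreeTable, path: Union[str, Path]) -> None:
    lines = []
    for fid, members in pedigree.families.items():
        roles = {m.role: m for m in members if m.present}
        mother = roles.get(Role.mother)
        father = roles.get(Role.father)
        for m in members:
            if not m.present:
                continue
            if m.role is Role.proband:
                fa = father.sample_id if father else "0"
                mo = mother.sample_id if mother else "0"
            else:
                fa = mo = "0"
            sex = "1" if m.sex is Sex.XY else "2"
            pheno = "2" if m.affected else "1"
            lines.append(f"{fid}\t{m.sample_id}\t{fa}\t{mo}\t{sex}\t{pheno}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sidecar TSV


def _parse_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in (".", "", "NA"):
            return None
        return float(value)
    return float(value)


def read_sidecar(path: Union[str, Path]) -> dict[str, dict]:
    """Load the annotation sidecar into a dict keyed by ``chrom:pos:ref:alt``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"sidecar {path}: missing columns {sorted(missing_cols)}")
    table: dict[str, dict] = {}
    for rec in df.to_dict(orient="records"):
        key = variant_key(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
        table[key] = rec
    return table


def _panel_from_row(row: dict) -> AnnotationPanel:
    mafs = {src: _parse_float(row[col]) for src, col in _MAF_COLUMNS.items()}
    verdicts = {}
    for tool in PREDICTOR_TOOLS:
        code = str(row[f"verdict_{tool}"]).strip() or "."
        if code not in _VERDICT_CODES:
            raise FormatError(f"unknown verdict code {code!r} for {tool}")
        verdicts[tool] = _VERDICT_CODES[code]
    return AnnotationPanel(
        maf_by_source=mafs,
        predictor_verdicts=verdicts,
        cadd_phred=_parse_float(row["cadd_phred"]),
        splice_delta=_parse_float(row["splice_delta"]),
    )


def _variant_from_row(family_id: str, row: dict) -> AnnotatedVariant:
    return AnnotatedVariant(
        family_id=family_id,
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        gene=row["gene"],
        hgvs_c=row["hgvs_c"],
        hgvs_p=row["hgvs_p"],
        consequence=Consequence(row["consequence"]),
        dbsnp_id=row["dbsnp_id"],
        panel=_panel_from_row(row),
    )


def _fmt_float(value: Optional[float]) -> str:
    return "." if value is None else repr(float(value))


def write_sidecar(variants: Iterable[AnnotatedVariant], path: Union[str, Path]) -> None:
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence.value,
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p,
            "dbsnp_id": v.dbsnp_id,
            "maf_kg1000": _fmt_float(v.panel.maf_by_source["KG1000"]),
            "maf_esp": _fmt_float(v.panel.maf_by_source["ESP"]),
            "maf_gnomad": _fmt_float(v.panel.maf_by_source["GNOMAD"]),
            "cadd_phred": _fmt_float(v.panel.cadd_phred),
            "splice_delta": _fmt_float(v.panel.splice_delta),
        }
        for tool in PREDICTOR_TOOLS:
            row[f"verdict_{tool}"] = _VERDICT_CODES_INV[v.panel.predictor_verdicts[tool]]
        rows.append(row)
    pd.DataFrame(rows, columns=list(SIDECAR_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

_GT_TO_ZYG = {
    (0, 0): Zygosity.hom_ref,
    (0, 1): Zygosity.het,
    (1, 0): Zygosity.het,
    (1, 1): Zygosity.hom_alt,
}
_ZYG_TO_GT = {
    Zygosity.hom_ref: (0, 0),
    Zygosity.het: (0, 1),
    Zygosity.hom_alt: (1, 1),
    Zygosity.missing: (None, None),
}


def read_family_vcf(
    path: Union[str, Path],
    sidecar: Union[str, Path],
    pedigree: PedigreeTable,
) -> tuple[list[AnnotatedVariant], FamilyGenotypes]:
    """Read one family's normalized VCF plus its annotation sidecar.

    Every VCF sample must appear in the pedigree and belong to one family.
    Parents named in the pedigree but absent from the VCF (dyads) are kept
    as members with ``present=False``; a parent role entirely absent from
    the pedigree is materialized the same way so downstream classification
    can reason about the missing parent.
    """
    annotations = read_sidecar(sidecar)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        family_ids = set()
        for s in samples:
            fid = pedigree.family_of(s)
            if fid is None:
                raise PedigreeMismatchError(f"VCF sample {s!r} not in pedigree")
            family_ids.add(fid)
        if len(family_ids) != 1:
            raise PedigreeMismatchError(
                f"VCF {path} mixes families {sorted(family_ids)}; one family per VCF"
            )
        family_id = family_ids.pop()

        members = [
            FamilyMember(m.sample_id, m.role, m.sex, m.affected, m.sample_id in samples)
            for m in pedigree.families[family_id]
        ]
        for role, sex in ((Role.mother, Sex.XX), (Role.father, Sex.XY)):
            if not any(m.role is role for m in members):
                members.append(
                    FamilyMember(f"{family_id}.{role.value}", role, sex, False, False)
                )
        fam = FamilyGenotypes(family_id=family_id, members=members)
        role_of = {m.sample_id: m.role for m in members}

        variants: list[AnnotatedVariant] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n = 0 if rec.alts is None else len(rec.alts)
                raise NormalizationError(
                    f"{rec.chrom}:{rec.pos}: {n} ALT alleles; split multiallelic "
                    "sites before running the pipeline"
                )
            key = variant_key(rec.chrom, rec.pos, rec.ref, rec.alts[0])
            if key in annotations:
                row = annotations[key]
            else:
                raise MissingAnnotationError(f"no sidecar row for {key}")
            variants.append(_variant_from_row(family_id, row))
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    zyg = Zygosity.missing
                else:
                    zyg = _GT_TO_ZYG.get(tuple(gt), Zygosity.missing)
                fam.set_genotype(key, role_of[s], zyg)
            for m in members:
                if not m.present:
                    fam.set_genotype(key, m.role, Zygosity.missing)
    return variants, fam


_CONTIGS = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"])


def write_family_vcf(
    variants: Iterable[AnnotatedVariant],
    fam: FamilyGenotypes,
    path: Union[str, Path],
) -> None:
    """Write a family's genotypes as an uncompressed single-family VCF."""
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    present = [m for m in fam.members if m.present]
    for m in present:
        header.add_sample(m.sample_id)
    ordered = sorted(variants, key=lambda v: (_CONTIGS.index(v.chrom), v.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.id = None if v.is_novel else v.dbsnp_id
            for m in present:
                rec.samples[m.sample_id]["GT"] = _ZYG_TO_GT[fam.genotype(v.key, m.role)]
            out.write(rec)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    """Read a GMT file (set id, description, then member genes, tab-separated).

    The universe defaults to the union of all member genes.
    """
    sets: dict[str, GeneSet] = {}
    universe: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs id, description, genes")
        set_id, name, *genes = parts
        genes = [g.strip() for g in genes if g.strip()]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no genes")
        sets[set_id] = GeneSet(set_id, name, frozenset(genes))
        universe.update(genes)
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


# ---------------------------------------------------------------------------
# Interaction edge lists


def read_edges(path: Union[str, Path], score_scale: str = "auto") -> EdgeList:
    """Read a STRING-dialect edge list (``protein1 protein2 combined_score``
    header, whitespace- or tab-separated) or a headerless 3-column file.

    ``score_scale``: ``"unit"`` for scores already in [0, 1], ``"milli"`` for
    the 0–1000 integer dialect (divided by 1000 on read), ``"auto"`` to
    choose ``milli`` when any score exceeds 1.
    """
    if score_scale not in ("auto", "unit", "milli"):
        raise FormatError(f"unknown score_scale {score_scale!r}")
    raw: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        if not raw and parts[0].lower() in ("protein1", "gene_a", "node1"):
            continue
        try:
            score = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
        raw.append((parts[0], parts[1], score))
    if score_scale == "auto":
        score_scale = "milli" if any(s > 1.0 for _, _, s in raw) else "unit"
    if score_scale == "milli":
        raw = [(a, b, s / 1000.0) for a, b, s in raw]
    rows = []
    for a, b, s in raw:
        if a == b:
            warnings.warn(f"dropping self-loop on {a!r}")
            continue
        rows.append((a, b, s))
    return EdgeList(rows)
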