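"""Domain types shared across the pipeline.

The pipeline operates on pre-annotated, normalized variants: one ALT allele
per record, annotations (population frequencies, in-silico predictor
verdicts, CADD, splice delta) carried in a sidecar table rather than VCF
INFO.  Predictor verdicts arrive pre-binarized to pathogenic/benign — this
package never re-thresholds raw tool scores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import FormatError

#: The fixed eleven-tool in-silico prediction panel, in canonical order.
PREDICTOR_TOOLS: tuple[str, ...] = (
    "ClinPred",
    "MetaRNN",
    "BayesDel_addAF",
    "REVEL",
    "CADD",
    "AlphaMissense",
    "MutPred2",
    "Polyphen-2",
    "MutationAssessor",
    "MutationTaster",
    "SIFT",
)

#: Population-frequency databases consulted by the rarity filter.
MAF_SOURCES: tuple[str, ...] = ("KG1000", "ESP", "GNOMAD")

#: dbSNP-id placeholder for variants absent from all population databases.
NOVEL = "NOVEL"


class Consequence(str, enum.Enum):
    missense = "missense"
    frameshift = "frameshift"
    stop_gained = "stop_gained"
    stop_lost = "stop_lost"
    start_gained = "start_gained"
    start_lost = "start_lost"
    splice_region = "splice_region"
    inframe_indel = "inframe_indel"
    synonymous = "synonymous"
    other = "other"


#: Consequence classes considered protein-altering by the cascade.
PROTEIN_ALTERING: frozenset[Consequence] = frozenset(
    {
        Consequence.missense,
        Consequence.frameshift,
        Consequence.stop_gained,
        Consequence.stop_lost,
        Consequence.start_gained,
        Consequence.start_lost,
        Consequence.splice_region,
    }
)


class Verdict(str, enum.Enum):
    pathogenic = "pathogenic"
    benign = "benign"
    missing = "missing"


class Zygosity(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"

    @property
    def is_carrier(self) -> bool:
        return self in (Zygosity.het, Zygosity.hom_alt)


class Role(str, enum.Enum):
    proband = "proband"
    mother = "mother"
    father = "father"


class Sex(str, enum.Enum):
    XX = "XX"
    XY = "XY"


@dataclass
class AnnotationPanel:
    """Per-variant annotation bundle consumed by the filter cascade.

    ``maf_by_source`` maps each of :data:`MAF_SOURCES` to a frequency in
    [0, 1] or ``None`` (not observed in that database — distinct from an
    observed frequency of exactly 0).  ``predictor_verdicts`` always carries
    all eleven tools of :data:`PREDICTOR_TOOLS`; individual verdicts may be
    :attr:`Verdict.missing`.
    """

    maf_by_source: dict[str, Optional[float]] = field(default_factory=dict)
    predictor_verdicts: dict[str, Verdict] = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    splice_delta: Optional[float] = None

    def __post_init__(self) -> None:
        for src in self.maf_by_source:
            if src not in MAF_SOURCES:
                raise FormatError(f"unknown MAF source {src!r}")
        for src in MAF_SOURCES:
            self.maf_by_source.setdefault(src, None)
        for src, f in self.maf_by_source.items():
            if f is not None and not (0.0 <= f <= 1.0):
                raise FormatError(f"MAF {f!r} from {src} outside [0, 1]")
        for tool in self.predictor_verdicts:
            if tool not in PREDICTOR_TOOLS:
                raise FormatError(f"unknown predictor tool {tool!r}")
        full = {t: self.predictor_verdicts.get(t, Verdict.missing) for t in PREDICTOR_TOOLS}
        self.predictor_verdicts = full
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise FormatError("CADD phred score must be nonnegative")
        if self.splice_delta is not None and not (0.0 <= self.splice_delta <= 1.0):
            raise FormatError("splice delta must lie in [0, 1]")

    @property
    def pathogenic_votes(self) -> int:
        """Number of tools voting pathogenic (missing counts as not-pathogenic)."""
        return sum(1 for v in self.predictor_verdicts.values() if v is Verdict.pathogenic)

    @property
    def present_mafs(self) -> list[float]:
        return [f for f in self.maf_by_source.values() if f is not None]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class AnnotatedVariant:
    """One normalized, annotated variant observed in one family."""

    family_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    consequence: Consequence
    dbsnp_id: str
    panel: AnnotationPanel

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position {self.pos} must be >= 1")
        if not self.ref or not self.alt:
            raise FormatError("REF and ALT must be non-empty")
        if "," in self.alt:
            raise FormatError(f"multiallelic ALT {self.alt!r}: normalize first")
        if self.ref == self.alt:
            raise FormatError("REF equals ALT")
        self.consequence = Consequence(self.consequence)

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_novel(self) -> bool:
        return self.dbsnp_id == NOVEL

    @property
    def on_x(self) -> bool:
        return self.chrom.removeprefix("chr").upper() == "X"


@dataclass
class FamilyMember:
    sample_id: str
    role: Role
    sex: Sex
    affected: bool
    present: bool = True


@dataclass
class FamilyGenotypes:
    """Genotype calls for one family (proband plus up to two parents).

    ``calls`` maps a variant key to per-role zygosity.  An absent member
    (``present=False``, e.g. an unavailable father in a dyad) has all calls
    :attr:`Zygosity.missing`.
    """

    family_id: str
    members: list[FamilyMember]
    calls: dict[str, dict[Role, Zygosity]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probands = [m for m in self.members if m.role is Role.proband]
        if len(probands) != 1:
            raise FormatError(
                f"family {self.family_id}: expected exactly one proband, got {len(probands)}"
            )
        if not probands[0].affected:
            raise FormatError(f"family {self.family_id}: proband must be affected")
        for role in (Role.mother, Role.father):
            if sum(1 for m in self.members if m.role is role) > 1:
                raise FormatError(f"family {self.family_id}: more than one {role.value}")
        for m in self.members:
            if not m.present:
                for per_role in self.calls.values():
                    per_role[m.role] = Zygosity.missing

    def member(self, role: Role) -> Optional[FamilyMember]:
        for m in self.members:
            if m.role is role:
                return m
        return None

    @property
    def proband(self) -> FamilyMember:
        m = self.member(Role.proband)
        assert m is not None
        return m

    def parent_present(self, role: Role) -> bool:
        m = self.member(role)
        return m is not None and m.present

    def genotype(self, key: str, role: Role) -> Zygosity:
        m = self.member(role)
        if m is None or not m.present:
            return Zygosity.missing
        return self.calls.get(key, {}).get(role, Zygosity.missing)

    def set_genotype(self, key: str, role: Role, zyg: Zygosity) -> None:
        self.calls.setdefault(key, {})[role] = zyg


@dataclass
class PedigreeTable:
    """Parsed 6-column PED content: per-family member roster keyed by sample id."""

    families: dict[str, list[FamilyMember]]

    def family_of(self, sample_id: str) -> Optional[str]:
        for fid, members in self.families.items():
            if any(m.sample_id == sample_id for m in members):
                return fid
        return None

    def member_for(self, sample_id: str) -> Optional[FamilyMember]:
        for members in self.families.values():
            for m in members:
                if m.sample_id == sample_id:
                    return m
        return None


@dataclass
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """GMT-style gene-set collection plus the background universe.

    The universe defaults (at read time) to the union of all set members;
    every set is a subset of the universe."""

    sets: dict[str, GeneSet]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for gs in self.sets.values():
            if not gs.genes:
                raise FormatError(f"gene set {gs.set_id!r} is empty")
            if not gs.genes <= self.universe:
                raise FormatError(f"gene set {gs.set_id!r} escapes the universe")


@dataclass
class EdgeList:
    """Undirected weighted interaction edges with confidence scores in [0, 1]."""

    rows: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for a, b, s in self.rows:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            if not (0.0 <= s <= 1.0):
                raise FormatError(f"edge score {s} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)
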