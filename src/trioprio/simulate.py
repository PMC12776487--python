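"""Synthetic annotated family cohorts with known ground truth.

The generator emulates the structure of a small exome-sequenced cohort of
case-parent trios and case-mother dyads: per-family variant tables with
population-frequency spectra, an eleven-tool predictor-verdict panel per
missense variant, and genotypes that respect Mendelian transmission — plus
*planted* variants with known inheritance modes (de novo, dominant from an
affected parent, dominant with incomplete penetrance, recessive homozygous,
compound heterozygous) so that every pipeline stage can be scored against
truth.

Background minor-allele frequencies follow a mixture: a point mass at
"novel" (absent from every database) with weight ``novel_weight``, and a
log-uniform draw on ``maf_bounds`` otherwise.  Background missense verdict
counts are binomial and concentrated below the consensus threshold; planted
variants draw uniformly from {6..11}.  Dyads are produced by dropping the
father *after* planting, so truth is known but the expected pipeline call is
demoted accordingly.  Optional genotyping noise perturbs written calls after
planting; the truth table is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, EvaluationError
from .inheritance import InheritanceCall, Mode
from .io import write_family_vcf, write_ped, write_sidecar
from .types import (
    MAF_SOURCES,
    NOVEL,
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    AnnotationPanel,
    Consequence,
    FamilyGenotypes,
    FamilyMember,
    PedigreeTable,
    Role,
    Sex,
    Verdict,
    Zygosity,
)

_BASES = ("A", "C", "G", "T")
_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: background consequence-class mixture (roughly exome-like at a coarse grain)
_CONSEQUENCE_MIX: tuple[tuple[Consequence, float], ...] = (
    (Consequence.synonymous, 0.30),
    (Consequence.missense, 0.40),
    (Consequence.frameshift, 0.05),
    (Consequence.stop_gained, 0.04),
    (Consequence.splice_region, 0.06),
    (Consequence.inframe_indel, 0.05),
    (Consequence.other, 0.10),
)

PLANTABLE_MODES = ("de_novo", "ad_inherited", "ad_incomplete", "ar_homozygous", "compound_het")


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults emulate the nine-family cohort the pipeline was designed
    around: 9 families of which 2/9 are case-mother dyads, one planted de
    novo variant per family, a 20% novel mass in the background frequency
    mixture, and zero genotyping error.
    """

    n_families: int = 9
    dyad_fraction: float = 2 / 9
    variants_per_family: int = 100
    planted: dict[str, int] = field(default_factory=lambda: {"de_novo": 1})
    novel_weight: float = 0.2
    maf_bounds: tuple[float, float] = (1e-5, 0.5)
    background_vote_p: float = 0.15
    genotype_error_rate: float = 0.0
    consanguinity_fraction: float = 0.0
    inbreeding_coefficient: float = 0.0625
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("need at least one family")
        for name, p in (
            ("dyad_fraction", self.dyad_fraction),
            ("novel_weight", self.novel_weight),
            ("genotype_error_rate", self.genotype_error_rate),
            ("consanguinity_fraction", self.consanguinity_fraction),
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        for mode in self.planted:
            if mode not in PLANTABLE_MODES:
                raise ConfigError(f"unknown plantable mode {mode!r}")
        if self.planted_slots > self.variants_per_family:
            raise ConfigError(
                f"planted variants ({self.planted_slots}) exceed "
                f"variants_per_family ({self.variants_per_family})"
            )
        lo, hi = self.maf_bounds
        if not (0 < lo < hi <= 1):
            raise ConfigError("maf_bounds must satisfy 0 < lo < hi <= 1")

    @property
    def planted_slots(self) -> int:
        # a compound-het event occupies two variant slots
        return sum(
            2 * n if mode == "compound_het" else n for mode, n in self.planted.items()
        )


@dataclass
class SimulatedCohort:
    config: SimConfig
    variants: list[AnnotatedVariant]
    families: dict[str, FamilyGenotypes]
    truth: pd.DataFrame

    def pedigree(self) -> PedigreeTable:
        return PedigreeTable(
            families={fid: fam.members for fid, fam in self.families.items()}
        )


# ---------------------------------------------------------------------------
# generation helpers


def _draw_maf(rng: np.random.Generator, cfg: SimConfig) -> Optional[float]:
    if rng.random() < cfg.novel_weight:
        return None
    lo, hi = cfg.maf_bounds
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _verdicts_from_votes(rng: np.random.Generator, votes: int) -> dict[str, Verdict]:
    votes = int(min(votes, len(PREDICTOR_TOOLS)))
    chosen = set(rng.choice(len(PREDICTOR_TOOLS), size=votes, replace=False).tolist())
    return {
        tool: (Verdict.pathogenic if i in chosen else Verdict.benign)
        for i, tool in enumerate(PREDICTOR_TOOLS)
    }


def _founder_genotype(rng: np.random.Generator, q: float, inbreeding: float) -> Zygosity:
    p_hom_alt = q * q + inbreeding * q * (1 - q)
    p_het = 2 * q * (1 - q) * (1 - inbreeding)
    u = rng.random()
    if u < p_hom_alt:
        return Zygosity.hom_alt
    if u < p_hom_alt + p_het:
        return Zygosity.het
    return Zygosity.hom_ref


def _transmit(rng: np.random.Generator, parent: Zygosity) -> int:
    if parent is Zygosity.hom_alt:
        return 1
    if parent is Zygosity.het:
        return int(rng.random() < 0.5)
    return 0


def _child_genotype(
    rng: np.random.Generator, mother: Zygosity, father: Zygosity
) -> Zygosity:
    n_alt = _transmit(rng, mother) + _transmit(rng, father)
    return (Zygosity.hom_ref, Zygosity.het, Zygosity.hom_alt)[n_alt]


_ERROR_STATES = (Zygosity.hom_ref, Zygosity.het, Zygosity.hom_alt)


def _perturb(rng: np.random.Generator, zyg: Zygosity, rate: float) -> Zygosity:
    if zyg is Zygosity.missing or rate <= 0 or rng.random() >= rate:
        return zyg
    others = [z for z in _ERROR_STATES if z is not zyg]
    return others[int(rng.integers(len(others)))]


# ---------------------------------------------------------------------------
# planting


_PLANT_GENOTYPES = {
    "de_novo": (Zygosity.het, Zygosity.hom_ref, Zygosity.hom_ref),
    "ar_homozygous": (Zygosity.hom_alt, Zygosity.het, Zygosity.het),
}

_TRIO_EXPECTED = {
    "de_novo": Mode.de_novo,
    "ad_inherited": Mode.ad_inherited_affected_parent,
    "ad_incomplete": Mode.ad_incomplete_penetrance,
    "ar_homozygous": Mode.ar_homozygous,
    "compound_het": Mode.compound_het,
}


def _dyad_expected(mode: str, carrier: str) -> Mode:
    """Expected pipeline call after the father is dropped (mother retained)."""
    if mode in ("ad_inherited", "ad_incomplete") and carrier == "mother":
        return _TRIO_EXPECTED[mode]
    if mode == "compound_het":
        return Mode.compound_het  # emitted phase-unknown
    return Mode.unknown_missing_parent


def simulate_cohort(
    cfg: SimConfig, out_dir: Optional[Union[str, Path]] = None
) -> SimulatedCohort:
    """Generate the cohort; optionally write VCFs + sidecars + PED + truth.

    Reproducible: identical config (including seed) yields identical
    in-memory objects and identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    n_dyads = round(cfg.dyad_fraction * cfg.n_families)
    n_consang = round(cfg.consanguinity_fraction * cfg.n_families)

    all_variants: list[AnnotatedVariant] = []
    families: dict[str, FamilyGenotypes] = {}
    truth_rows: list[dict] = []

    for fam_idx in range(cfg.n_families):
        fid = f"SIM{fam_idx + 1:03d}"
        is_dyad = fam_idx < n_dyads
        inbreeding = cfg.inbreeding_coefficient if fam_idx < n_consang else 0.0
        proband_sex = Sex.XY if rng.random() < 0.5 else Sex.XX

        # plant list: (mode, carrier_parent for the dominant modes).
        # ad_inherited carriers are drawn first — they fix the parental
        # affected statuses — then ad_incomplete carriers are drawn among
        # the *unaffected* parents so the planted label stays well-defined.
        plant_events: list[tuple[str, str]] = []
        affected = {"mother": False, "father": False}
        for _ in range(cfg.planted.get("ad_inherited", 0)):
            carrier = "mother" if rng.random() < 0.5 else "father"
            affected[carrier] = True
            plant_events.append(("ad_inherited", carrier))
        for mode in PLANTABLE_MODES:
            if mode == "ad_inherited":
                continue
            for _ in range(cfg.planted.get(mode, 0)):
                candidates = [p for p in ("mother", "father") if not affected[p]]
                if mode == "ad_incomplete" and candidates:
                    carrier = candidates[int(rng.integers(len(candidates)))]
                else:
                    carrier = "mother" if rng.random() < 0.5 else "father"
                plant_events.append((mode, carrier))

        mother_affected = affected["mother"]
        father_affected = affected["father"]
        members = [
            FamilyMember(f"{fid}.proband", Role.proband, proband_sex, affected=True),
            FamilyMember(f"{fid}.mother", Role.mother, Sex.XX, affected=mother_affected),
            FamilyMember(
                f"{fid}.father", Role.father, Sex.XY,
                affected=father_affected, present=True,
            ),
        ]
        fam = FamilyGenotypes(family_id=fid, members=members)

        variants: list[AnnotatedVariant] = []
        genotypes: dict[str, tuple[Zygosity, Zygosity, Zygosity]] = {}
        site_idx = 0

        def new_site(
            gene: str,
            consequence: Consequence,
            panel: AnnotationPanel,
            dbsnp: str,
        ) -> AnnotatedVariant:
            nonlocal site_idx
            chrom = _AUTOSOMES[site_idx % len(_AUTOSOMES)]
            pos = 1_000_000 + 10_000 * site_idx + int(rng.integers(1, 9_999))
            ref = _BASES[int(rng.integers(4))]
            alt = rng.choice([b for b in _BASES if b != ref])
            site_idx += 1
            v = AnnotatedVariant(
                family_id=fid, chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                gene=gene, hgvs_c=f"c.{site_idx}{ref}>{alt}", hgvs_p="",
                consequence=consequence, dbsnp_id=dbsnp, panel=panel,
            )
            variants.append(v)
            return v

        def planted_panel() -> tuple[AnnotationPanel, Optional[float], int, str]:
            maf = (
                None
                if rng.random() < 0.5
                else float(np.exp(rng.uniform(np.log(1e-5), np.log(1e-3))))
            )
            votes = int(rng.integers(6, 12))
            dbsnp = NOVEL if maf is None else f"rs{int(rng.integers(10**6, 10**9))}"
            panel = AnnotationPanel(
                maf_by_source={s: maf for s in MAF_SOURCES},
                predictor_verdicts=_verdicts_from_votes(rng, votes),
            )
            return panel, maf, votes, dbsnp

        # ---- planted variants ------------------------------------------
        for event_idx, (mode, carrier) in enumerate(plant_events):
            gene = f"PG{fid}_{event_idx}"
            if mode == "compound_het":
                panel1, maf1, votes1, db1 = planted_panel()
                panel2, maf2, votes2, db2 = planted_panel()
                v1 = new_site(gene, Consequence.missense, panel1, db1)
                v2 = new_site(gene, Consequence.missense, panel2, db2)
                genotypes[v1.key] = (Zygosity.het, Zygosity.het, Zygosity.hom_ref)
                genotypes[v2.key] = (Zygosity.het, Zygosity.hom_ref, Zygosity.het)
                pair_key = "|".join(sorted([v1.key, v2.key]))
                for v, maf, votes in ((v1, maf1, votes1), (v2, maf2, votes2)):
                    truth_rows.append(
                        {
                            "family_id": fid, "key": v.key, "gene": gene,
                            "true_mode": "compound_het",
                            "expected_call": _dyad_expected(mode, carrier).value
                            if is_dyad
                            else Mode.compound_het.value,
                            "pair_key": pair_key, "dyad": is_dyad,
                            "maf": np.nan if maf is None else maf,
                            "votes": votes,
                            "consequence": v.consequence.value,
                        }
                    )
                continue
            panel, maf, votes, dbsnp = planted_panel()
            v = new_site(gene, Consequence.missense, panel, dbsnp)
            if mode in _PLANT_GENOTYPES:
                genotypes[v.key] = _PLANT_GENOTYPES[mode]
            else:  # dominant modes: proband het, one carrier parent
                if carrier == "mother":
                    genotypes[v.key] = (Zygosity.het, Zygosity.het, Zygosity.hom_ref)
                else:
                    genotypes[v.key] = (Zygosity.het, Zygosity.hom_ref, Zygosity.het)
            effective_mode = mode
            if mode == "ad_incomplete" and affected[carrier]:
                # both parents affected: an unaffected carrier was unavailable
                effective_mode = "ad_inherited"
            expected = (
                _dyad_expected(effective_mode, carrier)
                if is_dyad
                else _TRIO_EXPECTED[effective_mode]
            )
            truth_rows.append(
                {
                    "family_id": fid, "key": v.key, "gene": v.gene,
                    "true_mode": mode, "expected_call": expected.value,
                    "pair_key": "", "dyad": is_dyad,
                    "maf": np.nan if maf is None else maf,
                    "votes": votes, "consequence": v.consequence.value,
                }
            )

        # ---- background variants ---------------------------------------
        n_background = cfg.variants_per_family - cfg.planted_slots
        classes = [c for c, _ in _CONSEQUENCE_MIX]
        probs = np.array([p for _, p in _CONSEQUENCE_MIX])
        probs = probs / probs.sum()
        for bg_idx in range(n_background):
            consequence = classes[int(rng.choice(len(classes), p=probs))]
            maf = _draw_maf(rng, cfg)
            verdicts: dict[str, Verdict] = {}
            cadd = None
            splice = None
            if consequence is Consequence.missense:
                votes = int(rng.binomial(len(PREDICTOR_TOOLS), cfg.background_vote_p))
                verdicts = _verdicts_from_votes(rng, votes)
            elif consequence in (Consequence.stop_gained, Consequence.stop_lost):
                cadd = float(rng.uniform(0, 40))
            elif consequence is Consequence.splice_region:
                splice = float(rng.uniform(0, 1))
            panel = AnnotationPanel(
                maf_by_source={s: maf for s in MAF_SOURCES},
                predictor_verdicts=verdicts,
                cadd_phred=cadd,
                splice_delta=splice,
            )
            dbsnp = NOVEL if maf is None else f"rs{int(rng.integers(10**6, 10**9))}"
            v = new_site(f"BG{bg_idx:04d}", consequence, panel, dbsnp)
            q = maf if maf is not None else 5e-4
            mo = _founder_genotype(rng, q, inbreeding)
            fa = _founder_genotype(rng, q, inbreeding)
            genotypes[v.key] = (_child_genotype(rng, mo, fa), mo, fa)

        # ---- genotyping noise, dyad demotion, registration --------------
        for v in variants:
            pro, mo, fa = genotypes[v.key]
            pro = _perturb(rng, pro, cfg.genotype_error_rate)
            mo = _perturb(rng, mo, cfg.genotype_error_rate)
            fa = _perturb(rng, fa, cfg.genotype_error_rate)
            fam.set_genotype(v.key, Role.proband, pro)
            fam.set_genotype(v.key, Role.mother, mo)
            fam.set_genotype(v.key, Role.father, fa)
        if is_dyad:
            father = fam.member(Role.father)
            assert father is not None
            father.present = False
            for key in list(fam.calls):
                fam.set_genotype(key, Role.father, Zygosity.missing)

        families[fid] = fam
        all_variants.extend(variants)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "family_id", "key", "gene", "true_mode", "expected_call",
            "pair_key", "dyad", "maf", "votes", "consequence",
        ],
    )
    cohort = SimulatedCohort(
        config=cfg, variants=all_variants, families=families, truth=truth
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SimulatedCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Emit one VCF + sidecar per family, a cohort PED, and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fid, fam in cohort.families.items():
        fam_variants = [v for v in cohort.variants if v.family_id == fid]
        vcf_path = out / f"{fid}.vcf"
        sidecar_path = out / f"{fid}.annotations.tsv"
        write_family_vcf(fam_variants, fam, vcf_path)
        write_sidecar(fam_variants, sidecar_path)
        paths[f"{fid}.vcf"] = vcf_path
        paths[f"{fid}.annotations.tsv"] = sidecar_path
    ped_path = out / "cohort.ped"
    write_ped(cohort.pedigree(), ped_path)
    paths["cohort.ped"] = ped_path
    truth_path = out / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth.tsv"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryReport:
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    confusion: pd.DataFrame
    n_planted: int
    funnel_concordance: Optional[float] = None


def evaluate_recovery(
    calls: Iterable[InheritanceCall],
    truth: pd.DataFrame,
    survivor_keys: Optional[set[str]] = None,
) -> RecoveryReport:
    """Score pipeline inheritance calls against the planted truth.

    Per true mode, sensitivity is the fraction of planted variants (pairs,
    for compound hets) whose call equals the *expected* call — planted
    variants in dyads are expected to be demoted to the missing-parent mode,
    and matching that demotion counts as correct.  Specificity for mode m is
    the fraction of planted items not expecting m that were not called m.
    """
    calls = list(calls)
    if len(truth) == 0:
        raise EvaluationError("empty truth table")
    if calls:
        call_fams = {c.family_id for c in calls}
        truth_fams = set(truth["family_id"])
        if not call_fams & truth_fams:
            raise EvaluationError(
                f"no overlap between call families {sorted(call_fams)[:3]}... and "
                f"truth families {sorted(truth_fams)[:3]}..."
            )
    by_key = {(c.family_id, c.key): c for c in calls}

    items: list[tuple[str, str, str]] = []  # (true_mode, expected, observed)
    seen_pairs: set[tuple[str, str]] = set()
    for row in truth.to_dict(orient="records"):
        if row["true_mode"] == "compound_het":
            pair_id = (row["family_id"], row["pair_key"])
            if pair_id in seen_pairs:
                continue
            seen_pairs.add(pair_id)
            c = by_key.get((row["family_id"], row["pair_key"]))
        else:
            c = by_key.get((row["family_id"], row["key"]))
        observed = c.mode.value if c is not None else "absent"
        items.append((row["true_mode"], row["expected_call"], observed))

    modes = sorted({m for m, _, _ in items})
    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for mode in modes:
        pos = [(e, o) for m, e, o in items if m == mode]
        sensitivity[mode] = (
            sum(1 for e, o in pos if e == o) / len(pos) if pos else 0.0
        )
    expected_modes = sorted({e for _, e, _ in items})
    for mode in expected_modes:
        neg = [(e, o) for _, e, o in items if e != mode]
        specificity[mode] = (
            sum(1 for e, o in neg if o != mode) / len(neg) if neg else 1.0
        )

    confusion = (
        pd.DataFrame(items, columns=["true_mode", "expected_call", "observed_call"])
        .value_counts()
        .rename("count")
        .reset_index()
    )
    concordance = None
    if survivor_keys is not None:
        planted_keys = set(truth["key"])
        concordance = (
            len(planted_keys & survivor_keys) / len(planted_keys)
            if planted_keys
            else 1.0
        )
    return RecoveryReport(
        sensitivity=sensitivity,
        specificity=specificity,
        confusion=confusion,
        n_planted=len(items),
        funnel_concordance=concordance,
    )
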