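"""The rare-variant prioritization cascade.

Stages, applied in fixed order to every variant:

1. ``consequence`` — keep protein-altering classes only (missense,
   frameshift, stop/start gain or loss, splice region).
2. ``rarity`` — keep variants whose maximum minor-allele frequency over the
   population databases with an observed value is strictly below the
   threshold (default 0.01).  A variant absent from every database (novel)
   passes: absence of a frequency is not evidence of commonness.
3. ``class_gate`` — a consequence-specific pathogenicity gate: missense
   variants need a consensus of at least ``consensus_min`` (default 6) of
   the 11 predictor verdicts; stop/start gain-loss variants need a CADD
   phred score at or above ``cadd_min``; splice-region variants need a
   splice delta at or above ``splice_min``.  Frameshift variants bypass the
   gate (no score-based predictor applies to them).
4. ``panel_tier`` — annotation only: membership in a phenotype gene panel
   assigns a tier but never discards a variant, so that genes with no prior
   phenotype association are retained for discovery.

Every variant receives a :class:`FilterDecision` recording the outcome of
each stage; :class:`FunnelReport` aggregates survivor counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigError, UsageError
from .types import (
    PROTEIN_ALTERING,
    AnnotatedVariant,
    AnnotationPanel,
    Consequence,
)

STAGES: tuple[str, ...] = ("consequence", "rarity", "class_gate", "panel_tier")

_LOF_CLASSES = frozenset(
    {
        Consequence.stop_gained,
        Consequence.stop_lost,
        Consequence.start_gained,
        Consequence.start_lost,
    }
)


@dataclass
class CascadeConfig:
    """Tunable thresholds of the cascade.

    ``maf_threshold`` uses a strict inequality (a frequency of exactly the
    threshold fails).  ``consensus_min`` of ``consensus_total`` predictor
    verdicts must be pathogenic for missense variants; missing verdicts
    count toward the denominator, never the numerator.
    """

    maf_threshold: float = 0.01
    consensus_min: int = 6
    consensus_total: int = 11
    cadd_min: float = 20.0
    splice_min: float = 0.5
    panel_genes: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ConfigError("maf_threshold must lie in (0, 1]")
        if not (0 <= self.consensus_min):
            raise ConfigError("consensus_min must be nonnegative")
        if self.consensus_total < 0:
            raise ConfigError("consensus_total must be nonnegative")


class StageResult(str, enum.Enum):
    passed = "pass"
    failed = "fail"
    not_applicable = "not_applicable"


@dataclass
class FilterDecision:
    """Per-variant trace of the cascade."""

    key: str
    family_id: str
    gene: str
    stages: dict[str, StageResult]
    final: bool
    reasons: list[str] = field(default_factory=list)
    tier: str = "other"
    support: Optional[int] = None


@dataclass
class FunnelReport:
    """Survivor counts along the cascade plus the full decision trace."""

    input_count: int
    survivors: dict[str, int]
    by_family: dict[str, dict[str, int]]
    decisions: list[FilterDecision]

    def __post_init__(self) -> None:
        counts = [self.input_count] + [self.survivors[s] for s in STAGES]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise UsageError("funnel survivor counts must be non-increasing")

    @property
    def final_survivors(self) -> list[FilterDecision]:
        return [d for d in self.decisions if d.final]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.decisions:
            row = {
                "family_id": d.family_id,
                "key": d.key,
                "gene": d.gene,
                **{f"stage_{s}": d.stages[s].value for s in STAGES},
                "final": d.final,
                "tier": d.tier,
                "support": "." if d.support is None else d.support,
                "reasons": "; ".join(d.reasons),
            }
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual stage predicates


def consequence_filter(v: AnnotatedVariant) -> bool:
    """Protein-altering consequence classes pass."""
    return v.consequence in PROTEIN_ALTERING


def rarity_filter(panel: AnnotationPanel, cfg: CascadeConfig) -> bool:
    """Max observed MAF strictly below the threshold; all-missing passes."""
    mafs = panel.present_mafs
    if not mafs:
        return True
    return max(mafs) < cfg.maf_threshold


def consensus_vote(
    panel: AnnotationPanel,
    cfg: CascadeConfig,
    consequence: Consequence = Consequence.missense,
) -> tuple[bool, int]:
    """Majority vote over the 11-tool predictor panel (missense only).

    Returns ``(passed, support_count)``.
    """
    if consequence is not Consequence.missense:
        raise UsageError(f"consensus vote applies to missense, not {consequence.value}")
    support = panel.pathogenic_votes
    return support >= cfg.consensus_min, support


def lof_gate(
    panel: AnnotationPanel,
    cfg: CascadeConfig,
    consequence: Consequence = Consequence.stop_gained,
) -> bool:
    """CADD gate for stop/start gain-loss variants; missing score fails."""
    if consequence not in _LOF_CLASSES:
        raise UsageError(f"CADD gate applies to stop/start classes, not {consequence.value}")
    return panel.cadd_phred is not None and panel.cadd_phred >= cfg.cadd_min


def splice_gate(
    panel: AnnotationPanel,
    cfg: CascadeConfig,
    consequence: Consequence = Consequence.splice_region,
) -> bool:
    """Splice-delta gate for splice-region variants; missing score fails."""
    if consequence is not Consequence.splice_region:
        raise UsageError(f"splice gate applies to splice_region, not {consequence.value}")
    return panel.splice_delta is not None and panel.splice_delta >= cfg.splice_min


# ---------------------------------------------------------------------------
# the cascade


def _decide(v: AnnotatedVariant, cfg: CascadeConfig) -> FilterDecision:
    stages: dict[str, StageResult] = {}
    reasons: list[str] = []
    support: Optional[int] = None
    alive = True

    if consequence_filter(v):
        stages["consequence"] = StageResult.passed
    else:
        stages["consequence"] = StageResult.failed
        reasons.append(f"consequence {v.consequence.value} is not protein-altering")
        alive = False

    if alive:
        if rarity_filter(v.panel, cfg):
            stages["rarity"] = StageResult.passed
        else:
            stages["rarity"] = StageResult.failed
            reasons.append(
                f"max MAF {max(v.panel.present_mafs):g} >= {cfg.maf_threshold:g}"
            )
            alive = False
    else:
        stages["rarity"] = StageResult.not_applicable

    if alive:
        if v.consequence is Consequence.missense:
            ok, support = consensus_vote(v.panel, cfg, v.consequence)
            stages["class_gate"] = StageResult.passed if ok else StageResult.failed
            if not ok:
                reasons.append(
                    f"consensus {support}/{cfg.consensus_total} below {cfg.consensus_min}"
                )
            alive = ok
        elif v.consequence in _LOF_CLASSES:
            ok = lof_gate(v.panel, cfg, v.consequence)
            stages["class_gate"] = StageResult.passed if ok else StageResult.failed
            if not ok:
                reasons.append(f"CADD {v.panel.cadd_phred} below {cfg.cadd_min:g} (or missing)")
            alive = ok
        elif v.consequence is Consequence.splice_region:
            ok = splice_gate(v.panel, cfg, v.consequence)
            stages["class_gate"] = StageResult.passed if ok else StageResult.failed
            if not ok:
                reasons.append(
                    f"splice delta {v.panel.splice_delta} below {cfg.splice_min:g} (or missing)"
                )
            alive = ok
        else:  # frameshift: no score-based gate applies
            stages["class_gate"] = StageResult.not_applicable
    else:
        stages["class_gate"] = StageResult.not_applicable

    tier = "other"
    if alive and cfg.panel_genes is not None:
        tier = "known_phenotype_gene" if v.gene in cfg.panel_genes else "other"
    stages["panel_tier"] = StageResult.passed if alive else StageResult.not_applicable

    return FilterDecision(
        key=v.key,
        family_id=v.family_id,
        gene=v.gene,
        stages=stages,
        final=alive,
        reasons=reasons,
        tier=tier,
        support=support,
    )


def run_cascade(
    variants: Iterable[AnnotatedVariant], cfg: Optional[CascadeConfig] = None
) -> FunnelReport:
    """Apply all stages to every variant and assemble the funnel report."""
    cfg = cfg or CascadeConfig()
    decisions = [_decide(v, cfg) for v in variants]

    def count_after(stage: str, subset: Iterable[FilterDecision]) -> int:
        idx = STAGES.index(stage)
        n = 0
        for d in subset:
            if all(d.stages[s] is not StageResult.failed for s in STAGES[: idx + 1]):
                n += 1
        return n

    survivors = {s: count_after(s, decisions) for s in STAGES}
    by_family: dict[str, dict[str, int]] = {}
    for fid in sorted({d.family_id for d in decisions}):
        fd = [d for d in decisions if d.family_id == fid]
        by_family[fid] = {s: count_after(s, fd) for s in STAGES}
        by_family[fid]["input"] = len(fd)
    return FunnelReport(
        input_count=len(decisions),
        survivors=survivors,
        by_family=by_family,
        decisions=decisions,
    )
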