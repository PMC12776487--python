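# Methods

## The problem and the pipeline's model of it

Small family-based exome studies of severe congenital phenotypes work from
a handful of case-parent trios and dyads. With no power for association,
causality is argued variant by variant: a candidate must be plausibly
damaging, rare in reference populations, and segregate compatibly with a
Mendelian model — ideally de novo in a simplex family, or co-segregating
with the phenotype in a multiplex one. trioprio encodes that argument as a
deterministic, fully traced pipeline over pre-annotated variants. It never
calls or annotates variants itself: VCFs are assumed normalized (split
multiallelics, left-aligned indels) and annotations — consequence class,
per-database MAFs, eleven pre-binarized in-silico pathogenicity verdicts,
CADD phred, SpliceAI delta — arrive in a sidecar table. The per-tool score
cutoffs used to binarize the predictors are upstream policy; this package
deliberately consumes verdicts, not raw scores.

## Filter cascade

Stages run in a fixed order; a variant's trace records pass / fail /
not-applicable per stage, and survivor counts are non-increasing by
construction.

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | rarity bound, strict (`MAF == 0.01` fails) |
| `consensus_min` / `consensus_total` | 6 / 11 | missense consensus vote |
| `cadd_min` | 20 (phred) | gate for stop/start gain-loss |
| `splice_min` | 0.5 (delta) | gate for splice-region variants |
| `panel_genes` | none | phenotype panel; tiering only |

Decisions made where the procedure was genuinely open:

* **MAF aggregation** across the three databases is the maximum over
  sources with an observed value — the most conservative rarity test. A
  variant absent from every database ("novel") passes: absence of a
  frequency observation is not evidence of commonness, and missing is kept
  representationally distinct from an observed 0.
* **Missing predictor verdicts** count toward the 11-tool denominator but
  never the numerator, since the consensus rule is defined against the
  fixed panel.
* **CADD ≥ 20 and SpliceAI delta ≥ 0.5** are the conventional community
  cutoffs for their respective tools; both are config-exposed because the
  source protocol names the tools without printing numeric thresholds.
* **Frameshifts bypass the class gate** — none of the score-based
  predictors applies to them; their case rests on consequence plus rarity.
* **Panel membership never excludes.** Discovery cohorts retain genes with
  no prior phenotype annotation; the panel stage only labels tiers.
* Rarity is applied to every class, including splice-region variants,
  before the class gate.

## Inheritance classification

The decision table is in `trioprio.inheritance` (module docstring). The
choices worth defending:

* **De novo requires positive evidence**: both parents present with
  non-missing hom-ref calls. Any absent parent or missing parental call
  demotes to `unknown_missing_parent` unless the present parent's genotype
  forces a conclusion (a carrier parent still supports the dominant
  sub-modes; a hom-ref single parent of a hom-alt proband forces a
  Mendelian inconsistency).
* **Homozygous proband with two hom-ref parents** is flagged
  (`de_novo_homozygous_flagged`) rather than silently called de novo: two
  independent de novo hits at one site are implausible, and the pattern
  more often reflects a hemizygous deletion or genotyping artefact. The
  pipeline preserves the call and annotates the doubt.
* **Penetrance semantics**: a carrier parent who is unaffected yields
  `ad_incomplete_penetrance`; an affected carrier parent yields
  `ad_inherited_affected_parent`. Variable expressivity is not modelled
  beyond the binary affected flag — phenotype granularity is out of scope.
* **Compound heterozygotes** are paired per gene from proband-het variants,
  trans by parental origin (one maternal-only, one paternal-only). With a
  parent unavailable, candidate pairs are emitted with a phase-unknown
  note, never asserted.
* **X chromosome**: an XY proband cannot be het (inconsistent); hemizygous
  with a carrier mother is `x_linked`; XX probands follow the autosomal
  table.
* `max_parent_miscalls` (default 0) optionally tolerates one parental
  conflict as possible genotyping error, demoting would-be inconsistencies
  to `unclassified` instead.

## Hub ranking

The interaction graph keeps every queried gene as a node regardless of
degree (node counts are reported quantities and sparse discovery lists are
mostly isolated). Edges with confidence ≥ threshold are retained;
the 0–1000 integer dialect of exported edge lists is rescaled to [0, 1] at
read time, and thresholds are always expressed on [0, 1]. Maximal cliques
come from pivoting Bron–Kerbosch (networkx); MCC(v) sums (|C| − 1)! over
maximal cliques containing v, so an isolated node scores 0! = 1 (the
standard CytoHubba convention). Ranking ties break by degree, then symbol,
making the ordering deterministic; k is an explicit parameter because
"top hubs" has no canonical size.

## Over-representation analysis

One-sided upper-tail hypergeometric probability P(X ≥ k) for overlap k
between an n-gene query and a K-gene set in an N-gene universe; this equals
Fisher's exact one-sided test on the 2×2 overlap table (asserted to 1e-12
in the tests). The universe defaults to the union of all GMT members and
can be overridden. Only sets with k ≥ 1 are tested — zero-overlap rows
carry no evidence of over-representation and inflate the correction burden.
Correction is Benjamini–Hochberg; web-service-specific corrections (and
therefore any published adjusted p-values computed with them) are not
reproduction targets.

**Calibration and discreteness.** The hypergeometric test is discrete and
hence conservative: at nominal α = 0.05 the attainable level — the exact
probability under the null that p < 0.05 — is typically 0.025–0.043 for
realistic set sizes. A null simulation therefore cannot, and should not,
produce a 5% rejection rate; the calibration test checks that the
empirical type-I rate matches the exact attainable level within binomial
error and never exceeds the nominal level beyond sampling slack.

## Synthetic cohorts

The generator emulates an annotated family-cohort dataset, not sequencing:
no reads, no base errors, no linkage structure.

* Defaults mirror the worked example's study shape: 9 families,
  dyad fraction 2/9, one planted de novo per family.
* Background MAFs: point mass "novel" with weight 0.2, otherwise
  log-uniform on [1e-5, 0.5]; the same value is written to all three
  database columns, so the fraction passing the rarity filter has the
  closed form w0 + (1 − w0)·ln(0.01/10⁻⁵)/ln(0.5/10⁻⁵), which the tests
  check within Monte-Carlo error.
* Verdicts are simulated directly as vote counts (background binomial with
  p = 0.15, concentrated below the consensus threshold; planted variants
  uniform on {6..11}), with the voting tools drawn without replacement —
  the pipeline consumes binarized verdicts, so simulating per-tool raw
  scores would add unverifiable structure.
* Founder genotypes are Hardy–Weinberg draws (with an optional inbreeding
  coefficient, default F = 0.0625 for a configurable fraction of families,
  emulating consanguinity as elevated background homozygosity only);
  probands receive one transmitted allele per parent, so non-planted trio
  genotypes are Mendelian-consistent by construction at zero error.
* Dyads are produced by dropping the father after planting: the truth table
  keeps the planted mode and additionally records the *expected* pipeline
  call (e.g. a planted de novo in a dyad is expected to be demoted to
  `unknown_missing_parent`; matching the demotion scores as correct).
* Genotyping noise flips each written call to one of the other two states
  with the configured probability, after planting; truth is untouched.

What passing recovery tests shows — and does not: perfect recovery at zero
error demonstrates the classifier and cascade are exact on clean,
well-formed input with the simulated annotation structure. It says nothing
about caller artefacts, segmental duplications, population-specific
frequency gaps, or annotation disagreements in real exomes, none of which
the generator models.

## Problem sizes and numerics

The test suite exercises: the full 2 × 5 × 5 × 2 × 2 genotype/presence/
affection enumeration against an independently written decision-table
oracle; 200 random graphs of ≤ 10 nodes against exhaustive subset
enumeration for cliques and MCC; recovery on 50-family cohorts (15 variants
per family at zero error; 20 replicates of 12 variants per family at 1%
genotyping error, against an exact error-model prediction obtained by
composing the corruption kernel with the classifier); and 2000-replicate
ORA null calibration on a 2000-gene universe with 100-gene queries. These
sizes give stable Monte-Carlo comparisons (4-standard-error bands) while
keeping the whole suite in seconds.

Numerical conventions: coordinates are 1-based VCF-style; frequencies and
splice deltas live in [0, 1] and are validated on construction; rarity and
gate comparisons use strict `<` only where the defining rule is strict
("MAF < 0.01"), and `>=` for the score gates; BH values are capped at 1;
enrichment rows sort by (adjusted p, raw p, set id) for determinism. All
simulator randomness flows from a single integer seed through one
generator; identical configs produce byte-identical output files.

## Known limitations

* Inheritance classification is genotype-only; it uses no read-level
  evidence, no joint-likelihood de novo model, and detects neither
  mosaicism nor phasing beyond parental origin.
* The ACMG evidence framework is not formalized — the cascade approximates
  its screening spirit (consequence, rarity, in-silico support), not its
  evidence codes.
* The packaged interaction edge list and gene sets are synthetic stand-ins
  shaped to published count-level numbers; they support worked examples and
  tests, not biological inference.
* Enrichment results depend strongly on the gene-set source and universe;
  adjusted p-values are comparable only within one collection and
  correction method.
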