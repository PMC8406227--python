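# Methods

## Problem setting

Low-biomass subsurface samples (drill cores of serpentinized rock and
sediment, 10¹–10⁴ cells cm⁻³) yield 16S rRNA amplicon libraries in which
laboratory reagents, drilling fluid and entrained seawater contribute a large
— sometimes dominant — share of reads. The pipeline codifies the screening
decision procedure for such data: classify each ASV's origin, remove suspect
reads, and report what remains alongside independent contamination indicators
(the perfluorocarbon drilling tracer) and the success rate of the screening
workflow itself. A second, independent component scores the metabolic
potential of partial genomes (MAGs/SAGs) by KO pathway completeness.

## Sequence identity

"99% similar" is underdetermined without fixing the alignment and the
denominator; our definition is:

- **Alignment**: global (Needleman–Wunsch) with free end gaps, scored
  match +1, mismatch −1, gap −2 (linear), computed by Biopython's
  `PairwiseAligner` with a substitution matrix in which only A/C/G/T
  self-matches are matches — any column involving an IUPAC ambiguity code is
  a mismatch. Free end gaps suit amplicons from a single primer set, which
  are near-equal length.
- **Identity**: matches divided by alignment columns between the first and
  last aligned pair, with the denominator floored at the **longer** sequence
  length. The floor is essential: the score-optimal free-end-gap alignment of
  two *unrelated* sequences is often a short perfect overlap, and without the
  floor "matches / non-terminal columns" returns values up to 1.0 for random
  pairs. Flooring at the longer length preserves every near-equal-length case
  (one substitution in 370 nt scores 369/370 ≈ 0.9973) while a 30-nt exact
  fragment of a 370-mer scores 30/370 ≈ 0.081 rather than 1.0.
- **Symmetry** is guaranteed by canonically ordering the two sequences before
  aligning; co-optimal alignments could otherwise give order-dependent match
  counts at equal score.
- With `end_gaps_free=False`, terminal gaps are penalized like internal ones
  and counted in the denominator. The threshold (default 0.99), the scoring
  and the end-gap treatment are all parameters of `IdentityParams`.

A shared-k-mer prescreen (k = 8, one shared word) skips pairs that cannot
plausibly reach the threshold. It is an optimization only: the test suite
asserts set equality of matches with and without it on 200-sequence sets. At
amplicon lengths the prescreen is deliberately permissive (random 370-mers
share ~2 words of length 8 in expectation); correctness never depends on it.

## The origin classifier

Evidence per ASV: the best control match at or above threshold (ties broken
NTC > drilling fluid > seawater, then lexicographic id — reagent controls are
the strongest contamination evidence), whitelist cover (exact sequence,
identity threshold, or bare-id membership), and an environment class derived
from the best database hit's description by case-insensitive keyword search
(contaminant keywords win when both classes match — discard on doubt; the
keyword lists replace the manual adjudication a human screener performs and
are fully configurable).

Cascade: R1 — control match, not whitelisted → contaminant. R2 — control
match, whitelisted → environment decides (subsurface-like → possibly
subsurface; contaminant-like → likely contaminant; otherwise the configurable
`unknown_env_policy_matched`, default likely contaminant). R3 — no control
match → contaminant-like environment → likely contaminant; subsurface-like
environment *or* whitelist cover → subsurface; otherwise
`unknown_env_policy_unmatched`, default possibly subsurface. Whitelist cover
can therefore never produce a hard contaminant call, and reading
likely-indigenous status as affirmative evidence in R3 is a deliberate
design choice (the conservative alternative is selectable via the policies).

The optional abundance gate (`abundance_gate_reads`, default off) reproduces
workflows in which only abundant taxa (e.g. > 5,000 reads) received a
database search: below the gate, environment evidence is ignored and the
ambiguous/absent branch fires. It is off by default because restricting
database evidence to abundant taxa is a labor constraint, not a statistical
principle.

Filtering removes *contaminant* and *likely contaminant* rows, reports the
per-sample removed-read fraction and flags samples left with zero reads.

## Summaries

- Category profiles are **reads-weighted** (the natural weighting for
  relative-abundance figures; ASV-count weighting would be an alternative).
  Zero-read samples are flagged, never divided.
- Family composition collapses families below 0.1% relative abundance in
  every sample into "other family"; unresolved ranks fall back to the deepest
  resolved rank as "(p) Phylum" / "(c) Class" / "(o) Order", and ASVs with no
  taxonomy at all go to "unknown bacteria" with a warning.
- The tracer comparison uses the Spearman rank correlation between the
  per-sample indigenous fraction (subsurface + possibly subsurface) and the
  interior tracer concentration. The p-value is a two-sided **exact
  permutation** value for n ≤ 10 (full enumeration, vectorized in chunks;
  10! ≈ 3.6 M pairings), asymptotic beyond. Sentinel tracer values (below
  detection, not determined) are excluded by default and counted in the
  report; substituting zero for below-detection values is available but
  conflates "not detected" with "absent". Fewer than 3 usable pairs yields an
  insufficient-data report rather than a correlation. Reported ranges
  contribute their midpoint.
- Screening accounting: "cells detected" is any sample whose PCR status is
  not the no-cells sentinel; sequenced ⊆ PCR-positive ⊆ cells-detected ⊆
  screened holds on every valid input. The sediment/crust split uses a
  substring heuristic (lithology containing "sand" → sediment) because
  lithology is free text; an override map is the escape hatch. Efficiency is
  reported at full precision with a half-up-rounded display twin.
- Sentinel measurements (BDL, BMQL, ADL, n.d., n.a., n.c.) parse to typed
  values that refuse arithmetic — they can never silently become zeros.

## Functional profiling

Pathway completeness is |defining KOs present| / |defining KOs|;
presence/absence by definition, so the score lattice is exactly
{k/|defining| : 0 ≤ k ≤ |defining|}. Marker matrices sum copy numbers over
each marker's KO list. The packaged definitions (18 pathways, 22 markers)
follow the widely used KEGG-Decoder-style KO sets for carbon fixation
(CBB, rTCA, Wood–Ljungdahl), heterotrophy (TCA, glycolysis, glyoxylate
shunt), denitrification steps, sulfate reduction, aerobic CO oxidation,
hydrogenases and terminal oxidases. They are data, not code: any KO-set
curation disagreement is resolved by editing the TSV, and the
Wood–Ljungdahl set carries 12 KOs so that "nearly complete, missing two
enzymes" is exactly 10/12.

## The synthetic generator

The generator emulates the *structure* of a low-biomass screening dataset,
not its biology: uniform random DNA (370 nt, V4V5-like) with rejection
sampling to keep indigenous ASVs below a 97% identity ceiling against each
other and every control; contaminant ASVs copied verbatim into the controls;
an NTC whose 147 entries are dominated by two contaminant taxa (110 + 21),
mirroring the reagent-control structure seen in real surveys; a 14-entry
drilling-fluid set and 30-entry seawater set; a whitelist covering half the
indigenous pool (optionally with decoys overlapping the contaminant pool);
per-sample multinomial read counts with the planted contaminant fraction
split uniformly over contaminants and the remainder log-normal (σ = 1.0)
over indigenous ASVs; and a tracer spanning 1–10⁵ log-linearly in the
planted fraction (the dynamic range of real tracer data) with optional
multiplicative noise. Default study conditions: 20 indigenous + 10
contaminant ASVs, 8 samples, 50,000 reads each, planted fractions linearly
spanning 0 to 1.

Before writing truth the generator **certifies** the separable regime by
exhaustive pairwise identity (and errors out if the constraints are
infeasible, e.g. more sequences than the length can separate). Passing
recovery tests therefore demonstrate correctness of the decision procedure
under clean evidence — they do not demonstrate robustness to what the
generator omits: chimeras, sequencing error, amplification bias from
whole-genome amplification, index hopping, phylogenetic correlation between
contaminant and indigenous taxa, or controls that only partially sample the
true contaminant pool. Near-threshold behavior can be probed with variant
contaminants placed an exact substitution count away from their control
copies (3 substitutions in 370 nt ≈ 0.9919, just above the default
threshold).

Genome construction inverts the completeness definition: a target k/|defining|
is realized by including the lexicographically first k defining KOs, and the
result is re-scored — any deviation (overlapping definitions, marker/pathway
KO collisions) is a hard error, so planted truth is exact, never approximate.

## Determinism and numerics

One seed governs a dataset; a fresh generator per stage is derived from it
(seed, stage-offset), so stages are independently reproducible.
Classification is order-deterministic: output order is table row order, ties
are broken by fixed precedence and lexicographic ids, and identical inputs
give byte-identical outputs. Reported percentages are rounded half-up at
display time only; internal computation is full-precision. Output files are
written atomically (temp file + rename).

Problem sizes used in the shipped tests and the acceptance script — 20–30
ASVs per community, 20 seeds, 200-sequence all-pairs oracle sets at 120–150
nt — were chosen as the smallest sizes at which every property is
non-vacuous (matches exist, all cascade branches fire, multinomial error is
well below the ±0.01 tolerance at depth 50,000).

## Known limitations

- The classifier is a codified rule cascade, not a statistical model: it does
  not use prevalence/frequency information (decontam-style inference is an
  explicit non-goal) and inherits the whitelist's and controls' blind spots.
- Environment adjudication by keyword is only as good as the keyword lists;
  descriptions matching neither class fall to the configurable policies.
- The identity definition is one defensible reading of "percent similarity";
  the threshold's meaning shifts with the definition, which is why both are
  configurable and documented rather than hard-coded.
- Exact permutation p-values stop at n = 10; beyond that the asymptotic
  approximation is used and flagged in the report.
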