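# Methods

## The comparison model

`concord` treats "how well does a disease model recapitulate its donor
tumour?" as a family of set-agreement problems over somatic events, one per
level of genomic complexity. All statistics are symmetric in the two
samples, bounded in [0, 1], and undefined (reported `NA`) when neither
sample contributes any event to the comparison — absence of a mutation
class is deliberately not scored as discordance. Trios are decomposed into
the three ordered pairs (T vs X, T vs O, X vs O); every pair is scored
exactly as it would be standalone, so trio results are pure restrictions.

### Simple somatic mutations

A mutation's identity is the tuple (chromosome, position, ref, alt). This
is the strict reading of "same position and same substitution": indels
match only on their exact allele strings, and a SNV never matches an indel
at the same site. Annotation category and read depths are carried along
but excluded from identity. Within-sample duplicate keys collapse before
counting (Jaccard is a set statistic), and per category M:

    J_M = C_M / (T_M + P_M - C_M)

with an "All Mutations" row over the union of categories. Variant-allele
fractions (alt/(alt+ref) depth) are extracted for descriptive plots only;
no score consumes them. A driver-panel summary tallies mutation-type
labels per gene over a configurable panel of 1-based inclusive gene spans
(default: eight pancreatic-cancer drivers, hg19 coordinates).

### Structural variants

Events are breakpoint pairs in one of four categories (DEL, DUP, INV,
TRA), canonicalised so the same physical junction always produces the same
tuple. Matching demands equal category and equal breakpoints; a
`bp_tolerance` option (default 0) admits caller jitter, in which case
pairing is greedy in position order with each event matching at most once.

Two different weightings coexist by design:

- **Base sums** (for Jaccard): an intra-chromosomal event contributes the
  span between its breakpoints; a translocation contributes 1 base. In
  chromosome-scoped sums a translocation contributes its unit size to each
  of the two chromosomes involved (the attribution is not derivable from
  the counting rule alone; contributing to both sides is consistent in
  spirit with the 0.5/0.5 count rule and is the package's fixed choice).
  Genome-wide category sums count each translocation once.
- **Weighted event counts** (for flags): 1 per intra-chromosomal event,
  0.5 to each chromosome of a translocation. A chromosome is flagged
  *elevated* (clustered rearrangements, the pattern chromothripsis leaves)
  with ≥ 5 weighted events in both samples, and *count-discordant* with an
  absolute difference ≥ 10. Both thresholds, and the S^c cut of 0.6
  (inclusive), are configuration values.

S^c counts only chromosomes with a defined J (≥ 1 event in either sample).
No formal chromothripsis test is attempted; the flag is a count heuristic.

### Copy number

Inputs are per-segment average integer copy numbers (`imean`) plus one
ploidy scalar per sample. Values are rescaled as imean/ploidy *before* the
agreement test, so whole-genome doubling cancels exactly: multiplying one
sample's track and ploidy by k > 0 provably changes no score (checked to
1e-12 in tests). The two segmentations are intersected into maximal
constant-value blocks by a boundary sweep; bases covered by neither sample
are dropped, bases covered with no fitted value count as covered-but-
undefined. Agreement means both values defined and |Δ| ≤ 0.25 (inclusive,
applied after rescaling; both tolerance and ordering are configurable).

The score follows the formula literally: G = I/(T+X−C), where C is the
union of defined bases, making T+X−C the co-defined footprint — agreement
over bases where both samples report a value. Bases defined in one sample
only therefore dilute nothing, but are still reported (T, X, C) for
transparency; `denominator="union"` gives the conventional union-Jaccard
instead. Genome scores aggregate the per-chromosome numerators and
denominators, never the mean of per-chromosome scores. Sex chromosomes are
scored like autosomes. A ploidy QC flag compares the pair's ploidies:
within 10 % → `comparable`, within 10 % of a 2× ratio → `doubled`, else
`ambiguous`; analysis proceeds regardless, the flag is reporting only.

## Synthetic data: what it emulates, and what it does not

The generator produces matched tumour/PDX/PDO call sets over a 24-
chromosome genome with human-scale lengths. Its defaults are the package's
reference study conditions:

- **SSM**: exactly 700 shared, 300 tumour-only, 300 model-only distinct
  mutations (so the overall Jaccard is 700/1300 by construction), drawn
  over 12 annotation categories with genome-realistic weights (intergenic
  and intronic calls dominate; the `Frame_Shift_Del` category receives
  true indel alleles). The category list itself is a package choice: the
  figure-style vocabulary such cohorts report is not fixed anywhere, so a
  standard Oncotator-like set of 12 labels is used. A hypermutator flag
  scales the load ×10 with the same structure, mimicking mismatch-repair
  deficiency (many mutations, unchanged SV/CN complexity).
- **SV**: per-chromosome shared/private intra-chromosomal events with a
  DEL-heavy category mix; `clustered` chromosomes confine all their events
  to one 5 Mb window, guaranteeing the elevated flag when ≥ 5 events are
  shared. Translocations are planned genome-wide (a breakpoint pair spans
  two chromosomes, so a per-chromosome plan cannot own one) and join
  random chromosome pairs.
- **CN**: one random segmentation template (8 segments/chromosome,
  breakpoints on a 10 kb grid) shared by both samples; integer-like states
  1–4 weighted toward diploid. The model's rescaled values equal the
  tumour's on concordant segments (plus jitter clipped to tolerance/2;
  a jitter SD above tolerance/4 is rejected as incompatible with the
  guarantee) and sit exactly 2× tolerance away on the designated
  discordant fraction (default 30 %). Ploidies are set so rescaling
  cancels the configured factor (default 2, emulating a genome-doubled
  xenograft).
- **Trio**: the organoid is derived by perturbing the *xenograft* (drop
  10 % of its mutations and 15 % of its SVs, add fresh privates, re-draw
  10 % of CN segments), matching how organoids are established from PDX
  tissue; X vs O concordance therefore exceeds T vs O by construction.

Every bundle carries a truth record computed at generation time by
straight-line set/sum arithmetic that never calls the scoring modules, so
recovering it is a genuine oracle test. The generator does **not** emulate
read-level evidence, caller-specific breakpoint jitter or false calls,
subclonal structure, mutational signatures, or allele-specific copy
number; passing tests demonstrate correctness of the concordance
arithmetic on well-formed call sets, not robustness to upstream calling
noise.

## Numerical and I/O choices

- Coordinates: VCF positions are 1-based, BEDPE and segment tables 0-based
  half-open; conversion happens only in readers/writers.
- Multi-allelic VCF records split into one call per ALT, each inheriting
  its own allele depth; non-PASS records are dropped by default
  (configurable — upstream pipelines normally pre-filter, but the choice
  is surfaced rather than assumed). Missing annotation keys degrade to an
  `Unannotated` category with a warning; a missing ploidy is a hard error
  because rescaling is impossible without it.
- Overlapping segments within one sample are an input defect, resolved
  deterministically by truncating the earlier segment at the later one's
  start (logged), never averaged.
- SV category labels accept common caller dialect synonyms
  case-insensitively ("deletion" → DEL, "ctx" → TRA, ...).
- All thresholds (0.6, 0.25, 5, 10, tolerances, PASS-only, SNV-only) live
  in one `Config` object whose resolved values are embedded in every
  report's provenance block; reruns on the same inputs are byte-identical.
- Scores are ratios of exact integer (or half-integer) accumulations, so
  oracle comparisons in the tests assert exact float equality; the only
  approximate comparison is synthetic CN recovery after values round-trip
  through text at 6 decimals, tested to within one block-length granule.

## Problem sizes

The default trio (≈ 2600 mutations, ≈ 20 SVs, 192 CN segments per sample)
simulates, writes, and scores end to end in a few seconds; the
oracle-equivalence suites use hundreds of small random instances (≤ 100
calls, ≤ 30 events, 10 kb toy genomes for the per-base scans), sized so
the full test suite stays interactive while still exercising every rule
(TRA weighting, tolerance boundaries, NA propagation) many times over.

## Known limitations

- Breakpoint matching with a positive tolerance is greedy, not optimal
  bipartite matching; with caller jitter larger than typical event spacing
  it can under-match.
- The "rescued variant" manual-review step real pipelines apply upstream
  is out of scope: inputs are taken as final call sets.
- No liftover or reference handling beyond chromosome names; both samples
  must be called on the same build.
- CN concordance compares total copy states only; balanced allele-specific
  changes are invisible.
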