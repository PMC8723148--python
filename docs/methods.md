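# Methods

This note records the models, conventions and numerical choices behind
`svtab`, the defaults that matter, and what the synthetic-data generators
do and do not emulate.

## Data model and coordinate conventions

All SV calls live in an `SVContainer`: a positions table (one row per
record: id, both breakends' chromosome/position/strand, quality, type),
a long-form filters table, one long-form (id, value_index, value) table
per INFO key, and a long-form FORMAT table. Multi-valued VCF entries are
never packed into one cell; `value_index` keeps their order.

Coordinates are 1-based VCF-style everywhere inside the package;
conversion to 0-based half-open happens only when reading/writing BED and
BEDPE. Breakend strand encodes which side survives in the derivative
chromosome: `+` means the segment to the *left* of the position is
retained (position = last retained base), `-` the segment to the right
(position = first retained base). This gives DEL = +/−, DUP = −/+, INV =
++ or −−, matching BEDPE community convention. Intrachromosomal records
are canonically ordered pos1 ≤ pos2 (swapping breakends together with
their strands); interchromosomal records by natural chromosome order, so
"the same event" is comparable across callers. `svlen` is defined only
for intrachromosomal records and equals pos2 − pos1 for DEL/DUP/INV.

## Caller normalization

Orientation fields are mapped as: Delly `CT` 3to5→(+,−), 5to3→(−,+),
3to3→(+,+), 5to5→(−,−); Lumpy `STRANDS` parsed from its leading `±±`;
Manta inversions via `INV3`→(+,+) / `INV5`→(−,−); bracket-notation
breakends by the VCF grammar (`t[p[`→(+,−), `t]p]`→(+,+), `]p]t`→(−,+),
`[p[t`→(−,−)), with any ALT bases beyond the REF allele kept as the
junction-inserted sequence (`insseq`). BND mate pairs collapse to the
mate with the smaller (chromosome, position); Gridss intrachromosomal
pairs are re-typed DEL/DUP/INV from their strand combination so that the
same event normalizes identically regardless of the caller, while
interchromosomal junctions stay BND. Unpartnered single breakends are
retained with an absent second breakend and excluded from merging and
classification. Missing CIPOS/CIEND become the degenerate interval
(0, 0). All original INFO keys are preserved as long-form tables.

`write_vcf` emits a caller-neutral dialect (SVTYPE/END/SVLEN/CIPOS/CIEND
plus a two-character `STRANDS` key, BND as MATEID-linked mate pairs) that
`read_vcf(..., caller="generic")` reads back losslessly; `generic` is a
fifth caller label added for exactly this round trip.

BEDPE reading takes the 1-based breakpoint as the interval *end* (a point
breakend is the conventional `[pos−1, pos)`); wider intervals become the
confidence interval unless explicit `cipos`/`ciend` columns are present,
which `write_bedpe` always emits (together with svtype/svlen/filter and
all other INFO keys as named trailing columns) to make the BEDPE round
trip lossless. A `.` strand is accepted and defaulted (`+` on side 1,
`-` on side 2).

## Annotation

BED intervals are indexed in per-chromosome interval trees (O(log n + k)
point queries). A 1-based position p overlaps a BED interval [s, e) iff
s < p ≤ e — i.e. exactly when the 0-based base p−1 is inside. The query
locus is the breakend point, not its confidence interval; each record
gets two annotations (suffix 1/2, one per breakend), preserving per-
breakend information that classification rules may OR together.

## Filtering

Conditions are `"item op value"` strings over svtype/svlen/qual/filter or
any INFO key, with ops `== != < <= > >= in not-in`, combined as a
conjunction; disjunction is the id-union of two filtered results
(`union`). Multi-valued INFO follows VCF semantics: a comparison holds if
any value satisfies it; a record with no value for the key fails positive
and passes negative comparisons. The grammar is deliberately minimal (no
parenthesized groups) to stay testable.

## Multi-caller merging

Two records link iff (i) coordinates agree under the chosen criterion —
proximity: |Δpos1| ≤ t and |Δpos2| ≤ t; confidence-interval: the CIPOS
intervals around pos1 share ≥1 bp and likewise around pos2 (both ends
required, the stricter symmetric choice); (ii) both breakends' strands
are equal, which under the normalization above also enforces type
compatibility; (iii) intrachromosomal spans [pos1, pos2] overlap ≥1 bp —
insertions span [pos1, pos1 + max(svlen, 1)], and the condition is waived
for interchromosomal pairs whose span is undefined. Events are transitive
closures of the link relation (union–find; a chain can span more than one
threshold — documented behavior of clustering-style merging). Candidate
pairs come from an interval tree over pos1 windows within (chromosome
pair, strand pair) groups; the test suite checks the whole procedure
against a brute-force all-pairs + connected-components oracle. The
representative record of each event is taken verbatim (no coordinate
averaging) from the first caller in input order that supports it;
membership is order-independent.

## Microhomology

Junction-spanning (two-way) extension, the standard microhomology
definition. In the canonical deletion frame (strands +/−): forward
f = max h with ref[p1+1..p1+h] = ref[p2+1..p2+h]; backward b = max
h ≤ max_len − f with ref[p1−h+1..p1] = ref[p2−h+1..p2]; hom_len = f + b,
hom_seq = ref[p1−b+1..p1+f]. A breakend whose strand differs from the
canonical one for its slot has its flanks reverse-complemented and its
forward/backward roles swapped, which makes an inversion junction and its
strand-flipped mirror give identical lengths (property-tested).
Comparison is case-insensitive, `N` never matches, windows truncate at
chromosome ends (not an error), and intrachromosomal results are capped
at the SV length — a deletion cannot show more homology than it removes
(forward extension keeps priority when the cap binds). Default search
window: 200 bp, comfortably above reported microhomology lengths at
rearrangement junctions. A non-empty junction insertion forces hom_len 0
(a novel templated insert interrupts homology); caller-provided
HOMLEN/HOMSEQ are left untouched under their original keys, with the
inferred values in `homlen`/`homseq`.

## Classification and feature matrices

Rules are evaluated first-match-wins; every record gets exactly one
class, the fallback catching the rest, so classes always partition the
records (row sums of the feature matrix equal record counts). Predicates
are disjunctions of condition conjunctions; definitions may carry
idempotent "preparer" callables that add required INFO (annotation,
derived keys) before evaluation.

`simple` (16 classes): DEL/DUP/INV × {<1 kb, 1–10 kb, 10–100 kb,
100 kb–1 Mb, >1 Mb} with `translocation` as the fallback. Making
translocation the fallback rather than an explicit BND rule keeps the
scheme at 16 columns while covering every record; the one distortion is
that insertions (no intrachromosomal length) also land there.

`pcawg_like` (25 classes): fragile-site SVs first (either breakend in a
CFS), then DEL/DUP/INV × {early, late} replication timing × {<50 kb,
50–500 kb, >500 kb}, then DEL/DUP/INV with unknown timing, translocation,
insertion, and `others`. The 50 kb / 500 kb breakpoints are the
length boundaries conventionally used for small vs medium tandem
duplications. Timing is classed by breakend 1's annotation; a breakend
with no timing zone or overlapping both kinds is `unknown` — this
tie-breaking cannot be expressed in the ANY-value condition grammar, so
the definition's preparer derives a single-valued `timingclass1` key.

## Signature extraction

The samples × classes matrix M is factorized as Mᵀ ≈ S·E (sklearn NMF,
Frobenius objective, multiplicative updates, random non-negative
initialization, 500 iterations). Per candidate rank k, `n_iter` restarts
each run on an independent Poisson-resampled copy of the counts; the
k·n_iter L1-normalized signature vectors are pooled and clustered by
cosine-distance k-medoids (seeded PAM, 5 restarts), and stability(k) is
the mean silhouette width, with singleton or identical clusters scoring 1
(perfectly stable, not undefined — sklearn's silhouette returns 0 there,
which is why it is computed in-package). Consensus signatures are
L1-normalized cluster means; exposures are per-sample non-negative least
squares of the original, un-resampled matrix.

Rank selection maximizes stability **minus** the mean relative Frobenius
reconstruction error (ties to the smaller k). Stability alone is not
discriminative: every rank at or below the truth tends to be near-
perfectly stable, because an under-complete factorization reproduces the
same merged signatures across restarts, so argmax-stability degenerates
to the smallest scanned rank. The combined score penalizes the large
residual of under-complete fits and the instability of over-complete
ones, and on planted-truth simulations selects the generating rank with a
wide margin. The full per-k table is always reported so the user can
override the choice.

Association testing is a two-sided Mann–Whitney rank-sum per signature
between carrier and non-carrier exposures with Benjamini–Hochberg
correction across signatures; with one sample per group the exact null
distribution is used (scipy's automatic method choice).

## Synthetic data: what it emulates, and what not

`simulate_caller_vcfs` reproduces the multi-caller merge study design:
truth events (DEL/DUP/INV/translocation cycle, spans 5–20 kb, spaced
50 kb apart so distinct events can never co-cluster) are emitted by all
four callers in their native dialects with per-caller positional offsets
drawn from [−jitter/2, +jitter/2] — so any two callers' positions for the
same event differ by at most `jitter` — and CIPOS/CIEND of ±jitter, which
guarantees pairwise CI overlap of shared breakends. Each caller adds 20%
private events in caller-specific regions, giving support-based filtering
something to remove. A truth table maps every emitted record (both BND
mates included) to its truth event.

`simulate_signature_matrix` draws exposures from gamma(shape 2, scale
50 by default in the examples) and counts Poisson around S·E;
`make_true_signatures` concentrates 90% of each signature's mass on its
own block of classes, the well-separated regime where recovery is well
posed. Toy references are uniform ACGT.

These generators emulate dialect variety, bounded positional scatter,
CI overlap and support structure — not realistic SV size spectra,
sequence context (no repeats or homology hotspots at junctions), caller-
specific sensitivity biases, overlapping true events, or correlated
signature exposures. Passing tests therefore demonstrate correctness of
the mechanics (parsing, predicates, clustering, extension, factorization
and selection) under controlled conditions, not calibrated performance on
real tumor cohorts.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 50 truth events × 4 callers for merge-truth recovery, up to 200
records per caller for merge-oracle equivalence, 1000 random junctions on
a 10 kb toy reference for microhomology, 100 random container/BED
instances for annotation, and a 200 × 16 count matrix with 3 planted
signatures, 8 restarts, ranks 2–5 for the signature scan. All randomness
flows from explicit seeds (numpy Generator); identical seeds give
identical results, including the NMF scan.

## Known limitations

Long-read caller dialects (Sniffles, cuteSV) are not parsed. Genotype
semantics beyond FORMAT pass-through, reciprocal-overlap merging,
CI-aware annotation, and nucleotide-level consequence annotation
(fusions, frameshifts) are out of scope. The `pcawg_like` scheme is a
reconstruction on the published axes (fragile sites, replication timing,
length) constrained to 25 classes, not a copy of any cohort's exact class
list; Gridss assembly INFO is passed through rather than unified.
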