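# Methods

## Pattern model and matching

A consensus is an ordered list of allowed-base sets over {A,C,G,T}, parsed
from bracket text (`[GA]GGT[TC]A`; `N` = the full set). A full-site element
is compiled from one half-site and a repeat geometry: IR appends the
reverse-complemented half after the spacer, DR repeats the half directly,
ER places the reverse-complemented half first. Spacer positions carry the
full set and are unconstrained. A pattern whose set list equals its own
reverse-complement mirror is flagged `self_rc`; the IR1 consensus is
self-RC, so one of its matches is the same physical site on either strand.

Matching counts mismatches only at constrained positions (allowed set a
proper subset of {A,C,G,T}). Subject characters outside A/C/G/T (e.g. N)
match nothing and therefore count as mismatches at constrained positions
but never at spacers — a conservative, deterministic rule: an ambiguous
window can still match if the budget absorbs it. The scanner encodes the
sequence as base indices and accumulates per-offset mismatch counts with
one vectorised pass per pattern position, which makes 30 kb windows cheap;
a pure-Python per-position oracle with the identical contract lives in the
test suite and the acceptance script, and the two are checked for exact
agreement on randomized instances.

Scanning defaults: mismatch budget 0 (the screen is a consensus match;
the budget is configurable because well-characterised positive controls
such as the IBABP element deviate from the consensus by one base), both
strands, with self-RC matches canonicalised to strand '+' so a physical
site is reported once. Non-self-RC patterns keep hits from both strands.
All overlapping hits are reported; any exclusion rule would be an
additional filter the screen does not define.

## Windows and coordinates

Coordinates are 0-based half-open internally; hits also expose 1-based
inclusive fields for display. The anchor is the 5′ end of a gene's first
annotated exon; with alternative transcripts, the 5′-most transcript wins,
ties broken by longest first exon then lexicographic transcript id
(deterministic; annotation formats do not define a unique "first exon").

The window spans `upstream` (default 20,000) bases strictly before the
anchor and `downstream` (default 10,000) bases starting at the anchor,
clipped at contig ends with clipping flags set. For a minus-strand gene the
genomic interval is the mirror `[anchor − downstream + 1, anchor + upstream + 1)`
and the sequence is reverse-complemented, so an unclipped window always
captures exactly `upstream` + `downstream` oriented bases and upstream /
downstream are biological directions. Gene-relative offsets use a
GenBank-like convention: the anchor base is +1, the base before it −1,
no position 0. Published element positions in the +700…+1600 range follow
this convention, but reproducing them verbatim requires the original
(unnamed, circa-2012) genome builds, so they are recorded as reference
values, not test targets.

## Screen and conservation filter

The per-species screen scans every gene window and keeps a map
gene → hits, each hit carrying genomic and gene-relative coordinates; genes
without hits are omitted from the map but counted in the screened
denominator. A hit inside two genes' overlapping windows is attributed to
both (information-preserving; the alternative would silently drop data).

Conservation is evaluated per ortholog group (orthology is an explicit TSV
input, never inferred). Presence mode — the default and the least
assumptive reading of "element at a comparable position" — requires ≥ 1 hit
in every member species. Positional mode additionally requires the maximum
pairwise difference of best-hit gene-relative offsets (best = fewest
mismatches, ties to the 5′-most) to stay within a tolerance, default
2,000 bp; this is a documented interpretation, not an established
definition. Candidates are ordered by positional spread.

## Synthetic benchmark

The generator emulates the screen's inputs: per species one contig of
i.i.d. background sequence (default uniform composition) with single-exon
genes every 42,000 bp (far enough apart that 30 kb windows never overlap),
strands alternating +/− so both orientations of the window machinery are
exercised. Elements are sampled to score an exact, requested number of
mismatches, planted at requested gene-relative offsets inside ortholog
groups (optionally on the opposite strand), and recorded as truth records.
Planted sites must not overlap; collisions are an error naming the specs.

With `clean_background=True` the background of each species is re-drawn
from a derived RNG stream until re-scanning every window recovers exactly
the truth set, certifying the bundle free of spurious matches — the
expected number of background IR1 hits per 30 kb window is ≈ 0.0286 by the
closed-form product formula, so a handful of redraws suffices. The
i.i.d. background keeps that expectation closed-form; it does not model
isochores, repeats or phylogenetic correlation, so perfect recovery here
demonstrates coordinate and scanning correctness, not performance on real
genomes, where paralogy and repeat-driven false positives are possible.
One RNG stream per species bundle, derived from the recorded seed;
identical seeds give byte-identical bundles.

## Assay quantification

ΔΔCt: ΔCt = Ct_target − Ct_housekeeping per sample, ΔΔCt = ΔCt − mean
control ΔCt, fold = 2^(−ΔΔCt). Control folds are computed identically, so
the control *mean ΔCt* is the reference and individual control folds equal
1 only when all control ΔCt coincide. Group summaries report mean ± SEM
(n−1 denominator). The model assumes perfect doubling per cycle; no
amplification-efficiency correction.

Relative luciferase activity = firefly/Renilla per well; fold induction =
mean treated RLA / mean control RLA. Renilla must be positive at
construction.

In-silico PCR uses exact primer matches only: a product spans each forward
match to each downstream match of the reverse complement of the reverse
primer, footprints included — sufficient for fixture-level amplicon sizing,
not a thermodynamic PCR model.

The t-test is the classical pooled-variance two-sided unpaired test
(Welch's correction behind a flag; reports of "Student's t-test" in this
literature conventionally mean the pooled form), with stars at
0.05/0.01/0.001. Zero pooled variance with equal means returns t = 0,
p = 1; with unequal means the statistic is undefined and raises.

## Problem sizes and numerical choices

The acceptance checks use 1,000 random scanner instances (sequences up to
250 bp including ambiguous bases, budgets 0–2), a 3-species × 5-gene clean
bundle (12 planted elements spanning both gene strands, both planting
strands, upstream and downstream offsets), and 200 random 30 kb windows
for the Monte-Carlo background comparison, whose acceptance band is ±3
standard errors using the Poisson SE of the analytic mean (a sample SE
degenerates when no hits occur). These sizes give sub-minute runtimes
while exercising every code path; the simulator scales to larger genomes
linearly.

Known limitations: GFF3 only (no GTF dialects, trans-splicing or fusion
annotations); orthology must be supplied; no PWM/information-content
scoring or match p-values — the screen is deliberately a consensus/
mismatch-budget model, matching how IR1 screens are defined.
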