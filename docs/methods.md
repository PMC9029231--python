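# Methods

## Scoring model

A position frequency matrix (counts per base per position) is converted to
a scoring model by adding a pseudocount (default 0.01 per cell — negligible
against real counts, avoids `ln 0`), normalising columns, and weighting
each column by its information content in nats,

    ci[i] = Σ_b f(b,i) · ln(4 f(b,i)),

so that a window s scores `raw(s) = Σ_i ci[i] · f(s_i, i)`.  Raw scores are
min/max-normalised by the attainable per-column bounds, giving scores in
[0, 1] with the consensus at exactly 1.0 (the matrix-similarity convention
of MatInspector-style tools; thresholds quoted as percentages are these
scores × 100).  A matrix whose columns are all uniform has no score spread
and is rejected.  Windows containing N are unscorable and never match;
both strands are scanned and only the better strand is kept per offset, so
palindromic sites are counted once.  Promoter sequences are stored 5'→3'
with the TSS at the 3' end; truncation to an analysis window keeps the
TSS-proximal bases.  Coordinates are 0-based, half-open.

## Permissive scan and candidate thresholds

Each motif is first scanned with a permissive threshold calibrated, on the
pooled test + control set, to yield about 5 matches/kb.  Pool-based
calibration keeps the threshold identical across FDR resampling runs, so
the null experiences exactly the same selection as the observed analysis.
The candidate thresholds are all distinct (conserved) scores observed in
either arm; candidates below the permissive threshold are discarded
because the scan censors site counts there (any such threshold would
either be inadmissible under complete counting or have undercounted
statistics).  Threshold comparisons are inclusive (`score ≥ t`), so every
candidate realises at least one hit.

## Conserved score

For each mouse hit, the central position of the match window is mapped
into each ortholog via an exact per-position map (no interpolation); the
motif-length ungapped ortholog window centred there is scored best-of-both
strands.  With a requirement of conservation in n species the conserved
score is `mouse` for n = 0, otherwise `min(mouse, n-th highest available
ortholog score)`; hits aligned in fewer than n species score 0.  This is
the unique reduction for which thresholding at t is equivalent to
"mouse ≥ t AND at least n ortholog windows ≥ t", which the test suite
verifies exhaustively.

## Enrichment statistics

At a threshold t, A and B count sites with conserved score ≥ t in the test
and control arms (total lengths lenA, lenB).  Admissible thresholds keep
the control frequency 1000·B/lenB within [0.01, 0.2] sites/kb.  Reported
statistics:

* `OR = (A/lenA)/(B/lenB)` (+∞ flagged when B = 0, never admissible);
* `AS = A − B·lenA/lenB`;
* one-sided exact binomial p.  The pipeline parameterises the test with
  the control-derived rate — X ~ Binomial(lenA, B/lenB), p = P(X ≥ A) —
  the convention of threshold-optimising enrichment tools in this family;
  `binomial_p` also exposes the symmetric conditional two-sample form
  X ~ Binomial(A+B, lenA/(lenA+lenB)).  The rate form treats the control
  arm as estimating the background rate; it is anti-conservative when B is
  small, which is why significance is always paired with the resampling
  group-wise FDR below.

The optimiser returns the admissible threshold maximising the configured
objective (OR, or AS subject to OR ≥ 2.5), breaking ties by smaller
p-value and then larger threshold.  `run_enrichment` evaluates the full
grid of window lengths × conservation levels per motif and reports the
best setting.

## Grouping and group-wise FDR

Matrices are grouped when ≥ 50% of either one's hit centres (centre =
offset + ⌊m/2⌋) lie within 4 bp of a hit centre of the other on the same
promoter; the relation is closed transitively (union-find), and each
group's optimum is its best member's objective value.  The FDR for a group
is estimated by re-partitioning the pooled a + b promoters into random
pseudo-test (a) and pseudo-control (b) arms, re-running the *entire*
threshold optimisation and grouping on each of (default) 100 runs, and
averaging the number of null groups with an equal-or-better optimum; ties
count as better.  Per-promoter scan results are cached across runs — valid
because scanning and conservation scoring are promoter-local and
arm-independent — so the resampling changes no count it would otherwise
have computed.  Reported results keep groups with FDR < 0.05 (strict).

## Flanking-region analysis

For a motif's optimised sites, the 100 bp on either side of each site are
extracted with *all* of that motif's site windows masked out of the
fragments and intervals clipped to promoter bounds.  These fragments are
compared, with the same scan/optimise machinery, against N random 200 bp
fragments drawn from the control promoters (promoter chosen proportional
to its eligible starts, N = max(1000, 5× the flank count), seeded).
Fragments carry their source coordinates, so conservation can be applied
if configured; the shipped analyses run flanks without a conservation
requirement.

## Regulatory-class classification

Genes are classified per timepoint from three contrasts (WT injured vs WT
uninjured; KO vs WT; KO injured vs KO uninjured) at fold-change ≥ 1.5 and
FDR < 0.01, compared on the log2 scale with an inclusive boundary at
exactly log2(1.5):

| WT response | KO vs WT | class   |
|-------------|----------|---------|
| up          | lower    | JunUP   |
| down        | higher   | JunDOWN |
| up / none   | higher   | AltUP   |
| down / none | lower    | AltDOWN |

JunUP genes are completely dependent when the knockout shows no injury
upregulation under the same cuts, else partially; a gene is
timecourse-complete when it is JunUP at some timepoint and the knockout is
never upregulated at any.  Control genes for the promoter analysis have no
significant genotype effect at any timepoint, < 1.3-fold genotype
difference throughout, and maximum expression above 7 (log2 array scale,
roughly the mean baseline) to avoid heterochromatic promoters.  Missing
contrasts yield class "none" with a flag, never imputation.

## Synthetic corpora

The simulator is a pure function of its spec (seed included; identical
spec ⇒ byte-identical FASTA).  Background sequence uses a base composition
of A/T 0.29, C/G 0.21 (≈ 42% GC, typical of mammalian promoter regions;
an order-1 transition matrix is accepted for composition-robustness
experiments).  Planted site counts are Poisson(rate × length) per promoter
— matching the rate model under test rather than fixing counts — with
non-overlapping placement (bounded retries), site sequences sampled
column-wise from the motif's frequencies, and random strand.  A motif may
instead co-occur with an anchor motif: one partner site per anchor with a
configured probability, at a uniform gap on a random side.

Ortholog bundles copy each promoter per species with independent per-base
substitutions at the divergence rate (default 0.25, in the range spanned
by rodent-to-primate promoter alignments), except planted-site windows,
which are kept fully intact with the retention probability (default 0.9)
and otherwise diverge like background; position maps are identity unless a
deletion rate introduces gaps.  Per-site retention outcomes are recorded
as ground truth.

The expression generator plants classes by group means (uninjured baseline
N(8, 0.5); effect size 2.0 log2 units, residual sd 0.25, 4 replicates by
default; partially dependent genes get half the knockout effect), computes
contrasts by Welch t-tests and Benjamini–Hochberg per contrast.  With the
default settings full-size contrasts are recovered essentially always,
while the half-size genotype contrast of partially dependent genes sits
close to the cuts and a small fraction of those calls wobble — by design,
the generator probes the cut boundary rather than hiding it.

The built-in motif collection (AP1, CRE = AP1 with one extra central base,
SRF, CEBP, E-box, NF-κB, MEF2) uses consensus-derived count matrices with
heterogeneous column sharpness — near-deterministic cores (dominant base ≈
0.95–0.99) and softer flanks (≈ 0.8–0.85), the shape of curated matrices.
This both matches real motif information content (~1.3–1.8 bits per core
column) and gives planted sites a graded score spectrum, without which the
flexible-threshold search would degenerate to a handful of candidate
thresholds.

What the simulations do **not** emulate: CpG islands and repeat structure,
indel evolution and phylogenetic tree correlation between species,
dinucleotide composition bias, array probe effects, or correlated
expression noise.  Passing tests therefore demonstrate the statistical
machinery under its own assumptions, not performance on real genomes.

## Problem sizes and calibration runs

The planted-power benchmark uses 200 + 200 promoters of 1 kb with an
AP1-like motif at 0.15 vs 0.05 sites/kb, retention 0.9 across five
pseudo-species, evaluated over 50 seeds; the primary screen optimises AS
(min OR 2.5) at the best conservation level of n = 0…5 and estimates the
group FDR with 100 resampling runs.  Because planted counts are Poisson,
around one seed in ten draws arm counts too close for any detector to
separate at p < 0.005 — the benchmark's detection ceiling, which the test
suite documents.  Null calibration uses 200 seeds of 40 + 40 × 600 bp
corpora with three motifs and identical plant rates in both arms; flanking
recovery uses 25 seeds of 60 + 60 × 1 kb with CRE planted only beside AP1
anchors, ranked against five decoys.  Class recovery uses 50 genes per
class at margin-clearing effects (3.0 log2 units, sd 0.15, 6 replicates),
where recovery is exact.

## Known limitations

* The rate-parameterised binomial is anti-conservative at small B; rely on
  the group-wise FDR for error control, as the reporting filter does.
* Conservation scoring rescales nothing for indels beyond the gap-removed
  window rule; a site whose ortholog window is shifted by an unmapped
  indel scores as diverged.
* Grouping compares hit locations only at each motif's own optimum
  threshold; two matrices for the same factor optimised at very different
  thresholds can land in different groups.
* The CLI's `simulate` subcommand exposes only the single-motif planting
  design; richer designs (co-occurrence, custom backgrounds) are available
  through the library API.
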