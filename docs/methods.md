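# Methods

## The boundary-calling model

Both dRNA-Seq (5′ ends) and Term-Seq (3′ ends) produce read ends that pile
up at single nucleotides where transcripts begin or end. The caller treats
the per-position end count r(x) on each strand as signal over a locally
estimated background: the ring window C(x) = {y : e < |x−y| ≤ w} with
exclusion radius e = 2 nt and outer radius w = 50 nt. The score is the
modified z-score Z(x) = (r(x) − m(C(x))) / σ(C(x)). Excluding the focal
position and ±2 nt keeps a genuine boundary's own pile-up (and small
mapping jitter around it) out of its background estimate; 50 nt is narrow
enough to track local coverage changes inside operons.

Z is computed on **raw counts** separately per biological replicate and
then averaged. Library-size (CPM) normalization enters only the TAP
comparison, which is cross-library; the z-score itself is scale-free in
the sense that its background is estimated from the same library.

### Filters and their order

1. **Background mask.** Any position with window mean m(C(x)) ≤ 0.25
   (inclusive) in *any* replicate is masked: with essentially no local
   reads the SD estimate is meaningless and a single stray read could
   score arbitrarily high. Positions with undefined Z (empty window, or
   zero window SD with `sd_floor = 0`) are likewise masked.
2. **TAP eligibility (dRNA-Seq only).** Primary transcripts carry
   5′-triphosphates that ligate sequencing adaptors only after TAP
   treatment, so true TSSs are enriched in TAP(+) over TAP(−); processed
   5′ ends (monophosphate) appear equally in both. Eligibility requires
   TAP(+) CPM strictly greater than 2 × TAP(−) CPM. By default the test
   must hold in **every** replicate pair, mirroring the conservative
   any-replicate mask; a pooled (replicate-averaged) variant is available
   as `tap_mode="pooled"`. No pseudocount is added: plus > 0 with minus
   = 0 passes, 0 vs 0 fails.
3. **Retention.** Averaged Z strictly greater than 12.
4. **Collapse.** Retained positions within 3 nt (|Δ| ≤ 3) of a stronger
   one are discarded, greedily in descending Z; equal Z ties resolve to
   the smaller coordinate so output is fully deterministic.

### Numerical choices

- σ is the **population** SD (divide by n) by default: the window is the
  complete local background, not a sample from it. `sd_mode="sample"`
  is exposed for sensitivity analysis.
- Zero-variance windows leave Z undefined (masked) rather than infinite;
  setting `sd_floor > 0` instead replaces σ by max(σ, sd_floor).
- Linear replicons truncate windows at their ends and compute m/σ over
  the remaining positions; an empty window masks the position. Circular
  replicons measure window distance around the origin.
- The statistic is computed with prefix sums in O(length); the test suite
  checks it against a literal per-position window loop to 1e-9 on random
  Poisson tracks, including both SD modes and circular topology.

## Annotation conventions

Gene assignment and the 500 nt cap are artifact conventions, not part of
the calling statistic: a TSS is assigned to the nearest same-strand gene
whose 5′ start lies at or downstream of it (distance = 5′-UTR length), a
TTS to the nearest gene whose 3′ end lies at or upstream (3′-UTR length);
equidistant ties resolve lexicographically by gene id. TSSs inside gene
bodies are reported as orphans rather than classified into an
internal/antisense taxonomy. Region overlap (e.g. smBGC membership) is
strand-agnostic inclusive containment.

## RNA-Seq density validation

For each called site the strand-matched RNA-Seq depth is extracted over
offsets −F..+F (default F = 100 nt), reversed for minus-strand sites so
positive offsets always point downstream along the transcript, and
averaged over sites. The step statistic is the ratio of mean density over
offsets 1..F to that over −F..−1, with the denominator floored at 1e−6.
Genuine TSS sets give ratios well above 1, TTS sets well below 1; flat
coverage gives exactly 1. Depth is used as given (no per-site scaling);
a per-site normalization could be added for strongly heterogeneous
expression but is not applied by default. Multiple coverage tracks (e.g.
growth phases) yield one profile each. The step is reported
quantitatively but not tested for significance.

## The synthetic-data generator

`txends.simulate` produces complete datasets with known truth, under
default conditions chosen to represent a well-powered bacterial
end-enrichment experiment: a 100 kb linear replicon, 40 genes (lengths
drawn uniformly from 300–1500 nt, a typical bacterial CDS range), true
TSSs 20–200 nt upstream of gene starts and TTSs 20–200 nt downstream of
gene ends (realistic UTR lengths), Poisson background at rate 1 per
position per library, spike strength 50 added at true sites, two
replicates, 20 processed 5′ sites spiked equally in TAP(+) and TAP(−)
(leak fraction 0.05 of TSS signal models imperfect TAP(−) depletion), 20
processed 3′ sites in Term-Seq, and step-function RNA-Seq coverage of
depth 20 (Gaussian noise, SD 2, truncated at zero) between each gene's
TSS and TTS over Poisson background elsewhere.

Design choices within the generator:

- **Spike separation.** Injected sites are placed at least 120 nt from
  any other same-strand spike, so no spike falls inside another's ring
  window. Two real boundaries closer than ~50 nt would inflate each
  other's background σ and suppress both scores — a genuine property of
  the statistic; keeping the generator's truth sites separated makes
  recovery rates measure the caller, not that geometric interaction.
- **Processed 3′ ends count as correct TTS calls** when measuring
  precision: they are genuine transcript 3′ boundaries, and Term-Seq has
  no analogue of the TAP filter to separate processing from termination.
  TSS precision, by contrast, counts only true TSSs — rejecting
  processed 5′ ends is exactly what the TAP filter is for, and their
  exclusion rate is reported separately.
- Counts are Poisson and coverage noise Gaussian because shot noise is
  the minimal model for sequencing counts; the caller itself makes no
  distributional assumption, so the model mainly sets test difficulty.

What passing on this generator does **not** show: robustness to
mappability gaps, position-specific ligation/priming biases, overlapping
transcription units, antisense transcription, or replicate disagreement
beyond Poisson variation — real libraries have all of these, and the
recovery rates reported on synthetic data are upper bounds.

## Problem sizes and determinism

The acceptance script and recovery tests use 100 kb genomes, 10 simulation
seeds for recovery and null rates, and 200 random tracks of length 2000
for the oracle comparison — sizes at which every quantity is stable to
reseeding while the whole suite stays fast on a single CPU. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
identical configuration and seed reproduce byte-identical track, site,
annotation and profile files, which the test suite asserts end to end
through the command-line interface.

## Known limitations

- Single-end alignments only; mate-pair information is ignored by design
  (the supported library chemistries are single-end).
- No condition-specific calling: replicates are assumed to measure the
  same underlying boundary set.
- The TAP fold test with very shallow libraries is noisy (CPM of a
  single read can exceed the threshold); the mask on m(C(x)) mitigates
  but does not remove this.
- Terminator/promoter motif discovery and transcript-unit assembly are
  out of scope; outputs are positions, scores and UTR lengths.
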