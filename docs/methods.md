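# Methods

This note records the models, conventions and numerical choices behind
`isopattern`, and what the synthetic tests do and do not demonstrate.

## Substrate and coordinates

All counting operates on `MaskedSequence`: uppercase A/C/G/T/N plus one
boolean mask flag per position. Repeat-derived positions (lowercase in
soft-masked FASTA, or N) keep their coordinates but are excluded from every
numerator and denominator. N is always masked (an N carries no countable
base); IUPAC ambiguity codes other than N are converted to masked N with a
warning rather than rejected, since real assemblies contain them and they
must not enter counting. Coordinates are 0-based, half-open everywhere;
BED output matches natively.

## Isochore segmentation

Segmentation is deliberately plain: consecutive non-overlapping windows of
100,000 bases (no sliding step, no HMM or recursive segmentation), G+C
computed over unmasked bases only, and threshold classification. The final
partial window is emitted at its true length. Windows with less than half
of their bases unmasked are labelled UNCLASSIFIED — heavily masked windows
give unstable G+C estimates; the 0.5 threshold is configurable.

The five-class scheme pins only its outer bounds to the analysis (L1 below
37% G+C, H3 above 52%); the interior boundaries 41 and 46 follow the
classical isochore-family literature and are explicit, configurable
assumptions, as is the 58% boundary that the six-class (chicken-style)
scheme adds for H4. A boundary value belongs to the higher class, making
classification monotone with half-open intervals. Maximal runs of
equal-class windows merge into segments with unmasked-base-weighted mean
G+C; UNCLASSIFIED windows break runs. No minimum segment length is imposed.

## Positional autocorrelation

For one dinucleotide, occurrences are all start positions with both bases
unmasked (overlaps allowed), counted on the given strand only — the
analysis treats a dinucleotide and its reverse complement (e.g. AG vs CT)
as distinct signals. The histogram counts ordered pairs at distances
d ∈ [2, 80]; distances 0–1 are undefined for a self-pair, so the
normalization constant is the mean count over [d_min, d_max] — any
difference from an interval nominally starting at 0 is a uniform scale
factor that cannot move peak positions.

**End effects.** By default only left pair members with full reach
(i ≤ L − 2 − d_max) are counted, which makes the flat-background
expectation constant in d (an unbiased estimator). This rule is not
symmetric under sequence reversal; a `both`-ends exclusion mode
(i ≥ d_max and j ≤ L − 2 − d_max) is exactly reflection-symmetric and is
what the strand-symmetry property test uses. Sequences shorter than
d_max + 4 contribute an all-zero histogram with a warning.

**Pooling.** Per isochore class, raw histograms of all segments are pooled
*before* normalization (pairs never span segment boundaries), so each class
has a single normalization constant — the only order under which "level
1.00" is well defined per class.

**Peaks.** Candidate peaks are strict local maxima of the 3-point-smoothed
profile (plateaus resolve to their leftmost point), filtered at the
normalized baseline (min height 1.0) and greedily thinned so no retained
peak sits within 5 bases of a higher one (ties keep the earlier). The
profile-level peak caller then refines each position to the argmax of the
*unsmoothed* normalized profile within one bin of the smoothed maximum.
The refinement matters because a periodic train planted at exact rounded
multiples of 10.4 splits each lag's pair mass over two adjacent integer
distances (e.g. lag 2 → 20.8 → counts at 20 and 21 in ratio ≈ 1:4); a
3-point running average then makes the two smoothed values equal in
expectation, and without refinement the reported position of that peak
would be decided by sampling noise. The refinement pins it to the bin that
actually carries the mass, making peak positions (10, 21, 31, 42, …)
deterministic. The plain array-level `find_peaks` applies no refinement.

**Period.** Peaks p₁ < p₂ < … get harmonic indices kᵢ = round(pᵢ/p₁)
(the first peak is taken as the fundamental) and the period is the
least-squares slope through the origin, T = Σkᵢpᵢ / Σkᵢ², with the
residual RMS reported. A peak list missing the fundamental yields T ≈ p₁;
callers must supply fundamental-containing lists.

## Trinucleotide tables

Overlapping 3-mers on the given strand; any window touching a masked
position is skipped, so the table total equals the number of valid windows
exactly. AAA and TTT keep distinct ranks (no reverse-complement
collapsing, matching how such tables are conventionally printed). All
rank order consumed downstream breaks ties lexicographically, which makes
the greedy extension automaton deterministic. For per-class tables a
window belongs to the segment containing its *start* position —
unambiguous for windows straddling a class boundary.

## The extension automaton

From a seed triplet ABC the motif grows downstream, then upstream:

1. **extend** — with right-edge dinucleotide BC, append the top-ranked
   continuation of family BCx (upstream mirrors with xAB, prepending).
   A step requires a positive count; a dead family stops the direction.
2. **collapse** — after each append, if the emitted tail ends in two
   copies of a length-k unit (k = 1, 2, 3; smallest k wins), all complete
   trailing copies — including seed bases — collapse into a repeat group
   `(unit)`. A homopolymer seed therefore collapses immediately (TTT →
   `(T)`).
3. **escape** — while the edge is a repeat group, the automaton takes the
   highest-ranked continuation that does *not* prolong the cycle (after
   `(T)`, A via TTA even if TTT ranks higher). If no non-prolonging
   continuation has a positive count, the cycle continues indefinitely:
   the group itself is wrapped as a closure and the direction stops (a
   pure one-triplet table yields `[(A)]`).
4. **closure** — when a direction creates a repeat group with the same
   unit as one it created earlier, the token run from just after the
   earlier twin through the new twin is wrapped into a closure flank
   `[...]` and the direction stops. Twin matching is direction-local: the
   group that absorbed the seed belongs to the downstream pass. On an
   AT-rich table ranked TTT > ATT (xTT), TTA the best TTx escape, AAT the
   best AAx escape, this produces `[(A)(T)](A)(T)[(A)(T)]` from seed TTT.

The automaton is a pure function of (table ranking, seed); every decision
— family consulted, full ranking, chosen base, rank used, event — is
recorded in a replayable trace. `max_steps` (default 40 per direction,
roughly twice the span of observed motifs) guards against pathological
tables; repeat units are capped at 3 bases, the largest unit the notation
uses. An optional stochastic mode samples continuations proportional to
counts under a caller-supplied seed; it exists for exploring near-ties and
is not used by any default path.

**Known representation limit.** Reverse-complement duality (extending the
complemented seed on the complement-counted table mirrors the motif) holds
token-for-token for seeds that do not collapse into a homopolymer cycle.
For homopolymer seeds both strands close into the same fully periodic
block pattern, but the finite rendering anchors its phase on the seed
letter: `[(A)(T)](A)(T)[(A)(T)]` (T-seeded) versus `[(T)(A)](T)(A)[(T)(A)]`
(A-seeded) denote the same bi-infinite pattern. Duality then holds up to a
rotation of the block cycle, and that is how it is tested.

## Resolution under the positioning constraint

A motif corresponds to a nucleosome positioning pattern only if no run of
purines or pyrimidines exceeds five residues. `resolve` removes the copy-
number uncertainty by exhaustive search: repeat counts 1–6 per group,
closure flanks expanded 0–2 copies. Groups inside a flank share one count
per group and flanks with identical periods share their whole assignment
— a periodic closure repeats the same resolved period, and this keeps the
search space polynomial in the number of distinct groups.

Candidates violating the run limit are discarded; among the rest the R/Y
projection is scored against an infinite period-10 RRRRRYYYYY tiling over
all 10 phases and both polarities, and the optimizer maximizes
lexicographically: matched fraction, then matched positions, then shortest,
then lexicographically smallest sequence. Fraction-first expresses the
constraint's intent (conformity), while the matched-positions tie-break
lays a perfectly conforming motif out at full length — `(A)(T)` resolves
to `AAAAATTTTT`, not `AT`; `(G)(C)` to `GGGGGCCCCC`; the AT-central
`(CA)CAG(A)(T)CTG(TG)` to the complement-symmetric `CACAGAAATTTCTGTG`
(14/16 positions = 87.5% conforming — alternating YR flanks can never
match a block tiling completely). Scoring uses bit-mask XOR/popcount, so
the full search stays in milliseconds.

## Consensus

Resolved motifs are aligned by gap-free sliding (motifs are short and
phase-locked to a period-10 pattern; gaps would be unidentifiable),
progressively: each motif maximizes summed positional identity of R/Y
projections against all already-placed motifs, ties taking the smallest
offset. Columns covered by fewer than half the motifs are trimmed; each
remaining column renders as its base if unanimous, R for {A,G}, Y for
{C,T}, N otherwise — the degenerate alphabet the consensus patterns of
this analysis actually use.

## Synthetic genomes

The generator emulates exactly what the analysis assumes, with recorded
ground truth: segments of i.i.d. bases with P(G)=P(C)=gc/2 (so realized
G+C concentrates within a binomial SD ≈ 0.0016 of target at 100 kb);
masked stretches of geometric length (mean 300 bp, the scale of common
interspersed repeats) placed until the requested masked fraction is hit
exactly; degenerate motifs (R/Y sampled uniformly) at non-overlapping
unmasked positions; periodic dinucleotide trains at
p₀ + round(k·period) + round(N(0, jitter)) with the planted positions
unmasked (a planted signal is by construction not a repeat). Plant order
is masks → motifs → periodic trains; later plants may overwrite earlier
ones, with coordinates recorded as planted. Each stage draws from its own
spawned stream of the spec seed, so the construction is fully
deterministic and stage-local.

**What the i.i.d. background does not model:** Markov dependence, CpG
depletion, repeat family structure, and composition gradients within
isochores. Passing tests therefore demonstrate that the pipeline recovers
planted structure against the simplest null with closed-form expectations
— not that real-genome peak visibility gradients across isochore classes
are reproduced. One consequence inside the tests themselves: under the
i.i.d. model all triplets of the same composition class are exactly
equiprobable, so the top-ranked triplet of a G+C-rich background is some
G/C-composed triplet, not specifically GGG or CCC; dominance of GGG/CCC
(or AAA/TTT) is only deterministic where the corresponding 10-mer motifs
are planted.

## Problem sizes and defaults

The default study conditions used throughout the tests and the acceptance
script: 100 kb sequences for periodicity recovery with 800 planted CG
(span ≈ 8.3 kb, signal-to-background ≈ 2:1 per harmonic bin); 300 kb per
class for mosaic recovery (window G+C SD ≈ 0.0009, so 2-percentage-point
margins from class boundaries give error rates far below the 5% budget);
600 kb of background for flatness bounds (smoothed profile SD ≈ 3%,
keeping the max under 1.15 with large margin). These sizes make every
expectation sharp while each test runs in well under a second.

## Limitations

* Windows, not change-point segmentation: class boundaries are localized
  only to window resolution.
* The closure rule is this package's operationalization of "periodic
  continuation"; the finite rendering of fully periodic motifs is
  phase-anchored on the seed (see above).
* Consensus alignment is progressive, not joint; with many motifs the
  placement can depend on input order (inputs here are few and short).
* No Fourier/periodogram analysis and no cross-correlation of different
  dinucleotides; bendability matrices are out of scope.
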