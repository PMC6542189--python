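# Methods

## Element geometry and coordinates

An element schema is a half-site over {A,C,G,T}, a spacer length, and the
derived consensus `half_site + N^spacer + revcomp(half_site)`.  The `n = 2·|half_site|`
informative positions are numbered 1..n ("primary positions"), skipping the
spacer, which sits implicitly between positions n/2 and n/2+1; position `p`
and position `n+1−p` form a palindromic pair.  Genomic coordinates are
0-based half-open (BED convention) everywhere; 1-based numbering exists only
inside an element.  Built-in schemas: ERE13 (`GGTCAnnnTGACC`), HRE13
(`GAACAnnnTGTTC`), their flank-extended 15-nt forms (`AGGTCAnnnTGACCT`,
`AGAACAnnnTGTTCT`, n = 12), and the spacer-less p53 element (`TGCCCGGGCA`).

## Variant space and half-site groups

Level k holds every element differing from the consensus at exactly k
primary positions: `C(n,k)·3^k` elements, enumerated in lexicographic
(positions, then bases) order.  The reverse complement of a variant maps a
substitution `(p, b)` to `(n+1−p, complement(b))`; it is an involution and a
bijection of each level onto itself.

A half-site group fixes n/2 primary positions.  Per palindromic pair the
group has a vacancy (neither member fixed), a double occupant (both fixed)
or a single; |V| = |D| because the fixed set has exactly n/2 members.  Two
distinct symmetries act on groups:

* the **reverse-complement** group maps the fixed set through the pair map.
  It preserves each pair's number of fixed members, hence preserves V, D and
  the algebraic state — which is why a group and its reverse complement
  carry the same signal and the display profile is mirror symmetric;
* the **set-complement** group fixes the complementary positions.  It swaps
  V with D and negates the state, which is the bijection behind the
  symmetric plateau censuses (6/60/120/60/6 and 56/140/56).

Groups equal to their own reverse complement ("innate palindromes") require
every pair wholly fixed or wholly vacant; they exist only for even n/2
(20 of the 924 groups at n = 12, none at n = 10).

### Display order

The axis lists one representative per reverse-complement pair (the
lexicographically smaller fixed set), sorted by vacancy count, then by the
hierarchy ranks of the vacancy pairs, then of the double-occupant pairs,
then lexicographically by fixed set; the right half is the reverse
complements of the left half in reversed order, so ends of the axis are
mutual reverse complements.  For n = 12 the innate groups form the center
block (positions 453–472 of 924).  The intra-block tiebreak beyond the
hierarchy is a package choice: any deterministic order preserves the tested
invariants (mirror pairing, block boundaries, plateau membership).

### State algebra

A state grouping partitions the n/2 pairs into weighted classes; a group's
state is the sum of its vacancy-pair weights minus its double-occupant-pair
weights.  Because |V| = |D|, the state is invariant to adding a constant to
every weight, so the reference class takes weight 0 without loss of
generality.  Distinct-state counting never uses floats: with algebraically
independent weights two states coincide exactly when their integer
class-coefficient vectors coincide, so the count is the number of distinct
vectors (a numeric oracle with square-root-of-prime weights is kept in the
tests as an independent check).  For the ten-position schemas the six
partition signatures give 3, 5, 9, 13, 25 and 51 states.  The value for the
(2,2,1) partition is 13 by direct enumeration — the ladder contains
±(X−Y)-type rungs (class vectors ±(1,−2,1), four groups each, realized by
V = {A-pair, C-pair} against D = {both B-pairs}) in addition to the nine
more obvious rungs, a case easy to miss when the ladder is written out by
hand.

## Scanning and counting

Scanning is sense-strand only: the reverse complement of an element is its
own entry in the variant space, and any observed symmetry must come from
the data, never from double-strand counting.  A window is reported when its
primary positions lie within Hamming distance k_max of the consensus;
windows with non-ACGT characters at primary *or* spacer positions are
skipped (the element location must be unambiguous; this affects only
assembly gaps).  Identification uses an exact-lookup index from the
2-bit-encoded primary bases to (element id, k), applied after a vectorized
mismatch-count filter; equivalence to a per-window brute-force scan is
enforced by test.  Multi-record FASTA inputs are scanned per record.

Peak counting uses the full-containment rule (element footprint inside the
peak interval), every containment counted, no per-peak deduplication and no
preference for the least-variant element.  Any-overlap counting and
per-peak-presence deduplication are available behind flags, and the older
unique-assignment convention (each peak labelled by its least-variant
element, ties broken leftmost-then-lexicographic and audited) is a separate
operation.  k-mer counting stores only observed k-mers (sorted 2-bit codes,
k ≤ 32); parity comparisons evaluate Pearson correlation, slope and
intercept of c(op(s)) against c(s) over all 4^k k-mers with absent ones as
zeros (the convention under which the missing-element tallies are
meaningful; a jointly-present-only mode is provided).  Sums are integer
exact, so a perfectly mirrored input reports correlation exactly 1.0.

## Noise model and significance

λ = N·L·m/4^n, where N is the peak count, L the nominal (mean) peak length
and m the number of elements aggregated in a unit.  The window count is
deliberately *not* reduced to N·(L−footprint+1): with the quantile
convention below, N·L reproduces the published threshold pairs for three
independent experiments exactly, and the reduced count does not.  The
resulting conservative bias (factor (L−w+1)/L) is negligible whenever
L ≫ footprint, the regime in which the significance bands are used here.
For variable-length peak sets Σ interval lengths replaces N·L.

Significance bounds on the S/N scale are lower = Q(p)/λ and
upper = Q(1−p)/λ with Q(q) the smallest integer whose Poisson CDF reaches q
(so CDF(0) ≥ p prints a lower bound of exactly 0.00).  Reported bounds are
rounded half-up to two decimals.  Bounds depend only on (λ, p); they bracket
1 and tighten toward it as λ grows.  No multiple-testing correction is
applied beyond the per-unit bounds.

## Plateau quantification

Plateau membership is structural — each group joins the plateau of its
algebraic state — never clustered from the empirical values; only structural
assignment can reproduce the exact integer censuses.  Per plateau the
summary reports the member count, mean, sample SD (ddof = 1; the population
SD is reported alongside, the convention not being fixed by the published
tables), and the difference from the 0-state plateau mean.  Class weights
(the step sizes X, Y, Z) are estimated by ordinary least squares of the
per-group S/N on the integer class vectors with the reference class
dropped; on noiseless synthetic input the fit is exact, and the algebraic
check report verifies plateau mean = zero mean + vector·weights with
residuals that scale linearly in the injected noise.

One arithmetic note: recomputing the differences-from-mean from the
published five-state plateau means 32.30/27.89/23.47/19.06/14.64 gives
+8.83/+4.42/0/−4.41/−8.83; a +X difference of +4.41 is consistent only with
the unrounded means, so the recomputed +4.42 differs in the last printed
digit.

## Synthetic data

`make_genome` draws an iid background (optionally block-heterogeneous and
GC-skewed) and inserts planted variants at non-overlapping uniform
positions with randomized spacers, returning a ground-truth table;
everything is reproducible from one seed.  `make_mirrored_genome` returns
S + N + revcomp(S): the sentinel prevents junction k-mers, so
reverse-complement parity of k-mer counts is exact by construction, not
asymptotic.

`make_peaks` emits a peak of length L centered on each occurrence with
probability P(occupancy model) plus uniformly placed background peaks.  The
occupancy model is logit P = α − β·k + Σ_substituted-positions w(pair) − γ·1[crossover],
where the crossover indicator fires when substitutions sit on both sides of
the spacer.  The logistic form is a modelling convenience; its contract is
what the analysis assumes and the tests verify: monotone decay in k, a pair
hierarchy, a crossover penalty, and exact reverse-complement symmetry
(P(e) = P(rc(e))).  A "dim" variant scales the weights toward zero and
lowers the baseline, emulating an attenuated-binding mutant that obeys the
same rules with shorter residence time.

What the generator does *not* emulate: chromatin accessibility, read-level
noise and peak-calling artifacts, genome repeat structure, and correlated
peak shapes.  Passing the recovery tests therefore shows the pipeline is
correct and calibrated under its stated model, not that any particular real
experiment satisfies that model.

## Problem sizes and numerical choices

The null-calibration simulation uses a 20 Mb uniform genome with 1,200
uniform 400-nt peaks, chosen so peak coverage stays near 2% (keeping
containment counts effectively independent Poisson draws) while group×level
expectations span λ ≈ 0.5–230.  The parameter-recovery experiment plants
the consensus and all thirty 1-nt variants at 1,000 copies each in 20 Mb,
yielding ≥ 20,000 peaks of 250 nt; the attenuated-model run reuses the same
genome with background peaks topping the set up to the wild-type peak count
(an attenuated factor retains non-specific chromatin interaction, and
equal N makes the amplitudes comparable on one λ scale).  Recovery is
judged against the generator's analytic expectation with the standard error
propagated from binomial planting noise plus ambient and cross-containment
Poisson terms.  Full-genome tabulation of long k-mers at mammalian scale is
supported by the sparse counter but is not part of the test suite.

## Known limitations

- Parity sums are exact only while squared counts fit 64-bit integers
  (genomes ≲ 10^9 nt per k-mer class); beyond that the correlation is
  float-accurate but not bit-exact.
- The intra-block axis order beyond (vacancy count, hierarchy ranks) is a
  documented package convention, not an empirical claim.
- `assign_unique` and per-peak-presence counting iterate containments in
  Python and are intended for peak-scale audits, not genome-scale loops.
- The occupancy model treats occurrences independently; cooperative or
  competitive binding between nearby elements is out of scope.
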