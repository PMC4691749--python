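# Methods

## Chromosome model

The parental chromosome is circular and partitioned into `L` segments
(default fixture: `L = 43`) by palindromic 34-bp loxPsym sites. Each segment
has a length in bp, an essential flag, a centromere flag (exactly one
segment), optional auxotrophic markers, and each designed junction carries a
functional annotation for the sequence abutting each half-site (CDS, 3′ UTR,
or other noncoding). In the default fixture the centromere sits on segment
2, the essential set is {2, 9, 12, 20}, slow-growth genes sit on
{6, 9, 19, 24}, markers are MET28 → segment 14 and LYS1 → segment 32, 40
junctions are CDS-UTR and three (indices 28, 36, 43) are NC-NC. The
essential and NC-NC placements are configurable stand-ins: the published
design specifies their counts, but not a machine-readable list, so the
fixture fixes one deterministic choice.

Segment lengths are not part of the design nomenclature; the fixture draws
them log-uniformly from [135, 5000] bp with a fixed seed (135 bp is the
smallest single-segment span the design admits). All bp coordinates inside
the package are 0-based half-open; GFF3 export converts to 1-based closed;
segment indices are 1-based.

A rearranged genome is a cyclic sequence of signed segment ids. Its
canonical form is the lexicographically smallest rotation of the sequence or
of its reflection (reverse order, all signs flipped — the same molecule read
from the other strand), comparing `(|id|, sign)` with `+` before `−`. All
deduplication, counting and reporting happens on canonical forms: a circular
molecule has no distinguished origin or strand.

## Simulator

Each recombination event picks two distinct loxPsym junctions of the
*current* genome and acts on the forward arc between them: deletion removes
the arc, inversion reverses and sign-flips it, tandem duplication repeats
it, inverted duplication appends its reflection. Site pairs closer than
82 bp are excluded (the minimum distance for loxP recombination), and pair
selection is distance-weighted (`exponential` with a 10-kb length scale by
default, `uniform` available) — recombination requires the two sites to
meet, which is likelier at short genomic separations. The 10-kb scale is a
package choice: the published event-distance distribution decays smoothly
without a printed decay constant.

The event count per lineage is Poisson with mean 6.2 by default (the
observed mean events per strain) or fixed. Viability is enforced after
every event: all essential segments at copy ≥ 1 and exactly one centromere
copy. An inviable proposal is rejected and its **sites** are resampled
while the drawn event type is kept; this models that inviable recombinants
are simply never recovered, without letting the viability filter skew the
realized deletion/inversion balance away from the designed equal chemistry
(the observed cohort balance, once selection-required deletions are
discounted, is consistent with equal rates). Marker-loss selection, when
configured, resamples whole lineages until the condition holds, with an
explicit failure after a bounded number of attempts.

`simulate_disjoint_events` is a preset that places events with pairwise
disjoint, non-adjacent parental spans (and away from the circular wrap
point). It exists to provide unambiguous event-level ground truth: when
footprints do not interact, classification is exactly invertible.

### Evidence generation

*Sequences.* Segment sequences are random nucleotide strings guaranteed free
of internal loxPsym occurrences (checked on the assembled circle, including
boundaries); the default site is a configurable 34-bp perfect palindrome
placeholder — only palindromicity and length are validated, since the true
site sequence is not needed for structure-level analyses.

*Short reads.* Error-free paired reads (default 100 bp, 500 ± 50 bp
inserts, convergent) are sampled uniformly from the circular sequence. No
quality scores, base errors, or aligner emulation: flank matching is exact,
which is the desk-scale stand-in for single-end alignment of trisected
reads.

*Depths.* Observed per-segment mean depth is copy number × mean ×
a per-segment bias factor shared between the strain and reference libraries
(so it cancels in ratios, emulating mappability/GC bias), with sampling
noise drawn independently per base and averaged over the segment
(Poisson or negative-binomial with per-base size parameter, default 10).
Averaging per-base draws understates the correlation induced by read length,
so simulated depth noise is tighter than real data of the same nominal
depth, particularly for short segments; systematic error is carried entirely
by the bias term. Deleted segments read exactly zero — cross-mapping
artifacts (real segments can read near the deletion threshold when absent)
are documented but not emulated.

*Long pairs.* 10-kb ± 1-kb inserts (sd configurable) with 90-bp reads;
both reads must fall entirely inside single segment bodies (reads hitting a
loxPsym site or boundary are resampled, as the real aligner drops them), and
each read is recorded as a segment anchor: (segment, offset, strand in the
segment frame).

## Junction calling

A read is trisected when the loxPsym site occurs exactly once with ≥ 15 bp
flanks on both sides (reason codes: absent / insufficient flank / multiple
occurrences). A left flank maps to `iR` if it is a suffix of segment `i`,
or to `iL` if its reverse complement is a prefix; symmetrically for right
flanks; multi-segment matches are unmapped-ambiguous. Aggregated pairs are
parental iff designed; novel pairs need ≥ 3 supporting reads; pairs with one
unmapped flank are off-target candidates, always reported, and flagged as
likely ligation artifacts at support ≤ 2.

## Copy-number estimation

Segments with strain depth strictly below 5 are deleted (copy 0) and
excluded. The rest start at `N_i = 1`; each iteration forms
`M_ij = (N_j·D_rj/D_tj)(D_ti/D_ri)` over retained calibrators `j ≠ i`,
updates `N_i` to the most frequent rounded value of its row (ties to the
larger value; a row-maximum update is available as `update="max"`), and
stops when every `CV_i = stdev(EM_i)/mean(EM_i)` (computed on unrounded
estimates) is below ε = 0.25, or at the iteration cap with `converged =
False`. Two numerical choices depart from the plainest reading and are
deliberate: candidates are clamped to ≥ 1 for retained segments (depth
above the deletion threshold implies presence; without the clamp, noiseless
skewed genomes such as copies (1, 1, 3, 4) oscillate or collapse copy-1
segments to zero), and zero-copy segments do not vote as calibrators (the
calibration constant `k = (N_tj/N_rj)(D_rj/D_tj)` is uninformative at
`N_tj = 0`). The estimator is exact on noiseless depths whenever the strict
modal copy number is 1, and scale-invariant under global rescaling of the
strain library.

## Reconstruction

The evidence graph has vertices `iL`/`iR` for every retained segment, `N_i`
parallel segment edges `iL—iR`, and the observed junction multiset as edges
(the published tandem-duplication ring construction is equivalent to the
parallel segment edges). A genome is an alternating Eulerian circuit —
segment edge, junction edge, segment edge, … — decoded to signed ids by
traversal direction. Feasibility requires junction-degree(`iL`) =
junction-degree(`iR`) = `N_i` at every vertex plus connectivity; this
balanced bicolored-degree condition was verified against brute-force
enumeration over all signed circular sequences with ≤ 5 segments and copies
≤ 2 (total length ≤ 6 — full brute force over length-10 sequences is not
tractable in this implementation language, but the covered range already
exercises parallel edges, self-pairs `{iR,iR}`, and multi-duplication
ambiguity).

Enumeration is depth-first over junction edges with sorted adjacency lists
(deterministic), anchored so the walk starts by traversing the smallest
retained segment in + orientation; decoded circuits are deduplicated by
canonical form. `count_genomes` counts canonical classes without storing
genomes (hashes only); a `rotations-fixed` convention that counts every
rotation and strand reading separately is provided because the counting
convention behind published feasible-solution totals is not stated.

Junction multiplicities: parental junctions default to the minimum of their
flanking copy numbers, novel junctions to 1, and an explicit multiplicity
column overrides both. `infer_junction_multiplicities` instead balances
degrees structurally — starting from 1 everywhere and incrementing only
junctions whose two half-sites both show a degree deficit (read support
breaks ties) — which resolves adjacencies reused by duplications without
trusting noisy support ratios.

### Long-insert filtering

Each long pair's two anchors are placed on every occurrence of their
segments in a candidate; the pair is PE if some placement is convergent with
an implied circular span inside [7500, 12500] bp (the aligner window used
for the real 10-kb libraries), SE if it places but never properly, unmapped
if a segment is absent. Candidates are rejected if SE pairs cluster (≥ 3
sharing a 1-kb anchor bin) or if any of their novel junctions is spanned by
zero PE pairs; among survivors the maximal regular-mapping rate wins and the
lexicographically smallest canonical form is reported (with no long pairs at
all, every candidate survives and the smallest is reported).

Two candidates that differ only by swapping or flipping duplicated arcs
whose separation is smaller than the ±2.5-kb window slack present identical
PE/SE/cluster/coverage statistics to this criterion and cannot be separated
by 10-kb pairs at any depth; with the fixture's short segments this leaves
roughly 5–8 % of duplication-bearing strains with 2–3 surviving candidates
(the true genome always among them). This mirrors the real study, where
long-insert filtering left a handful of strains with several feasible
solutions.

## Event classification

Relative to the parental order: maximal zero-copy parental runs are
deletions; maximal parental runs at copy ≥ 2 are matched to their contiguous
genome occurrences and classified tandem (one shared direction) or inverted
(alternating directions); maximal minority-orientation runs outside
duplicated regions that read as reversed consecutive parental intervals are
inversions. The dominant direction is the strict sign majority over the
whole molecule; an exact tie is treated as unclassifiable and falls through
to complex. Novel junctions not predicted by any event endpoint are
complex, with contiguous complex junctions merged into one complex event;
junctions predicted by two or more events (e.g. an inversion endpoint later
consumed by a deletion) are labelled `multiple`. Interleaved repeats that
defeat interval matching are deliberately left to the complex fallback
rather than guessed. On disjoint-span simulations classification recovers
the generating event list exactly; on overlapping events it degrades to
complex/multiple labels, never to wrong simple calls.

`event_distance` is the sum of parental segment lengths across the affected
arc (undefined for complex events), matching a "distance between the sites
prior to the event" reading.

## Statistics

- `fisher_one_sided`: exact hypergeometric upper tail (scipy), cross-checked
  in the tests against exhaustive fixed-margin enumeration for all margins
  ≤ 20. The slow-growth enrichment table (3,4,0,57) evaluates to
  8.40 × 10⁻⁴ (printed elsewhere rounded to one significant figure).
- `deletion_enrichment`: per-segment one-sided Fisher, significance at the
  Bonferroni family-wise threshold α/L (1.2 × 10⁻³ for α = 0.05, L = 43).
- `rate_equality_test`: conditional exact binomial test (x | x+y ~
  Binomial(·, ½)), two-sided by doubling the smaller tail, capped at 1; a
  `minlike` variant is provided since the convention behind published
  values is unstated. (93, 89) → 0.824; (50, 44) → 0.61 under doubling
  (0.66 under some conventions; not forced).
- `junction_type_null`: junction-type counts with half-site tallies
  `n_C = 2·CC + CU + CN` (cyclically), probabilities `p_X = n_X/2T`, and
  Poisson means `T·p_X·p_Y` (`T·p_X²` for like pairs) exactly as the
  counting scheme defines them — deliberately without a combinatorial
  factor 2 for unlike pairs, which is the published form; two-sided p by
  doubled smaller Poisson tail.
- `synthetic_lethal_sample_size`: `(2 ln T + ln 10)/d²` (the α = 0.05
  shorthand), with the exact `ln(P/α)/d²`, `P = T(T−1)/2`, behind
  `exact=True`. (43, 0.20) → 245.6; (5000, 0.05) → 7734.8.
- `trajectory_count`: exact big-integer `[C(n,2)]^k` or `[2·C(n,2)]^k`.
- `amplification_group_test`: two-sided two-sample t (pooled by default,
  Welch optional).

## Problem sizes used by the test suite

The acceptance-style suites run at desk scale chosen for coverage per unit
time: 200 round-trip strains (1–8 events, copies ≤ 3; duplication-bearing
strains additionally filtered with 1000 simulated 10-kb pairs, ~1.8×
physical coverage — far below real library depth, past the point where
uniqueness stops improving with depth), exhaustive oracle equivalence for
parents of 2–5 segments with total length ≤ 6, 500 noiseless + 200 noisy
copy-number strains, 5000 rate-test null simulations, and 300
disjoint-event classification strains. Each is seeded and deterministic.

## Known limitations

- Exact flank matching has no analogue of soft-clip/mismatch-tolerant
  breakpoint discovery; ectopic (non-loxPsym) rearrangements are out of
  scope by design.
- The depth model's per-base independence makes simulated depth noise
  optimistic for short segments; cross-mapping between homologous segments
  is not emulated, so the deletion threshold's real-data caveats are only a
  configurable parameter here.
- Mixed populations (two genomes in one sample) surface only as an
  infeasible evidence graph, not as a deconvolution.
- The published per-strain structures require the original sequencing data
  and are not reproduced here; all validation is simulation-based.
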