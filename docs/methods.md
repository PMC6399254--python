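# Methods

This note documents the models, parameter choices, and known limitations of
`omvar`, in the spirit of the methods documentation of mature simulation and
inference packages.

## The measurement model

A nick-label optical map is an ordered list of label positions along a DNA
molecule. Three error processes separate a molecule's map from the in silico
map of the region it came from:

- **Missed labels** (false negatives): each true label is observed with
  probability 1 − `fn_rate` (default 0.06).
- **False labels**: a Poisson process at `fp_per_100kb` (default 0.6) per
  100 kb of molecule length.
- **Sizing error**: each inter-label distance d is observed as d + ε with
  ε ~ Normal(0, σ(d)), σ(d)² = (1000·`sizing_sf`)² + (`sizing_sr`·d)², with
  defaults sf = 0.20 kb (additive) and sr = 0.01 (relative). These mirror
  the standard vendor alignment parameter conventions (`-sf` in kb).

Labels closer than the instrument resolution (`resolution_bp`, 450 bp) merge
into one label at the chain midpoint. Merging is transitive: a maximal chain
of labels with consecutive gaps ≤ 450 bp becomes a single label at the
midpoint of its first and last member; this never creates new
sub-resolution adjacencies, so the operation is idempotent.

Molecule lengths follow a log-normal law (σ = 0.55) whose location is solved
numerically so that, after truncation at the 150-kb length floor, the
length-weighted median (N50) is 262 kb. Only the floor and the N50 are
empirically grounded; the log-normal shape is a modelling choice. Coverage
defaults to 79×.

### What the simulator does not model

Fragile-site molecule breakage, chimeric molecules, stretch-factor drift
along a molecule, and assembly errors in consensus maps (contigs are
noise-attenuated copies of the haplotypes, fragmented at a configurable
Poisson rate, with per-process noise scaled by `consensus_factor`, default
1/√coverage). Passing tests therefore demonstrate correctness of the
algorithms under the stated error model, not performance on every artifact
of real data.

## Alignment

The aligner is a dynamic program over chains of (query label, reference
label) pairs maximizing

    Σ steps [ match_bonus − min(outlier_pen, (d_q − d_r)² / (sf_pen² + (sr_pen·d_r)²))
              − c_q·(skipped query labels) − c_r·(skipped reference labels) ]

with chain start and end free (local alignment), both orientations tried,
and at most K labels skippable per step. Defaults: match_bonus 3.0,
c_q = c_r = 1.5, sf_pen = 500 bp, sr_pen = 0.02, K = 12, outlier_pen = 6.

Two parameters deserve comment:

- **`outlier_pen`** caps the per-step sizing penalty. Without a cap, a chain
  meeting a large indel either breaks (no spanning evidence reaches the
  caller) or absorbs the size change into shifted mis-pairings, hiding the
  indel. With the cap, crossing an indel costs a bounded amount — the
  "outlier interval" device of production aligners. The value 6 (about two
  matched labels' worth of score) keeps one SV crossing from pushing a
  shorter molecule's alignment under the confidence floor.
- **`K = 12`** matches the skip depth of the standard vendor alignment
  practice; a deletion removing k reference labels needs K ≥ k to be
  crossed, so K must cover the largest indels in scope (~50 kb at 10-kb
  label spacing).

**Split alignment.** After the best chain is found, maximal runs of at least
`min_labels_per_segment` (5) unaligned labels — end flanks and interior gaps
alike — are re-aligned recursively. A long chain can also *absorb* an
inverted or translocated block at outlier cost; `refine_alignment` detects
windows of consecutive poorly fitting steps (penalty ≥ 0.4·outlier_pen;
inverted blocks produce elevated but not necessarily capped penalties
because point reflection preserves central distances), excises them, splits
the host segment, and re-aligns each window independently against all
references in both orientations. The result is a split alignment whose
segments partition the query.

**Confidence** is defined as −log₁₀ P(a label-shuffled query of the same
label count reaches the observed score at its best placement). The null is
estimated once per (reference, parameter set) from 10,000 permuted queries
(gap resampling from the pooled reference gap distribution), stratified into
label-count buckets, against a ~400-label reference window; the fitted
Gumbel location is shifted by scale·ln(N_total/N_window), using the
max-stability of the Gumbel family to account for the full search space. The
Gumbel right tail extends the empirical distribution beyond its 1/N
resolution, so the conventional filter threshold of 9 (p < 10⁻⁹) is
expressible; clean 20+-label alignments score far above it, and random
placements far below. The null seed derives deterministically from the
reference signature, so the calibration is a cached property of the
reference. An early-exit heuristic stops the orientation/reference search
once a placement reaches 85% of the maximum attainable score (no competing
placement can be meaningfully better).

## Indel calling

For every pair of nick sites adjacent on the reference *or on some aligned
map*, the caller collects the reference distance d₀ and the corresponding
distances d₁…dₙ on all maps whose alignments pair both sites (interior
unpaired labels contribute to distance, not to pairing; a pair made adjacent
on a molecule by deleted labels defines its own interval). Five hypotheses
about the true spanned length t are scored:

| hypothesis | t |
|---|---|
| H₀ | d₀ on both chromosomes |
| H_hom | d₀ + Δ |
| H_het(ins) | ½ mixture of d₀ and d₀ + Δ, Δ ≥ +2 kb |
| H_het(del) | same with Δ ≤ −2 kb |
| H_tri | ½ mixture of d₀ + Δ₁ and d₀ + Δ₂ |

Per-molecule likelihood: Normal(t, σ(t)) **plus a uniform contamination
component** (5% over a 500-kb window). The contamination term absorbs
mis-paired or chimeric spanning distances; without it, a handful of
shift-paired molecules at a homozygous SV drags the fit to the heterozygous
mixture. Mixture weights are fixed at ½ (the diploid expectation), which
stabilizes small-n fits. Δ is profiled by a coarse grid plus bounded local
refinement; H_tri is fitted by 2-component EM with 5 seeded restarts, and
its components must each exceed the 2-kb floor *and differ by at least
2 kb* — two indel alleles closer than the calling floor are not
distinguishable from a homozygous indel by this method, and an unconstrained
two-mean mixture overfits unimodal evidence by splitting the mean.

A call is emitted when the winning alternative's log₁₀ LR over H₀ reaches
`lr_cutoff_log10` (default 3), |Δ̂| > 2 kb, and the molecules better
explained by the variant component number at least `min_support` (default
10; the loose threshold 6 is used for high-confidence lists under uneven
molecule support, and is the setting of the validation studies). Overlapping
same-type calls from nested interval keys are reduced to the best-LR call,
localized to the tightest member interval. A fast path returns H₀ without
optimization when every |dᵢ − d₀| is below the size floor (no alternative
could win), which keeps genome-wide scans cheap.

The CR module calls |d_contig − d₀| > max(2 kb, 3σ(d₀)) discrepancies on
contig alignments without zygosity; MCR applies the MR statistics to
molecule alignments composed through each molecule's best-scoring contig.
Bagging normalization resamples a locus's molecules with replacement to
round(n · 10⁶ / total aligned molecules), a no-op for samples at or above
one million aligned molecules.

## Complex SVs

Candidates come from split alignments of consensus contigs. Query-adjacent
segment pairs are classified on the junction vector d (right junction bp −
left junction bp): different chromosomes → inter-chromosomal break end;
|d| > 5 Mb → intra-chromosomal break end; orientation flip within 5 Mb →
inversion; backward jump onto overlapping same-orientation intervals →
duplication (breakpoints = the unit interval). Molecules then vote:
split-aligned consistently with the candidate near its breakpoints
(window 200 kb) → supporting; contiguously aligned across the breakpoint →
rejecting, scored as if notionally split at the breakpoint. Each molecule's
score is `S_M = min over the two adjacent split maps of n/(n+l)·ln n`
(natural log; with more than two split maps, minimum over adjacent pairs).
After per-molecule de-duplication (largest score wins; a molecule on both
sides goes to its higher-scoring side), the candidate is accepted iff
`S_s > S_r` (strict).

For duplications, a rejecting molecule must anchor at least 20 kb outside
the unit on both sides: a single tandem copy with its flank is
reference-like over the unit's own coordinates and discriminates nothing.
Detectability floor: a duplicated unit (or any rearranged block) carrying
fewer labels than `min_labels_per_segment` cannot form a split segment and
is invisible to this module — the same kind of floor as the 4-label minimum
for the small-inversion search, which re-aligns poorly aligned contig
windows in reversed orientation (acceptance margin 3.0 score units; spans
over 5 Mb are re-typed as intra-chromosomal break ends). Adjudication with
`S_s ≈ S_r` is indecisive for heterozygous complex SVs (supporting and
rejecting molecules arrive in near-equal numbers); the validation studies
therefore implant homozygous complex SVs.

## Genome classification and population structure

The coverage-state classifier, the ≥3-recurrent-SV complexity rule (indels
count above 10 kb; an all-indel region needs one above 100 kb), the feature
filters (SDs ≥ 10 kb and ≥ 0.95 identity; tandem repeats score > 2000;
subtelomeric 7 Mb, pericentromeric 9 Mb), and the permutation overlap test
(uniform re-placement in allowed space, lengths preserved, overlap-event
count statistic, p = (1+k)/(n+1)) follow the standard population
optical-mapping study design. The 92× threshold is parameterizable as
(n_samples × fraction), its published form being 60% of 154 samples.
Permutation p-values are uniform only up to the discreteness of the count
statistic; validity checks use enough regions and features for the statistic
to be fine-grained. Boundary curation of complex regions is deterministic
(outermost qualifying SV ± one label interval) rather than manual.

Cross-sample SV merging uses single-linkage with reciprocal overlap ≥ 0.5
and size agreement within max(2 kb, 20%); insertions are compared on their
[start, start+size) footprint. The occurrence matrix codes hom = 2, het = 1,
unknown-zygosity presence = 1. The population tree is neighbor joining on
Euclidean distances between per-population allele-frequency vectors; PCA is
a plain SVD of column-centered allele counts (no frequency scaling), with a
deterministic sign convention. Sharing fractions are averaged over 100
balanced sub-samples. The size ANOVA is one-way across super-populations per
locus with ≥ 10 carriers, Bonferroni-corrected at α = 0.05.

Trio simulation transmits one whole haplotype per parent (chromosome-level
re-draws stand in for recombination when requested); trio studies draw both
parents' SVs from one shared non-overlapping locus pool, since independent
placement would fabricate colliding distinct SVs no real trio carries.

## Validation studies and problem sizes

The studies in `omvar.studies` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 150–200 implanted indels of 3–50 kb on
18–24 Mb of simulated genome at 79×; SV-free type-I replicates sharing one
5-Mb reference with independent molecule noise; 20 homozygous complex SVs
(5 per type) on 2×10 Mb; 10–20 trios on 3 Mb with 10 SVs per parent of
5–30 kb (bracketing the ~11 kb average size of the large-indel regime);
4-population nested cohorts (divergence F = 0.1 per split, 6 samples per
population, 60 loci) for topology recovery; and constructed cohorts for
sharing-fraction recovery. Sizes were chosen to give stable rates in minutes
on a single core.

## Known limitations

- Breakpoints are label-interval resolution, never basepair-precise.
- Indels below 2 kb are out of scope by design.
- Label-free insertions are invisible to distance-based calling only if
  shorter than the size floor; they are detected by distance but carry no
  interior label evidence.
- Heterozygous complex SVs are at the edge of the S_s > S_r rule's power.
- The confidence scale is internally calibrated; its threshold of 9 is
  comparable only within this package, not across aligners.
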