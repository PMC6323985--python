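# Methods

This note documents the models, numerical choices and known limitations of
`cistromeqc`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All coordinates everywhere in the package are 0-based half-open (BED
convention). The single exception is wiggle output, whose fixedStep
declaration is 1-based per the wig standard: a track starting at 0-based
position 0 is written with `start=1`. narrowPeak column 10 (summit offset)
value −1 is represented as *absent* (`None`), not as offset 0. Tag input is
a minimal 3-column TSV (chrom, 5′ position, strand); BED6 is also accepted,
with the 5′ position taken as `start` for + reads and `end − 1` for −
reads. BAM input is deliberately not a dependency — upstream pipelines
produce deduplicated positions anyway.

## Mappability

**Model.** A position i is mappable for read length k under exact matching
iff some m-mer starting at i with m ≤ k occurs exactly once in the
collection {chromosomes ∪ their reverse complements}. MUL[i] is the
smallest such m, or −1 if the suffix runs into a sequence boundary while
still ambiguous. Reads extend rightward only — this is the convention of
the underlying read-mapping problem, where a read's genomic coordinate is
its 5′ end on the forward strand.

**Algorithm.** All chromosomes and their reverse complements are
concatenated with separators; the suffix array is built by SA-IS (linear
time, integer alphabet), the LCP array by Kasai's algorithm, and MUL is
read off adjacent-rank LCP maxima: with L = max(LCP[i], LCP[i+1]) (LCP
beyond the last rank defined as 0), MUL[SA[i]] = L+1 if the symbol at
SA[i]+L is a base, else −1.

**Separators.** Each separator is a *distinct* symbol ordered below
A < C < G < T. A single repeated separator symbol would create spurious
long common prefixes between suffixes of different segments; distinct
symbols guarantee LCP values never extend across a segment boundary, so no
reported unique match can span one. Non-ACGT characters (N runs, IUPAC
ambiguity codes) are likewise replaced by distinct separators: a k-mer
containing them is never mappable, matching aligner behaviour, and such
positions get MUL = −1. Sequences are upper-cased; soft-masking carries no
meaning here.

**A subtlety worth recording:** the unmappable *fraction* is not exactly
invariant under reverse-complementing the input chromosomes, because MUL
reads extend rightward and positions near the 3′ end are truncated
differently in the two orientations (e.g. genome `AAC` has MUL [2,2,1] but
`GTT` has [1,2,−1]). The exactly conserved quantity — asserted by the
property tests — is the number of uniquely mappable k-*reads* (positions
i ≤ len−k with a unique k-mer), which bijects under i ↦ len−k−i. For
genomes much longer than max MUL the fraction difference is negligible.

**Scale.** The implementation is linear-time but pure Python; it is sized
for the package's synthetic and per-contig use. A whole human genome run
(the published ~12.4% unmappable at k=30 for GRCh38) is possible via
`scripts/grch38_unmappable.py` given the assembly FASTA and several
CPU-hours, and is not part of the test suite.

## Peak merging

Merging is single-linkage union of overlaps: two peaks join when they share
at least one base under half-open coordinates (abutting intervals do not
merge), and chains A–B–C collapse into one merged peak even when A and C
are disjoint. A merged peak's **frequency** is its number of constituent
peaks, *not* distinct callers — two overlapping peaks from the same caller
count 2. A per-caller presence vector is kept separately for Chapman's
two-source estimator. Clusters (one TF, one caller, across experiments) and
meta-clusters (clusters merged across callers) use the same geometry;
meta-cluster coordinates are the union span, with no summit re-estimation.
`min_callers` (default 1) optionally drops weakly supported meta-clusters.

## Capture–recapture estimators

The spectrum-based estimators assume homogeneous Poisson(λ) captures.
Numerical choices:

- **Chao** uses the bias-corrected form f₁(f₁−1)/(2(f₂+1)) when f₂ = 0, so
  it is defined for every non-empty spectrum.
- **Lanumteang–Böhning** is the three-frequency extension of Chao:
  f̂₀ = f₁²/(2f₂) · 3f₁f₃/(2f₂²) = 3f₁³f₃/(4f₂³). The multiplier has
  expectation 1 under homogeneous Poisson captures (checked by simulation
  in the tests) and exceeds 1 under capture-rate heterogeneity. Undefined
  unless f₁, f₂, f₃ > 0.
- **Zelterman**: λ̂ = 2f₂/f₁; undefined unless f₁, f₂ > 0.
- **ZTP MLE**: λ/(1−e^(−λ)) = T/S is strictly increasing in λ, so the root
  is bracketed on (10⁻⁸, 50] and found by bisection to absolute tolerance
  10⁻⁹ — derivative-free with guaranteed convergence. Undefined when
  T/S ≤ 1 (all singletons; N̂ would be unbounded).
- **Chapman** with more than two callers is the unweighted mean of the
  pairwise estimates over all caller pairs.

The expected peak count is the unweighted arithmetic mean of the *defined*
estimators; undefined ones are excluded rather than imputed. Every defined
estimate satisfies N̂ ≥ S.

## QC metrics

NRF, PBC1, PBC2 are computed on (chrom, pos5, strand) multisets exactly as
defined by ENCODE. FRiP counts a tag as in-peak by its 5′ position only
(half-open containment) — the simplest defensible convention, since
fragment length is not observed in the tag representation.

**Cross-correlation.** For shift d ∈ [0, max_shift], the Pearson
correlation between per-position + strand and shifted − strand 5′-count
vectors, per chromosome over the covered span, combined across chromosomes
by overlap-length weighting. cc_frag and the fragment-length estimate are
taken outside a ±5 bp exclusion zone around the read length (the phantom
peak); NSC = cc_frag/cc_min, RSC = (cc_frag−cc_min)/(cc_read−cc_min).
Errors are raised for single-stranded input and zero-variance coverage.
NSC/RSC are meaningful only when the baseline correlation cc_min is
positive, which in real data comes from the large-scale covariation of both
strands inside mappable/open regions; the synthetic generator reproduces
this by placing background tags in broad blocks (see below).

**FNCM** = observed peaks for one caller / expected peak count (mean of
estimators). Values well below 1 flag false negatives. The same pooled N̂
is used for every caller; no per-caller sensitivity adjustment is
attempted.

**FPCM** = observed f₁ / E[f₁] with E[f₁] = N̂·λ̂·e^(−λ̂), the Poisson pmf
at 1 scaled by the population size. Values well above 1 flag
caller-specific false positives. **λ̂ source:** the ZTP MLE, with Zelterman
as fallback. This was a genuinely open design point, settled empirically:
Zelterman's λ̂ = 2f₂/f₁ has the contaminant (excess f₁) in its own
denominator, so injected singleton noise *lowers* λ̂ enough that E[f₁]
overshoots and FPCM falls below 1 — the metric would point the wrong way.
The MLE's λ̂ depends on f₁ only through the aggregate mean T/S and keeps
FPCM ≈ 1 on clean data and monotonically increasing in the noise rate, as
the tests verify. No pass/fail thresholds are hard-coded; both metrics are
reported raw.

## PWM scanning

PCMs are converted to log₂-odds with a pseudocount (default 1.0)
distributed proportionally to the background (default uniform 0.25).

**Score threshold.** The threshold for p-value p is the smallest achieved
score t with P(score(random background word) ≥ t) ≤ p; tied scores form
one group (the tail probability at t counts every word scoring exactly t).
It is computed *exactly* by best-first branch-and-bound enumeration of the
score tail: partial words are expanded in order of an optimistic completion
bound, so complete words appear in non-increasing score order and only the
~p·4^L words at or above the threshold are ever visited — trivially few at
the site-prediction p = 10⁻⁴ even for long matrices. If the enumeration
would exceed a 2×10⁶-operation budget (very long matrices at loose
p-values), the implementation falls back to a discretized
dynamic-programming convolution of per-position score distributions, with
per-position scores rounded on a grid 4L times finer than the nominal bin
(10⁻³ of the matrix's total score range), keeping the accumulated rounding
below an eighth of a nominal bin. The enumeration path was chosen over the
DP as primary because discretization cannot, in principle, bound the
threshold error by one bin when a word lies within rounding distance of
the cutoff and the neighbouring achieved-score gap is wide.

**Scanning** reports all hits ≥ threshold on both strands (minus-strand
hits via the reverse-complemented matrix, coordinates on the forward
strand); windows containing N are skipped; overlapping hits are all
reported. On i.i.d. background the expected hit count is
2·(n−L+1)·P(score ≥ t), which ties the threshold semantics to the scanner
and is verified within sampling error by the tests.

## Synthetic data generator

The generator emits the world the estimators assume, with defaults chosen
as a realistic small experiment: four callers, Poisson(λ=1.5) captures,
200 bp sites (width jitter SD 20 bp, floor 50 bp), 10 bp placement jitter
— small relative to site width so single-linkage merging still groups true
detections — 147 bp fragments (nucleosomal), 36 bp reads, and
non-overlapping site placement with ≥ 100 bp gaps so positional jitter
cannot bridge adjacent sites.

Under the Poisson capture model, each site's Poisson(λ) captures are
attributed to uniformly random callers — a caller can contribute two
overlapping peaks at one site — which makes the merged-peak frequency
spectrum *exactly* zero-truncated Poisson, the estimators' model. The
per-caller Bernoulli model (independent detection with probability p per
caller) exercises robustness to model misfit: there the estimators carry a
small bias (binomial ≠ Poisson zero mass), which is why FNCM tracks p only
to within a few hundredths. False peaks are Poisson(noise_rate·N_true) per
caller at uniform positions. Background tags fall in broad 2 kb blocks
covering ~20% of the genome rather than uniformly: real libraries
concentrate in mappable open chromatin, and this large-scale two-strand
covariation is what keeps cc_min positive so NSC is interpretable.

What a green test does **not** establish: the generator has no sequence
content in its peaks (tags are positions, not reads), no
heterogeneous-affinity sites (all sites share one λ), no chromatin or
mappability coupling between modules, and no caller-specific width or
shift biases. Estimator performance under capture heterogeneity
(Mh models) is out of scope.

## Degenerate inputs and tie-breaking

- Empty genome, empty tag list, empty spectrum: errors naming the metric.
- Empty peak list into `frequency_spectrum`: S = 0 spectrum (not an error).
- PBC2 with no two-tag positions: +∞, serialized as the string `"inf"`.
- Merged/meta-cluster output is always sorted (chrom, start, end);
  estimator averaging is order-invariant by construction.
- Seeds: every generator takes either a `SimulationConfig.seed` or an
  explicit `numpy.random.Generator`; identical seeds give byte-identical
  outputs.

## Known limitations

- Pure-Python SA-IS limits whole-genome mappability runs to hours, not
  minutes; per-contig runs are practical.
- Cross-correlation builds dense per-chromosome count vectors over the
  covered span; extremely sparse tags over huge spans waste memory.
- The Chapman generalisation beyond two sources (pairwise mean) is a
  pragmatic choice; a log-linear multi-source model would use the full
  overlap pattern.
- FPCM's E[f₁] assumes the homogeneous Poisson capture model; under strong
  heterogeneity the baseline shifts away from 1 even without noise.
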