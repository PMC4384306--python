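# Methods

## Pattern family and codec

A gapped n-mer is a `{k, m}` string beginning and ending with `m`.  The
restriction reflects the modelling assumption that the pattern is the
*minimal* span of interacting positions: a leading or trailing ignored
position would describe the same dependence structure in a wider frame.
The type-ID codec (binary expansion, `0→k`, `1→m`, strip leading `k`s,
append `m`) is a bijection between `[0, 2^(f−1))` and the patterns of frame
length ≤ `f`; the package checks this exhaustively for frames up to 8.  The
default maximum frame of 6 gives 32 matrices, which keeps an exhaustive
sweep cheap and every matrix estimable from a small site collection (a
frame of 7 doubles the family to 64 and squares nothing else; it is a
constructor argument).

## Weight matrices

Background word frequencies are estimated by sliding the `l_n`-wide frame
over the background sequence and reading only the μ considered positions.
A Dirichlet pseudocount of `1/4^μ` per word with denominator `total + 1`
keeps every `e_b > 0` and makes the frequencies sum to exactly 1.  Site
counts receive the analogous smoothing (`+ e_b` in the numerator,
`L + 1` in the denominator), so the log-weights are finite for any input.
The per-column shift `c_i = −max_b` makes the column maximum exactly 0,
which in turn bounds the normalized score `S` in `[0, 1]`: the numerator
(sum of matched weights) and denominator (sum of column minima) are both
non-positive, and the denominator is the most negative value the numerator
can attain.  With at least one site and μ ≥ 1 the denominator is strictly
negative, since a word with zero counts always weighs less than the column
maximum; the degenerate all-zero column case cannot arise from real input
and is mapped to score 1 defensively.

Sequences are handled case-insensitively.  The formulas are defined only
over A/C/G/T, so ambiguity codes are excluded rather than imputed: aligned
sites containing them are rejected at load, background frames containing
them are excluded from both the count and the total, and scanning windows
containing them are skipped identically on true and scrambled peaks, which
keeps the null comparison symmetric.

## Thresholds

A threshold position `x ∈ [0, 1]` is converted to a score threshold τ by a
nearest-rank rule: τ is the largest *observed* site score such that the
fraction of sites scoring strictly below it is ≤ x.  No interpolation is
used — an interpolated quantile can exceed every observed score at that
rank, silently dropping the sites that define the percentile.  The rule
makes τ monotone in x, puts τ(0) at the weakest and τ(1) at the strongest
known site, and handles ties coherently (equal-scoring sites are all
identified or none).  The default sweep uses steps of 0.25 (five
positions); a 0.01 step (101 positions) is the fine-grained option.

## Peaks, scrambles, and the null

Peaks are trimmed to their central 100 bp (start offset `⌊(q−100)/2⌋`,
the even-parity choice when a single-base ambiguity is unavoidable);
shorter peaks are excluded and the exclusion count logged.  The false
positive model is `P = 100` uniform permutations of each peak's
nucleotides — the scramble preserves mononucleotide composition exactly
while destroying positional structure.  A dinucleotide-preserving shuffle
would additionally control neighbour correlations; it is intentionally not
implemented, as the plain permutation is the defining null here.
Scrambles are seeded per peak by hashing `(seed, peak_id)` into an
independent generator stream, so results are reproducible and independent
of peak order.  Scanning is forward-strand by default; `both_strands=True`
scores each window's reverse complement as well and keeps the maximum.

## Evaluation

Peak-level classification (positive iff any window scores ≥ τ) over the
threshold sweep yields TPR = TP/N and FPR = FP/(P·N); the ROC curve adds
the theoretical endpoints (0,0) and (1,1) when the sweep does not reach
them and is integrated with the trapezoidal rule.  Because the sweep is
over percentile positions of the known-site scores rather than all real
thresholds, the curve has at most `1/step + 3` points.

The RZ score compares, per peak, the integer site count `r` with the
rational mean scramble count `a` (denominator `P`).  The ±0.5 margin makes
the comparison decidable: the implementation uses exact integer arithmetic
(`2(P·r − Σ) vs P`), so boundary cases land deterministically in the
branch the defining inequalities dictate — a difference of exactly +0.5 is
borderline (z = 0.5) and exactly −0.5 is a miss (z = 0).  This asymmetry
means a pure chance predictor has expected RZ marginally *below* 0.5 (by
half the probability of landing exactly on −0.5, about 0.002 under the
default simulation geometry); the simulated baseline is reported rather
than the idealized constant.

The random-guesser simulation draws Binomial(windows, rate) counts per
peak and scramble, equivalent to independent Bernoulli calls per window;
at rates 0 and 1 every peak is borderline and RZ is exactly 0.5.

## Cross-matrix statistics

* **Chi-square**: Pearson's `Σ (O−E)²/E` over the three outcome
  categories (hits, borderlines, misses) of a matrix against a reference
  matrix (the mononucleotide `m` by convention), df = 2, significance
  bands at 0.05 and 0.01.  A category with expected count 0 leaves the
  statistic undefined; it is dropped with df reduced and a warning — the
  standard conservative fallback.  No multiple-testing correction is
  applied across the 31 × grid tests; bands are reported raw.
* **Correlation**: prediction vectors concatenate, peak by peak, the
  per-nucleotide counts of distinct predicted sites covering each
  position (length `N · l_c`).  Standard Pearson correlation is used; a
  constant vector (a matrix predicting nothing, or everything, at that
  threshold) has undefined correlation and is reported as r = 0 with a
  warning.
* **Clustering**: agglomerative clustering on `1 − r` distances with
  average linkage (UPGMA), the default pairing for correlation-derived
  distances; linkage is configurable.  The newick export uses the
  ultrametric convention (node height = half the merge distance) so
  leaf-to-leaf path lengths equal cophenetic distances.
* **Cross-validation**: RZ is re-estimated on random half-sized peak
  subsets drawn without replacement (100 replicates by default).  Since a
  peak's z does not depend on other peaks, subset RZ is the subset mean of
  precomputed z values; replicate spread measures the stability of the
  full-set score.

## Synthetic data

The generator emulates the three inputs: aligned sites drawn
position-independently from a probabilistic motif, 100-bp peaks carrying a
controlled number of motif draws planted at uniform non-overlapping
positions over an i.i.d. background, and an i.i.d. background sequence.
Defaults reflect a typical 7-bp-site experiment: site length 7 (consensus
TTTTTTG with 0.8 per-position dominance — a sharply defined but not
deterministic motif, comparable to footprint-derived site collections),
101 aligned sites, 3142 peaks of 100 bp, 100 scrambles per peak, uniform
base composition.  Uniform composition was chosen over a genome-specific
AT bias to keep the null exactly exchangeable; composition is a parameter.

What the generator deliberately does **not** emulate: positional
clustering of sites within peaks, flanking-sequence preferences, strand
asymmetry, dinucleotide background structure, and overlapping/offset
binding (the T-run redundancy of real HB-like sites).  Passing tests on
synthetic data therefore demonstrate correctness of the machinery and
qualitative recoverability of planted signal, not performance claims on
genomic data.

## Problem sizes

The test suite and the acceptance script run at desk scale: tens of peaks,
10–20 scrambles, 20–50 kb backgrounds — sizes at which every quantity is
also recomputable by the brute-force oracles the tests carry (naive
per-window scoring, naive UPGMA, hand-counted backgrounds).  The
random-guesser baseline uses 500 peaks × 20 scrambles × 94 windows × 20
replicates, large enough that the Monte-Carlo standard error of the mean
RZ is ≈ 0.005.  The full-genome, 3142-peak configuration of the defaults
runs unchanged, only longer.

## Known limitations

* Scoring assumes equal-length aligned sites; no alignment is performed.
* No FDR-based or background-calibrated thresholds — thresholds come from
  the known-site score distribution only.
* AUROC is reported without confidence intervals; the RZ replicate spread
  from cross-validation is the provided uncertainty measure.
* The per-pattern background pass re-scans the background sequence for
  each pattern; for genome-scale backgrounds and all 32 patterns this is
  the dominant cost (linear in genome length per pattern).
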