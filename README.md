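# gapmer

Systematic evaluation of **gapped n-mer weight-matrix models** of
transcription factor (TF) binding.

Classical position weight matrices (PWMs) treat every nucleotide of a
binding site independently; dinucleotide and n-mer models capture
dependence between *adjacent* positions only.  Real TF binding sites —
for example the T-rich sites of the *Drosophila* gap protein HUNCHBACK —
can show dependence between *non-adjacent* positions.  `gapmer` makes no
prior assumption about which positions interact: it enumerates **every**
dependence pattern up to a fixed frame width, builds one weight matrix per
pattern from the same aligned binding sites, and measures which pattern
best separates real ChIP peaks from composition-matched scrambled controls.

The package is aimed at regulatory genomicists who have (a) a set of
aligned, equal-length known binding sites, (b) ChIP peaks for the same
factor, and (c) a background sequence (typically the genome).

## The model

A *gapped n-mer* is a string over `{k, m}` — `m` marks a position that is
considered, `k` one that is ignored — that begins and ends with `m`.
Each pattern has an integer **type ID**: write the ID in binary, map
`0→k` / `1→m`, strip leading `k`s, append a terminal `m`.  With a maximum
frame of 6 the IDs 0–31 enumerate all 32 patterns (`m` = 0, `mm` = 1,
`mkkkkm` = 16, `mmmmmm` = 31).

For a pattern with μ considered positions and frame width `l_n = μ + κ`,
aligned sites of length `l` give a `4^μ × (l − l_n + 1)` weight matrix

    w_bi = ln( (n_bi + e_b) / (e_b (L + 1)) ) + c_i

where `n_bi` counts sites carrying word `b` at frame start `i`, `L` is the
number of sites, `e_b` is the pseudocount-smoothed background frequency

    e_b = (#frames matching b + 1/4^μ) / (#frames + 1)

and `c_i = −max_b ln(·)` shifts each column's maximum to 0.  A length-`l`
sequence σ scores

    S_σ = 1 − ( Σ_i w[word(σ,i), i] ) / ( Σ_i min_b w_bi )  ∈ [0, 1],

so the consensus scores 1 and the worst possible sequence 0.  Score
thresholds τ are set from a percentile position `x ∈ [0,1]` of the known
sites' own score distribution (`x = 0` keeps all known sites, `x = 1`
only the strongest).

Each matrix is evaluated against `P` composition-preserving scrambles of
every 100-bp peak: peak-level TPR/FPR over the threshold sweep give a ROC
curve and its trapezoidal **AUROC**, and at each single threshold the
**RZ score** is the mean over peaks of

    z = 1   if r − a > 0.5,     z = 0.5  if −0.5 < r − a ≤ 0.5,
    z = 0   if r − a ≤ −0.5,

with `r` the predicted-site count on the true peak and `a` the average
count on its scrambles.  A random guesser scores RZ ≈ 0.5.  Matrices are
then compared with chi-square tests on their (hit, borderline, miss)
tallies, Pearson correlation of per-nucleotide prediction vectors, and
UPGMA clustering on `1 − r` distances.

## Worked example

```python
import gapmer as g

spec = g.SyntheticSpec(
    motif=g.consensus_motif("TTTTTTG", 0.9),
    n_sites=101, n_peaks=50, sites_per_peak=2,
    background_length=50_000, seed=1,
)
sites, peaks, background = g.generate_fixtures(spec)

model = g.GappedMatrixAnalysis(
    sites, peaks, background, patterns=[0, 1, 16], n_scrambles=20, seed=1,
)
res = model.fit(threshold_step=0.25)
print(res.summary().round(3))
```

```
        pattern  mu  frame_length  n_frames  AUROC  RZ@x=0  RZ@x=0.25  RZ@x=0.5  RZ@x=0.75  RZ@x=1
type_id
0             m   1             1         7  0.900    0.91       0.93      0.86       0.86    0.86
1            mm   2             2         6  0.917    0.95       0.95      0.86       0.86    0.86
16       mkkkkm   2             6         2  0.698    0.71       0.80      0.80       0.80    0.80
```

Every matrix separates the planted peaks from their scrambles far better
than the 0.5 random baseline; the fully gapped `mkkkkm` matrix, which
reads only the two outer bases of each 6-bp frame, is weaker here because
the planted motif has no internal gap — exactly the behaviour the
cross-matrix statistics quantify:

```python
chi2 = res.chi2_vs_reference("mkkkkm", x=0.0)
#  chi2 = 35.200, df = 2, p < 0.01  -> mkkkkm's hit/borderline/miss tallies
#  differ significantly from the mononucleotide matrix m
print(res.cluster(0.0))
#  (mkkkkm:0.139,(m:0.029,mm:0.029):0.110);  -> m and mm predict almost the
#  same nucleotides; mkkkkm is the outlier
```

The same analysis runs from the shell on FASTA/BED inputs:

```sh
gapmer simulate -o fixtures --n-peaks 50
gapmer run --sites fixtures/sites.txt --peaks fixtures/peaks.fasta \
    --background fixtures/background.fasta -o results_dir
```

which writes per-pattern weight matrices, rate tables, AUROC and RZ
tables, chi-square comparisons, a correlation matrix, a newick dendrogram,
and a `manifest.json`.

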