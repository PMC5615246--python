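# aracne-kit

Reverse engineering of transcriptional regulatory networks from gene
expression matrices, in the ARACNE family: pairwise dependence between a
transcription factor (TF) and a candidate target is measured with
**adaptive-partitioning mutual information (apMI)** on ranked profiles, a
**permutation null model** turns a p-value into an MI cutoff, the **data
processing inequality (DPI)** prunes presumptively indirect edges from
TF–TF–target triangles, and an optional **bootstrap** stage consolidates
edges by occurrence count under a Poisson significance model with
Bonferroni correction.

The package is aimed at computational biologists who want a transparent,
fully tested, pure-Python implementation of this pipeline — for method
study, for benchmarking against ground-truth simulations, or for running
on moderately sized expression matrices — together with a synthetic-data
generator that produces networks with known wiring (including regulatory
cascades) so every stage can be validated end to end.

## The model

For genes *x*, *y* with expression ranked across *M* samples, MI is the
plug-in estimate

> I(x; y) = (1/M) Σᵢ log [ f(xᵢ, yᵢ) / (f(xᵢ) f(yᵢ)) ]   (nats)

with densities taken piecewise-constant on an adaptive partition of the
rank plane: starting from [0, M)², rectangles are quartered at interval
midpoints while the four quadrant counts reject local uniformity under a
chi-square test (critical value 7.815 = χ²₀.₀₅, df 3; rectangles with
fewer than 8 points are never split). The partition frontier is held in a
FIFO queue and traversed breadth-first; the queue provably stays small
(≤ M − 3 entries) and the traversal order does not change the estimate.
Ranking makes every result invariant to monotone transforms of the data.

Edges are kept when their MI exceeds the null cutoff: the empirical upper
quantile of n₀ MI values (default 100,000) computed on a row-permuted
matrix, with an exponential tail extrapolation for p-values below 1/n₀.
For every TF pair (t₁, t₂) and gene *g* with all three edges present, the
DPI — I(g₁; g₃) ≤ min(I(g₁; g₂), I(g₂; g₃)) for a Markov chain
g₁ → g₂ → g₃ — removes the strictly weakest edge of the triangle. With
*B* bootstraps, per-resample networks are accumulated into MI-sum and
occurrence-count matrices, and an edge seen *k* times is claimed when
P(Poisson(λ) ≥ k) · (#observed edges) < α, with λ the mean occurrence per
possible edge slot.

## Worked example

`python examples/03_dpi_chain.py` simulates the cascade TF1 → TF2 → G at
M = 500 and prints:

```
I(TF1;TF2) = 0.740 nats
I(TF2;G)   = 0.576 nats
I(TF1;G)   = 0.371 nats  <- indirect shortcut
edges after DPI: [frozenset({'G', 'TF2'}), frozenset({'TF1', 'TF2'})]
```

The shortcut TF1–G has the smallest MI of the triangle — exactly what the
DPI predicts for a Markov chain — so pruning leaves only the two direct
edges. `examples/04_full_pipeline.py` runs the whole pipeline on a
simulated 10-TF, 60-target network (41 true edges) and reports
`precision = 0.974, recall = 0.902`: nearly all direct links recovered,
with cascade shortcuts removed.

The same pipeline is available from the shell:

```sh
aracne-kit simulate --n-tf 10 --n-targets 60 --density 0.06 \
    --samples 300 --seed 0 --out-prefix toy
aracne-kit run --expression toy.expression.tsv --tfs toy.tfs.txt \
    --output network.tsv --pvalue 1e-4 --n0 5000 --seed 0
```

The output TSV has columns `Regulator  Target  MI  Count  AdjPvalue`
(count and adjusted Poisson p-value are meaningful in bootstrap mode).

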