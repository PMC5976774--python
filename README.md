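# cpca — contrastive principal component analysis

`cpca` finds low-dimensional structure that is **enriched in one dataset
relative to another**. PCA answers "where does this dataset vary most?";
contrastive PCA (cPCA) answers "where does my *target* dataset vary more
than a *background* dataset does?" — the question that matters when the
dominant variance is uninteresting: demographic variation shared by
cancer and control expression cohorts, cell-type heterogeneity shared by
pre- and post-treatment single-cell samples, texture shared by signal and
signal-free images. It is written for anyone who currently reaches for
PCA on sample-by-feature matrices (bulk or single-cell expression,
genotypes, images) and has a sensible comparison dataset.

## The method

Let `{x_i}` (target, n samples) and `{y_i}` (background, m samples) live in
`R^d` with empirical covariances `C_X`, `C_Y`. For a unit direction `v`
write the variance pair

```
lambda_X(v) = v' C_X v        lambda_Y(v) = v' C_Y v
```

Given a contrast strength `alpha >= 0`, the first contrastive principal
component (cPC) solves

```
v* = argmax_{|v|=1}  lambda_X(v) - alpha * lambda_Y(v)
```

which is exactly the leading eigenvector of `C = C_X - alpha * C_Y`; the
top-k cPCs are its leading eigenvectors by signed eigenvalue. `alpha = 0`
recovers PCA on the target; `alpha = inf` projects the target onto the
null space of the background before running PCA there. Geometrically the
cPCs sweep the lower-right Pareto frontier of the set of variance pairs
`U = {(lambda_X(v), lambda_Y(v))}`, each `alpha` picking the tangency
point of a slope-`1/alpha` supporting line — the `geometry` module turns
these facts into executable checks.

Because the only free parameter is `alpha`, the library scans a
logarithmic grid (alpha = 0 plus 40 values in [0.1, 1000]), clusters the
resulting subspaces by the product of the cosines of their principal
angles, and returns one *medoid* `alpha` per cluster: a handful of
genuinely different views to inspect instead of a knob to tune. A
kernelized variant (`cpca.kernel`) runs the same contrast in an RBF
feature space for nonlinear structure. cPCA is exploratory: it returns
directions and embeddings, not p-values.

## Worked example

`examples/subgroup_discovery.py` plants a two-subgroup mean shift in a
target dataset along an axis orthogonal to the strong covariance both
datasets share, then runs the automatic alpha scan:

```
medoid views (alpha, angle of cPC1 to planted axis, 2-means accuracy):
  alpha=   0.326   angle= 1.43 rad   accuracy=0.570
  alpha=   0.838   angle= 0.21 rad   accuracy=0.500
  alpha=    8.89   angle= 0.18 rad   accuracy=1.000
  alpha=     151   angle= 1.42 rad   accuracy=0.762
PCA baseline:          angle= 1.50 rad   accuracy=0.552
```

Reading the numbers: the `alpha = 8.89` medoid view aligns its first cPC
with the planted subgroup axis (0.18 rad) and its 2-d embedding separates
the subgroups perfectly under 2-means, while PCA's first component is
essentially orthogonal to the signal (1.50 rad ≈ pi/2) and clusters at
chance — the planted structure is invisible without the contrast. The
other examples cover the alpha-clustering spectrum, glyph-on-texture
images, the kernel variant on concentric rings, and the variance-pair
frontier.

The same pipeline is available from the shell:

```
cpca demo subgroup --seed 0 --out demo/
cpca auto --target demo/target.csv --background demo/background.csv --out results/
cpca fit  --target demo/target.csv --background demo/background.csv --alpha 2.0 --out results_a2/
```

CSV/TSV (header row of feature ids, optional `sample_id` column) and
MatrixMarket (`.mtx` plus `<stem>_features.txt` / `<stem>_samples.txt`)
inputs are supported, with `--top-dispersion N` to keep the N
highest-dispersion (variance/mean) target features first, as is standard
for expression matrices.

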