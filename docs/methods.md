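# Methods

This note documents the model behind `grnspa`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not establish about real data.

## Steady-state perturbation model

All components share one linear steady-state model. A gene regulatory
network is an N×N matrix *A* with `A[i, j]` the effect of regulator *j*
on target *i*; diagonal entries are negative self-decay terms that keep
the dynamics stable and are never counted as regulatory links. A
single-knockdown screen is encoded by the design matrix *P* (−1 at the
perturbed gene, 0 elsewhere; *r* replicates concatenate *r* copies of
−I into an N×rN matrix), and the steady-state log₂ fold-change response
is

    Y = −A⁻¹ (s·P)

where *s* is the actual knockdown size in log₂ units. The −1 entries of
*P* are indicators — the analyst knows *which* gene was perturbed, not
by how much — so inference and selection only ever see *Y* and the
indicator *P*. The benchmark default is *s* = 3 (an 8-fold knockdown),
which gives fold changes of realistic magnitude (self-responses of
about −3 log₂ units). This matters beyond realism: the prediction
safeguard threshold is 1/max(*Y*), and multi-log₂-unit fold changes are
what keep that threshold comfortably below the singular values of
reasonable candidate networks, as it is in real fold-change data. With
unit-strength knockdowns, max(*Y*) ≈ 1 and the threshold would sit
exactly on the candidates' singular-value bulk, making predictions
knife-edge dependent on rounding.

## Synthetic gold standards

`generate_true_network` emulates the statistics of curated bacterial
regulatory subnetworks rather than extracting them from a database:

- `round(sparsity · N)` non-self-loop links, default sparsities in the
  benchmark span 1.5–1.95 links/gene;
- regulators drawn from a TF subset (default 53% of genes, reflecting
  that only about half of the genes in such subnetworks have outgoing
  edges) with preferential attachment, producing hub-heavy out-degree
  distributions;
- off-diagonal weights uniform in [0.5, 1.5] with random sign, diagonal
  −1;
- off-diagonal weights are then shrunk by a constant factor until the
  spectral abscissa is below −0.01 **and** the condition number is at
  most `cond_max` (default 8).

The condition bound is deliberate. With stability alone, random signed
networks routinely come out with condition numbers of 50–200; the
steady-state response is then dominated by a single near-critical
direction, which empirically destroys both the edge ordering of L1
paths and the monotone badness-of-fit trend — no selection criterion
can recover either. Bounding the amplification keeps the simulated
screen in the regime where perturbation inference is informative, which
is the regime the benchmark is meant to probe. `cond_max` is exposed for
experiments with harder conditions.

## Noise model

`add_noise` adds i.i.d. Gaussian noise at a target signal-to-noise
ratio defined spectrally: SNR = σ_min(Y)/σ_max(E), the weakest signal
direction over the strongest noise direction. The noise standard
deviation is calibrated analytically from the expected extreme singular
value of an N×M Gaussian matrix, E[σ_max] ≈ σ(√N+√M), and the realized
SNR fluctuates around the target with the sampling variation of that
extreme (within ~10% in the test suite). Presets: "low" noise = SNR 10,
"high" noise = SNR 0.1. These are named stand-ins chosen to produce a
clearly easy and a clearly hard regime; they bracket the qualitative
behavior (near-maximal recovery at SNR 10, near-chance recovery at
SNR 0.1).

Replicates share one design but receive independent noise draws (the
noise matrix spans all rN columns).

## Inference backends

All backends fit the inverted steady-state relation A·Y ≈ −P row by
row — each network row is a penalized regression of the corresponding
design row on the expression matrix — and return a *sparsity sweep*:
one candidate per integer link count between `round(min_lpg·N)` and
`round(max_lpg·N)` (for 100 genes and 1–5 links/gene, 401 candidates).

- **Relaxed lasso** (default L1 backend). A shared 200-point
  logarithmic penalty grid runs from the smallest penalty that zeroes
  every coefficient down to 10⁻⁴ of it; the support at each grid point
  is collected, missing integer link counts are filled by truncating
  the next denser support to its k largest-|weight| entries, and each
  candidate's weights are then re-estimated by ordinary least squares
  on its own support (diagonal always included). The refit step removes
  the L1 shrinkage bias: without it, sparse candidates are
  systematically attenuated, their largest singular values fall below
  the 1/max(Y) safeguard, and their predictions zero out — flattening
  the badness-of-fit curve precisely where selection needs resolution.
  Support selection, and hence edge accuracy, is identical with or
  without the refit (`refit=False` restores the raw path).
- **Ridge with cutoffs**: one dense L2 fit (penalty 1.0 by default; no
  canonical value exists, so it is configurable), thresholded to each
  target link count by |weight|.
- **Tree-ensemble importances**: per-gene random-forest regressions of
  each gene on all others (√(N−1) features per split, seedable), with
  **reversed** edge direction — the importance of gene *j* in
  predicting gene *i* yields the edge *i*→*j*, i.e. the predicted gene
  becomes the regulator, the empirically stronger orientation for
  knockdown data. All weights are nonnegative importances; candidates
  are unsigned and are fed to the pseudoinverse predictor as-is.

Keep-k ties at equal |weight| break deterministically by (|weight|
descending, regulator index, target index). Keep-k candidates are
nested, and diagonal (self-loop) entries of the source network are
carried into every candidate: they are not links, but a candidate
stripped of its self-decay terms would be near-singular and could not
predict expression.

## The criterion

For each candidate: K_raw = number of genes with at least one
off-diagonal outgoing edge (a gene regulating only itself is not a
regulator); the prediction Ŷ = −A†P uses an SVD pseudoinverse with
singular values below 1/max|Y| zeroed (max of the *measured* matrix;
the max-abs convention keeps the threshold positive — a signed-max
variant is available); the raw badness of fit is the RMS difference
after dividing each matrix by its own max-abs entry (RMS chosen for
smoothness and scale-freeness; a zero matrix is left unscaled). If every
singular value of a candidate falls below the threshold the candidate
is flagged degenerate and predicts zero.

The normalization chain across the sweep is: min–max scale the raw
errors to [0, 1] → exponentiate → min–max normalize again, giving L;
min–max normalize K_raw, giving K; GRNIC = K + L. The exponential
mirrors AIC's log-likelihood on the error scale; the pre-scaling bounds
its argument so the transform is comparable across datasets; the
post-normalization makes the two addends commensurate. Exact order of
these steps is an interpretation fixed here — both terms are
constructed to span [0, 1] on every run. Degenerate rules: a term that
is constant across the sweep (including single-candidate sweeps)
normalizes to all-zeros; ties at the minimum resolve to the smaller
link count (parsimony). Alternative transforms (square, cube,
log(1−·)) are deliberately not part of the public contract.

## Evaluation

Edge accuracy is directed and sign-blind on non-self-loop edges:
an edge is correct when its (regulator, target) pair appears in the
gold standard, regardless of weight sign — necessary for the unsigned
tree backend to be scored on the same footing. F1 = 2tp/(2tp+fp+fn),
defined as 0 when tp = 0. Per-sweep reports include the max-F1
candidate and compare true, selected, and max-F1 sparsities in
links/gene.

The experiment-wise shuffle control permutes gene values within each
column of a predicted matrix: it preserves each experiment's value
distribution while destroying gene identity. Structured predictions
score markedly worse after shuffling, and the decreasing
badness-vs-density trend disappears, confirming the fit signal reflects
network structure rather than value ranges.

## Problem sizes and determinism

The test suite and the acceptance script run the benchmark at five
50-gene networks × 3 replicates with the L1 backend (a few seconds per
network), 100-gene sweeps for cardinality checks, and 15–30-gene
systems for unit-level properties. All randomness flows through
explicit integer seeds: network topology, noise draws, forest
construction, and shuffles are all reproducible, and the pipeline
manifest records the seed and configuration of every run.

## Known limitations

- The simulator is linear and steady-state: no mRNA/protein kinetics,
  no saturation, no time courses. Real fold-change data adds
  model-mismatch error on top of measurement noise, so passing
  benchmarks here demonstrate correctness of the selection machinery,
  not expected field performance.
- Selection quality is bounded by the inference method: at the
  high-noise preset no backend recovers much structure, and the
  criterion can only pick the least-bad candidate.
- Occasional aberrant cases occur (roughly one network in five at the
  low-noise preset): the penalty term can dominate when regulator count
  grows faster than the fit improves, pushing the selection toward the
  sparse end of the sweep. This is a property of the criterion itself,
  not of the implementation.
- Undirected networks and AUPR/AUROC-style full-spectrum evaluation are
  out of scope.
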