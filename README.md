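# sparsetrack

Sparse microbial source tracking with unknown-source estimation.

A *sink* microbiome sample (an OTU/ASV count vector) is modeled as a convex
combination of many candidate *source* samples plus one aggregate *unknown*
source. When candidate panels are large — e.g. assembled from public
repositories — most candidates contribute nothing, and unpenalized
source-tracking estimators smear mass across these nuisance sources.
`sparsetrack` selects the few truly contributing sources and estimates their
mixing proportions together with the unknown fraction.

## Model

For a sink `x` over `N` taxa and candidate sources `Y_1..Y_M` with latent
relative-abundance profiles `γ_i` (rows summing to 1):

```
β_j  = Σ_{i=1}^{M+1} α_i γ_ij
Y_i  ~ Multinomial(C_i, γ_i)          i = 1..M+1
x    ~ Multinomial(C, β)
α_i  ~ Exp(λ) · 1{Σ_{i≤M} α_i ≤ 1}    i = 1..M
```

where `α` (length M+1, summing to 1) are the mixing proportions, entry M+1
the unknown source, and the truncated exponential prior with rate `λ`
shrinks known-source mass. Inference has two stages:

1. **Screening** — L1-penalized, simplex-constrained least squares in
   relative-abundance space:
   `min ‖Γᵀα − x̂‖² + λ‖α‖₁  s.t.  α ≥ 0, Σα ≤ 1`,
   solved by accelerated projected gradient. The nonnegative part of the
   fit residual, rescaled to counts, becomes the unknown source's plug-in
   pseudo-count profile.
2. **Penalized EM** — for each `λ` on a grid, EM alternates exact updates:
   responsibilities `p(i|j) = α_i γ_ij / β_j`; profile update
   `γ_ij ∝ x_j p(i|j) + y_ij`; and an exact α-maximization via 1-D dual
   root finding. The fit with the highest observed-data log-likelihood is
   returned.

Accuracy is summarized by three functionals against ground truth: MSE
(summed squared proportion error over candidates), AE (absolute error of
the unknown proportion) and FPR (total mass misattributed to
non-contributing sources).

## Worked example

Simulate a 50-candidate panel in which 10 sources contribute and 40% of the
sink comes from a hidden unknown community, then deconvolve it:

```python
import numpy as np
from sparsetrack import SimulationConfig, SparseSourceTracker, build_dataset, evaluate

config = SimulationConfig(
    n_taxa=500, n_candidates=50, n_contributing=10,
    unknown_prop=0.4, n_sinks=1, seed=7,
)
panel = build_dataset(config)
problem, truth = panel.problems[0], panel.true_alphas[0]

est = SparseSourceTracker().fit(problem)
report = evaluate(truth, est.proportions_)

print(f"selected lambda       : {est.lambda_:g}")
print(f"EM iterations         : {est.n_iter_}")
print(f"candidates selected   : {len(est.support_)} of {problem.n_sources}")
print(f"estimated unknown     : {est.unknown_proportion_:.3f} (true 0.400)")
print(f"MSE over candidates   : {report.mse:.5f}")
print(f"false-positive mass   : {report.fpr:.4f}")
top = np.argsort(est.proportions_[:-1])[::-1][:3]
for i in top:
    print(f"  {problem.source_ids[i]}: est {est.proportions_[i]:.3f}  true {truth[i]:.3f}")
```

Output:

```
selected lambda       : 0.01
EM iterations         : 12
candidates selected   : 27 of 50
estimated unknown     : 0.339 (true 0.400)
MSE over candidates   : 0.00136
false-positive mass   : 0.0844
  S046: est 0.372  true 0.375
  S036: est 0.085  true 0.094
  S028: est 0.054  true 0.044
```

The estimator recovers the dominant contributors at close to their true
proportions, attributes most of the remaining mass to the unknown source,
and leaves under a tenth of the sink on the 40 nuisance candidates.

`SparseSourceTracker` follows scikit-learn conventions (`fit`,
`get_params`/`set_params`, trailing-underscore fitted attributes,
`clone`-compatible), so it composes with sklearn tooling. Equivalent
functional APIs live in `sparsetrack.selection`, `sparsetrack.em`,
`sparsetrack.simulate` and `sparsetrack.metrics`.

## Command line

```
sparsetrack simulate --n-candidates 50 --n-contributing 10 --n-sinks 30 \
    --unknown 0.4 --depth 10000 --seed 1 --out panel/
sparsetrack track --counts panel/counts.tsv --metadata panel/metadata.tsv \
    --out results/ --seed 1
sparsetrack evaluate --estimates results/proportions_sink_001.tsv \
    --truth panel/truth.tsv --sink-id sink_001 --out report.tsv
```

Count tables are TSV (taxa × samples or the transpose, stated explicitly —
orientation is never guessed); metadata is TSV with columns
`SampleID`, `Env`, `SourceSink`. All commands are deterministic given their
inputs and seed.

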