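# Methods

## Generative model

A sink count vector `x` over `N` taxa is treated as a multinomial sample of
`C` reads from the mixture `β_j = Σ_{i=1}^{M+1} α_i γ_ij`, where the `γ_i`
are latent relative-abundance profiles of `M` observed candidate sources
plus one unobserved ("unknown") source, and `α` is the vector of mixing
proportions (`Σ α_i = 1`). Observed source counts `Y_i` are themselves
multinomial realizations of `γ_i` at depth `C_i`, so source profiles are
estimated jointly rather than plugged in as exact. Sparsity enters through
an exponential prior with rate `λ` on the known proportions `α_1..α_M`,
truncated to `Σ_{i≤M} α_i ≤ 1`; the unknown proportion is unpenalized and
absorbs whatever the candidates cannot explain.

The penalized observed-data objective maximized by the EM (additive
constants dropped) is

```
l(α, γ) = Σ_j x_j log β_j + Σ_{i=1}^{M+1} Σ_j y_ij log γ_ij − λ Σ_{i≤M} α_i
```

where row M+1 of `Y` holds the unknown source's plug-in pseudo-counts
(below). Including the plug-in row's data term keeps the objective the
exact quantity the γ-update maximizes, which is what makes the
per-iteration monotonicity checked by the tests hold.

## Screening and initialization

EM on this likelihood is non-convex, and with hundreds of candidates the
initialization decides which basin is reached. The screening step solves

```
min_α ‖Γᵀα − x̂‖² + λ_sel ‖α‖₁   s.t. α ≥ 0, Σ_{i≤M} α_i ≤ 1
```

with `x̂ = x/C` and `Γ` the observed source profiles `Y_i/C_i`. Because
`α ≥ 0`, the L1 term is the linear functional `λ_sel Σα`, so the problem is
a smooth convex QP over the capped simplex; it is solved by FISTA with an
explicit Euclidean projection onto `{α ≥ 0, Σα ≤ 1}` (clip at zero, else
sort-based simplex projection), to a projected-gradient fixed-point
tolerance of 1e-10. Entries below `support_tol = 1e-8` are zeroed; those
zeros are preserved by the EM (a source with `α_i = 0` receives zero
responsibility and zero updated mass), so the screening support is the
selection.

`λ_sel` defaults to 1e-6, the value a half-split cross-validation over
simulated sinks selects (held-out mean squared taxon residual is flat below
~1e-4 and rises steeply above it; `cross_validate_lambda` re-derives this
on any panel). For a single sink, cross-validation is skipped and the
default used.

**Unknown plug-in.** The unknown source's pseudo-counts are the nonnegative
part of the screening residual, rescaled to counts:

```
Ŷ_{M+1} = C · max(0, x̂ − Γᵀα̂)
```

This subtracts *all* selected sources. Subtracting only the top selected
source was considered and rejected: when several sources contribute, the
top-only residual still contains the other contributors' profiles, the
likelihood becomes flat along the trade-off between their proportions and
the unknown's, and the prior then resolves the tie by handing everything to
the unknown (absolute error on a 40% unknown rises to ~0.3–0.4). The
full-residual plug-in removes that degeneracy (that variant remains
available as `init_unknown_profile(..., subtract="top_source")`). The
plug-in row is held fixed across EM iterations as pseudo-data; the
unknown's γ row still updates.

Initial proportions: the screened `α̂` with mass `1 − Σα̂` on the unknown;
if the screen selects nothing, uniform over candidates with 50% unknown.

## EM updates

- E-step: `p(i|j) = α_i γ_ij / Σ_{i'} α_{i'} γ_{i'j}`; columns with zero
  mixture mass get the uniform distribution over active sources (they carry
  zero weight in every M-step sum unless the sink has reads there, in which
  case the log-clamp below applies).
- γ-step: `γ_ij ∝ x_j p(i|j) + y_ij`, rows renormalized, applied to all
  M+1 rows.
- α-step: maximizes `Σ_i c_i log α_i − λ Σ_{i≤M} α_i` on the probability
  simplex with `c_i = Σ_j x_j p(i|j)`. Stationarity gives
  `α_i = c_i/(λ+ν)` for known sources and `α_{M+1} = c_{M+1}/ν`; the
  multiplier `ν` solving `Σ α(ν) = 1` is bracketed (halving from an upper
  bound `Σc + λ + 1`) and found by Brent's method to 1e-12. When
  `c_{M+1} = 0` the system degenerates and the closed form applies:
  `α = c/Σc` if `λ ≤ Σc`, else `α_i = c_i/λ` with the remainder on the
  unknown. `c_i = 0` maps to an exact zero.

The full-simplex equality `Σ_{i=1}^{M+1} α_i = 1` is enforced (it implies
the prior's truncation constraint and keeps `α` a distribution for the
E-step). Convergence is declared when the relative change of the penalized
objective drops below `tol` (default 1e-6; the EM property tests use
tighter values since at count depths of 10⁴ the objective magnitude makes
1e-6 a loose absolute bar). Iteration cap 1000. Logs of `β` and `γ` are
clamped at 1e-12; the residual-based unknown profile makes taxa with reads
but no mixture mass rare.

## Choosing λ

EM runs once per value of the grid (default `1e-8 … 1e-2`, log-spaced) from
the same initialization, and the state with the highest observed-data
log-likelihood wins, ties toward the larger (sparser) λ. The comparison
excludes the prior's `−λΣα` and `M log λ` terms: `M log λ` differs by
hundreds of nats across the grid and would make selection monotone in λ
regardless of fit. At typical read depths (10⁴) the exponential prior is a
weak force against the multinomial likelihood, so in practice sparsity is
driven by the screening support and λ acts as a mild shrinkage refinement
— consistent with the screening penalty itself being cross-validated to a
small value.

## Synthetic data

The simulator emulates the benchmark design used to evaluate sparse source
tracking: `M` candidate communities plus one hidden unknown, each
subsampled to a fixed depth (default 10,000 reads — sinks use the same
default, a symmetric choice); a fixed contributing subset of size `K`;
per-sink mixing vectors drawn from a Pareto II (Lomax) distribution
(shape 1.0 by default) scaled to `1 − unknown_prop`, with the unknown
proportion appended; sinks drawn multinomially from the implied mixture.
Defaults are `M = 50`, `K = 10`, 30 sinks, 500 taxa. When no real table is
supplied, base communities use independent log-normal taxon weights
(σ = 2.0), giving the skewed rank-abundance structure of real communities.
Nuisance sources for spiked panels are manufactured by abundance shuffling:
richness drawn uniformly between the real sources' min and max
nonzero-taxon counts, taxa chosen uniformly, counts drawn without
replacement (per synthetic source) from the pool of real nonzero counts.

What the simulator does not emulate: phylogenetic or co-occurrence
structure among taxa, environmental gradients between sources (profiles
are exchangeable draws), overdispersion beyond multinomial sampling, and
compositional artifacts of amplicon processing. Passing the recovery tests
therefore shows the estimator inverts its own generative model at
realistic depths and panel sizes — not that it is robust to real-data
effects outside that model.

The Lomax form of the mixing draw (support starting at zero) was chosen
over the classical `x_m = 1` Pareto because it produces the intended
heavy-tailed dominance: the largest mixed proportion exceeds that of a
uniform draw in ≳90% of trials at shape 1.0, which the `x_m = 1` form does
not.

## Evaluation metrics

`mse` is the *sum* of squared proportion errors over the M candidates (the
benchmark convention; `mean=True` gives the conventional mean), `ae` the
absolute error of the unknown proportion, and `fpr` the total estimated
mass on sources whose true proportion is exactly zero — exact zeros are
taken from the simulator's constructed truth, so no tolerance is applied.
For any estimate on the simplex, FPR + mass on true contributors +
estimated unknown = 1.

## Baseline

`baseline_em` is the estimator with the sparse-selection contribution
removed: uniform initial proportions over all M+1 sources, observed
profiles, a selection-free unknown plug-in `max(0, x − mean_i Y_i)`, and
λ = 0 — the classical unpenalized mixture EM that established
source-tracking tools implement. On spiked panels it spreads roughly 8–10%
of the sink over nuisance sources where the sparse estimator leaves 3–4%,
and its unknown estimate degrades accordingly; the acceptance script
recomputes this comparison.

## Numerical and design notes

- Problem assembly keeps the union of taxa observed in the sink or any
  candidate (zero-filled); sink-only taxa are retained because they are
  precisely the evidence for the unknown source.
- Count tables must be integer counts; relative abundances are rejected
  (the multinomial model is defined on reads).
- Orientation of count tables is declared by the caller, never guessed.
- Ties in argmax (top source, CV λ, grid-search λ) break deterministically:
  lowest index for sources, larger value for penalties.
- All simulation randomness flows through one `numpy` generator seeded
  from the config, so panels and exports are byte-reproducible.
- Test and verification problem sizes (e.g. the 20-candidate,
  5-contributing recovery panel; 100 randomized monotonicity instances at
  M ≤ 10, N ≤ 50) are chosen to exercise the same regimes as the full
  design at a fraction of the cost; the full 50-candidate design runs in
  the worked example.

## Known limitations

- The unknown profile is a plug-in, not re-estimated between iterations;
  with very large true unknown fractions (>90%) and strongly overlapping
  sources its residual construction can misallocate mass.
- The exponential prior is weak at high read depth (see above); users
  wanting penalty-driven shrinkage at depth 10⁵+ would need λ values on
  the order of the read count, outside the default grid.
- Per-sink independence: multiple sinks are fit separately; no information
  is shared across sinks beyond the screening penalty's cross-validation.
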