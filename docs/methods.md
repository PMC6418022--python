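# Methods

This note records the model assumptions, the numerical choices, and what
the synthetic test-bed does and does not establish.

## Sequence model and preprocessing

A record is treated as a circular sequence over `{A, C, G, T}`. Cleaning
uppercases, maps `U → T`, and silently drops every other symbol while
counting it in a `CleaningReport`; complete mtDNA records contain only
rare ambiguity codes, and dropping (rather than erroring or keeping a
third state) keeps every walk step strictly ±1. Cleaning never reorders
retained symbols.

Realignment to a common origin (e.g. placing the control region of the
heavy strand at the end of the record) is an explicit per-record circular
rotation supplied by the user as a 0-based breakpoint table. The package
does not locate the D-loop itself: annotation-driven detection is a
separate problem, and published pipelines rarely state a reproducible
procedure for it. Rotation changes the scaling exponents (the walk is
re-threaded) but none of the composition statistics.

## Walks and estimators

Both exponent estimators consume the ±1 **increments**, not the walk
positions; each builds its own cumulative profile internally. Feeding
positions would integrate twice and measure a different process.

**DFA** (first order). Profile `y_k = Σ_{i≤k}(x_i − x̄)`; non-overlapping
windows of length `L` tile the profile from the start; a least-squares
line is removed per window; `F(L)` is the RMS of the residuals over the
covered points. When `L` does not divide `n`, the trailing `n mod L`
points are excluded and the normalizer is the number of covered points —
this keeps `F(L)` an RMS rather than mixing in uncovered zeros. Only
first-order detrending is offered.

**R/S**. Per block of length `L`: the range of the cumulative deviations
from the block mean, divided by the block's population standard
deviation; averaged over `⌊n/L⌋` blocks. Zero-variance blocks are
skipped; window sizes whose blocks all degenerate are dropped. No
Anis–Lloyd small-sample correction is applied, so on short uncorrelated
series the estimate sits above 0.5 (the test suite brackets it at
0.50–0.65 for n = 4096). This is the naive estimator family and is
documented as a caveat rather than corrected, because the downstream
indices are calibrated against published values produced by the same
estimator family.

**Window grid.** ~40 log-spaced integer sizes between 4 and `⌊n/2⌋`
(odd `n` rounds down), deduplicated. Log spacing gives each octave equal
weight in the regression; a dense integer grid would overweight large
`L`. The regression is ordinary least squares of `ln(stat)` on `ln L`
(the slope is base-invariant); `r²` is reported with every estimate and
exceeds 0.95 on i.i.d. input.

Degenerate inputs fail loudly: constant steps give an identically zero
DFA profile and zero-variance R/S blocks, and both estimators raise a
`DegenerateSeriesError` rather than returning a meaningless slope.

## Composition statistics

Probabilities are per sequence, never pooled across records. Entropy is
computed directly in base 2 with the `0·log 0 = 0` convention, so exact
binary compositions give exact entropies (the equiprobable case returns
exactly 2.0 bits). ξ with zero purines is returned as an explicit
undefined flag (`None`) instead of infinity, so the failure surfaces at
the index computation with a clear message rather than as a silent
non-finite number. The entropy profile drops windows that would overhang
the sequence end; partial windows would mix window sizes within one
profile.

`D` and `C` are computed and exported but deliberately excluded from the
indices: on real mtDNA compositions `D` tracks `H` almost linearly and
`C = H·D` adds no independent signal.

## Indices

The logarithms in v1–v3 are **natural, at both nesting levels**. This is
the one genuinely underdetermined constant in the construction; it was
fixed by recomputing all 96 published index values for the 32-species
reference table from their published inputs — natural logs reproduce
every value to ≲3×10⁻⁴, while base-2 or base-10 do not come close. The
fixture tolerance of 5×10⁻³ reflects the 4–5-decimal rounding of the
printed inputs, not estimator noise. The DFA fractal dimension uses the
same `2 − exponent` transform as the Hurst one.

For exponents in (0, 1), `ln(2 − e) ∈ (0, ln 2)`, so the indices are
defined whenever ξ > 0; empirical mtDNA inputs always give negative
values because the outer argument is below 1. Inputs outside (0, 1)
raise `IndexDomainError`.

## Clustering

Textbook UPGMA on the Euclidean distance matrix in (v1, v2, v3) space:
merge the pair with minimal average inter-cluster distance at height =
average/2; update distances as size-weighted averages. Ties are broken
by the lexicographically smallest leaf label of each cluster, making
trees reproducible under input permutation. Indices are **not**
standardized by default (a z-score option exists); the reference
construction gives no indication of scaling, and the raw index ranges
are comparable. Cophenetic distance equals twice the height of the
lowest common ancestor; since heights are non-decreasing along the merge
order, the tree is ultrametric, and the Newick export preserves this
(branch length = parent height − child height, leaves at height 0).

## Synthetic test-bed

* `gen_iid` — i.i.d. bases; the equiprobable case is the
  maximum-entropy/random-walk null (H → 2, ξ → 1, β → 0.5).
* `gen_markov_steps` — two-state ±1 chain, stay probability (1+ρ)/2, so
  the lag-1 autocorrelation is exactly ρ. Its correlations are geometric
  (summable), so the DFA slope returns to 0.5 at large windows — the
  short-memory control that separates "correlated" from "long memory".
* `gen_longmemory_steps` — fractional Gaussian noise with Hurst
  parameter h, synthesized exactly by circulant spectral embedding
  (verified against the analytic autocovariance across replications),
  then sign-thresholded to ±1. Exact ±1 long-memory processes are hard
  to construct; signing a Gaussian maps autocorrelation ρ to
  (2/π)·arcsin ρ, preserving the power-law tail, at the cost of a small
  downward bias in the recovered exponent (h = 0.8 recovers β ≈ 0.75 at
  n = 16384). The recovery tolerance of ±0.1 absorbs this bias.

What passing tests show: the estimators distinguish no memory, short
memory and long memory at mtDNA-scale lengths, and the index algebra
matches its published values. What they do not show: that real genomes
satisfy the generators' stationarity — real mtDNA has gene structure,
strand asymmetry and a hypervariable control region, none of which the
generators emulate. Exact reproduction of published exponent tables from
raw GenBank sequences is correspondingly not claimed; the estimator
variant behind any particular published table (windowing, corrections)
is rarely fully specified, and the indices are validated at the algebra
level instead.

## Problem sizes and determinism

The null-calibration and recovery checks use series of length 16384
(comparable to a mitochondrial genome) with 20–50 replicate seeds —
enough for the slope means to stabilize well inside the stated bands.
All generators are fully determined by an integer seed; the acceptance
script derives per-replicate seeds from a single `--seed` via
`numpy.random.SeedSequence.spawn`.

## Known limitations

* R/S without small-sample correction overestimates α on short series.
* The CLI processes whole records; per-region (gene-block) indices are
  out of scope.
* Automatic control-region detection is not provided; rotations are user
  input.
* Bootstrap support and tree-comparison metrics are not implemented.
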