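"""Long-range-correlation exponents of ±1 step series.

Two estimators are provided, both operating on the increments (the ±1
steps), with the integrated profile built internally:

* :func:`hurst_rs` — classic rescaled-range (R/S) analysis. For each block
  size L the series is cut into ⌊n/L⌋ non-overlapping blocks; each block
  contributes the range of its cumulative-deviation profile divided by its
  standard deviation; the Hurst exponent α is the slope of log⟨R/S⟩ against
  log L. No small-sample (Anis–Lloyd) correction is applied, so α carries
  the naive estimator's finite-sample upward bias on short series.

* :func:`dfa_exponent` — detrended fluctuation analysis (first order).
  The profile y_k = Σ_{i≤k}(x_i − x̄) is cut into non-overlapping windows
  of length L, a least-squares line is removed per window, and the root
  mean square of the residuals over the covered points is the fluctuation
  F(L); the DFA exponent β is the slope of log F(L) against log L.
  Uncorrelated steps give β = 0.5; persistence gives β > 0.5.

Window sizes run from 4 to ⌊n/2⌋ (odd n rounds the maximum down), on a
log-spaced integer grid (~40 sizes) so each octave carries equal weight in
the regression. Fits use ordinary least squares on natural logs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .walks import StepSeries

DEFAULT_N_WINDOWS = 40
MIN_WINDOW = 4


class DegenerateSeriesError(ValueError):
    """Raised when a series has no usable fluctuation (e.g. constant steps)."""


@dataclasses.dataclass(frozen=True)
class ScalingEstimate:
    """A scaling exponent with its per-window statistics and fit diagnostics.

    ``exponent`` equals ``slope`` — the log–log regression slope of the
    per-window statistic (mean R/S, or F(L)) against window size.
    ``B`` is the largest block size used, at most ⌊n/2⌋.
    """

    method: str  # "RS" or "DFA"
    exponent: float
    window_sizes: np.ndarray
    stat_per_window: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    B: int

    def fractal_dimension(self) -> float:
        """The fractal dimension 2 − exponent of the walk (see module docs)."""
        return fractal_dimension(self.exponent)


def window_grid(
    n: int,
    l_min: int = MIN_WINDOW,
    l_max: int | None = None,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> np.ndarray:
    """Log-spaced integer window sizes in [l_min, l_max] (default [4, n//2]).

    Sizes are rounded to integers and deduplicated, so short series yield
    fewer than ``n_windows`` sizes.
    """
    if l_max is None:
        l_max = n // 2
    if l_min < 2:
        raise ValueError(f"l_min must be >= 2, got {l_min}")
    if l_max < l_min:
        raise ValueError(f"l_max={l_max} < l_min={l_min} (series too short?)")
    grid = np.unique(
        np.rint(np.exp(np.linspace(np.log(l_min), np.log(l_max), n_windows))).astype(int)
    )
    return grid[(grid >= l_min) & (grid <= l_max)]


def dfa_profile(steps: StepSeries) -> np.ndarray:
    """The integrated mean-centered profile y_k = Σ_{i≤k}(x_i − x̄)."""
    x = steps.steps.astype(float)
    return np.cumsum(x - x.mean())


def dfa_fluctuation(profile: np.ndarray, L: int) -> float:
    """RMS fluctuation F(L) after per-window linear detrending.

    Windows of length L tile the profile from the start; the trailing
    ``n mod L`` points are excluded and the normalizer is the number of
    covered points, keeping F(L) a root mean square.
    """
    n = profile.size
    m = n // L
    if m < 1:
        raise ValueError(f"window size {L} exceeds series length {n}")
    y = profile[: m * L].reshape(m, L)
    t = np.arange(L, dtype=float)
    tc = t - t.mean()
    denom = (tc * tc).sum()
    if denom == 0.0:  # L == 1: residuals are identically zero
        return 0.0
    slope = (y * tc).sum(axis=1) / denom
    resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * tc
    return float(np.sqrt((resid * resid).sum() / (m * L)))


def _loglog_fit(sizes: np.ndarray, stats_: np.ndarray, method: str, B: int) -> ScalingEstimate:
    fit = stats.linregress(np.log(sizes), np.log(stats_))
    return ScalingEstimate(
        method=method,
        exponent=float(fit.slope),
        window_sizes=np.asarray(sizes, dtype=int),
        stat_per_window=np.asarray(stats_, dtype=float),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        B=int(B),
    )


def dfa_exponent(
    steps: StepSeries,
    l_min: int = MIN_WINDOW,
    l_max: int | None = None,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> ScalingEstimate:
    """First-order DFA exponent β of a ±1 step series.

    Requires n ≥ 16 so at least two window sizes fit between 4 and ⌊n/2⌋.
    Raises :class:`DegenerateSeriesError` when every fluctuation vanishes
    (constant steps make the profile identically zero).
    """
    n = steps.n
    if n < 16:
        raise ValueError(f"DFA needs n >= 16, got {n}")
    sizes = window_grid(n, l_min=l_min, l_max=l_max, n_windows=n_windows)
    if sizes.size < 2:
        raise ValueError("fewer than 2 valid window sizes; series too short")
    profile = dfa_profile(steps)
    fluct = np.array([dfa_fluctuation(profile, int(L)) for L in sizes])
    keep = fluct > 0.0
    if not keep.any():
        raise DegenerateSeriesError(
            "all fluctuations are zero (constant step series has no profile)"
        )
    if keep.sum() < 2:
        raise DegenerateSeriesError("fewer than 2 window sizes with nonzero fluctuation")
    return _loglog_fit(sizes[keep], fluct[keep], "DFA", B=int(sizes.max()))


def hurst_rs(
    steps: StepSeries,
    l_min: int = MIN_WINDOW,
    l_max: int | None = None,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> ScalingEstimate:
    """Rescaled-range Hurst exponent α of a ±1 step series.

    Blocks with zero standard deviation are skipped; a window size whose
    blocks are all skipped is dropped. Raises
    :class:`DegenerateSeriesError` if fewer than two sizes survive.
    """
    n = steps.n
    if n < 16:
        raise ValueError(f"R/S needs n >= 16, got {n}")
    sizes = window_grid(n, l_min=l_min, l_max=l_max, n_windows=n_windows)
    if sizes.size < 2:
        raise ValueError("fewer than 2 valid window sizes; series too short")
    x = steps.steps.astype(float)
    kept_sizes, kept_stats = [], []
    for L in sizes:
        m = n // L
        blocks = x[: m * L].reshape(m, L)
        centered = blocks - blocks.mean(axis=1, keepdims=True)
        z = np.cumsum(centered, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        sd = blocks.std(axis=1)
        valid = sd > 0.0
        if not valid.any():
            continue
        kept_sizes.append(int(L))
        kept_stats.append(float(np.mean(rng[valid] / sd[valid])))
    if len(kept_sizes) < 2:
        raise DegenerateSeriesError(
            "fewer than 2 window sizes with nonzero block variance"
        )
    return _loglog_fit(
        np.array(kept_sizes), np.array(kept_stats), "RS", B=int(max(kept_sizes))
    )


def fractal_dimension(exponent: float) -> float:
    """Fractal dimension of a walk from its scaling exponent: 2 − exponent.

    Valid for exponents in (0, 1]; the result lies in [1, 2).
    """
    if not 0.0 < exponent <= 1.0:
        raise ValueError(f"exponent must be in (0, 1], got {exponent}")
    return 2.0 - exponent


def write_scaling_table(estimate: ScalingEstimate, path) -> None:
    """Export (L, statistic) pairs for log–log plotting."""
    from pathlib import Path

    col = "F" if estimate.method == "DFA" else "RS"
    with Path(path).open("w") as fh:
        fh.write(f"L\t{col}\n")
        for L, s in zip(estimate.window_sizes, estimate.stat_per_window):
            fh.write(f"{L}\t{s:.10g}\n")
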