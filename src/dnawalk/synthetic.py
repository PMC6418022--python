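"""Synthetic sequences and step series with controlled composition and
correlation structure.

Three generators cover the null and alternative regimes of the scaling
estimators:

* :func:`gen_iid` — i.i.d. bases with arbitrary probabilities; the
  equiprobable case is the maximum-entropy null (H → 2 bits, ξ → 1,
  DFA β → 0.5).
* :func:`gen_markov_steps` — a two-state ±1 chain with stay probability
  (1 + ρ)/2, so the lag-1 autocorrelation is ρ. Correlations are summable,
  hence β → 0.5 at large window sizes: short memory, not long memory.
* :func:`gen_longmemory_steps` — fractional Gaussian noise with Hurst
  parameter h synthesized exactly by circulant (spectral) embedding, then
  sign-thresholded to ±1. Signing a Gaussian maps autocorrelation ρ to
  (2/π)·arcsin ρ, which preserves the power-law tail, so the series keeps
  its long-memory exponent with a small downward finite-sample bias.

Every generator is fully determined by its seed and exact in length.
"""

from __future__ import annotations

import numpy as np

from .seqio import ALPHABET, NucleotideSequence
from .walks import StepSeries


def gen_iid(
    n: int,
    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | None = None,
) -> NucleotideSequence:
    """Draw n bases independently with probabilities (p_A, p_C, p_G, p_T)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError(f"probs must be 4 non-negative values summing to 1, got {probs}")
    rng = np.random.default_rng(seed)
    symbols = "".join(rng.choice(list(ALPHABET), size=n, p=p / p.sum()))
    return NucleotideSequence(id=f"iid_n{n}_seed{seed}", symbols=symbols)


def gen_iid_steps(n: int, seed: int | None = None) -> StepSeries:
    """Fair-coin ±1 steps — the random-walk null for DFA and R/S."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return StepSeries(rule="iid", steps=rng.choice((-1, 1), size=n))


def gen_markov_steps(n: int, rho: float, seed: int | None = None) -> StepSeries:
    """Two-state ±1 Markov chain with P(stay) = (1 + ρ)/2.

    ρ = 0 reduces to i.i.d. fair-coin steps; ρ → 1 gives long runs but the
    correlation is still geometric (short memory).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    stay = (1.0 + rho) / 2.0
    flips = rng.random(n) >= stay  # True = switch state before emitting
    flips[0] = False
    state0 = 1 if rng.random() < 0.5 else -1
    signs = np.where(np.cumsum(flips) % 2 == 0, 1, -1)
    return StepSeries(rule=f"markov_rho{rho:g}", steps=state0 * signs)


def _fgn_autocovariance(h: float, n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (
        np.abs(k - 1) ** (2 * h) - 2 * k ** (2 * h) + (k + 1) ** (2 * h)
    )


def fgn(n: int, h: float, seed: int | None = None) -> np.ndarray:
    """Fractional Gaussian noise, unit variance, by circulant embedding.

    The autocovariance γ(k) = ½(|k−1|^{2h} − 2k^{2h} + (k+1)^{2h}) is
    embedded in a 2n-circulant whose eigenvalues are non-negative for
    h ∈ (0, 1); the first n coordinates of a complex spectral sample then
    carry exactly the fGn covariance.
    """
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must be in (0, 1), got {h}")
    gamma = _fgn_autocovariance(h, n)
    circ = np.concatenate([gamma[: n + 1], gamma[n - 1:0:-1]])
    eigs = np.fft.fft(circ).real
    # tiny negatives from roundoff only; clip rather than fail
    eigs = np.clip(eigs, 0.0, None)
    rng = np.random.default_rng(seed)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # Re(ifft(sqrt(λ) z)) has covariance circulant(γ)/m per unit z-variance;
    # the sqrt(m) rescale makes the first n coordinates exact fGn.
    sample = np.fft.ifft(np.sqrt(eigs) * z) * np.sqrt(m)
    return sample.real[:n]


def gen_longmemory_steps(n: int, h: float, seed: int | None = None) -> StepSeries:
    """±1 long-memory steps: sign of fGn with Hurst parameter h.

    Requires h ∈ (0.5, 1) — the persistent regime the DFA recovery tests
    target. A power-of-two n makes the FFT embedding fastest but any n ≥ 1
    works. The sign-thresholding attenuates the effective exponent slightly
    below h.
    """
    if not 0.5 < h < 1.0:
        raise ValueError(f"h must be in (0.5, 1), got {h}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    g = fgn(n, h, seed=seed)
    steps = np.where(g >= 0.0, 1, -1).astype(np.int64)
    return StepSeries(rule=f"fgn_h{h:g}", steps=steps)


def write_steps_tsv(steps: StepSeries, path) -> None:
    """Export a step series as TSV (index, step) with the generator label
    echoed in a header comment for provenance."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(f"# rule={steps.rule} n={steps.n}\n")
        fh.write("index\tstep\n")
        for i, s in enumerate(steps.steps, start=1):
            fh.write(f"{i}\t{s}\n")
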