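"""Compositional information statistics of a nucleotide sequence.

For one sequence of length M with base counts N_A, N_C, N_G, N_T and
empirical probabilities p_i = N_i / M:

* Chargaff ratio   ξ = (N_C + N_T) / (N_A + N_G) — pyrimidines over purines
  on one strand; ξ > 1 means a pyrimidine excess.
* Shannon entropy  H = −Σ p_i log2 p_i, in bits; maximum log2(4) = 2 at
  equiprobability, with the convention 0·log 0 = 0.
* Disequilibrium   D = Σ (p_i − 1/4)², the squared distance from the
  equiprobable composition; 0 at equiprobability, maximum 3/4 when a single
  base fills the sequence.
* LMC complexity   C = H·D — entropy weighted by disequilibrium; vanishes
  at both extremes (uniform and single-base compositions).

Probabilities are always computed per sequence, never pooled across
records. All four statistics depend on the composition only, so they are
invariant under any permutation (in particular, any circular rotation) of
the sequence.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .seqio import ALPHABET, NucleotideSequence


@dataclasses.dataclass(frozen=True)
class CompositionSummary:
    """Counts, probabilities and information statistics for one sequence.

    ``xi`` is ``None`` when the sequence contains no purines (division by
    zero); every other field is still populated. Downstream consumers must
    check before using ξ.
    """

    id: str
    counts: tuple[int, int, int, int]  # N_A, N_C, N_G, N_T
    M: int
    probabilities: tuple[float, float, float, float]
    xi: float | None
    H: float
    D: float
    C: float

    @property
    def xi_defined(self) -> bool:
        return self.xi is not None


@dataclasses.dataclass(frozen=True)
class EntropyProfile:
    """Local Shannon entropy in sliding windows (the 'entropic microscope').

    Windows of length ``window`` start every ``step`` positions; windows
    that would overhang the end of the sequence are dropped.
    """

    id: str
    window: int
    step: int
    start_positions: np.ndarray  # 0-based window starts
    values: np.ndarray  # H per window, bits


def _counts(symbols: str) -> np.ndarray:
    arr = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)
    return np.array([int((arr == ord(b)).sum()) for b in ALPHABET])


def shannon_entropy(probabilities: np.ndarray) -> float:
    """H = −Σ p_i log2 p_i in bits, with 0·log 0 = 0.

    Computed directly in base 2 (not by base conversion) so exact binary
    probabilities give exact entropies: the equiprobable four-base case
    returns exactly 2.0.
    """
    p = np.asarray(probabilities, dtype=float)
    nz = p[p > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def disequilibrium(probabilities: np.ndarray) -> float:
    """D = Σ (p_i − 1/4)² over the four base probabilities."""
    p = np.asarray(probabilities, dtype=float)
    return float(((p - 0.25) ** 2).sum())


def summarize(seq: NucleotideSequence) -> CompositionSummary:
    """Compute counts, p_i, ξ, H, D and C = H·D for one sequence."""
    n = _counts(seq.symbols)  # A, C, G, T
    M = int(n.sum())
    p = n / M
    purines = int(n[0] + n[2])
    pyrimidines = int(n[1] + n[3])
    xi = pyrimidines / purines if purines > 0 else None
    H = shannon_entropy(p)
    D = disequilibrium(p)
    return CompositionSummary(
        id=seq.id,
        counts=tuple(int(v) for v in n),
        M=M,
        probabilities=tuple(float(v) for v in p),
        xi=xi,
        H=H,
        D=D,
        C=H * D,
    )


def entropy_profile(seq: NucleotideSequence, window: int, step: int = 1) -> EntropyProfile:
    """Local Shannon entropy over non-overhanging windows.

    Each window's H uses that window's own empirical probabilities.
    """
    M = seq.M
    if not 1 <= window <= M:
        raise ValueError(f"window must be in [1, {M}], got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    starts = np.arange(0, M - window + 1, step)
    values = np.empty(starts.size)
    for i, s in enumerate(starts):
        n = _counts(seq.symbols[s:s + window])
        values[i] = shannon_entropy(n / window)
    return EntropyProfile(
        id=seq.id, window=window, step=step, start_positions=starts, values=values
    )


def write_entropy_profile(profile: EntropyProfile, path) -> None:
    """Export (start, H) pairs as TSV."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("start\tH\n")
        for s, h in zip(profile.start_positions, profile.values):
            fh.write(f"{s}\t{h:.10g}\n")
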