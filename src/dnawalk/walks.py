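"""DNA-walks: map a sequence to ±1 steps under a biochemical dichotomy and
accumulate the walk path X_n = x_0 + sum_{i<=n} x_i with x_0 = 0.

Three rules partition the alphabet:

* ``RY`` — purine {A, G} -> +1, pyrimidine {C, T} -> -1 (transversion axis)
* ``SW`` — strong bond {C, G} -> +1, weak bond {A, T} -> -1 (GC content)
* ``KM`` — amino {A, C} -> +1, keto {G, T} -> -1
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .seqio import NucleotideSequence

#: Bases mapped to +1 under each rule; the complement maps to -1.
RULES: dict[str, frozenset[str]] = {
    "RY": frozenset("AG"),
    "SW": frozenset("CG"),
    "KM": frozenset("AC"),
}


@dataclasses.dataclass(frozen=True)
class StepSeries:
    """An ordered ±1 step series x_1 ... x_n.

    ``rule`` records the provenance of the encoding: one of the biochemical
    rules for sequence-derived series, or a generator label for synthetic
    series.
    """

    rule: str
    steps: np.ndarray

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=np.int64)
        object.__setattr__(self, "steps", steps)
        if steps.size == 0:
            raise ValueError("step series must contain at least one step")
        if not np.isin(steps, (-1, 1)).all():
            raise ValueError("steps must all be +1 or -1")

    @property
    def n(self) -> int:
        return int(self.steps.size)


@dataclasses.dataclass(frozen=True)
class WalkPath:
    """Walk positions X_1 ... X_n (X_0 = 0 implicit)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size == 0:
            raise ValueError("walk path must contain at least one position")
        increments = np.diff(np.concatenate(([0], pos)))
        if not np.isin(increments, (-1, 1)).all():
            raise ValueError("consecutive walk positions must differ by exactly 1")

    @property
    def n(self) -> int:
        return int(self.positions.size)

    @property
    def final(self) -> int:
        """Endpoint X_M = (#+1 steps) − (#−1 steps)."""
        return int(self.positions[-1])


def map_steps(seq: NucleotideSequence, rule: str) -> StepSeries:
    """Encode a cleaned sequence as ±1 steps under ``rule``.

    The mapping is position-wise and deterministic: each base maps to +1 if
    it belongs to the rule's positive class, else −1.
    """
    try:
        positive = RULES[rule]
    except KeyError:
        raise ValueError(f"unknown walk rule {rule!r}; expected one of {sorted(RULES)}")
    arr = np.frombuffer(seq.symbols.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int64)
    for base in positive:
        lut[ord(base)] = 1
    return StepSeries(rule=rule, steps=lut[arr])


def walk(steps: StepSeries) -> WalkPath:
    """Accumulate steps into the walk path of running partial sums."""
    return WalkPath(positions=np.cumsum(steps.steps))


def write_walk_trace(steps: StepSeries, path: str | Path) -> None:
    """Export a TSV trace: 1-based step index, step, position.

    A leading ``0\\t0\\t0`` row encodes the implicit origin X_0 = 0 so plotted
    traces start at zero.
    """
    pos = walk(steps).positions
    with Path(path).open("w") as fh:
        fh.write("index\tstep\tposition\n")
        fh.write("0\t0\t0\n")
        for i, (s, p) in enumerate(zip(steps.steps, pos), start=1):
            fh.write(f"{i}\t{s}\t{p}\n")
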