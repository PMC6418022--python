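"""Sequence input/output: FASTA reading with cleaning, circular rotation,
and tab-separated tables for features, walk traces and rotation coordinates.

All coordinates are 0-based, half-open. Non-ACGT symbols (IUPAC ambiguity
codes, gaps, whitespace artefacts) are removed during reading and tallied
in a :class:`CleaningReport`; ``U`` is mapped to ``T`` first so RNA-style
records survive intact.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

ALPHABET = ("A", "C", "G", "T")
_VALID = frozenset(ALPHABET)

#: Column order of the feature table (one row per sequence).
FEATURE_COLUMNS = (
    "id", "xi", "H", "D", "C",
    "alpha_RY", "alpha_SW", "alpha_KM",
    "beta_RY", "beta_SW", "beta_KM",
    "v1", "v2", "v3",
)


@dataclasses.dataclass(frozen=True)
class NucleotideSequence:
    """A cleaned nucleotide sequence S = s_1 ... s_M over {A, C, G, T}.

    Mitochondrial genomes are circular molecules, so ``circular`` defaults
    to True; :func:`rotate` refuses to act on linear sequences.
    """

    id: str
    symbols: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError(f"sequence {self.id!r} has no symbols")
        bad = set(self.symbols) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT symbols {sorted(bad)}; "
                "clean it first (see clean_symbols)"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def M(self) -> int:
        """Sequence length (number of retained symbols)."""
        return len(self.symbols)


@dataclasses.dataclass(frozen=True)
class CleaningReport:
    """Audit record of what cleaning removed from one raw record."""

    n_removed: int
    removed_symbols: tuple[tuple[str, int], ...]  # (symbol, count), sorted
    original_length: int

    @classmethod
    def from_counter(cls, removed: Counter, original_length: int) -> "CleaningReport":
        return cls(
            n_removed=sum(removed.values()),
            removed_symbols=tuple(sorted(removed.items())),
            original_length=original_length,
        )


def clean_symbols(raw: str) -> tuple[str, Counter]:
    """Uppercase, map U->T, drop everything outside {A,C,G,T}.

    Returns the cleaned string and a Counter of dropped characters
    (as they appeared after uppercasing). Retained symbols keep their
    relative order.
    """
    upper = raw.upper().replace("U", "T")
    kept = []
    removed: Counter = Counter()
    for ch in upper:
        if ch in _VALID:
            kept.append(ch)
        else:
            removed[ch] += 1
    return "".join(kept), removed


def read_fasta(
    path: str | Path, circular: bool = True
) -> list[tuple[NucleotideSequence, CleaningReport]]:
    """Read a multi-record FASTA file into cleaned sequences.

    Each record yields a ``(NucleotideSequence, CleaningReport)`` pair in
    file order. The full header line (description) is stored as the id.

    Raises ``ValueError`` on an empty file, a file with no FASTA records,
    or a record whose symbols are all removed by cleaning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        raw = str(rec.seq)
        cleaned, removed = clean_symbols(raw)
        if not cleaned:
            raise ValueError(
                f"record {rec.description!r} in {path} has no valid ACGT symbols"
            )
        seq = NucleotideSequence(
            id=rec.description or rec.id, symbols=cleaned, circular=circular
        )
        out.append((seq, CleaningReport.from_counter(removed, len(raw))))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as uncompressed FASTA with fixed line width."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.symbols), width):
                fh.write(seq.symbols[i:i + width] + "\n")


def rotate(seq: NucleotideSequence, breakpoint: int) -> NucleotideSequence:
    """Rotate a circular sequence so position ``breakpoint`` becomes position 0.

    The new symbol order is ``symbols[breakpoint:] + symbols[:breakpoint]``;
    the multiset of symbols is unchanged. Used to realign mitochondrial
    records to a common origin (e.g. placing the H-strand control region at
    the end, in the direction of transcription).
    """
    if not seq.circular:
        raise ValueError(f"cannot rotate non-circular sequence {seq.id!r}")
    if not 0 <= breakpoint <= seq.M:
        raise ValueError(
            f"breakpoint {breakpoint} out of range [0, {seq.M}] for {seq.id!r}"
        )
    k = breakpoint % seq.M
    return dataclasses.replace(seq, symbols=seq.symbols[k:] + seq.symbols[:k])


def read_rotation_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of ``id<TAB>breakpoint`` (0-based) rotations."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "breakpoint"],
                     dtype={"id": str}, comment="#")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in rotation table: {dups}")
    return {row.id: int(row.breakpoint) for row in df.itertuples()}


def write_feature_table(rows: Sequence, path: str | Path, decimals: int = 10) -> None:
    """Serialize feature vectors to a TSV with the canonical column order.

    ``rows`` may be any objects exposing the :data:`FEATURE_COLUMNS`
    attributes (duck-typed so this module stays independent of the index
    layer). Floats are written fixed-point with ``decimals`` places
    (default 10, enough to round-trip every feature exactly at table scale).
    """
    if not rows:
        raise ValueError("cannot write an empty feature table")
    if decimals < 5:
        raise ValueError("feature tables carry at least 5 decimals")
    data = {col: [getattr(r, col) for r in rows] for col in FEATURE_COLUMNS}
    df = pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{decimals}f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a feature-table TSV as a DataFrame indexed by row order."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns {sorted(missing)}")
    return df
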