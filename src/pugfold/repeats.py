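"""Detection and parsing of poly(UG) dinucleotide repeat chains.

Poly(UG) ("pUG") RNAs are GU dinucleotide simple-sequence repeats; a repeat
chain may begin with either G or U, and odd-length runs are counted in half
repeats (e.g. the 59-nt NEAT1 tract is 29.5 repeats).  All coordinates here
are 1-based inclusive at nucleotide level; fold placement works at repeat
level (1 repeat = 2 nt), matching the (GU)_n bookkeeping used throughout the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

#: Number of GU repeats incorporated by one pUG fold (12 repeats, 12 Gs, 24 nt).
FOLD_REPEATS = 12

_NUCLEOTIDES = frozenset("ACGU")


class RepeatError(ValueError):
    """Raised when a sequence cannot be interpreted as a pUG repeat chain."""


def _normalize(sequence: str) -> str:
    if not isinstance(sequence, str) or not sequence.strip():
        raise RepeatError("empty sequence")
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise RepeatError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class PUGSequence:
    """A single uninterrupted GU/UG repeat chain.

    ``n_repeats`` counts GU dinucleotide units at 0.5 granularity, so an
    odd-length run such as UGU...GU (25 nt) is 12.5 repeats.  ``phase`` is
    the identity of the first nucleotide (G-start or U-start).
    """

    sequence: str
    n_repeats: float
    phase: str
    n_nt: int


@dataclass(frozen=True)
class RepeatRun:
    """A maximal GU/UG run inside a longer sequence (1-based inclusive)."""

    start: int
    end: int
    n_repeats: float
    n_g: int
    phase: str

    @property
    def n_nt(self) -> int:
        return self.end - self.start + 1


def _alternating_spans(seq: str) -> list[tuple[int, int]]:
    """Maximal spans (0-based inclusive) of strictly alternating G/U."""
    spans: list[tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] not in "GU":
            i += 1
            continue
        j = i
        while j + 1 < n and seq[j + 1] in "GU" and seq[j + 1] != seq[j]:
            j += 1
        spans.append((i, j))
        i = j + 1
    return spans


def parse_pug(sequence: str) -> PUGSequence:
    """Parse a sequence that is one uninterrupted GU/UG repeat run.

    T is silently converted to U and lowercase is accepted.  Sequences with
    interruptions (anything other than perfect G/U alternation) raise
    :class:`RepeatError`; use :func:`find_pug_runs` for those.
    """
    seq = _normalize(sequence)
    spans = _alternating_spans(seq)
    if spans != [(0, len(seq) - 1)]:
        raise RepeatError(
            "interrupted repeat: sequence is not a single GU/UG run "
            "(use find_pug_runs)"
        )
    return PUGSequence(
        sequence=seq, n_repeats=len(seq) / 2.0, phase=seq[0], n_nt=len(seq)
    )


def find_pug_runs(sequence: str, min_repeats: float = 1.0) -> list[RepeatRun]:
    """All maximal GU/UG runs with at least ``min_repeats`` repeat units.

    Runs are returned in 5'->3' order, non-overlapping and maximal (not
    extendable in either direction).
    """
    if min_repeats <= 0:
        raise ValueError("min_repeats must be positive")
    seq = _normalize(sequence)
    runs = []
    for i, j in _alternating_spans(seq):
        n_rep = (j - i + 1) / 2.0
        if n_rep < min_repeats:
            continue
        sub = seq[i : j + 1]
        runs.append(
            RepeatRun(
                start=i + 1,
                end=j + 1,
                n_repeats=n_rep,
                n_g=sub.count("G"),
                phase=sub[0],
            )
        )
    return runs


def valid_fold_starts(
    pug: PUGSequence | RepeatRun | float, fold_repeats: int = FOLD_REPEATS
) -> list[int]:
    """Repeat-level start positions where a ``fold_repeats``-repeat fold fits.

    Accepts a parsed chain, a run, or a bare repeat count.  Folds require
    full repeats, so a trailing half repeat contributes nothing.
    """
    if fold_repeats < 1:
        raise ValueError("fold_repeats must be >= 1")
    n_repeats = pug if isinstance(pug, (int, float)) else pug.n_repeats
    n_full = int(math.floor(n_repeats))
    return list(range(1, n_full - fold_repeats + 2))


def scan_fasta(path: str | Path, min_repeats: float = FOLD_REPEATS) -> pd.DataFrame:
    """Scan every record of a FASTA file for pUG runs.

    Returns a table with columns record_id, start, end, n_repeats, n_g,
    phase (one row per run, records with no qualifying run contribute none).
    """
    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        for run in find_pug_runs(str(record.seq), min_repeats=min_repeats):
            rows.append(
                {
                    "record_id": record.id,
                    "start": run.start,
                    "end": run.end,
                    "n_repeats": run.n_repeats,
                    "n_g": run.n_g,
                    "phase": run.phase,
                }
            )
    return pd.DataFrame(
        rows, columns=["record_id", "start", "end", "n_repeats", "n_g", "phase"]
    )
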