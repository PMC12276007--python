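"""Combinatorics of pUG fold placement on a repeat chain.

A pUG fold occupies 12 consecutive GU repeats.  On a chain of n repeats the
legal repeat-level starts are 1..n-11, and a *configuration* is any set of
non-overlapping placements.  A configuration is *maximal* when no further
fold fits into any gap or flank.  Two folds with zero intervening repeats
form an *adjacent double* fold, which behaves as a single RNase T1-resistant
24-repeat block.

Two distinct measures are provided and deliberately kept separate:

* the uniform distribution over maximal configurations
  (:func:`enumerate_configurations` + :func:`adjacency_stats`), which for a
  29-repeat chain gives 6/27 = 22.2% adjacent doubles; and
* a sequential kinetic model (:func:`simulate_sequential_folding`) in which
  folds nucleate one at a time at uniformly random legal starts, which for
  the same chain gives ~27% adjacent doubles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .repeats import FOLD_REPEATS


@dataclass(frozen=True, order=True)
class FoldPlacement:
    """One fold occupying repeats start_repeat .. start_repeat+fold_repeats-1."""

    start_repeat: int
    fold_repeats: int = FOLD_REPEATS

    def __post_init__(self) -> None:
        if self.start_repeat < 1 or self.fold_repeats < 1:
            raise ValueError("placement indices are 1-based and positive")

    @property
    def end_repeat(self) -> int:
        return self.start_repeat + self.fold_repeats - 1


@dataclass(frozen=True)
class FoldConfiguration:
    """A sorted set of non-overlapping fold placements on one chain."""

    n_repeats: float
    placements: tuple[FoldPlacement, ...]
    fold_repeats: int = FOLD_REPEATS

    def __post_init__(self) -> None:
        placements = tuple(sorted(self.placements))
        object.__setattr__(self, "placements", placements)
        prev_end = 0
        for p in placements:
            if p.start_repeat <= prev_end:
                raise ValueError("placements overlap")
            if p.end_repeat > self.n_repeats:
                raise ValueError("placement extends past chain 3' end")
            prev_end = p.end_repeat

    @property
    def n_folds(self) -> int:
        return len(self.placements)

    def gaps(self) -> list[int]:
        """Free full-repeat gap lengths: 5' flank, inter-fold gaps, 3' flank."""
        n_full = int(math.floor(self.n_repeats))
        edges = [0] + [p.end_repeat for p in self.placements]
        starts = [p.start_repeat for p in self.placements] + [n_full + 1]
        return [s - e - 1 for e, s in zip(edges, starts)]

    @property
    def n_adjacent_pairs(self) -> int:
        return sum(
            1
            for a, b in zip(self.placements, self.placements[1:])
            if b.start_repeat == a.end_repeat + 1
        )

    @property
    def is_maximal(self) -> bool:
        return all(g < self.fold_repeats for g in self.gaps())


@dataclass(frozen=True)
class PlacementStats:
    """Tallies over an ensemble or enumeration of configurations."""

    n_configs: int
    n_single: int
    n_double: int
    n_triple_plus: int
    n_adjacent_double: int
    fraction_adjacent: float


@dataclass(frozen=True)
class Fragment:
    """An RNase T1-protected core block of one or more adjacent folds."""

    start_repeat: int
    end_repeat: int
    n_folds_contained: int
    five_prime_terminus: str  # "PPP" or "HO"
    three_prime_terminus: str  # "OH" or "cyclicP"

    @property
    def n_repeats(self) -> int:
        return self.end_repeat - self.start_repeat + 1

    @property
    def n_nt(self) -> int:
        return 2 * self.n_repeats


def enumerate_configurations(
    n_repeats: float,
    fold_repeats: int = FOLD_REPEATS,
    maximal_only: bool = False,
) -> list[FoldConfiguration]:
    """Every non-empty set of non-overlapping fold placements, in
    lexicographic order of start positions.

    With ``maximal_only`` only configurations to which no further fold can
    be added are returned.  A chain shorter than one fold yields an empty
    list.
    """
    if n_repeats < 0:
        raise ValueError("n_repeats must be non-negative")
    if fold_repeats < 1:
        raise ValueError("fold_repeats must be >= 1")
    n = int(math.floor(n_repeats))
    last = n - fold_repeats + 1
    results: list[FoldConfiguration] = []

    def extend(prefix: tuple[FoldPlacement, ...], min_start: int) -> None:
        for s in range(min_start, last + 1):
            placements = prefix + (FoldPlacement(s, fold_repeats),)
            cfg = FoldConfiguration(n, placements, fold_repeats)
            if not maximal_only or cfg.is_maximal:
                results.append(cfg)
            extend(placements, s + fold_repeats)

    extend((), 1)
    return results


def adjacency_stats(configs: list[FoldConfiguration]) -> PlacementStats:
    """Classify configurations by fold count and adjacent-double content."""
    if not configs:
        raise ValueError("empty configuration list")
    n_single = sum(1 for c in configs if c.n_folds == 1)
    n_double = sum(1 for c in configs if c.n_folds == 2)
    n_triple_plus = sum(1 for c in configs if c.n_folds >= 3)
    n_adjacent = sum(1 for c in configs if c.n_adjacent_pairs >= 1)
    return PlacementStats(
        n_configs=len(configs),
        n_single=n_single,
        n_double=n_double,
        n_triple_plus=n_triple_plus,
        n_adjacent_double=n_adjacent,
        fraction_adjacent=n_adjacent / len(configs),
    )


def _legal_starts(free: np.ndarray, fold_repeats: int) -> np.ndarray:
    """1-based starts whose fold_repeats-long window is entirely free."""
    if free.size < fold_repeats:
        return np.empty(0, dtype=int)
    window = np.convolve(free.astype(int), np.ones(fold_repeats, dtype=int), "valid")
    return np.flatnonzero(window == fold_repeats) + 1


def simulate_sequential_folding(
    n_repeats: float,
    n_molecules: int,
    seed: int,
    fold_repeats: int = FOLD_REPEATS,
) -> list[FoldConfiguration]:
    """Stochastic sequential nucleation: per molecule, folds are placed one
    at a time at a start drawn uniformly among currently legal starts until
    none remain.  Every returned configuration is maximal by construction.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(math.floor(n_repeats))
    out: list[FoldConfiguration] = []
    for _ in range(n_molecules):
        free = np.ones(n, dtype=bool)
        placements: list[FoldPlacement] = []
        while True:
            legal = _legal_starts(free, fold_repeats)
            if legal.size == 0:
                break
            s = int(legal[rng.integers(legal.size)])
            free[s - 1 : s - 1 + fold_repeats] = False
            placements.append(FoldPlacement(s, fold_repeats))
        out.append(FoldConfiguration(n, tuple(placements), fold_repeats))
    return out


def sequential_placement_distribution(
    n_repeats: float, fold_repeats: int = FOLD_REPEATS
) -> dict[FoldConfiguration, Fraction]:
    """Exact outcome distribution of the sequential model, by recursion over
    every ordered sequence of uniform choices.  Exponential in chain length;
    intended for small chains and as the oracle for the simulator.
    """
    n = int(math.floor(n_repeats))
    probs: dict[FoldConfiguration, Fraction] = {}

    def recurse(free: tuple[bool, ...], placements: tuple[FoldPlacement, ...],
                prob: Fraction) -> None:
        legal = _legal_starts(np.array(free), fold_repeats)
        if legal.size == 0:
            cfg = FoldConfiguration(n, placements, fold_repeats)
            probs[cfg] = probs.get(cfg, Fraction(0)) + prob
            return
        p = prob / int(legal.size)
        for s in legal:
            s = int(s)
            new_free = list(free)
            new_free[s - 1 : s - 1 + fold_repeats] = [False] * fold_repeats
            recurse(tuple(new_free), placements + (FoldPlacement(s, fold_repeats),), p)

    recurse(tuple([True] * n), (), Fraction(1))
    return probs


def predict_t1_fragments(
    config: FoldConfiguration, five_prime_chemistry: str = "PPP"
) -> list[Fragment]:
    """RNase T1-resistant fragments of a configuration after full digestion.

    Exposed single-stranded guanosines are cut, so maximal blocks of
    adjacent folds survive as one fragment.  A block starting at repeat 1
    keeps the transcript's 5' chemistry (PPP for a transcript, HO for a
    dephosphorylated RNA); internal blocks get the 5'-hydroxyl left by T1.
    A block reaching the chain 3' end keeps the 3'-OH; internal blocks end
    in a 2',3'-cyclic phosphate.
    """
    if five_prime_chemistry not in ("PPP", "HO"):
        raise ValueError("five_prime_chemistry must be 'PPP' or 'HO'")
    if not config.placements:
        raise ValueError("configuration has no placements")
    blocks: list[list[FoldPlacement]] = [[config.placements[0]]]
    for p in config.placements[1:]:
        if p.start_repeat == blocks[-1][-1].end_repeat + 1:
            blocks[-1].append(p)
        else:
            blocks.append([p])
    fragments = []
    for block in blocks:
        start, end = block[0].start_repeat, block[-1].end_repeat
        fragments.append(
            Fragment(
                start_repeat=start,
                end_repeat=end,
                n_folds_contained=len(block),
                five_prime_terminus=five_prime_chemistry if start == 1 else "HO",
                three_prime_terminus="OH" if end == config.n_repeats else "cyclicP",
            )
        )
    return fragments
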