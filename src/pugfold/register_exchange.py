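"""Segmental register-exchange model of pUG fold dynamics.

The pUG fold is built from four 3-repeat segments.  When single-stranded
repeats flank the fold (any chain longer than 12 repeats, with the fold
ensemble stochastically positioned), the two *terminal* segments can swap
register with the flanks through transient expanded loops or bulges — a
fast local opening — while the fold core only opens through slow global
unfolding.  In the EX1 limit every opening event exchanges the segment's
imino protons with solvent deuterium, and deuteration is irreversible, so
the ensemble imino survival is the biexponential

    S(t) = a exp(-(k_flip + k_unfold) t) + (1 - a) exp(-k_unfold t)

with fast amplitude a = exchangeable_segments / 4 = 1/2 whenever at least
one flanking repeat exists — independent of chain length, which is why the
measured fast-phase ratios (~50%) do not grow from 13 to 18 repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_SEGMENTS = 4
#: Terminal segments (5' and 3') able to exchange register with flanks.
TERMINAL_SEGMENTS = 2


def exchangeable_fraction(
    flank_5: float,
    flank_3: float,
    n_segments: int = N_SEGMENTS,
    exchangeable_segments: int = TERMINAL_SEGMENTS,
) -> float:
    """Fast-phase amplitude from the flanking repeat counts.

    0 with no flanking repeats (the minimal fold is monophasic); otherwise
    both terminal segments participate through the stochastic position
    ensemble, giving exchangeable_segments / n_segments, capped at 1.
    """
    if flank_5 < 0 or flank_3 < 0:
        raise ValueError("flank lengths must be non-negative")
    if flank_5 + flank_3 == 0:
        return 0.0
    return min(exchangeable_segments / n_segments, 1.0)


@dataclass(frozen=True)
class RegisterExchangeModel:
    """Four-segment fold with flank-dependent terminal register exchange.

    Rates are in h^-1: ``k_flip`` is the register-exchange opening rate of
    each terminal segment, ``k_unfold`` the global unfolding rate.
    """

    k_flip: float
    k_unfold: float
    flank_5: float = 0.0
    flank_3: float = 0.0
    n_segments: int = N_SEGMENTS

    def __post_init__(self) -> None:
        if self.k_flip < 0 or self.k_unfold < 0:
            raise ValueError("rates must be non-negative")
        if self.flank_5 < 0 or self.flank_3 < 0:
            raise ValueError("flank lengths must be non-negative")

    @property
    def exchangeable_segments(self) -> int:
        return 0 if self.flank_5 + self.flank_3 == 0 else TERMINAL_SEGMENTS

    @property
    def fast_amplitude(self) -> float:
        return exchangeable_fraction(self.flank_5, self.flank_3,
                                     self.n_segments)


@dataclass
class HDXPrediction:
    """Predicted imino survival I(t)/I(0) for an HDX experiment."""

    times: np.ndarray
    survival: np.ndarray
    fast_amplitude: float
    k_fast: float  # k_flip + k_unfold
    k_slow: float  # k_unfold
    stderr: np.ndarray | None = None  # Monte-Carlo standard error per point


def analytic_hdx(model: RegisterExchangeModel, times: np.ndarray) -> HDXPrediction:
    """Closed-form EX1 survival curve of the register-exchange scheme."""
    t = np.asarray(times, dtype=float)
    a = model.fast_amplitude
    survival = (a * np.exp(-(model.k_flip + model.k_unfold) * t)
                + (1.0 - a) * np.exp(-model.k_unfold * t))
    return HDXPrediction(times=t, survival=survival, fast_amplitude=a,
                         k_fast=model.k_flip + model.k_unfold,
                         k_slow=model.k_unfold)


def gillespie_hdx(
    model: RegisterExchangeModel,
    n_molecules: int,
    times: np.ndarray,
    seed: int,
) -> HDXPrediction:
    """Stochastic realization of the register-exchange scheme.

    Per molecule, each exchange-competent terminal segment opens after an
    exponential waiting time at rate k_flip (irreversibly deuterating its
    iminos) and the whole molecule unfolds after an exponential waiting
    time at rate k_unfold (deuterating everything).  The ensemble mean of
    the unexchanged segment fraction is reported with its Monte-Carlo
    standard error at each requested time.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    n_seg = model.n_segments
    n_exch = model.exchangeable_segments

    def waiting(rate: float, shape) -> np.ndarray:
        if rate <= 0:
            return np.full(shape, np.inf)
        return rng.exponential(1.0 / rate, shape)

    t_unfold = waiting(model.k_unfold, (n_molecules, 1))
    # exchange time per segment: terminal segments race flip vs unfold,
    # interior segments only exchange on global unfolding
    t_seg = np.broadcast_to(t_unfold, (n_molecules, n_seg)).copy()
    if n_exch > 0:
        t_flip = waiting(model.k_flip, (n_molecules, n_exch))
        t_seg[:, :n_exch] = np.minimum(t_flip, t_unfold)

    # fraction of unexchanged segments per molecule at each time point
    frac = (t_seg[:, :, None] > t[None, None, :]).mean(axis=1)
    survival = frac.mean(axis=0)
    stderr = frac.std(axis=0, ddof=1) / np.sqrt(n_molecules)
    return HDXPrediction(times=t, survival=survival,
                         fast_amplitude=model.fast_amplitude,
                         k_fast=model.k_flip + model.k_unfold,
                         k_slow=model.k_unfold, stderr=stderr)
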