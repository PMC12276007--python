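"""Seeded synthetic datasets with the statistical structure of the assay suite.

Every generator draws all of its randomness from one ``numpy`` Generator
constructed from the ``seed`` argument, so identical arguments reproduce
bit-identical outputs.  Defaults mirror the experimental designs: CD scans
from 210-340 nm in 1 nm steps; folding traces of 180 points over 330 min;
HDX sampling from 0.3 h (first spectrum within ~20 min of D2O addition),
dense quarter-hour points to 3 days, then daily points to 3 weeks; melts
ramped 20 -> 81.5 degrees C in 1.5-degree steps.

The CD band model is four Gaussians at the pUG fold's characteristic peaks
(negative 245 nm, positive 260 and 281 nm, negative 304 nm; width 6 nm).
Absolute band amplitudes are arbitrary package constants, since every
analysis downstream is ratio-based against the (GU)_12 reference.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cd import (CDSpectrum, GU12_FOLDED_FRACTION, MolarCD,
                 ELLIPTICITY_CONSTANT, expected_fraction_folded)
from .kinetics import LN2, ExchangeSeries, KineticTrace
from .placement import FoldConfiguration, predict_t1_fragments

# (center nm, delta_eps amplitude); widths share CD_BAND_SIGMA
CD_BANDS = ((245.0, -6.0), (260.0, 9.0), (281.0, 7.5), (304.0, -5.0))
CD_BAND_SIGMA = 6.0
WAVELENGTH_GRID = np.arange(210.0, 341.0, 1.0)

DEFAULT_CONCENTRATION = 20e-6  # M, typical CD sample
DEFAULT_PATH_LENGTH = 0.1  # cm (1 mm cuvette)
DEFAULT_NOISE_SD = 0.02  # fraction of dynamic range


def gu12_reference(wavelengths: np.ndarray | None = None) -> MolarCD:
    """The canonical (GU)_12 molar CD basis spectrum.

    This is the reference against which synthetic sample spectra are scaled
    and measured; its shape is the four-Gaussian band model.
    """
    wl = WAVELENGTH_GRID if wavelengths is None else np.asarray(wavelengths, float)
    delta = np.zeros_like(wl)
    for center, amp in CD_BANDS:
        delta += amp * np.exp(-((wl - center) ** 2) / (2.0 * CD_BAND_SIGMA**2))
    return MolarCD(wl.copy(), delta)


def generate_cd_spectrum(
    n_nt: int,
    n_folds: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    fraction: float | None = None,
    concentration: float = DEFAULT_CONCENTRATION,
    path_length: float = DEFAULT_PATH_LENGTH,
) -> CDSpectrum:
    """Synthetic raw CD spectrum of an n_nt chain carrying n_folds pUG folds.

    The molar CD is the (GU)_12 basis scaled by
    expected_fraction_folded(n_nt, n_folds) / 0.95, so that measuring the
    spectrum against :func:`gu12_reference` returns the generating fraction.
    ``fraction`` overrides the fold-count arithmetic to generate a chain at
    an arbitrary folded fraction.  Additive Gaussian noise is scaled to the
    dynamic range of the noiseless ellipticity.
    """
    if fraction is None:
        fraction = expected_fraction_folded(n_nt, n_folds)
    rng = np.random.default_rng(seed)
    basis = gu12_reference()
    delta = basis.delta_eps * (fraction / GU12_FOLDED_FRACTION)
    scale = ELLIPTICITY_CONSTANT * concentration * path_length * n_nt
    theta = delta * scale
    if noise_sd > 0:
        span = float(np.ptp(theta))
        if span == 0.0:  # unfolded chain: noise floor from the reference scale
            span = float(np.ptp(basis.delta_eps)) * scale
        theta = theta + rng.normal(0.0, noise_sd * span, theta.shape)
    return CDSpectrum(wavelengths=basis.wavelengths.copy(), theta=theta,
                      concentration=concentration, path_length=path_length,
                      n_nt=n_nt)


def generate_folding_trace(
    t_half_min: float,
    duration_min: float = 330.0,
    n_points: int = 180,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    signal_start: float = 0.0,
    signal_end: float = -6.0,
) -> KineticTrace:
    """Single-exponential CD folding trace with the given half-life (min).

    ``t_half_min=inf`` produces a flat (non-folding) trace.  Defaults follow
    the folding assays: 180 points over 5.5 h, signal developing toward the
    negative 245 nm peak.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, duration_min, n_points)
    if np.isinf(t_half_min):
        signal = np.full_like(times, signal_start)
    else:
        k = LN2 / t_half_min
        signal = signal_end + (signal_start - signal_end) * np.exp(-k * times)
    if noise_sd > 0:
        signal = signal + rng.normal(
            0.0, noise_sd * abs(signal_end - signal_start), signal.shape)
    return KineticTrace(times=times, signal=signal, time_unit="min")


def default_hdx_schedule() -> np.ndarray:
    """Sampling times (h): 0.3 h, then every 0.25 h to 72 h, then daily to
    3 weeks."""
    dense = np.arange(0.3, 72.0 + 1e-9, 0.25)
    sparse = np.arange(96.0, 504.0 + 1e-9, 24.0)
    return np.concatenate([dense, sparse])


def generate_hdx_series(
    mode: str = "mono",
    i0: float = 1.0,
    k: float | None = None,
    k_fast: float | None = None,
    k_slow: float | None = None,
    fast_fraction: float | None = None,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExchangeSeries:
    """Synthetic normalized HDX integrals with floor 0.

    ``mode='mono'`` uses rate ``k``; ``mode='biexp'`` uses ``k_fast``,
    ``k_slow`` and ``fast_fraction`` (all rates in h^-1).  Noise is additive
    Gaussian with sd = noise_sd * i0.
    """
    t = default_hdx_schedule() if times is None else np.asarray(times, float)
    rng = np.random.default_rng(seed)
    if mode == "mono":
        if k is None or k < 0:
            raise ValueError("mono mode needs a non-negative rate k")
        y = i0 * np.exp(-k * t)
    elif mode == "biexp":
        if k_fast is None or k_slow is None or fast_fraction is None:
            raise ValueError("biexp mode needs k_fast, k_slow, fast_fraction")
        if k_fast < 0 or k_slow < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in [0, 1]")
        y = i0 * (fast_fraction * np.exp(-k_fast * t)
                  + (1.0 - fast_fraction) * np.exp(-k_slow * t))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * i0, y.shape)
    return ExchangeSeries(times=t, integrals=y)


def generate_melt_curve(
    tm_c: float,
    dt_c: float = 2.5,
    baseline_folded: float = -6.0,
    baseline_unfolded: float = -0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    ramp_start: float = 20.0,
    ramp_stop: float = 81.5,
    ramp_step: float = 1.5,
) -> KineticTrace:
    """Boltzmann-sigmoid thermal melt sampled on the standard ramp
    (20 -> 81.5 degrees C in 1.5-degree steps, 42 points).

    A Tm outside the ramp triggers a warning (the transition cannot be
    resolved from such a curve).
    """
    temps = np.arange(ramp_start, ramp_stop + ramp_step / 2.0, ramp_step)
    if not (ramp_start <= tm_c <= ramp_stop):
        warnings.warn(f"Tm {tm_c} degC lies outside the {ramp_start}-{ramp_stop} "
                      "degC ramp", stacklevel=2)
    rng = np.random.default_rng(seed)
    y = baseline_unfolded + (baseline_folded - baseline_unfolded) / (
        1.0 + np.exp((temps - tm_c) / dt_c))
    if noise_sd > 0:
        y = y + rng.normal(
            0.0, noise_sd * abs(baseline_folded - baseline_unfolded), y.shape)
    return KineticTrace(times=temps, signal=y, time_unit="C")


def generate_digest_table(
    configs: list[FoldConfiguration],
    five_prime_chemistry: str = "PPP",
):
    """Aggregate RNase T1-resistant fragments of a configuration ensemble.

    Returns a DataFrame keyed by (length_repeats, n_folds, termini) with
    molecule counts and stain-weighted intensities (intensity proportional
    to count x fragment nt length, emulating an intercalating stain).
    """
    import pandas as pd

    if not configs:
        raise ValueError("empty ensemble")
    rows = []
    for cfg in configs:
        if not cfg.placements:
            continue
        for frag in predict_t1_fragments(cfg, five_prime_chemistry):
            rows.append((frag.n_repeats, frag.n_folds_contained,
                         frag.five_prime_terminus, frag.three_prime_terminus,
                         frag.n_nt))
    if not rows:
        raise ValueError("ensemble contains no folds")
    df = pd.DataFrame(rows, columns=["length_repeats", "n_folds",
                                     "five_prime", "three_prime", "length_nt"])
    table = (df.groupby(["length_repeats", "n_folds", "five_prime",
                         "three_prime", "length_nt"])
             .size().reset_index(name="count"))
    table["stain_intensity"] = table["count"] * table["length_nt"]
    table["intensity_fraction"] = (table["stain_intensity"]
                                   / table["stain_intensity"].sum())
    return table.sort_values(["length_repeats", "five_prime", "three_prime"],
                             ignore_index=True)
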