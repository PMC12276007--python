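"""Circular-dichroism quantification of pUG folding.

Raw ellipticity theta (millidegrees) is converted to molar CD absorption

    delta_eps = theta / (32980 * C * L * N)

with C the strand concentration (M), L the cuvette path length (cm) and N
the number of nucleotides.  Because the pUG fold dominates the CD signal,
the ratio of a sample's delta_eps to that of the minimal fold (GU)_12 at
the characteristic peaks (245, 281, 304 nm), scaled by the 0.95 folded
fraction of (GU)_12 itself (its 3'-terminal U is unstructured), measures
the fraction of the chain engaged in pUG folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Conversion constant between millidegrees and molar CD absorption.
ELLIPTICITY_CONSTANT = 32980.0

#: Peak wavelengths used for fraction-folded analysis (nm).
PEAK_WAVELENGTHS = (245.0, 281.0, 304.0)

#: Wavelengths monitored during folding kinetics (nm).
KINETIC_WAVELENGTHS = (243.0, 264.0, 284.0, 304.0)

#: Folded fraction of the (GU)_12 reference (3'-terminal U unstructured).
GU12_FOLDED_FRACTION = 0.95

#: Nucleotides engaged per pUG fold in the fold-counting arithmetic.
NT_PER_FOLD = 24


@dataclass
class CDSpectrum:
    """Raw ellipticity vs wavelength plus the Eq-1 metadata (C, L, N)."""

    wavelengths: np.ndarray
    theta: np.ndarray
    concentration: float  # molar
    path_length: float  # cm
    n_nt: int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.wavelengths.shape != self.theta.shape:
            raise ValueError("wavelength and theta grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.concentration <= 0 or self.path_length <= 0 or self.n_nt < 1:
            raise ValueError("C and L must be positive and N >= 1")


@dataclass
class MolarCD:
    """Molar CD absorption (delta_eps) on the source wavelength grid."""

    wavelengths: np.ndarray
    delta_eps: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_eps = np.asarray(self.delta_eps, dtype=float)

    def value_at(self, wavelength: float) -> float:
        """delta_eps at a wavelength: nearest grid point for grids at most
        2 nm coarse, linear interpolation otherwise."""
        step = float(np.median(np.diff(self.wavelengths)))
        if step > 2.0:
            return float(np.interp(wavelength, self.wavelengths, self.delta_eps))
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.delta_eps[idx])


@dataclass
class FoldedFraction:
    """Fraction-folded read-out at one or more CD peaks."""

    per_peak: dict[float, float]
    mean_fraction: float
    wavelengths_used: tuple[float, ...] = field(default=PEAK_WAVELENGTHS)


def molar_cd(spectrum: CDSpectrum) -> MolarCD:
    """Convert raw ellipticity to molar CD absorption, elementwise."""
    scale = ELLIPTICITY_CONSTANT * spectrum.concentration * spectrum.path_length * spectrum.n_nt
    return MolarCD(spectrum.wavelengths.copy(), spectrum.theta / scale)


def fraction_folded(
    sample: MolarCD,
    reference_gu12: MolarCD,
    wavelengths: tuple[float, ...] = PEAK_WAVELENGTHS,
    normalization: float = GU12_FOLDED_FRACTION,
) -> FoldedFraction:
    """Fraction folded from signed peak ratios against the (GU)_12 reference.

    per-peak fraction = (delta_eps_sample / delta_eps_ref) * normalization.
    Sample and reference peaks share sign, so the ratio is positive for a
    folded sample at every characteristic peak.
    """
    ref_scale = float(np.max(np.abs(reference_gu12.delta_eps)))
    per_peak: dict[float, float] = {}
    for wl in wavelengths:
        ref_val = reference_gu12.value_at(wl)
        if abs(ref_val) < 1e-6 * max(ref_scale, 1e-300):
            raise ValueError(f"reference delta_eps is ~0 at {wl} nm")
        per_peak[wl] = sample.value_at(wl) / ref_val * normalization
    mean = float(np.mean(list(per_peak.values())))
    return FoldedFraction(per_peak=per_peak, mean_fraction=mean,
                          wavelengths_used=tuple(wavelengths))


def expected_fraction_folded(
    n_nt: int, n_folds: int, nt_per_fold: int = NT_PER_FOLD
) -> float:
    """Model fraction folded for an integer number of folds on an n_nt chain.

    Each fold engages nt_per_fold nucleotides, so e.g. two folds on the
    58-nt (GU)_29 engage 48/58 = 83% of the chain.
    """
    if n_folds < 0 or n_nt < 1:
        raise ValueError("n_folds must be >= 0 and n_nt >= 1")
    if n_folds * nt_per_fold > n_nt:
        raise ValueError("folds exceed chain capacity")
    return n_folds * nt_per_fold / n_nt


def mean_folds_from_fraction(
    fraction: float, n_nt: int, nt_per_fold: int = NT_PER_FOLD
) -> float:
    """Average fold count implied by a measured folded fraction (inverse of
    :func:`expected_fraction_folded`); 73% folded on 58 nt gives ~1.76."""
    if not 0.0 <= fraction <= 1.05:
        raise ValueError("fraction must lie in [0, 1] (5% noise tolerance)")
    return fraction * n_nt / nt_per_fold
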