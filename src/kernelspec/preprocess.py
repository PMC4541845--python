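"""Spectral preprocessing: wavelength cropping and Savitzky-Golay filtering.

The camera's signal-to-noise ratio degrades toward both ends of the 400-1000 nm
range, so spectra are cropped to 430-980 nm before modeling.  Savitzky-Golay
local polynomial smoothing (default window 21 bands, order 2) suppresses random
noise; its first derivative removes baseline offsets and sharpens overlapping
absorption features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .segmentation import SpectrumMatrix

__all__ = ["SGParams", "crop_wavelengths", "savitzky_golay", "preprocess_spectra"]


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay window (odd), polynomial order, and derivative order."""

    frame: int = 21
    polyorder: int = 2
    deriv: int = 1

    def __post_init__(self) -> None:
        if self.frame % 2 == 0 or self.frame < 3:
            raise ValueError("frame must be odd and >= 3")
        if not 0 <= self.polyorder < self.frame:
            raise ValueError("polyorder must satisfy 0 <= polyorder < frame")
        if not 0 <= self.deriv <= self.polyorder:
            raise ValueError("deriv must satisfy 0 <= deriv <= polyorder")


def crop_wavelengths(spectra: SpectrumMatrix, lo: float, hi: float) -> SpectrumMatrix:
    """Keep bands with lo <= wavelength <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    keep = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return SpectrumMatrix(
        spectra.values[:, keep], spectra.wavelengths[keep],
        labels=spectra.labels, side=spectra.side, region_ids=spectra.region_ids,
    )


def savitzky_golay(spectra: SpectrumMatrix, params: SGParams = SGParams(),
                   scale_by_spacing: bool = True) -> SpectrumMatrix:
    """Row-wise SG smoothing / differentiation.

    ``scale_by_spacing=True`` expresses derivatives per nm using the mean band
    spacing; with False the derivative is per band index.  Edges are handled by
    scipy's polynomial fit over the truncated window (``mode='interp'``).
    """
    if spectra.values.shape[1] < params.frame:
        raise ValueError(
            f"need at least frame={params.frame} bands, got {spectra.values.shape[1]}"
        )
    delta = float(np.mean(np.diff(spectra.wavelengths))) if scale_by_spacing else 1.0
    out = savgol_filter(
        spectra.values, window_length=params.frame, polyorder=params.polyorder,
        deriv=params.deriv, delta=delta, axis=1, mode="interp",
    )
    return SpectrumMatrix(out, spectra.wavelengths.copy(), labels=spectra.labels,
                          side=spectra.side, region_ids=spectra.region_ids)


def preprocess_spectra(spectra: SpectrumMatrix, lo: float = 430.0, hi: float = 980.0,
                       params: SGParams = SGParams(),
                       scale_by_spacing: bool = True) -> SpectrumMatrix:
    """Standard chain: crop to [lo, hi] nm, then SG smooth + derivative."""
    return savitzky_golay(crop_wavelengths(spectra, lo, hi), params, scale_by_spacing)
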