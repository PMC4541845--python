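"""Kernel/background segmentation and per-kernel mean spectrum extraction.

Seeds are imaged on a matte black stage, so a single well-chosen band —
empirically the one near 850 nm, where kernel/background reflectance contrast
is largest — separates kernels from background by thresholding.  Connected
components (8-connectivity) above a minimum area become kernel regions; each
region contributes one mean reflectance spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology as skmorph
from skimage.filters import threshold_otsu

from .hypercube import Hypercube

__all__ = [
    "KernelRegion",
    "SpectrumMatrix",
    "pick_segmentation_band",
    "segment",
    "extract_mean_spectra",
]


@dataclass
class KernelRegion:
    """One segmented kernel: a binary mask inside a tight bounding box.

    ``bbox`` is half-open ``(row0, col0, row1, col1)`` in cube coordinates.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    region_id: int
    variety: object = None
    side: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        r0, c0, r1, c1 = self.bbox
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ValueError("mask shape does not match bbox")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean() + self.bbox[0]), float(cc.mean() + self.bbox[1])

    def pixels(self) -> tuple[np.ndarray, np.ndarray]:
        """Global (row, col) index arrays of the mask's foreground pixels."""
        rr, cc = np.nonzero(self.mask)
        return rr + self.bbox[0], cc + self.bbox[1]


@dataclass
class SpectrumMatrix:
    """Kernels x bands matrix of mean relative reflectance."""

    values: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray | None = None
    side: str | None = None
    region_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.wavelengths):
            raise ValueError("values must be (kernels, bands) matching wavelengths")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("one label per row required")
        if self.region_ids is None:
            self.region_ids = np.arange(self.values.shape[0])
        else:
            self.region_ids = np.asarray(self.region_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pick_segmentation_band(cube: Hypercube,
                           kernel_roi: tuple[np.ndarray, np.ndarray],
                           background_roi: tuple[np.ndarray, np.ndarray]) -> int:
    """Band maximizing kernel-vs-background mean reflectance contrast.

    ROIs are (row_indices, col_indices) pixel sets (the study protocol uses
    20x20-pixel patches).  Ties break to the lowest band index.
    """
    kr, kc = np.asarray(kernel_roi[0]), np.asarray(kernel_roi[1])
    br, bc = np.asarray(background_roi[0]), np.asarray(background_roi[1])
    if kr.size == 0 or br.size == 0:
        raise ValueError("both ROIs must be nonempty")
    kernel_mean = cube.data[kr, kc, :].mean(axis=0)
    background_mean = cube.data[br, bc, :].mean(axis=0)
    contrast = np.abs(kernel_mean - background_mean)
    return int(np.argmax(contrast))  # argmax returns first max -> lowest index on ties


def segment(cube: Hypercube, band: int, threshold: float | str = "otsu",
            min_area: int = 50, opening_radius: int = 0) -> list[KernelRegion]:
    """Threshold one band, label 8-connected components, drop specks.

    Regions are ordered row-major by centroid.  Touching-kernel suspects
    (area > 2.5x the median region area) trigger a warning — the acquisition
    protocol places seeds separately, so merged blobs indicate layout trouble.
    """
    if not cube.calibrated:
        raise ValueError("segment expects a calibrated cube")
    img = cube.band_image(band)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold '{threshold}'")
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    fg = img > thr
    if opening_radius > 0:
        fg = skmorph.binary_opening(fg, skmorph.disk(opening_radius))
    labeled = measure.label(fg, connectivity=2)
    regions: list[KernelRegion] = []
    props = measure.regionprops(labeled)
    kept = [p for p in props if p.area >= min_area]
    if not kept:
        warnings.warn("segmentation found no regions above min_area", stacklevel=2)
        return []
    kept.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    areas = np.array([p.area for p in kept])
    med = np.median(areas)
    for i, p in enumerate(kept):
        r0, c0, r1, c1 = p.bbox
        regions.append(KernelRegion(mask=p.image.copy(), bbox=(r0, c0, r1, c1), region_id=i))
        if p.area > 2.5 * med:
            warnings.warn(
                f"region {i} area {p.area} is an outlier (median {med:.0f}); "
                "possibly touching kernels", stacklevel=2,
            )
    return regions


def extract_mean_spectra(cube: Hypercube, regions: list[KernelRegion]) -> SpectrumMatrix:
    """One mean spectrum per region, averaging only validity-masked pixels.

    Regions whose every pixel is invalid in some band are excluded with a
    warning (their mean would be undefined there).
    """
    validity = cube.validity()
    rows_out, labels, ids = [], [], []
    dropped = []
    for reg in regions:
        rr, cc = reg.pixels()
        if rr.max() >= cube.shape[0] or cc.max() >= cube.shape[1]:
            raise ValueError(f"region {reg.region_id} exceeds cube bounds")
        spectra = cube.data[rr, cc, :]          # (npix, bands)
        vmask = validity[rr, cc, :]
        counts = vmask.sum(axis=0)
        if (counts == 0).any():
            dropped.append(reg.region_id)
            continue
        mean = (spectra * vmask).sum(axis=0) / counts
        rows_out.append(mean)
        labels.append(reg.variety)
        ids.append(reg.region_id)
    if dropped:
        warnings.warn(f"regions {dropped} fully invalid in some band; excluded", stacklevel=2)
    values = np.array(rows_out) if rows_out else np.empty((0, cube.n_bands))
    lab = np.array(labels, dtype=object) if labels else None
    side = regions[0].side if regions else None
    return SpectrumMatrix(values, cube.wavelengths, labels=lab, side=side,
                          region_ids=np.array(ids, dtype=int))
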