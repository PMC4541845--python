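"""Synthetic hyperspectral seed-image generator with full ground truth.

Every stage of the analysis is exercised on cubes whose statistical structure
matches what the method assumes about real maize-kernel acquisitions:

* 477 bands spanning 400-1000 nm; dark stage background vs. bright kernels,
  with kernel/background contrast maximal at 850 nm (the shared reflectance
  baseline peaks there);
* four varieties with distinct smooth reflectance curves built as the shared
  baseline plus class- and side-specific Gaussian bumps — two varieties are
  made nearly identical on the germ-up side over 680-940 nm but distinct
  germ-down, emulating the side disparity seen in real kernels;
* per-kernel spectral variability (overall scale, tilt, and smooth random
  wiggles) so varieties overlap realistically rather than being separable
  from a single noiseless curve;
* class-dependent elliptical shapes with rough boundaries (drives area,
  aspect ratio, circularity, solidity) and class-dependent spatially
  correlated multiplicative texture fields (drives GLCM contrast/entropy);
* raw counts synthesized as B + (W - B) * reflectance with explicit
  dark/white reference frames, so calibration is exercised end to end.

Cubes are bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .hypercube import Hypercube, ReferenceFrames
from .segmentation import KernelRegion
from .features import FeatureTable, MORPH_NAMES, TEXTURE_NAMES

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "FixtureConfig",
    "generate_cube",
    "generate_study",
    "generate_feature_fixture",
]

SIDES = ("germ_up", "germ_down")


@dataclass(frozen=True)
class ClassSpec:
    """Spectral, shape, and texture parameters of one variety.

    Bumps are (center nm, width nm, amplitude) Gaussians added to the shared
    baseline; axes are (mean, sd) of the ellipse semi-axes in pixels;
    ``roughness`` scales a smooth periodic radial perturbation of the
    boundary; the texture field is unit-mean with the given amplitude and
    Gaussian correlation length (pixels).
    """

    name: str
    bumps_up: tuple = ()
    bumps_down: tuple = ()
    axis_a: tuple = (16.0, 0.7)
    axis_b: tuple = (11.0, 0.6)
    roughness: float = 0.02
    texture_amp: float = 0.08
    texture_corr: float = 2.0


def _default_classes() -> tuple[ClassSpec, ...]:
    # HU and SU share a flat germ-up profile over 680-940 nm (their bumps sit
    # below 680) but differ there germ-down — the side-disparity construction.
    return (
        ClassSpec("HANG",
                  bumps_up=((470, 25, 0.022), (620, 40, -0.019), (930, 25, 0.019)),
                  bumps_down=((460, 25, 0.019), (650, 40, -0.016), (915, 25, 0.018)),
                  axis_a=(16.6, 0.9), axis_b=(11.9, 0.7),
                  roughness=0.020, texture_amp=0.06, texture_corr=2.0),
        ClassSpec("SU",
                  bumps_up=((505, 25, 0.001), (585, 30, 0.029)),
                  bumps_down=((480, 25, 0.020), (600, 25, 0.015), (740, 30, -0.030)),
                  axis_a=(14.8, 0.9), axis_b=(11.0, 0.7),
                  roughness=0.028, texture_amp=0.05, texture_corr=3.0),
        ClassSpec("HU",
                  bumps_up=((505, 25, 0.013), (585, 30, 0.019)),
                  bumps_down=((560, 30, 0.020), (780, 30, 0.035), (900, 30, -0.010)),
                  axis_a=(16.0, 0.9), axis_b=(12.8, 0.7),
                  roughness=0.015, texture_amp=0.09, texture_corr=1.5),
        ClassSpec("YAN",
                  bumps_up=((450, 25, -0.019), (700, 40, 0.019), (960, 20, 0.016)),
                  bumps_down=((460, 25, -0.001), (650, 40, -0.036), (915, 25, -0.003)),
                  axis_a=(18.6, 0.9), axis_b=(10.0, 0.7),
                  roughness=0.040, texture_amp=0.14, texture_corr=2.5),
    )


@dataclass
class GeneratorConfig:
    """Study-scale defaults: 4 varieties x 150 kernels x both sides."""

    classes: tuple = field(default_factory=_default_classes)
    kernels_per_class: int = 150
    sides: tuple = SIDES
    n_bands: int = 477
    wl_range: tuple = (400.0, 1000.0)
    # shared baseline: low in the blue, peaking at 850 nm
    base_level: float = 0.15
    base_amp: float = 0.45
    base_center: float = 850.0
    base_width: float = 170.0
    germ_down_scale: float = 0.97
    background_reflectance: float = 0.04
    # per-pixel, per-band additive reflectance noise
    spectral_noise_sd: float = 0.01
    # per-kernel curve variability: overall scale, linear tilt, smooth wiggles
    kernel_scale_sd: float = 0.04
    kernel_tilt_sd: float = 0.035
    wiggle_count: int = 6
    wiggle_amp_sd: float = 0.034
    wiggle_width: float = 38.0
    # per-kernel relative jitter of the class texture parameters (lognormal sd)
    texture_amp_jitter: float = 0.18
    texture_corr_jitter: float = 0.20
    # imaging geometry and references
    cell: int = 52
    jitter: float = 2.0
    batch_size: int = 24
    dark_level: float = 120.0
    white_level: float = 3600.0
    seed: int = 0

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_range[0], self.wl_range[1], self.n_bands)

    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def class_curve(self, class_idx: int, side: str) -> np.ndarray:
        """Mean reflectance curve of a variety on one side (no kernel noise)."""
        wl = self.wavelengths()
        curve = self.base_level + self.base_amp * np.exp(
            -(((wl - self.base_center) / self.base_width) ** 2)
        )
        spec = self.classes[class_idx]
        bumps = spec.bumps_up if side == "germ_up" else spec.bumps_down
        for center, width, amp in bumps:
            curve = curve + amp * np.exp(-(((wl - center) / width) ** 2))
        if side == "germ_down":
            curve = curve * self.germ_down_scale
        return curve

    def reference_frames(self) -> ReferenceFrames:
        wl = self.wavelengths()
        illum = 1.0 - 0.25 * ((wl - 700.0) / 300.0) ** 2   # smooth lamp spectrum
        dark = np.full(self.n_bands, self.dark_level)
        white = self.dark_level + (self.white_level - self.dark_level) * illum
        return ReferenceFrames(dark=dark, white=white)


def _rasterize_kernel(spec: ClassSpec, cell: int, rng: np.random.Generator,
                      jitter: float, roughness_scale: float = 1.0):
    """One rough-edged rotated ellipse inside a cell; returns (mask, meta)."""
    a = np.clip(rng.normal(*spec.axis_a), spec.axis_a[0] - 2.5 * spec.axis_a[1],
                spec.axis_a[0] + 2.5 * spec.axis_a[1])
    b = np.clip(rng.normal(*spec.axis_b), spec.axis_b[0] - 2.5 * spec.axis_b[1],
                spec.axis_b[0] + 2.5 * spec.axis_b[1])
    angle = rng.uniform(0, np.pi)
    cy = cell / 2.0 + rng.uniform(-jitter, jitter)
    cx = cell / 2.0 + rng.uniform(-jitter, jitter)
    rough = spec.roughness * roughness_scale
    harmonics = []
    if rough > 0:
        for h in range(2, 6):
            harmonics.append((h, rng.normal(0, 1), rng.uniform(0, 2 * np.pi)))
        norm = np.sqrt(sum(c * c for _, c, _ in harmonics) / 2.0) or 1.0
    yy, xx = np.mgrid[0:cell, 0:cell]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    boundary = np.ones_like(r)
    if rough > 0:
        theta = np.arctan2(v, u)
        g = np.zeros_like(theta)
        for h, c, phi in harmonics:
            g += c * np.cos(h * theta + phi)
        boundary = 1.0 + rough * g / norm
    mask = r <= boundary
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("kernel touches its cell border; enlarge cell or shrink axes")
    meta = {"a": float(a), "b": float(b), "angle": float(angle),
            "center": (float(cy), float(cx))}
    return mask, meta


def _kernel_curve(config: GeneratorConfig, base: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply per-kernel scale/tilt/wiggle variation to a class mean curve."""
    wl = config.wavelengths()
    lo, hi = config.wl_range
    t = (wl - (lo + hi) / 2.0) / (hi - lo)
    curve = base * (1.0 + rng.normal(0, config.kernel_scale_sd))
    curve = curve + rng.normal(0, config.kernel_tilt_sd) * t
    for _ in range(config.wiggle_count):
        center = rng.uniform(lo, hi)
        amp = rng.normal(0, config.wiggle_amp_sd)
        curve = curve + amp * np.exp(-(((wl - center) / config.wiggle_width) ** 2))
    return np.clip(curve, 0.01, 0.95)


def generate_cube(config: GeneratorConfig, side: str, kernel_classes,
                  seed: int = 0):
    """Render one raw cube holding the given kernels plus references and truth.

    Parameters
    ----------
    kernel_classes
        Sequence of class indices, one kernel each, laid out on a grid of
        non-touching cells.

    Returns
    -------
    (raw_cube, refs, truth) where ``truth`` is a list of per-kernel dicts with
    keys ``class_idx``, ``label``, ``region`` (a ground-truth
    :class:`KernelRegion`), ``curve`` (the class mean curve), and the ellipse
    parameters used.
    """
    if side not in config.sides:
        raise ValueError(f"unknown side {side!r}")
    rng = np.random.default_rng(seed)
    kernel_classes = list(kernel_classes)
    n = len(kernel_classes)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    cell = config.cell
    rows, cols = nrows * cell, ncols * cell
    wl = config.wavelengths()

    reflectance = np.full((rows, cols, config.n_bands),
                          config.background_reflectance, dtype=np.float32)
    truth = []
    for i, cls_idx in enumerate(kernel_classes):
        spec = config.classes[cls_idx]
        gr, gc = divmod(i, ncols)
        mask, meta = _rasterize_kernel(spec, cell, rng, config.jitter)
        curve = config.class_curve(cls_idx, side)
        kcurve = _kernel_curve(config, curve, rng)
        field = rng.normal(size=(cell, cell))
        amp_k = spec.texture_amp * np.exp(rng.normal(0, config.texture_amp_jitter))
        corr_k = spec.texture_corr * np.exp(rng.normal(0, config.texture_corr_jitter))
        if corr_k > 0:
            field = gaussian_filter(field, corr_k)
        fvals = field[mask]
        fsd = fvals.std()
        field = (field - fvals.mean()) / (fsd if fsd > 0 else 1.0)
        tex = np.clip(1.0 + amp_k * field, 0.2, None)
        rr, cc = np.nonzero(mask)
        reflectance[gr * cell + rr, gc * cell + cc, :] = (
            kcurve[None, :] * tex[rr, cc, None]
        ).astype(np.float32)
        r0, c0 = gr * cell, gc * cell
        rloc, cloc = np.nonzero(mask)
        bbox = (r0 + rloc.min(), c0 + cloc.min(), r0 + rloc.max() + 1, c0 + cloc.max() + 1)
        region = KernelRegion(
            mask=mask[rloc.min():rloc.max() + 1, cloc.min():cloc.max() + 1],
            bbox=tuple(int(x) for x in bbox), region_id=i,
            variety=spec.name, side=side,
        )
        truth.append({"class_idx": cls_idx, "label": spec.name, "region": region,
                      "curve": kcurve, "class_curve": curve, **meta,
                      "center_global": (meta["center"][0] + r0, meta["center"][1] + c0)})

    if config.spectral_noise_sd > 0:
        noise = rng.standard_normal(reflectance.shape, dtype=np.float32)
        noise *= np.float32(config.spectral_noise_sd)
        reflectance += noise

    # raw counts, built in place: B + (W - B) * R
    refs = config.reference_frames()
    reflectance *= (refs.white - refs.dark).astype(np.float32)
    reflectance += refs.dark.astype(np.float32)
    raw_cube = Hypercube(reflectance, wl, calibrated=False)
    return raw_cube, refs, truth


def batch_plan(config: GeneratorConfig) -> list[list[int]]:
    """Class-interleaved batches covering every (class, kernel) pair once."""
    order = [c for k in range(config.kernels_per_class)
             for c in range(len(config.classes))]
    bs = config.batch_size
    return [order[i:i + bs] for i in range(0, len(order), bs)]


def generate_study(config: GeneratorConfig, side: str):
    """Yield (raw_cube, refs, truth) batches for one side of the full study."""
    side_idx = list(config.sides).index(side)
    for b, classes in enumerate(batch_plan(config)):
        seed = int(np.random.SeedSequence(
            [config.seed, side_idx, b]).generate_state(1)[0] % (2**31))
        yield generate_cube(config, side, classes, seed=seed)


# ---------------------------------------------------------------------------
# Direct feature fixture (no imaging) for fast classifier tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Gaussian class clusters emitted straight as a FeatureTable."""

    n_classes: int = 4
    n_per_class: int = 150
    n_spectral: int = 20
    separation: float = 3.0     # between-class mean distance in within-SD units
    seed: int = 0


def generate_feature_fixture(config: FixtureConfig = FixtureConfig()) -> FeatureTable:
    """Feature table with known class structure: class means ``separation``
    apart (in units of the unit within-class SD), split over spectral,
    morphology, and texture groups."""
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_spectral + len(MORPH_NAMES) + len(TEXTURE_NAMES)
    means = rng.normal(size=(config.n_classes, n_feat))
    means /= np.linalg.norm(means, axis=1, keepdims=True)
    means *= config.separation
    X = np.concatenate([
        means[c] + rng.normal(size=(config.n_per_class, n_feat))
        for c in range(config.n_classes)
    ])
    labels = np.repeat([f"class_{c}" for c in range(config.n_classes)],
                       config.n_per_class)
    spectral_cols = [f"b{i}" for i in range(config.n_spectral)]
    df = pd.concat(
        [pd.DataFrame(X[:, :config.n_spectral], columns=spectral_cols),
         pd.DataFrame(X[:, config.n_spectral:config.n_spectral + 5],
                      columns=list(MORPH_NAMES)),
         pd.DataFrame(X[:, config.n_spectral + 5:], columns=list(TEXTURE_NAMES))],
        axis=1, keys=["spectral_selected", "morphology", "texture"],
        names=["group", "feature"],
    )
    return FeatureTable(df, labels)
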