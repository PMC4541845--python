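"""End-to-end orchestration: calibrate -> segment -> spectra/features ->
preprocess -> select wavelengths -> classify, per kernel side.

A run is fully determined by its :class:`RunConfig`; the global seed fans out
to per-stage seeds through a fixed derivation so each stage is independently
reproducible.  With ``out_dir`` set, every stage persists its artifact
(CSV/JSON) and ``resume=True`` reuses artifacts already on disk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hypercube import calibrate
from .segmentation import SpectrumMatrix, extract_mean_spectra, segment
from .preprocess import SGParams, preprocess_spectra
from .band_selection import (SelectionResult, one_hot, plsda_choose_components,
                             plsda_coef_select, plsda_fit, spa_choose_n)
from .features import FeatureTable, MORPH_NAMES, TEXTURE_NAMES, morphology, texture_features
from .classify import GridSpec, SplitSpec, comparison_frame, run_comparison
from .synthetic import GeneratorConfig, generate_study

__all__ = ["RunConfig", "run", "extract_side", "select_bands", "build_master_table",
           "stage_seed", "spectra_to_csv", "spectra_from_csv"]

_STAGE_IDS = {"generate": 1, "spa": 2, "split": 3, "svm": 4, "permutation": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    sid = _STAGE_IDS.get(stage)
    if sid is None:
        raise ValueError(f"unknown stage '{stage}'")
    return int(np.random.SeedSequence([global_seed, sid]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything that determines a run (serializable)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sides: tuple = ("germ_up", "germ_down")
    seg_wavelength: float = 850.0
    threshold: object = "otsu"
    min_area: int = 50
    crop: tuple = (430.0, 980.0)
    sg: SGParams = field(default_factory=SGParams)
    texture_band_range: tuple = (51, 477)
    # SPA: candidate starts (int = top-norm columns), model-size grid
    spa_starts: int = 8
    spa_n_grid: tuple = (5, 10, 15, 20, 25, 30)
    # PLS-DA selector: bands kept per side; latent variables searched by RMSECV
    plsda_n_bands: dict = field(default_factory=lambda: {"germ_up": 26, "germ_down": 19})
    plsda_max_components: int = 15
    plsda_classifier_components: int = 11
    split: SplitSpec = field(default_factory=SplitSpec)
    grid: GridSpec = field(default_factory=lambda: GridSpec.coarse(step=2))
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        # fan the global seed out to the stochastic stages
        self.generator.seed = stage_seed(self.seed, "generate")
        self.split = SplitSpec(self.split.train_per_class, self.split.test_per_class,
                               stage_seed(self.seed, "split"))
        self.grid.seed = stage_seed(self.seed, "svm")


def extract_side(config: RunConfig, side: str) -> dict:
    """Imaging stages for one side: generate/calibrate/segment/measure.

    Returns raw mean spectra plus per-kernel morphology and texture matrices,
    with variety labels matched from the generator's ground truth.
    """
    gen = config.generator
    spectra_rows, morph_rows, tex_rows, labels = [], [], [], []
    for raw, refs, truth in generate_study(gen, side):
        cube = calibrate(raw, refs)
        band = cube.band_index(config.seg_wavelength)
        regions = segment(cube, band, threshold=config.threshold, min_area=config.min_area)
        centers = np.array([t["center_global"] for t in truth])
        spectra = extract_mean_spectra(cube, regions)
        kept_regions = [r for r in regions if r.region_id in set(spectra.region_ids)]
        for reg, row in zip(kept_regions, spectra.values):
            d = np.linalg.norm(centers - np.array(reg.centroid), axis=1)
            j = int(np.argmin(d))
            if d[j] > 6.0:
                warnings.warn(f"region at {reg.centroid} matches no ground-truth kernel",
                              stacklevel=2)
                continue
            reg.variety = truth[j]["label"]
            reg.side = side
            spectra_rows.append(row)
            labels.append(truth[j]["label"])
            morph_rows.append(morphology(reg).as_array())
            tex_rows.append(texture_features(cube, reg,
                                             band_range=config.texture_band_range).as_array())
    return {
        "spectra": SpectrumMatrix(np.array(spectra_rows), gen.wavelengths(),
                                  labels=np.array(labels, dtype=object), side=side),
        "morph": np.array(morph_rows),
        "texture": np.array(tex_rows),
    }


def select_bands(pre: SpectrumMatrix, config: RunConfig, side: str) -> dict:
    """SPA and PLS-DA-coefficient wavelength selection on preprocessed spectra."""
    spa = spa_choose_n(
        pre.values, pre.labels, n_grid=config.spa_n_grid, starts=config.spa_starts,
        seed=stage_seed(config.seed, "spa"),
    )
    Y, _ = one_hot(pre.labels)
    ncomp = plsda_choose_components(pre.values, pre.labels,
                                    max_components=config.plsda_max_components)
    model = plsda_fit(pre.values, Y, ncomp)
    n_bands = config.plsda_n_bands.get(side, 20)
    plsda = SelectionResult(selected=plsda_coef_select(model, n_bands),
                            method="plsda_coef")
    plsda.rmse_trace = {}
    return {"spa": spa, "plsda": plsda, "plsda_components": ncomp}


def build_master_table(pre: SpectrumMatrix, selections: dict, morph: np.ndarray,
                       texture: np.ndarray) -> FeatureTable:
    """Master table carrying all five groups the six feature sets draw on.

    All spectral groups hold the preprocessed (cropped, SG-derivative)
    spectra: the full set every band, the selected sets the chosen bands.
    """
    blocks = {
        "spectral_full": pd.DataFrame(
            pre.values, columns=[f"{w:.2f}nm" for w in pre.wavelengths]),
        "spectral_spa": pd.DataFrame(
            pre.values[:, selections["spa"].selected],
            columns=[f"{pre.wavelengths[i]:.2f}nm" for i in selections["spa"].selected]),
        "spectral_plsda": pd.DataFrame(
            pre.values[:, selections["plsda"].selected],
            columns=[f"{pre.wavelengths[i]:.2f}nm" for i in selections["plsda"].selected]),
        "morphology": pd.DataFrame(morph, columns=list(MORPH_NAMES)),
        "texture": pd.DataFrame(texture, columns=list(TEXTURE_NAMES)),
    }
    df = pd.concat(blocks.values(), axis=1, keys=blocks.keys(),
                   names=["group", "feature"])
    return FeatureTable(df, np.asarray(pre.labels), pre.side)


def spectra_to_csv(sm: SpectrumMatrix, path: Path) -> None:
    df = pd.DataFrame(sm.values, columns=[repr(float(w)) for w in sm.wavelengths])
    df.insert(0, "region_id", sm.region_ids)
    df.insert(1, "variety", sm.labels)
    df.to_csv(path, index=False)


def spectra_from_csv(path: Path, side: str) -> SpectrumMatrix:
    df = pd.read_csv(path)
    wl = np.array([float(c) for c in df.columns[2:]])
    return SpectrumMatrix(df.iloc[:, 2:].to_numpy(float), wl,
                          labels=df["variety"].to_numpy(), side=side,
                          region_ids=df["region_id"].to_numpy())


def run(config: RunConfig, resume: bool = False,
        feature_sets: dict | None = None, methods=("svm", "plsda")) -> dict:
    """Execute the full pipeline for every configured side.

    Returns ``{"sides": {side: {...}}, "comparison": DataFrame}`` and, when
    ``config.out_dir`` is set, persists per-stage artifacts plus a provenance
    record sufficient to reproduce the run.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    per_side: dict[str, dict] = {}
    for side in config.sides:
        spectra_path = out / f"spectra_{side}.csv" if out else None
        feats_path = out / f"image_features_{side}.csv" if out else None
        if resume and spectra_path and spectra_path.exists() and feats_path.exists():
            spectra = spectra_from_csv(spectra_path, side)
            fdf = pd.read_csv(feats_path)
            morph = fdf[list(MORPH_NAMES)].to_numpy(float)
            texture = fdf[list(TEXTURE_NAMES)].to_numpy(float)
        else:
            ext = extract_side(config, side)
            spectra, morph, texture = ext["spectra"], ext["morph"], ext["texture"]
            if out:
                spectra_to_csv(spectra, spectra_path)
                fdf = pd.DataFrame(np.hstack([morph, texture]),
                                   columns=list(MORPH_NAMES) + list(TEXTURE_NAMES))
                fdf.insert(0, "variety", spectra.labels)
                fdf.to_csv(feats_path, index=False)

        pre = preprocess_spectra(spectra, *config.crop, params=config.sg)

        sel_path = out / f"selection_{side}.json" if out else None
        if resume and sel_path and sel_path.exists():
            saved = json.loads(sel_path.read_text())
            selections = {
                "spa": SelectionResult(saved["spa"]["selected"],
                                       {int(k): v for k, v in saved["spa"]["rmse_trace"].items()},
                                       "spa", saved["spa"]["start_band"]),
                "plsda": SelectionResult(saved["plsda"]["selected"], {}, "plsda_coef"),
                "plsda_components": saved["plsda_components"],
            }
        else:
            selections = select_bands(pre, config, side)
            if out:
                sel_path.write_text(json.dumps({
                    "spa": selections["spa"].to_dict(pre.wavelengths),
                    "plsda": selections["plsda"].to_dict(pre.wavelengths),
                    "plsda_components": int(selections["plsda_components"]),
                }, indent=1))

        master = build_master_table(pre, selections, morph, texture)
        results = run_comparison(master, config.split, config.grid,
                                 config.plsda_classifier_components,
                                 feature_sets=feature_sets, methods=methods)
        per_side[side] = {"results": results, "selections": selections, "master": master}
        if out:
            (out / f"results_{side}.json").write_text(json.dumps(
                {k: {m: r.to_dict() for m, r in cell.items()}
                 for k, cell in results.items()}, indent=1))

    comparison = comparison_frame(
        {side: d["results"] for side, d in per_side.items()})
    if out:
        comparison.to_csv(out / "comparison.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=1))
    return {"sides": per_side, "comparison": comparison}


def _provenance(config: RunConfig) -> dict:
    import sklearn
    cfg = asdict(config)
    cfg["grid"]["c_grid"] = [float(x) for x in config.grid.c_grid]
    cfg["grid"]["gamma_grid"] = [float(x) for x in config.grid.gamma_grid]
    return {
        "kernelspec_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
        "config": json.loads(json.dumps(cfg, default=str)),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_IDS},
    }
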