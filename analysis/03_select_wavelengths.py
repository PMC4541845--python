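"""Preprocess the extracted spectra and select informative wavelengths.

Spectra are cropped to 430-980 nm and Savitzky-Golay filtered (window 21,
order 2, first derivative); SPA then picks a minimal low-collinearity band
set per side (model size chosen by the PLS-DA RMSECV plateau), and the
PLS-DA regression-coefficient ranking provides the comparator set.  The
chosen wavelengths and the RMSE-vs-N traces go to results/.
"""

import json
from pathlib import Path

from kernelspec import RunConfig, preprocess_spectra
from kernelspec.pipeline import select_bands, spectra_from_csv

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = RunConfig(seed=SEED)
    for side in config.sides:
        spectra = spectra_from_csv(OUT / f"spectra_{side}.csv", side)
        pre = preprocess_spectra(spectra, *config.crop, params=config.sg)
        sel = select_bands(pre, config, side)
        spa, plsda = sel["spa"], sel["plsda"]
        payload = {
            "side": side,
            "spa": spa.to_dict(pre.wavelengths),
            "plsda_coef": plsda.to_dict(pre.wavelengths),
            "plsda_latent_variables": int(sel["plsda_components"]),
        }
        (RESULTS / f"selected_bands_{side}.json").write_text(json.dumps(payload, indent=1))
        (OUT / f"selection_{side}.json").write_text(json.dumps({
            "spa": spa.to_dict(pre.wavelengths),
            "plsda": plsda.to_dict(pre.wavelengths),
            "plsda_components": int(sel["plsda_components"]),
        }, indent=1))
        nm = ", ".join(f"{pre.wavelengths[i]:.1f}" for i in spa.selected)
        print(f"{side}: SPA kept {len(spa.selected)} bands "
              f"(start {spa.start_band}): {nm}")
        print(f"  PLS-DA model: {sel['plsda_components']} latent variables; "
              f"coefficient ranking kept {len(plsda.selected)} bands")


if __name__ == "__main__":
    main()
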