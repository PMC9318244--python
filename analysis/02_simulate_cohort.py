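#!/usr/bin/env python
"""Simulate the study-sized paired-illumination cohort.

Generates 97 synthetic lesions (20 melanomas — 8 in situ, 12 invasive —
23 dysplastic nevi, 54 benign nevi), each rendered under polarized (PL)
and non-polarized (NPL) illumination, and writes the PNGs plus a
pipeline-ready manifest under scratch/cohort/ (images are bulky
and regenerable, so they live outside the tracked results). Border irregularity and
texture roughness increase from BN through DN to MM; invasive melanomas
are rougher than in-situ ones.
"""

from pathlib import Path

import pandas as pd

from lesionfd.synthetic import SyntheticLesionParams, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 42

PRESETS = {
    "BN": SyntheticLesionParams(
        base_radius=170.0, irregularity_amplitude=0.05, texture_hurst=0.60
    ),
    "DN": SyntheticLesionParams(
        base_radius=180.0, irregularity_amplitude=0.15, texture_hurst=0.50
    ),
    "MM_insitu": SyntheticLesionParams(
        base_radius=220.0, irregularity_amplitude=0.25, texture_hurst=0.40
    ),
    "MM_invasive": SyntheticLesionParams(
        base_radius=230.0, irregularity_amplitude=0.35, texture_hurst=0.30
    ),
}
SIZES = {"BN": 54, "DN": 23, "MM_insitu": 8, "MM_invasive": 12}


def main() -> None:
    entries = generate_cohort(SIZES, PRESETS, seed=SEED)
    manifest_path = write_cohort(entries, OUT)

    # fold the melanoma sub-presets into one MM group with a stage label
    manifest = pd.read_csv(manifest_path)
    stage = manifest["group"].map(
        {"MM_insitu": "in_situ", "MM_invasive": "invasive"}
    )
    manifest["melanoma_stage"] = stage
    manifest["group"] = manifest["group"].replace(
        {"MM_insitu": "MM", "MM_invasive": "MM"}
    )
    manifest.to_csv(manifest_path, index=False)

    counts = manifest[manifest.illumination == "PL"].group.value_counts()
    print(f"simulated {counts.sum()} lesions: {counts.to_dict()} "
          f"({int(stage.notna().sum() // 2)} melanomas staged)")
    print(f"manifest: {manifest_path}")


if __name__ == "__main__":
    main()
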