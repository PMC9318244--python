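#!/usr/bin/env python
"""Parameter recovery: does the pipeline see the generator's knobs?

Two checks, written to results/parameter_recovery.csv:

1. Border irregularity -> shape FD. Two cohorts of 20 lesions differing
   only in irregularity amplitude (0.05 vs 0.35) are pushed through
   segmentation and shape FD; a Mann-Whitney U test asks whether the FD
   distributions separate.
2. Texture roughness -> surface FD. fBm textures at Hurst 0.2 / 0.5 / 0.8
   (10 seeds each, 64 px blocks) should give strictly monotone mean
   surface FD: rougher texture, higher intensity-difference FD.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

import lesionfd as lf
from lesionfd.synthetic import (
    SyntheticLesionParams, _rng, fbm_field, lesion_seed, render_lesion,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def shape_fd_cohort(amplitude: float, label: str, n: int = 20) -> np.ndarray:
    fds = []
    for i in range(n):
        params = SyntheticLesionParams(
            seed=lesion_seed(42, label, i), irregularity_amplitude=amplitude
        )
        blended, _ = lf.segment(render_lesion(params))
        fds.append(lf.shape_fd(blended).fd)
    return np.array(fds)


def main() -> None:
    rows = []

    low = shape_fd_cohort(0.05, "low")
    high = shape_fd_cohort(0.35, "high")
    p = mannwhitneyu(low, high).pvalue
    print(f"shape FD: amplitude 0.05 mean {low.mean():.4f}, "
          f"0.35 mean {high.mean():.4f}, Mann-Whitney p = {p:.2e}")
    rows.append({"check": "irregularity_separation", "statistic": "mannwhitney_p",
                 "value": p, "low_mean": low.mean(), "high_mean": high.mean()})

    means = {}
    for hurst in (0.2, 0.5, 0.8):
        fds = []
        for seed in range(10):
            f = fbm_field(64, hurst, _rng(seed, "fbm-fixture"))
            img = np.floor((f - f.min()) / (f.max() - f.min()) * 255 + 0.5).astype(np.uint8)
            fds.append(lf.surface_fd(img).fd)
        means[hurst] = float(np.mean(fds))
        rows.append({"check": "hurst_response", "statistic": f"mean_fd_h{hurst}",
                     "value": means[hurst]})
    order = "monotone decreasing" if means[0.2] > means[0.5] > means[0.8] else "NOT monotone"
    print(f"surface FD vs Hurst: {({h: round(m, 4) for h, m in means.items()})} -> {order}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "parameter_recovery.csv", index=False)
    print(f"wrote {OUT / 'parameter_recovery.csv'}")


if __name__ == "__main__":
    main()
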