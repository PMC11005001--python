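#!/usr/bin/env python
"""Calibration and power of the moderated differential test.

Null data: fraction of raw p below 0.05 and BH discovery counts across
three seeds.  Planted data (log2FC 1.0, within-group SD 0.5, 4 vs 4):
sensitivity of BH-significant and raw-p calls and the error of the median
estimated effect.  Writes results/03_calibration.json.
"""

import json
from pathlib import Path

from epiphos import benchmarks

SEED = 0
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    calib = benchmarks.null_calibration(seed=SEED, n_features=5000, n_seeds=3)
    rec = benchmarks.effect_recovery(seed=SEED)
    out = {"null": calib, "recovery": rec}
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "03_calibration.json").write_text(json.dumps(out, indent=1) + "\n")
    print(json.dumps(out, indent=1))
    print(
        "\nnull raw-p fraction per seed:",
        [round(f, 4) for f in calib["raw_p_fraction_per_seed"]],
    )
    print(
        f"recovery: BH sensitivity {rec['bh_sensitivity']:.1%}, raw-p "
        f"sensitivity {rec['raw_p_sensitivity']:.1%}, median effect error "
        f"{rec['median_effect_error']:.3f} (the BH figure sits well below "
        "the raw-p one because the noncentrality at these settings caps "
        "unadjusted power near 0.81; see docs/methods.md)"
    )


if __name__ == "__main__":
    main()
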