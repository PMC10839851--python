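#!/usr/bin/env python
"""Univariate event-vs-object activation contrast.

Smoothed per-subject event-minus-object beta contrast maps, a sign-flip
max-statistic group test, and mean betas per ROI and condition.
"""

from pathlib import Path

import pandas as pd

from dualhub import pipeline

CONFIG = Path(__file__).resolve().parents[1] / "results" / "demo_config.json"


def main() -> None:
    cfg = pipeline.load_config(CONFIG)
    pipeline.run_pipeline(cfg, stages=["univariate"])
    tab = pd.read_csv(Path(cfg["paths"]["out_root"]) / "univariate"
                      / "roi_mean_betas.tsv", sep="\t")
    print(tab.groupby(["roi", "condition"])["mean_beta"].mean()
          .round(3).to_string())


if __name__ == "__main__":
    main()
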