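#!/usr/bin/env python
"""Final summary table: per-ROI group rho/z with permutation p-values."""

from pathlib import Path

import pandas as pd

from dualhub import pipeline

CONFIG = Path(__file__).resolve().parents[1] / "results" / "demo_config.json"


def main() -> None:
    cfg = pipeline.load_config(CONFIG)
    pipeline.run_pipeline(cfg, stages=["report"])
    tab = pd.read_csv(Path(cfg["paths"]["out_root"]) / "report"
                      / "summary.tsv", sep="\t")
    print(tab.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
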