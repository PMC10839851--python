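#!/usr/bin/env python
"""Searchlight and ROI RSA.

Per subject and concept type: Fisher-z maps of the partial Spearman
correlation between the searchlight neural RDM and the semantic RDM,
controlling the visual RDM, plus event-minus-object difference maps and
an ROI table.
"""

from pathlib import Path

import pandas as pd

from dualhub import pipeline

CONFIG = Path(__file__).resolve().parents[1] / "results" / "demo_config.json"


def main() -> None:
    cfg = pipeline.load_config(CONFIG)
    pipeline.run_pipeline(cfg, stages=["rsa"])
    tab = pd.read_csv(Path(cfg["paths"]["out_root"]) / "rsa" / "roi_rsa.tsv",
                      sep="\t")
    print(tab.groupby(["roi", "concept_type"])[["rho", "z"]].mean()
          .round(3).to_string())


if __name__ == "__main__":
    main()
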