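#!/usr/bin/env python
"""gPPI connectivity analysis.

Per seed ROI: first-eigenvariate seed series, gPPI design (seed,
psychological, interaction, constant), event-minus-object interaction
contrast per subject, and a sign-flip group p map.
"""

from pathlib import Path

from dualhub import pipeline

CONFIG = Path(__file__).resolve().parents[1] / "results" / "demo_config.json"


def main() -> None:
    cfg = pipeline.load_config(CONFIG)
    pipeline.run_pipeline(cfg, stages=["ppi"])
    print("wrote seed series, subject interaction contrasts and group "
          f"p maps under {cfg['paths']['out_root']}/ppi")


if __name__ == "__main__":
    main()
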