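#!/usr/bin/env python
"""Fit the GLMs.

For every subject: the condition-level GLM (event / object / catch
regressors plus 180 s high-pass and constant) for univariate contrasts,
and the least-squares-separate GLMs giving one activation map per
concept for RSA.
"""

from pathlib import Path

from dualhub import pipeline

CONFIG = Path(__file__).resolve().parents[1] / "results" / "demo_config.json"


def main() -> None:
    cfg = pipeline.load_config(CONFIG)
    pipeline.run_pipeline(cfg, stages=["glm"])
    print("wrote condition betas and per-concept LSS betas under "
          f"{cfg['paths']['out_root']}/glm")


if __name__ == "__main__":
    main()
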