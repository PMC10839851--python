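#!/usr/bin/env python
"""Build the model RDMs.

Semantic RDMs (one minus cosine between concept embedding vectors) and
visual RDMs (mean over cross-concept image pairs of one minus Pearson
between image feature vectors), separately for event and object concepts.
"""

from pathlib import Path

import numpy as np

from dualhub import pipeline
from dualhub.rdm import RDM

CONFIG = Path(__file__).resolve().parents[1] / "results" / "demo_config.json"


def main() -> None:
    cfg = pipeline.load_config(CONFIG)
    pipeline.run_pipeline(cfg, stages=["rdm"])
    out = Path(cfg["paths"]["out_root"]) / "rdm"
    for ctype in ("event", "object"):
        sem = RDM.from_tsv(out / f"semantic_{ctype}.tsv")
        vis = RDM.from_tsv(out / f"visual_{ctype}.tsv")
        r = np.corrcoef(sem.vector(), vis.vector())[0, 1]
        print(f"{ctype}: {sem.n} concepts, {sem.vector().size} pairs, "
              f"semantic-visual RDM correlation r = {r:+.3f}")


if __name__ == "__main__":
    main()
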