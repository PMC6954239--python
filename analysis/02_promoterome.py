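#!/usr/bin/env python
"""Step 2: build the promoterome from the simulated CTSS tracks.

Runs the full pipeline (normalize, classify, cluster, assign, call DI
status, profile dynamics) and prints the headline summary.  Artifacts land
under results/promoterome/.
"""

import json
from pathlib import Path

from dualinit.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "promoterome"


def main():
    ctss_paths = {p.stem.replace("ctss_", ""): str(p)
                  for p in sorted(DATA.glob("ctss_*.tsv"))}
    cfg = PipelineConfig(
        ctss_paths=ctss_paths,
        genome_path=str(DATA / "genome.fa"),
        gene_models_path=str(DATA / "genes.bed12"),
        outdir=str(OUT),
    )
    summary = run_pipeline(cfg, force=True)
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
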