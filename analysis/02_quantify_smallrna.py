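#!/usr/bin/env python
"""Quantify mature miRNA abundance in every small-RNA sample.

For each FASTQ written by 01_simulate_data.py: trim the 3' adapter by
exact prefix search, keep 18-28 nt inserts, map them to the toy genome
allowing zero mismatches, and aggregate counts in the ±3 nt window around
each annotated miRNA 5' end (reference sequence = max-count window member;
abundance = summed counts at the reference's 5' position).  Writes per-line
miRNA count matrices under results/run/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mirpipe import pipeline

SEED = 1
OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cfg = pipeline.demo_config(SEED)
    sim_state = pipeline.load_sim_state(cfg, OUTDIR)
    pipeline.stage_quant(cfg, OUTDIR, sim_state)
    for line in pipeline.CELL_LINES:
        print(f"wrote {OUTDIR / f'mirna_counts_{line}.tsv'}")


if __name__ == "__main__":
    main()
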