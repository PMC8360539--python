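#!/usr/bin/env python
"""Step 1: generate the ground-truthed synthetic study.

Writes paired FASTQ files, the sample sheet, the pedigree and the truth
tables to scratch/sim (large outputs live under scratch/, not results/).
"""

from pathlib import Path

from mhctyper.cli import simulate

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    simulate.callback(seed=1, out_dir=ROOT / "scratch" / "sim",
                      n_individuals=None, n_triads=None, depth=None,
                      n_localities=3)
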