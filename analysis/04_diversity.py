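#!/usr/bin/env python
"""Step 4: diversity summaries over the called genotypes.

Writes the per-exon diversity table (unique DNA/AA alleles, per-individual
statistics, PSM, MAA) and the across-locality sharing table to results/.
"""

from pathlib import Path

import pandas as pd

from mhctyper.cli import diversity

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
GENO = ROOT / "scratch" / "genotyping"
OUT = ROOT / "results"

if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    diversity.callback(genotype_path=str(GENO / "genotypes.tsv"),
                       sample_sheet=str(SIM / "sample_sheet.tsv"), out_dir=OUT)
    print(pd.read_csv(OUT / "diversity.tsv", sep="\t").to_string(index=False))
    print(pd.read_csv(OUT / "sharing.tsv", sep="\t").to_string(index=False))
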