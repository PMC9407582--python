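#!/usr/bin/env python
"""Classify each discovered SV sequence against the repeat library by
Smith-Waterman local alignment on both strands (score cutoff 1000,
coverage floor 0.5) and tabulate sites per TE family.

Reads results/pipeline/ and writes annotations.tsv + family_counts.tsv.
"""

from pathlib import Path

import pandas as pd

from ripscan.cli import run_annotate

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main() -> None:
    run_annotate(OUTDIR)
    annotations = pd.read_csv(OUTDIR / "annotations.tsv", sep="\t")
    counts = pd.read_csv(OUTDIR / "family_counts.tsv", sep="\t")
    print(f"annotated {len(annotations)} SVs; {annotations['passed'].sum()} passed the cutoff")
    print(counts.to_string(index=False))


if __name__ == "__main__":
    main()
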