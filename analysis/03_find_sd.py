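#!/usr/bin/env python
"""Detect putative Shine-Dalgarno sequences and their pairing geometry.

Scans the 30 nt upstream of every start codon for maximal perfect
antiparallel complements (4-12 nt) of the mature tail called in the
previous step, histograms D_toStart, and filters matches to the optimal
window. On the synthetic bundle the histogram should peak at the planted
modal distance of 17 (7-nt spacer, pairing starting at the CCUCC core).
"""

from pathlib import Path

import pandas as pd

from tailscope import seq_io
from tailscope.sd_detect import TailSequence, dtostart_histogram, filter_optimal, find_sd_matches

ROOT = Path(__file__).resolve().parents[1] / "results"
BUNDLE = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
OPTIMAL = (15, 21)  # the documented window for a 15-nt tail


def main() -> None:
    tail_call = pd.read_csv(ROOT / "tail_call.tsv", sep="\t")
    tail = TailSequence(tail_call.loc[tail_call.is_mature, "tail_rna"].iloc[0])
    annotation = seq_io.read_annotation_gff3(
        BUNDLE / "genome.fasta", BUNDLE / "annot.gff3"
    )
    matches = []
    for gene_id in annotation.gene_ids:
        up = seq_io.extract_upstream(annotation, gene_id)
        matches.extend(find_sd_matches(up, tail))
    hist = dtostart_histogram(matches)
    kept = filter_optimal(matches, *OPTIMAL)
    pd.DataFrame(
        {
            "gene": [m.gene_id for m in matches],
            "sd": [m.sd for m in matches],
            "m": [m.m for m in matches],
            "g": [m.g for m in matches],
            "p_start": [m.p_start for m in matches],
            "p_end": [m.p_end for m in matches],
            "DtoStart": [m.d_to_start for m in matches],
            "in_optimal_range": [OPTIMAL[0] <= m.d_to_start <= OPTIMAL[1] for m in matches],
        }
    ).to_csv(ROOT / "sd_matches.tsv", sep="\t", index=False)
    pd.DataFrame({"DtoStart": list(hist), "count": list(hist.values())}).to_csv(
        ROOT / "dtostart_histogram.tsv", sep="\t", index=False
    )
    mode = max(hist, key=hist.get)
    print(f"tail: {tail.rna}")
    print(f"{len(matches)} putative SD matches across {len(annotation.gene_ids)} genes")
    print(f"D_toStart histogram: {hist}")
    print(f"modal D_toStart = {mode}; {len(kept)} matches in optimal range {OPTIMAL}")


if __name__ == "__main__":
    main()
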