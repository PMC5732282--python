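#!/usr/bin/env python
"""Observed vs expected anti-SD site usage and core anti-SD inference.

Builds the per-site usage table from the optimal-range SD matches, for all
genes and for the HEG/LEG expression classes, and infers the core anti-SD
as the longest run of sites used more than expected. With the synthetic SD
pool (complements of AGAAAGGAGGUGAUC segments centred on the GGAGG-pairing
core), the favored sites should cover the planted pairing footprint and
extend 5' through CCUCC.
"""

from pathlib import Path

import pandas as pd

from tailscope.expression import HEG, LEG, classify, read_abundance_tsv
from tailscope.sd_detect import SDMatch, TailSequence
from tailscope.usage_stats import SiteUsageTable, infer_core_asd

ROOT = Path(__file__).resolve().parents[1] / "results"
BUNDLE = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"


def load_matches():
    df = pd.read_csv(ROOT / "sd_matches.tsv", sep="\t")
    df = df[df.in_optimal_range]
    return [
        SDMatch(
            gene_id=r.gene, sd=r.sd, m=r.m, upstream_interval=(0, 0),
            p_start=r.p_start, p_end=r.p_end, g=r.g, d_to_start=r.DtoStart,
        )
        for r in df.itertuples()
    ]


def main() -> None:
    tail_call = pd.read_csv(ROOT / "tail_call.tsv", sep="\t")
    tail = TailSequence(tail_call.loc[tail_call.is_mature, "tail_rna"].iloc[0])
    matches = load_matches()
    classes = classify(read_abundance_tsv(BUNDLE / "abundance.tsv"))
    class_of = dict(zip(classes.frame.gene_id, classes.frame.gene_class))

    tables = {"all": SiteUsageTable.build(matches, tail)}
    for label in (HEG, LEG):
        subset = [m for m in matches if class_of.get(m.gene_id) == label]
        tables[label] = SiteUsageTable.build(subset, tail, gene_class=label)
        print(f"{label}: {len(subset)} matches in {len(set(m.gene_id for m in subset))} genes")

    pd.concat([t.to_frame() for t in tables.values()]).to_csv(
        ROOT / "usage_table.tsv", sep="\t", index=False
    )
    core = infer_core_asd(tables["all"], tail)
    pd.DataFrame(
        [{"core_start": core.start, "core_end": core.end, "core_rna": core.rna,
          "extended_start": core.extended_start, "extended_rna": core.extended_rna}]
    ).to_csv(ROOT / "core_asd.tsv", sep="\t", index=False)

    print(tables["all"].to_frame().round(3).to_string(index=False))
    print(f"core aSD: sites [{core.start},{core.end}] = {core.rna}; "
          f"extended through CCUCC: {core.extended_rna}")


if __name__ == "__main__":
    main()
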