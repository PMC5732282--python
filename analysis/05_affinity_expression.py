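#!/usr/bin/env python
"""SD usage vs duplex binding affinity, contrasted between HEG and LEG.

Enumerates the 4-8 nt SD sequences complementary to the extended core
anti-SD, computes each duplex's hybridization free energy, fits usage on
ΔG with a quadratic OLS (the minimal model with an interior optimum), and
contrasts highly vs lowly expressed genes. With the synthetic abundance
boost on AGGAGG, the HEG class should concentrate usage on that SD.
"""

from pathlib import Path

import pandas as pd

from tailscope.affinity import contrast_heg_leg, duplex_dG, fit_usage_vs_affinity
from tailscope.expression import HEG, LEG, classify, read_abundance_tsv
from tailscope.seq_io import rna_revcomp
from tailscope.usage_stats import enumerate_core_sd_set

ROOT = Path(__file__).resolve().parents[1] / "results"
BUNDLE = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"


def main() -> None:
    core = pd.read_csv(ROOT / "core_asd.tsv", sep="\t").iloc[0]
    matches = pd.read_csv(ROOT / "sd_matches.tsv", sep="\t")
    matches = matches[matches.in_optimal_range]
    classes = classify(read_abundance_tsv(BUNDLE / "abundance.tsv"))
    class_of = dict(zip(classes.frame.gene_id, classes.frame.gene_class))

    sd_set = enumerate_core_sd_set(core.extended_rna)["sd"]
    rows = []
    for sd in sd_set:
        dg = duplex_dG(sd, rna_revcomp(sd))
        sub = matches[matches.sd == sd]
        rows.append(
            {
                "sd": sd, "m": len(sd), "dG_kcal_mol": dg,
                "usage_all": len(sub),
                "usage_heg": sum(class_of.get(g) == HEG for g in sub.gene),
                "usage_leg": sum(class_of.get(g) == LEG for g in sub.gene),
            }
        )
    aff = pd.DataFrame(rows)
    aff.to_csv(ROOT / "affinity.tsv", sep="\t", index=False)
    print(aff.round(2).to_string(index=False))

    fits = {}
    for label, col in (("all", "usage_all"), (HEG, "usage_heg"), (LEG, "usage_leg")):
        pts = pd.DataFrame({"sd": aff.sd, "usage": aff[col], "dG": aff.dG_kcal_mol})
        fits[label] = fit_usage_vs_affinity(pts, gene_class=label)
        print(f"{label}: R2 = {fits[label].r_squared:.4f}, "
              f"P = {fits[label].p_value:.4g}, optimum dG = {fits[label].opt_dG}")
    pd.DataFrame(
        [{"gene_class": k, "r2": f.r_squared, "p": f.p_value,
          "opt_dG": f.opt_dG, "quad_coef": f.curvature} for k, f in fits.items()]
    ).to_csv(ROOT / "fit.tsv", sep="\t", index=False)

    contrast = contrast_heg_leg(fits[HEG], fits[LEG])
    contrast.table.to_csv(ROOT / "heg_leg_contrast.tsv", sep="\t", index=False)
    print(f"HEG-enriched SD: {contrast.top_sd} "
          f"(prop HEG {contrast.table.set_index('sd').loc[contrast.top_sd, 'prop_heg']:.2f} "
          f"vs LEG {contrast.table.set_index('sd').loc[contrast.top_sd, 'prop_leg']:.2f})")


if __name__ == "__main__":
    main()
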