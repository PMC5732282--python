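"""Expression classes from protein abundance.

Genes are ranked by protein abundance (ppm, PaxDB-style) and the top and
bottom deciles of the genes with non-zero abundance become the highly and
lowly expressed classes (HEG / LEG). Zero or missing abundances are
excluded before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

__all__ = ["ExpressionClasses", "classify", "read_abundance_tsv"]

logger = logging.getLogger(__name__)

HEG, LEG, OTHER, EXCLUDED = "HEG", "LEG", "other", "excluded"


@dataclass
class ExpressionClasses:
    """Per-gene abundance, rank (1 = highest, over non-zero genes) and class."""

    frame: pd.DataFrame  # gene_id, abundance, rank, gene_class

    @property
    def heg(self) -> list:
        return self.frame.loc[self.frame.gene_class == HEG, "gene_id"].tolist()

    @property
    def leg(self) -> list:
        return self.frame.loc[self.frame.gene_class == LEG, "gene_id"].tolist()

    def gene_class(self, gene_id: str) -> str:
        row = self.frame.loc[self.frame.gene_id == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene id {gene_id!r}")
        return row.iloc[0].gene_class


def read_abundance_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Two-column TSV gene_id<TAB>abundance_ppm (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if isinstance(df.iloc[0, 1], str):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["gene_id", "abundance"][: df.shape[1]]
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")
    return df


def classify(
    abundance: Union[pd.DataFrame, Mapping[str, float]], fraction: float = 0.10
) -> ExpressionClasses:
    """Rank genes by abundance and label the top/bottom ``fraction`` deciles.

    Genes with zero or missing abundance are excluded from ranking. Ties at
    a decile boundary are broken by lexicographic gene id (deterministic)
    and logged. With fewer than 1/``fraction`` ranked genes the classes are
    empty, which is logged as a warning.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    if isinstance(abundance, Mapping):
        df = pd.DataFrame(
            {"gene_id": list(abundance), "abundance": list(abundance.values())}
        )
    else:
        df = abundance[["gene_id", "abundance"]].copy()
    if df.empty:
        raise ValueError("empty abundance table")
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")
    ranked_mask = df["abundance"].fillna(0) > 0
    ranked = df[ranked_mask].sort_values(
        ["abundance", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    n = len(ranked)
    k = int(np.floor(fraction * n))
    if k == 0:
        logger.warning(
            "only %d genes with non-zero abundance: floor(%.2f * %d) = 0, "
            "HEG/LEG classes are empty", n, fraction, n,
        )
    df = df.set_index("gene_id")
    df["rank"] = pd.Series(range(1, n + 1), index=ranked["gene_id"]).astype("Int64")
    df["gene_class"] = EXCLUDED
    df.loc[ranked["gene_id"], "gene_class"] = OTHER
    if k > 0:
        heg_ids = ranked["gene_id"].iloc[:k]
        leg_ids = ranked["gene_id"].iloc[-k:]
        df.loc[heg_ids, "gene_class"] = HEG
        df.loc[leg_ids, "gene_class"] = LEG
        for label, ids in ((HEG, heg_ids), (LEG, leg_ids)):
            boundary = df.loc[ids, "abundance"].iloc[-1 if label == HEG else 0]
            n_tied = int((df.loc[ranked["gene_id"], "abundance"] == boundary).sum())
            if n_tied > 1:
                logger.info(
                    "%s boundary abundance %g is tied among %d genes; "
                    "resolved by gene id order", label, boundary, n_tied,
                )
    return ExpressionClasses(df.reset_index()[["gene_id", "abundance", "rank", "gene_class"]])
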