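"""Observed vs expected anti-SD site usage and core anti-SD inference.

Each base of the 3' tail is an "aSD site". The observed usage of site p is
the number of putative SD matches whose paired tail segment covers p. Under
the null that an SD of length m is equally likely to pair with any of the
L - m + 1 possible tail windows, the expected usage is

    expected(p) = sum_m c(p, m, L) * N_m / (L - m + 1),

with N_m the number of observed matches of length m and
c(p, m, L) = min(p, L - p + 1, m, L - m + 1) the number of length-m windows
covering site p. Central sites are covered by more windows, so expected
usage peaks at the middle of the tail; the observed/expected ratio corrects
for this geometry. The core anti-SD is the longest contiguous run of sites
used more than expected (ratio > 1), optionally extended 5' through the
conserved CCUCC motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .sd_detect import SDMatch, TailSequence
from .seq_io import rna_revcomp

__all__ = [
    "SiteUsageTable",
    "CoreASD",
    "observed_usage",
    "expected_usage",
    "usage_ratio",
    "infer_core_asd",
    "enumerate_core_sd_set",
]


def observed_usage(matches: Sequence[SDMatch], L: int) -> np.ndarray:
    """Per-site observed counts: each match increments every covered tail site."""
    obs = np.zeros(L, dtype=float)
    for m in matches:
        if not (1 <= m.p_start <= m.p_end <= L):
            raise ValueError(
                f"match segment [{m.p_start},{m.p_end}] outside tail of length {L}"
            )
        obs[m.p_start - 1 : m.p_end] += 1
    return obs


def _coverage_coefficient(p: int, m: int, L: int) -> int:
    return min(p, L - p + 1, m, L - m + 1)


def expected_usage(
    n_m: Union[Mapping[int, float], Sequence[SDMatch]],
    L: int,
    min_len: int = 4,
    max_len: int = 12,
    eq2_literal: bool = False,
) -> np.ndarray:
    """Null-model expected per-site usage, all length-m windows equiprobable.

    ``n_m`` is either a mapping length -> count or a match list from which
    the length spectrum is taken. ``eq2_literal`` substitutes, at site 6 of
    a 15-nt tail only, the historically printed coefficients for m = 11 (6)
    and m = 12 (5) in place of the combinatorial window counts (5 and 4);
    it exists for comparison and breaks conservation, so it is off by
    default.
    """
    if L < max_len:
        raise ValueError(f"tail length {L} shorter than max SD length {max_len}")
    if not isinstance(n_m, Mapping):
        counts: Dict[int, float] = {}
        for match in n_m:
            counts[match.m] = counts.get(match.m, 0) + 1
        n_m = counts
    exp = np.zeros(L, dtype=float)
    for m, count in n_m.items():
        if count == 0:
            continue
        if not (min_len <= m <= max_len):
            raise ValueError(f"SD length {m} outside [{min_len},{max_len}]")
        windows = L - m + 1
        for p in range(1, L + 1):
            c = _coverage_coefficient(p, m, L)
            if eq2_literal and L == 15 and p == 6 and m in (11, 12):
                c = {11: 6, 12: 5}[m]
            exp[p - 1] += c * count / windows
    return exp


def usage_ratio(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Per-site observed/expected; sites with expected == 0 are NaN (undefined)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected site vectors differ in length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    return ratio


@dataclass
class SiteUsageTable:
    """Per-site observed, expected and ratio for one gene class."""

    tail: TailSequence
    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray
    n_m: Dict[int, int]
    gene_class: str = "all"

    @classmethod
    def build(
        cls,
        matches: Sequence[SDMatch],
        tail: TailSequence,
        min_len: int = 4,
        max_len: int = 12,
        gene_class: str = "all",
        eq2_literal: bool = False,
    ) -> "SiteUsageTable":
        """Compute the table from matches already filtered to the optimal
        D_toStart range (and, for HEG/LEG tables, to the gene class)."""
        obs = observed_usage(matches, tail.L)
        n_m: Dict[int, int] = {}
        for m in matches:
            n_m[m.m] = n_m.get(m.m, 0) + 1
        exp = expected_usage(
            n_m, tail.L, min_len=min_len, max_len=max_len, eq2_literal=eq2_literal
        )
        return cls(tail, obs, exp, usage_ratio(obs, exp), n_m, gene_class)

    @property
    def L(self) -> int:
        return self.tail.L

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_class": self.gene_class,
                "site": np.arange(1, self.L + 1),
                "base": list(self.tail.rna),
                "observed": self.observed,
                "expected": self.expected,
                "ratio": self.ratio,
            }
        )


@dataclass(frozen=True)
class CoreASD:
    """The favored contiguous anti-SD segment, plus its CCUCC-extended form."""

    start: int  # 1-based tail sites, inclusive
    end: int
    rna: str
    extended_start: int
    extended_rna: str
    species: str = ""


def infer_core_asd(table: SiteUsageTable, tail: Optional[TailSequence] = None) -> CoreASD:
    """Longest contiguous run of sites with observed/expected ratio > 1.

    Ties between equally long runs go to the run with the larger summed
    observed - expected. The extended core prepends tail bases back through
    the full CCUCC motif when the run starts inside, or immediately 3' of,
    the motif; otherwise it equals the core.
    """
    if tail is None:
        tail = table.tail
    favored = np.nan_to_num(table.ratio, nan=0.0) > 1.0
    runs: List[Tuple[int, int]] = []
    start = None
    for idx in range(table.L + 1):
        on = idx < table.L and favored[idx]
        if on and start is None:
            start = idx
        elif not on and start is not None:
            runs.append((start + 1, idx))  # 1-based inclusive
            start = None
    if not runs:
        raise ValueError("no favored sites: no aSD site has observed/expected > 1")
    def run_key(run: Tuple[int, int]) -> Tuple[int, float]:
        a, b = run
        excess = float(np.sum(table.observed[a - 1 : b] - table.expected[a - 1 : b]))
        return (b - a + 1, excess)
    a, b = max(runs, key=run_key)
    c1, c2 = tail.core
    ext_start = c1 if c1 <= a <= c2 + 1 else a
    return CoreASD(
        start=a,
        end=b,
        rna=tail.segment(a, b),
        extended_start=ext_start,
        extended_rna=tail.segment(ext_start, b),
        species=tail.species,
    )


def enumerate_core_sd_set(
    extended_core: str,
    min_len: int = 4,
    max_len: int = 8,
    matches: Optional[Sequence[SDMatch]] = None,
) -> pd.DataFrame:
    """All SD strings complementary to (substrings of) the extended core.

    Returns a DataFrame (sd, m, usage) of the deduplicated substrings of the
    reverse complement of the extended core with lengths in range; ``usage``
    counts how often each string occurs verbatim as a match's SD (0 when no
    matches are supplied).
    """
    if not (1 <= min_len <= max_len <= 8) or min_len < 4:
        raise ValueError("SD lengths for the core set must satisfy 4 <= min <= max <= 8")
    anti = rna_revcomp(extended_core.upper().replace("T", "U"))
    seen: Dict[str, int] = {}
    for m in range(min_len, max_len + 1):
        for i in range(0, len(anti) - m + 1):
            seen.setdefault(anti[i : i + m], 0)
    if matches is not None:
        for match in matches:
            if match.sd in seen:
                seen[match.sd] += 1
    rows = sorted(seen.items(), key=lambda kv: (len(kv[0]), kv[0]))
    return pd.DataFrame(
        {"sd": [r[0] for r in rows], "m": [len(r[0]) for r in rows],
         "usage": [r[1] for r in rows]}
    )
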