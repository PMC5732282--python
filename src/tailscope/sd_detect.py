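"""Shine-Dalgarno detection by complementarity to the 16S rRNA 3' tail.

A putative SD sequence is a maximal ungapped stretch of the 30-nt region
upstream of a start codon that is the exact antiparallel Watson-Crick
complement of a segment of the mature 3' tail (G:U wobble pairs do not
count). Each match implies a pairing geometry summarised by D_toStart: the
number of mRNA nucleotides spanned from the base opposite the rRNA 3'
terminus to the first base of the start codon,

    D_toStart = g + (L - p_start + 1),

where g is the spacer (nt strictly between the SD 3' base and the start
codon), L the tail length and p_start the 1-based 5'-most tail site of the
paired segment. The canonical GGAGG/CCUCC pairing with a 7-nt spacer on the
15-nt Bacillus subtilis tail gives D_toStart = 17.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .seq_io import UpstreamRegion, rna_revcomp

__all__ = [
    "TailSequence",
    "SDMatch",
    "find_sd_matches",
    "filter_optimal",
    "dtostart_histogram",
    "best_per_gene",
]

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class TailSequence:
    """The mature 16S rRNA 3' tail (RNA, 5'->3') with its CCUCC core."""

    rna: str
    species: str = ""
    core: Tuple[int, int] = field(init=False)  # 1-based inclusive sites of CCUCC

    def __post_init__(self) -> None:
        rna = self.rna.upper().replace("T", "U")
        object.__setattr__(self, "rna", rna)
        if not re.fullmatch(r"[ACGU]+", rna):
            raise ValueError("tail must be an RNA string over ACGU")
        pos = rna.rfind("CCUCC")
        if pos < 0:
            raise ValueError("tail must contain the CCUCC core motif")
        if not (10 <= len(rna) <= 20):
            raise ValueError(f"tail length {len(rna)} outside the supported 10..20 range")
        object.__setattr__(self, "core", (pos + 1, pos + 5))

    @property
    def L(self) -> int:
        return len(self.rna)

    def segment(self, p_start: int, p_end: int) -> str:
        """1-based inclusive tail segment."""
        if not (1 <= p_start <= p_end <= self.L):
            raise ValueError(f"segment [{p_start},{p_end}] outside [1,{self.L}]")
        return self.rna[p_start - 1 : p_end]


@dataclass
class SDMatch:
    """One putative SD sequence and its pairing geometry.

    ``upstream_interval`` holds the SD's position relative to the first base
    of the start codon (negative, half-open): an SD occupying the 5 bases
    ending 7 nt before the start codon is (-12, -7).
    """

    gene_id: str
    sd: str
    m: int
    upstream_interval: Tuple[int, int]
    p_start: int
    p_end: int
    g: int
    d_to_start: int
    dG: Optional[float] = None

    def validate(self, tail: TailSequence) -> None:
        if not (self.p_end - self.p_start + 1 == self.m == len(self.sd)):
            raise ValueError("inconsistent match length")
        if self.sd != rna_revcomp(tail.segment(self.p_start, self.p_end)):
            raise ValueError("sd is not the antiparallel complement of its tail segment")
        if self.d_to_start != self.g + (tail.L - self.p_start + 1):
            raise ValueError("D_toStart inconsistent with spacer and tail segment")


def find_sd_matches(
    upstream: Union[str, UpstreamRegion],
    tail: TailSequence,
    min_len: int = 4,
    max_len: int = 12,
    gene_id: str = "",
) -> List[SDMatch]:
    """All maximal perfect-complement matches between an upstream window and the tail.

    The upstream RNA must read 5'->3' and end immediately before the start
    codon. A match is maximal if it cannot be extended by one more
    Watson-Crick pair in either direction within the two windows; maximal
    runs shorter than ``min_len`` or longer than ``max_len`` are not
    reported (sub-windows of a longer perfect duplex are never counted
    separately). N bases never pair.
    """
    if isinstance(upstream, UpstreamRegion):
        if not gene_id:
            gene_id = upstream.gene_id
        upstream = upstream.rna
    u = upstream.upper().replace("T", "U")
    if not re.fullmatch(r"[ACGUN]*", u):
        raise ValueError("upstream must be RNA over ACGUN")
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    n, L = len(u), tail.L
    matches: List[SDMatch] = []
    # Antiparallel pairing places upstream position x against tail position y
    # with x + y constant along a duplex; scan each such anti-diagonal for
    # maximal runs of Watson-Crick pairs.
    for s in range(0, n + L - 1):
        x_lo = max(0, s - (L - 1))
        x_hi = min(n - 1, s)
        run_start = None
        for x in range(x_lo, x_hi + 2):
            paired = x <= x_hi and _is_pair(u[x], tail.rna[s - x])
            if paired and run_start is None:
                run_start = x
            elif not paired and run_start is not None:
                matches.extend(
                    _emit(u, tail, gene_id, run_start, x - run_start, s, min_len, max_len)
                )
                run_start = None
    matches.sort(key=lambda m: (m.upstream_interval, m.p_start))
    return matches


def _emit(
    u: str,
    tail: TailSequence,
    gene_id: str,
    i: int,
    r: int,
    s: int,
    min_len: int,
    max_len: int,
) -> List[SDMatch]:
    if not (min_len <= r <= max_len):
        return []
    n, L = len(u), tail.L
    j0 = s - (i + r - 1)
    g = n - (i + r)
    p_start = j0 + 1
    match = SDMatch(
        gene_id=gene_id,
        sd=u[i : i + r],
        m=r,
        upstream_interval=(i - n, i + r - n),
        p_start=p_start,
        p_end=j0 + r,
        g=g,
        d_to_start=g + (L - p_start + 1),
    )
    match.validate(tail)
    return [match]


def filter_optimal(
    matches: Sequence[SDMatch], range_lo: int, range_hi: int
) -> List[SDMatch]:
    """Keep matches whose D_toStart lies in [range_lo, range_hi] (inclusive)."""
    if range_lo > range_hi:
        raise ValueError("range_lo must be <= range_hi")
    return [m for m in matches if range_lo <= m.d_to_start <= range_hi]


def dtostart_histogram(matches: Sequence[SDMatch]) -> Dict[int, int]:
    """Counts of putative SD matches per D_toStart distance (pre-filter)."""
    return dict(sorted(Counter(m.d_to_start for m in matches).items()))


def best_per_gene(matches: Sequence[SDMatch]) -> List[SDMatch]:
    """One match per gene: longest, then smallest D_toStart, then 5'-most."""
    best: Dict[str, SDMatch] = {}
    for m in matches:
        key = (-m.m, m.d_to_start, m.upstream_interval)
        cur = best.get(m.gene_id)
        if cur is None or key < (-cur.m, cur.d_to_start, cur.upstream_interval):
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda m: m.gene_id)
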