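"""Mapping reads onto the 3' end of the 16S rDNA and calling the mature tail.

The mature 16S rRNA 3' terminus is trimmed post-transcriptionally by several
exoribonucleases, so the genomic rDNA annotation can overshoot the RNA that
is actually present in the cell. Reads from non-ribo-depleted RNA-Seq pile
up at the true terminus: aligning them to the final stretch of the annotated
rDNA and histogramming where each read's 3'-most base lands reveals the
mature end(s).

Alignment is a deterministic exact-seed (default 20-mer) ungapped
seed-and-extend with a small substitution budget. Reads are only trusted for
terminus calling if they reach at least the final C of the conserved CCUCC
anti-Shine-Dalgarno core and are error-free from that motif to their 3' end.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .seq_io import ReadSet, revcomp, transcribe
from .sd_detect import TailSequence

__all__ = [
    "ReferenceTail3Region",
    "ReadAlignmentHit",
    "TerminusDistribution",
    "TailCall",
    "align_reads",
    "filter_hits",
    "terminus_distribution",
    "call_tail",
    "map_terminus",
]

CCUCC_DNA = "CCTCC"


@dataclass(frozen=True)
class ReferenceTail3Region:
    """The final stretch of an annotated 16S rDNA (DNA, 5'->3').

    ``ccucc_end`` is the 0-based index of the final C of the conserved CCUCC
    core (CCTCC at the DNA level).
    """

    sequence: str
    ccucc_end: int
    species: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if CCUCC_DNA not in seq:
            raise ValueError("reference 3' region must contain the CCTCC motif")
        e = self.ccucc_end
        if not (4 <= e < len(seq)) or seq[e - 4 : e + 1] != CCUCC_DNA:
            raise ValueError(f"ccucc_end={e} does not point at the final C of CCTCC")

    @classmethod
    def from_sequence(cls, sequence: str, species: str = "") -> "ReferenceTail3Region":
        """Locate the 3'-most CCTCC occurrence and anchor ``ccucc_end`` there."""
        seq = sequence.upper()
        pos = seq.rfind(CCUCC_DNA)
        if pos < 0:
            raise ValueError("reference 3' region must contain the CCTCC motif")
        return cls(seq, pos + 4, species)


@dataclass(frozen=True)
class ReadAlignmentHit:
    """One ungapped best hit of a read on the reference, in reference orientation."""

    read_id: str
    count: int
    ref_start: int
    ref_end: int  # half-open
    read_start: int
    read_end: int
    strand: str  # '+' if the read aligned as-is, '-' if reverse-complemented
    mismatch_ref_positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start != self.read_end - self.read_start:
            raise ValueError("ungapped hit must have equal-length intervals")
        for p in self.mismatch_ref_positions:
            if not (self.ref_start <= p < self.ref_end):
                raise ValueError("mismatch position outside aligned interval")

    @property
    def terminal_ref_pos(self) -> int:
        """Reference position of the read's 3'-most aligned base."""
        return self.ref_end - 1 if self.strand == "+" else self.ref_start

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_ref_positions)

    @property
    def aligned_len(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class TerminusDistribution:
    """Read-count histogram over candidate 3' end positions."""

    counts: Dict[int, int] = field(default_factory=dict)
    retained_total: int = 0
    discarded_total: int = 0
    unmapped_total: int = 0
    ccucc_end: Optional[int] = None

    @property
    def offsets(self) -> Dict[int, int]:
        """Counts keyed by offset relative to the final C of CCUCC."""
        if self.ccucc_end is None:
            raise ValueError("distribution has no CCUCC anchor")
        return {pos - self.ccucc_end: n for pos, n in sorted(self.counts.items())}

    def frequency(self, pos: int) -> float:
        return self.counts.get(pos, 0) / self.retained_total if self.retained_total else 0.0


@dataclass(frozen=True)
class TailCall:
    """Candidate mature tails and the designated (longest) one."""

    candidates: Tuple[TailSequence, ...]
    mature: TailSequence


def _kmer_index(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _best_diagonal_hit(
    read_seq: str, ref_seq: str, diagonals: Sequence[int], max_mismatch: int
) -> Optional[Tuple[int, int, int, int, Tuple[int, ...]]]:
    """Best full-overlap ungapped alignment over the given diagonals.

    A diagonal d places read position i at reference position i + d. Returns
    (ref_start, ref_end, read_start, read_end, mismatch_ref_positions) of the
    best valid hit (most aligned bases, fewest mismatches, leftmost on the
    reference) or None.
    """
    best = None
    best_key = None
    for d in sorted(set(diagonals)):
        read_start = max(0, -d)
        read_end = min(len(read_seq), len(ref_seq) - d)
        if read_end - read_start <= 0:
            continue
        mism = tuple(
            i + d
            for i in range(read_start, read_end)
            if read_seq[i] != ref_seq[i + d]
        )
        if len(mism) > max_mismatch:
            continue
        aligned = read_end - read_start
        key = (-aligned, len(mism), read_start + d)
        if best_key is None or key < best_key:
            best_key = key
            best = (read_start + d, read_end + d, read_start, read_end, mism)
    return best


def align_reads(
    reads: ReadSet,
    ref: ReferenceTail3Region,
    seed_len: int = 20,
    max_mismatch: int = 2,
) -> List[ReadAlignmentHit]:
    """Seed-and-extend ungapped alignment of reads onto the 3' region.

    A read is considered on every diagonal sharing an exact ``seed_len``-mer
    with the reference, in both orientations; the extension spans the full
    read/reference overlap on that diagonal. At most ``max_mismatch``
    substitutions are tolerated. One best hit is reported per read (most
    aligned bases, then fewest mismatches, then leftmost reference
    position, with '+' orientation preferred on exact ties). Reads with no
    seeded diagonal within budget are unmapped and simply absent from the
    result.
    """
    index = _kmer_index(ref.sequence, seed_len)
    hits: List[ReadAlignmentHit] = []
    for rec in reads:
        if len(rec.sequence) < seed_len:
            continue
        per_read_best = None
        per_read_key = None
        for strand, seq in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
            diagonals = [
                p - i
                for i in range(len(seq) - seed_len + 1)
                for p in index.get(seq[i : i + seed_len], ())
            ]
            if not diagonals:
                continue
            hit = _best_diagonal_hit(seq, ref.sequence, diagonals, max_mismatch)
            if hit is None:
                continue
            ref_start, ref_end, read_start, read_end, mism = hit
            key = (-(ref_end - ref_start), len(mism), ref_start, strand)
            if per_read_key is None or key < per_read_key:
                per_read_key = key
                per_read_best = ReadAlignmentHit(
                    rec.read_id, rec.count, ref_start, ref_end,
                    read_start, read_end, strand, mism,
                )
        if per_read_best is not None:
            hits.append(per_read_best)
    return hits


def filter_hits(
    hits: Sequence[ReadAlignmentHit], ref: ReferenceTail3Region
) -> List[ReadAlignmentHit]:
    """Retention rule for terminus calling.

    A hit is kept iff its terminal reference position reaches at least the
    final C of CCUCC and it has zero mismatches within or 3' of the motif
    (reference positions >= ccucc_end - 4).
    """
    zone_start = ref.ccucc_end - 4
    kept = []
    for hit in hits:
        if hit.terminal_ref_pos < ref.ccucc_end:
            continue
        if any(p >= zone_start for p in hit.mismatch_ref_positions):
            continue
        kept.append(hit)
    return kept


def terminus_distribution(
    retained: Sequence[ReadAlignmentHit], ref: Optional[ReferenceTail3Region] = None
) -> TerminusDistribution:
    """Histogram of 3'-most aligned positions, weighted by read multiplicity."""
    counts: Dict[int, int] = defaultdict(int)
    total = 0
    for hit in retained:
        counts[hit.terminal_ref_pos] += hit.count
        total += hit.count
    return TerminusDistribution(
        counts=dict(counts),
        retained_total=total,
        ccucc_end=ref.ccucc_end if ref is not None else None,
    )


def call_tail(
    dist: TerminusDistribution,
    ref: ReferenceTail3Region,
    tail_5prime_anchor: str = "GATCACCTCC",
    min_frac: float = 0.10,
) -> TailCall:
    """Call candidate mature tails from the terminus distribution.

    Every end position carrying at least ``min_frac`` of the retained reads
    becomes a candidate tail running from the conserved 5' anchor through
    that end (DNA transcribed to RNA). The designated mature tail is the
    longest candidate, mirroring the convention of adopting the longest of
    several major termini.
    """
    if dist.retained_total == 0 or not dist.counts:
        raise ValueError("empty terminus distribution")
    anchor_pos = ref.sequence.rfind(tail_5prime_anchor.upper())
    if anchor_pos < 0:
        raise ValueError(f"5' anchor {tail_5prime_anchor!r} not found in reference")
    candidates = []
    for pos in sorted(dist.counts):
        if dist.frequency(pos) >= min_frac and pos >= anchor_pos + len(tail_5prime_anchor) - 1:
            rna = transcribe(ref.sequence[anchor_pos : pos + 1])
            candidates.append(TailSequence(rna, species=ref.species))
    if not candidates:
        raise ValueError("no terminus reaches min_frac of retained reads")
    mature = max(candidates, key=lambda t: t.L)
    return TailCall(tuple(candidates), mature)


def map_terminus(
    reads: ReadSet,
    ref: ReferenceTail3Region,
    seed_len: int = 20,
    max_mismatch: int = 2,
) -> Tuple[List[ReadAlignmentHit], TerminusDistribution]:
    """Align, filter and histogram in one step, with full read accounting."""
    hits = align_reads(reads, ref, seed_len=seed_len, max_mismatch=max_mismatch)
    retained = filter_hits(hits, ref)
    dist = terminus_distribution(retained, ref)
    mapped_total = sum(h.count for h in hits)
    dist.discarded_total = mapped_total - dist.retained_total
    dist.unmapped_total = reads.total_reads - mapped_total
    return retained, dist
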