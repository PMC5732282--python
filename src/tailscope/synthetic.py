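"""Synthetic inputs with controlled ground truth.

Every pipeline stage can be exercised without downloads: the generator
emulates (i) 51-nt single-end RNA-Seq reads covering the 3' end of a 16S
rDNA reference, drawn from a mixture of true 3' termini with i.i.d.
substitution errors plus a fraction of interior windows that the CCUCC
retention filter must remove; (ii) a bacterial genome whose genes carry
Shine-Dalgarno motifs planted at controlled spacings upstream of their
start codons; and (iii) a protein-abundance table in which designated SD
classes can be enriched among highly expressed genes.

Each generator draws from its own labelled substream of the master seed, so
individual stages are reproducible in isolation and the whole bundle is
byte-identical for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import seq_io
from .seq_io import CDSRecord, GenomeAnnotation, Read, ReadSet, revcomp, rna_revcomp, transcribe
from .sd_detect import TailSequence, find_sd_matches
from .terminus_map import ReferenceTail3Region

__all__ = [
    "BSU_TAIL",
    "ECO_TAIL",
    "SyntheticSpec",
    "synthetic_tail3_reference",
    "gen_tail_reads",
    "gen_genome",
    "gen_abundance",
    "simulate_bundle",
]

#: Mature 3' tails used throughout: 15 nt (B. subtilis-like) and 13 nt
#: (E. coli-like), both carrying the conserved CCUCC core at sites 6-10.
BSU_TAIL = "GAUCACCUCCUUUCU"
ECO_TAIL = "GAUCACCUCCUUA"

_READS_STREAM, _GENOME_STREAM, _ABUND_STREAM, _REF_STREAM = 1, 2, 3, 4

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the real datasets the generator emulates: ~51-nt single
    reads at 1% substitution error, a dominant mature terminus 5 nt past
    the CCUCC core with minor shorter forms, 30-nt upstream windows with SD
    motifs drawn from complements of the B. subtilis-like tail at spacers
    centred on 7 nt, and log-normal protein abundances.
    """

    seed: int = 0
    # reads
    n_reads: int = 20_000
    read_len: int = 51
    terminus_mixture: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.60, 3: 0.25, 0: 0.15}
    )
    error_rate: float = 0.01
    interior_fraction: float = 0.10
    # genome
    n_genes: int = 300
    sd_pool: Mapping[str, float] = field(
        default_factory=lambda: {
            "AGGAGG": 0.25, "GGAGG": 0.25, "AGGAG": 0.15,
            "AAAGGAG": 0.15, "GGAG": 0.10, "GAGG": 0.10,
        }
    )
    spacer_dist: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.10, 6: 0.20, 7: 0.40, 8: 0.20, 9: 0.10}
    )
    sdless_fraction: float = 0.20
    gc: float = 0.45
    # abundance
    zero_abundance_fraction: float = 0.10
    abundance_sigma: float = 1.0
    heg_effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mix in (("terminus_mixture", self.terminus_mixture),
                          ("sd_pool", self.sd_pool),
                          ("spacer_dist", self.spacer_dist)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        if not (0.0 <= self.interior_fraction < 1.0):
            raise ValueError("interior_fraction must lie in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def synthetic_tail3_reference(
    species: str = "bsu", seed: int = 0, length: Optional[int] = None, gc: float = 0.5
) -> ReferenceTail3Region:
    """A synthetic stand-in for the final stretch of an annotated 16S rDNA.

    The 3' portion is the known mature tail (at the DNA level) followed by a
    short genomic extension that the maturation machinery would trim away;
    the 5' filler is random sequence constrained to contain no second CCTCC
    or anchor occurrence. The real annotated rDNA is not shipped; this is a
    synthetic construct with the same landmark structure.
    """
    tail = {"bsu": BSU_TAIL, "eco": ECO_TAIL}[species]
    mature_dna = tail.replace("U", "T")
    if length is None:
        length = 85 if species == "bsu" else 60
    ext_len = 5
    bg_len = length - len(mature_dna) - ext_len
    if bg_len < 41:
        raise ValueError("reference too short for 51-nt reads ending at the CCUCC core")
    rng = np.random.default_rng([int(seed), _REF_STREAM])
    for _ in range(100):
        bg = _random_dna(rng, bg_len, gc)
        ext = _random_dna(rng, ext_len, gc)
        seq = bg + mature_dna + ext
        if seq.count("CCTCC") == 1 and seq.count("GATCACCTCC") == 1:
            return ReferenceTail3Region.from_sequence(seq, species=species)
    raise RuntimeError("could not build a reference without spurious CCTCC motifs")


def gen_tail_reads(
    spec: SyntheticSpec, ref: ReferenceTail3Region
) -> Tuple[ReadSet, pd.DataFrame]:
    """Reads ending at termini drawn from the mixture, plus a per-read truth table.

    A ``spec.interior_fraction`` share of reads are interior windows of the
    reference (ending strictly before the CCUCC core) that exercise the
    retention filter. Truth records each read's true end, terminus offset,
    error count, and whether any error fell at reference positions within
    or 3' of the CCUCC motif (the filter's exclusion zone).
    """
    rlen = spec.read_len
    if len(ref.sequence) < rlen:
        raise ValueError("reference shorter than the read length")
    offsets = sorted(spec.terminus_mixture)
    probs = np.array([spec.terminus_mixture[o] for o in offsets])
    for o in offsets:
        end = ref.ccucc_end + o
        if not (rlen - 1 <= end < len(ref.sequence)):
            raise ValueError(f"terminus offset {o:+d} falls outside the reference")
    rng = spec.rng(_READS_STREAM)
    zone_start = ref.ccucc_end - 4
    bases = np.frombuffer(b"ACGT", dtype="S1")
    records = []
    rows = []
    is_interior = rng.random(spec.n_reads) < spec.interior_fraction
    offset_draws = rng.choice(len(offsets), size=spec.n_reads, p=probs)
    interior_ends = rng.integers(rlen - 1, ref.ccucc_end, size=spec.n_reads)
    for i in range(spec.n_reads):
        if is_interior[i]:
            end = int(interior_ends[i])
            offset: Optional[int] = None
        else:
            offset = offsets[offset_draws[i]]
            end = ref.ccucc_end + offset
        start = end - rlen + 1
        seq = np.frombuffer(ref.sequence[start : end + 1].encode(), dtype="S1").copy()
        err_mask = rng.random(rlen) < spec.error_rate
        n_err = int(err_mask.sum())
        zone_err = 0
        if n_err:
            for j in np.nonzero(err_mask)[0]:
                alt = bases[bases != seq[j]]
                seq[j] = alt[rng.integers(3)]
                if start + j >= zone_start:
                    zone_err += 1
        records.append(Read(f"read{i}", seq.tobytes().decode(), 1))
        rows.append(
            (f"read{i}", bool(is_interior[i]), end,
             offset if offset is not None else np.nan, n_err, zone_err)
        )
    truth = pd.DataFrame(
        rows, columns=["read_id", "interior", "true_end", "offset", "n_errors",
                       "errors_in_motif_zone"],
    )
    return ReadSet(records), truth


def _build_upstream(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    tail: TailSequence,
    sd: Optional[str],
    spacer: Optional[int],
    max_attempts: int = 60,
) -> Tuple[str, list, bool]:
    """A 30-nt upstream window whose SD content is exactly as planted.

    Resamples the background until the complementarity scan finds exactly
    the planted match (or none for SD-less genes); after ``max_attempts``
    the last draw is accepted and flagged as carrying spurious matches.
    """
    width = 30
    for attempt in range(max_attempts):
        up = list(_random_dna(rng, width, spec.gc))
        if sd is not None:
            sd_dna = sd.replace("U", "T")
            pos = width - spacer - len(sd)
            up[pos : pos + len(sd)] = sd_dna
        up_dna = "".join(up)
        matches = find_sd_matches(transcribe(up_dna), tail)
        if sd is None:
            ok = not matches
        else:
            ok = (
                len(matches) == 1
                and matches[0].sd == sd
                and matches[0].g == spacer
            )
        if ok:
            return up_dna, matches, False
    return up_dna, matches, True


def gen_genome(
    spec: SyntheticSpec, tail: Optional[TailSequence] = None
) -> Tuple[GenomeAnnotation, pd.DataFrame]:
    """A single-contig genome with SD motifs planted at sampled spacings.

    Every SD string in the pool must be a perfect complement of a tail
    segment (a substring of the tail's reverse complement). Genes land on
    random strands; the 30-nt window upstream of each start codon contains
    exactly the planted SD match (background resampled to suppress spurious
    complements; residual failures are recorded in the truth table).
    """
    if tail is None:
        tail = TailSequence(BSU_TAIL, species="bsu")
    anti = rna_revcomp(tail.rna)
    for sd in spec.sd_pool:
        if sd.replace("T", "U") not in anti:
            raise ValueError(
                f"SD {sd!r} is not a substring of the tail's reverse complement "
                f"{anti!r}; it could never arise from perfect SD/aSD pairing"
            )
    rng = spec.rng(_GENOME_STREAM)
    sds = sorted(spec.sd_pool)
    sd_p = np.array([spec.sd_pool[s] for s in sds])
    spacers = sorted(spec.spacer_dist)
    sp_p = np.array([spec.spacer_dist[g] for g in spacers])

    parts = []
    cds_records = []
    rows = []
    pos = 0
    pad = 10
    for i in range(spec.n_genes):
        gene_id = f"g{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        has_sd = rng.random() >= spec.sdless_fraction
        sd = str(rng.choice(sds, p=sd_p)).replace("T", "U") if has_sd else None
        spacer = int(rng.choice(spacers, p=sp_p)) if has_sd else None
        upstream, matches, spurious = _build_upstream(rng, spec, tail, sd, spacer)
        n_codons = int(rng.integers(20, 41))
        cds = "ATG" + "".join(rng.choice(_CODONS, size=n_codons)) + "TAA"
        cassette = upstream + cds
        if strand == "+":
            parts.append(cassette)
            cds_records.append(
                CDSRecord(gene_id, "chr", pos + 30, pos + len(cassette), "+")
            )
        else:
            parts.append(revcomp(cassette))
            cds_records.append(CDSRecord(gene_id, "chr", pos, pos + len(cds), "-"))
        pos += len(cassette)
        parts.append(_random_dna(rng, pad, spec.gc))
        pos += pad
        match = matches[0] if (has_sd and matches) else None
        rows.append(
            {
                "gene_id": gene_id,
                "strand": strand,
                "has_sd": has_sd,
                "sd": sd or "",
                "m": len(sd) if sd else 0,
                "g": spacer if spacer is not None else np.nan,
                "p_start": match.p_start if match else np.nan,
                "p_end": match.p_end if match else np.nan,
                "d_to_start": match.d_to_start if match else np.nan,
                "spurious": spurious,
                "n_matches": len(matches) if has_sd or spurious else 0,
            }
        )
    genome = GenomeAnnotation({"chr": "".join(parts)}, cds_records)
    return genome, pd.DataFrame(rows)


def gen_abundance(truth: pd.DataFrame, spec: SyntheticSpec) -> pd.DataFrame:
    """Log-normal protein abundances, optionally boosted per SD class.

    Genes whose planted SD appears in ``spec.heg_effect`` have their
    abundance multiplied by the given factor, enriching the top decile for
    those SD classes; a ``spec.zero_abundance_fraction`` share of genes get
    zero abundance (excluded from expression ranking downstream). The
    returned frame keeps the intended boost per gene as truth.
    """
    rng = spec.rng(_ABUND_STREAM)
    n = len(truth)
    base = np.exp(rng.normal(3.0, spec.abundance_sigma, size=n)) * 10.0
    boost = np.array([spec.heg_effect.get(sd, 1.0) for sd in truth["sd"]])
    abundance = base * boost
    zero = rng.random(n) < spec.zero_abundance_fraction
    abundance[zero] = 0.0
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "abundance": abundance,
            "boost": boost,
        }
    )


def simulate_bundle(
    spec: SyntheticSpec,
    species: str = "bsu",
    out_dir: Optional[Path] = None,
) -> Dict[str, object]:
    """Generate reads, genome, annotation and abundance in one call.

    With ``out_dir`` set, writes reads.fastq, ref3.fasta, genome.fasta,
    annot.gff3, abundance.tsv and truth/*.tsv.
    """
    ref = synthetic_tail3_reference(species, seed=spec.seed)
    tail = TailSequence({"bsu": BSU_TAIL, "eco": ECO_TAIL}[species], species=species)
    reads, reads_truth = gen_tail_reads(spec, ref)
    genome, genome_truth = gen_genome(spec, tail)
    abundance = gen_abundance(genome_truth, spec)
    bundle = {
        "ref": ref,
        "tail": tail,
        "reads": reads,
        "reads_truth": reads_truth,
        "genome": genome,
        "genome_truth": genome_truth,
        "abundance": abundance,
    }
    if out_dir is not None:
        out = Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        seq_io.write_fastq(reads, out / "reads.fastq")
        seq_io.write_fasta({f"ref3_{species}": ref.sequence}, out / "ref3.fasta")
        seq_io.write_fasta({"chr": genome.sequences["chr"]}, out / "genome.fasta")
        seq_io.write_annotation_gff3(genome, out / "annot.gff3")
        abundance[["gene_id", "abundance"]].to_csv(
            out / "abundance.tsv", sep="\t", index=False, header=False
        )
        reads_truth.to_csv(out / "truth" / "reads.tsv", sep="\t", index=False)
        genome_truth.to_csv(out / "truth" / "genes.tsv", sep="\t", index=False)
        abundance.to_csv(out / "truth" / "abundance.tsv", sep="\t", index=False)
    return bundle
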