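"""End-to-end orchestration: map tail -> find SD -> usage -> affinity.

`run_all` wires the stages together on real or synthetic inputs, writes
every stage's table under the output directory and records a manifest
(parameters, package version, input digests) so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml

from . import __version__, seq_io
from .affinity import (
    UsageAffinityFit,
    contrast_heg_leg,
    duplex_dG,
    fit_usage_vs_affinity,
)
from .expression import HEG, LEG, classify, read_abundance_tsv
from .sd_detect import (
    SDMatch,
    TailSequence,
    best_per_gene,
    dtostart_histogram,
    filter_optimal,
    find_sd_matches,
)
from .seq_io import GenomeAnnotation, extract_upstream
from .terminus_map import ReferenceTail3Region, call_tail, map_terminus
from .usage_stats import SiteUsageTable, enumerate_core_sd_set, infer_core_asd

__all__ = ["PipelineConfig", "PipelineStageError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, with a master seed and manifest."""

    out_dir: Union[str, Path] = "tailscope_out"
    reads: Optional[str] = None
    ref3: Optional[str] = None
    genome: Optional[str] = None
    annotation: Optional[str] = None
    abundance: Optional[str] = None
    tail: Optional[str] = None  # override: skip terminus mapping
    seed_len: int = 20
    max_mismatch: int = 2
    min_frac: float = 0.10
    min_sd_len: int = 4
    max_sd_len: int = 12
    optimal_range: Union[str, Tuple[int, int]] = "auto"
    upstream_width: int = 30
    classify_fraction: float = 0.10
    engine: str = "auto"
    best_per_gene_only: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if isinstance(raw.get("optimal_range"), list):
            raw["optimal_range"] = tuple(raw["optimal_range"])
        return cls(**raw)


def _digest(path: Optional[Union[str, Path]]) -> Optional[str]:
    if path is None:
        return None
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _auto_range(hist: Dict[int, int]) -> Tuple[int, int]:
    """[mode - 2, mode + 4] around the modal D_toStart (explicit ranges are
    the documented way to reproduce published windows)."""
    mode = max(hist, key=lambda d: (hist[d], -d))
    return mode - 2, mode + 4


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("map-tail")
def _stage_map_tail(config, out: Path) -> TailSequence:
    if config.reads is None or config.ref3 is None:
        raise FileNotFoundError("terminus mapping needs --reads and --ref FASTA")
    reads = seq_io.read_fastq(config.reads)
    reads = seq_io.dedupe_reads(reads)
    ref_seqs = seq_io.read_fasta(config.ref3)
    ref = ReferenceTail3Region.from_sequence(next(iter(ref_seqs.values())))
    retained, dist = map_terminus(
        reads, ref, seed_len=config.seed_len, max_mismatch=config.max_mismatch
    )
    rows = [
        {
            "end_pos": pos,
            "offset_vs_ccucc": pos - ref.ccucc_end,
            "count": n,
            "frac": n / dist.retained_total,
        }
        for pos, n in sorted(dist.counts.items())
    ]
    pd.DataFrame(rows).to_csv(out / "terminus_distribution.tsv", sep="\t", index=False)
    tail_call = call_tail(dist, ref, min_frac=config.min_frac)
    pd.DataFrame(
        {
            "tail_rna": [t.rna for t in tail_call.candidates],
            "length": [t.L for t in tail_call.candidates],
            "is_mature": [t == tail_call.mature for t in tail_call.candidates],
        }
    ).to_csv(out / "tail_call.tsv", sep="\t", index=False)
    logger.info(
        "map-tail: %d retained / %d discarded / %d unmapped; mature tail %s",
        dist.retained_total, dist.discarded_total, dist.unmapped_total,
        tail_call.mature.rna,
    )
    return tail_call.mature


@_stage("find-sd")
def _stage_find_sd(
    config, tail: TailSequence, annotation: GenomeAnnotation, out: Path
) -> Tuple[List[SDMatch], List[SDMatch], Tuple[int, int]]:
    matches: List[SDMatch] = []
    for gene_id in annotation.gene_ids:
        up = extract_upstream(annotation, gene_id, width=config.upstream_width)
        matches.extend(
            find_sd_matches(
                up, tail, min_len=config.min_sd_len, max_len=config.max_sd_len
            )
        )
    if config.best_per_gene_only:
        matches = best_per_gene(matches)
    hist = dtostart_histogram(matches)
    if config.optimal_range == "auto":
        if not hist:
            raise ValueError("no SD matches found; cannot derive an optimal range")
        lo, hi = _auto_range(hist)
    else:
        lo, hi = config.optimal_range
    kept = filter_optimal(matches, lo, hi)
    pd.DataFrame(
        {
            "gene": [m.gene_id for m in matches],
            "sd": [m.sd for m in matches],
            "m": [m.m for m in matches],
            "g": [m.g for m in matches],
            "p_start": [m.p_start for m in matches],
            "p_end": [m.p_end for m in matches],
            "DtoStart": [m.d_to_start for m in matches],
            "in_optimal_range": [lo <= m.d_to_start <= hi for m in matches],
        }
    ).to_csv(out / "sd_matches.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"DtoStart": list(hist), "count": list(hist.values())}
    ).to_csv(out / "dtostart_histogram.tsv", sep="\t", index=False)
    logger.info(
        "find-sd: %d matches, %d in optimal range [%d,%d]", len(matches), len(kept), lo, hi
    )
    return matches, kept, (lo, hi)


@_stage("usage")
def _stage_usage(
    config,
    tail: TailSequence,
    kept: List[SDMatch],
    class_of: Optional[Dict[str, str]],
    out: Path,
):
    tables = {
        "all": SiteUsageTable.build(
            kept, tail, config.min_sd_len, config.max_sd_len, gene_class="all"
        )
    }
    if class_of is not None:
        for label in (HEG, LEG):
            subset = [m for m in kept if class_of.get(m.gene_id) == label]
            tables[label] = SiteUsageTable.build(
                subset, tail, config.min_sd_len, config.max_sd_len, gene_class=label
            )
    pd.concat([t.to_frame() for t in tables.values()]).to_csv(
        out / "usage_table.tsv", sep="\t", index=False
    )
    core = infer_core_asd(tables["all"], tail)
    pd.DataFrame(
        [
            {
                "core_start": core.start,
                "core_end": core.end,
                "core_rna": core.rna,
                "extended_start": core.extended_start,
                "extended_rna": core.extended_rna,
            }
        ]
    ).to_csv(out / "core_asd.tsv", sep="\t", index=False)
    logger.info("usage: core aSD %s (extended %s)", core.rna, core.extended_rna)
    return tables, core


@_stage("affinity")
def _stage_affinity(config, tail, core, kept, class_of, out: Path):
    core_set = enumerate_core_sd_set(core.extended_rna, 4, min(8, config.max_sd_len), kept)
    core_set["dG_kcal_mol"] = [
        duplex_dG(sd, seq_io.rna_revcomp(sd), engine=config.engine)
        for sd in core_set["sd"]
    ]
    usage_cols = {"usage_all": core_set["usage"]}
    if class_of is not None:
        for label, col in ((HEG, "usage_heg"), (LEG, "usage_leg")):
            subset = [m for m in kept if class_of.get(m.gene_id) == label]
            tagged = enumerate_core_sd_set(
                core.extended_rna, 4, min(8, config.max_sd_len), subset
            )
            usage_cols[col] = tagged["usage"]
    aff = pd.DataFrame({"sd": core_set["sd"], "m": core_set["m"],
                        "dG_kcal_mol": core_set["dG_kcal_mol"], **usage_cols})
    aff.to_csv(out / "affinity.tsv", sep="\t", index=False)

    fits: Dict[str, UsageAffinityFit] = {}
    fit_rows = []
    for label, col in (("all", "usage_all"), (HEG, "usage_heg"), (LEG, "usage_leg")):
        if col not in aff:
            continue
        pts = pd.DataFrame({"sd": aff["sd"], "usage": aff[col], "dG": aff["dG_kcal_mol"]})
        fits[label] = fit_usage_vs_affinity(pts, gene_class=label)
        fit_rows.append(
            {
                "gene_class": label,
                "r2": fits[label].r_squared,
                "p": fits[label].p_value,
                "opt_dG": fits[label].opt_dG,
                "quad_coef": fits[label].curvature,
            }
        )
    pd.DataFrame(fit_rows).to_csv(out / "fit.tsv", sep="\t", index=False)

    contrast = None
    if HEG in fits and LEG in fits:
        try:
            contrast = contrast_heg_leg(fits[HEG], fits[LEG])
        except ValueError as exc:
            logger.warning("HEG/LEG contrast skipped: %s", exc)
    if contrast is not None:
        contrast.table.to_csv(out / "heg_leg_contrast.tsv", sep="\t", index=False)
        logger.info(
            "affinity: HEG-enriched SD %s; sharpness HEG %.3g vs LEG %.3g",
            contrast.top_sd, contrast.sharpness_heg, contrast.sharpness_leg,
        )
    return aff, fits, contrast


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage and return the run manifest.

    Stages: terminus mapping (skipped when ``config.tail`` overrides the
    tail) -> SD detection over all annotated CDSs -> site-usage tables for
    all genes and, when an abundance table is supplied, for HEG/LEG ->
    core-aSD inference -> duplex affinities and usage-vs-ΔG fits ->
    HEG/LEG contrast. Any failure raises :class:`PipelineStageError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.tail:
        tail = TailSequence(config.tail)
        logger.info("tail override: %s (terminus mapping skipped)", tail.rna)
    else:
        tail = _stage_map_tail(config, out)

    if config.genome is None or config.annotation is None:
        raise PipelineStageError(
            "find-sd", FileNotFoundError("genome FASTA and annotation are required")
        )
    try:
        if str(config.annotation).endswith((".gff", ".gff3")):
            annotation = seq_io.read_annotation_gff3(config.genome, config.annotation)
        else:
            annotation = seq_io.read_annotation_tsv(config.genome, config.annotation)
    except Exception as exc:
        raise PipelineStageError("load-annotation", exc) from exc

    class_of = None
    if config.abundance is not None:
        try:
            if not Path(config.abundance).exists():
                raise FileNotFoundError(
                    f"abundance file not found: {config.abundance}"
                )
            classes = classify(
                read_abundance_tsv(config.abundance), fraction=config.classify_fraction
            )
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("classify-expression", exc) from exc
        class_of = dict(zip(classes.frame.gene_id, classes.frame.gene_class))
        classes.frame.to_csv(out / "expression_classes.tsv", sep="\t", index=False)

    matches, kept, (lo, hi) = _stage_find_sd(config, tail, annotation, out)
    tables, core = _stage_usage(config, tail, kept, class_of, out)
    aff, fits, contrast = _stage_affinity(config, tail, core, kept, class_of, out)

    manifest = {
        "tailscope_version": __version__,
        "python": platform.python_version(),
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "optimal_range_used": [lo, hi],
        "tail": tail.rna,
        "core_asd": core.rna,
        "core_asd_extended": core.extended_rna,
        "n_matches": len(matches),
        "n_matches_optimal": len(kept),
        "input_digests": {
            name: _digest(getattr(config, name))
            for name in ("reads", "ref3", "genome", "annotation", "abundance")
            if getattr(config, name)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
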