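"""Readers and writers for the pipeline's plain-text formats.

Ratio tracks travel as 4-column TSV (chrom, probe_start 0-based, strand,
log2_ratio), one file per (strand, replicate).  Annotation is BED6 or GTF
(GTF's 1-based closed coordinates are converted on read).  Domains and
planted truth are written as BED6.  All coordinates are 0-based half-open
internally and in every output.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .classification import DomainClass
from .types import (
    FormatError,
    GeneModel,
    ProbeMap,
    RatioTrack,
    TranscriptDomain,
    TruthSet,
)

logger = logging.getLogger(__name__)

_TRACK_COLUMNS = ["chrom", "probe_start", "strand", "log2_ratio"]


def write_ratio_track(track: RatioTrack, path) -> None:
    pd.DataFrame(
        {
            "chrom": track.probe_map.chrom,
            "probe_start": track.probe_map.positions,
            "strand": track.probe_map.strand,
            "log2_ratio": track.values,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_ratio_track(path, expected_strand: str, probe_length: int = 25) -> Dict[str, RatioTrack]:
    """Read a 4-column TSV into one RatioTrack per chromosome.

    Probes are sorted by position (with a logged warning if the file was
    unsorted); duplicate positions, non-numeric ratios and strand mismatches
    are format errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_TRACK_COLUMNS, dtype={"chrom": str, "strand": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty ratio-track file") from None
    if df.empty:
        raise FormatError(f"{path}: empty ratio-track file")
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    if ratios.isna().any():
        bad = df.loc[ratios.isna()].index[0] + 1
        raise FormatError(f"{path}: non-numeric log2_ratio at line {bad}")
    starts = pd.to_numeric(df["probe_start"], errors="coerce")
    if starts.isna().any():
        raise FormatError(f"{path}: non-integer probe_start")
    if (df["strand"] != expected_strand).any():
        raise FormatError(f"{path}: strand column does not match expected strand {expected_strand!r}")
    df = df.assign(log2_ratio=ratios, probe_start=starts.astype(np.int64))
    tracks: Dict[str, RatioTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        if not sub["probe_start"].is_monotonic_increasing:
            logger.warning("%s: probes for %s were unsorted; sorting", path, chrom)
            sub = sub.sort_values("probe_start")
        if sub["probe_start"].duplicated().any():
            raise FormatError(f"{path}: duplicate probe position on {chrom}")
        pmap = ProbeMap(
            chrom=str(chrom),
            strand=expected_strand,
            positions=sub["probe_start"].to_numpy(),
            probe_length=probe_length,
        )
        tracks[str(chrom)] = RatioTrack(probe_map=pmap, values=sub["log2_ratio"].to_numpy())
    return tracks


def read_gene_catalog(path) -> List[GeneModel]:
    """Read BED6 (0-based half-open) or GTF gene features (converted)."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    return _read_bed6(path)


def _read_bed6(path: Path) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{ln}: BED6 requires 6 columns (strand is mandatory)")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: missing or invalid strand {strand!r}")
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(f"{path}:{ln}: start ({start}) must be < end ({end})")
            genes.append(GeneModel(chrom=chrom, strand=strand, start=start, end=end, name=name))
    return genes


def _read_gtf(path: Path) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{ln}: GTF requires >= 8 columns")
            chrom, _src, feature, start, end, _score, strand, _frame = fields[:8]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: missing or invalid strand {strand!r}")
            start0, end0 = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
            if start0 >= end0:
                raise FormatError(f"{path}:{ln}: start must be < end after conversion")
            name = f"gene_{ln}"
            if len(fields) > 8:
                for attr in fields[8].split(";"):
                    attr = attr.strip()
                    for key in ("gene_id", "gene_name"):
                        if attr.startswith(key):
                            name = attr[len(key):].strip().strip('"')
            genes.append(GeneModel(chrom=chrom, strand=strand, start=start0, end=end0, name=name))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def write_truth_bed(truth: TruthSet, path) -> None:
    """Planted truth as BED6: name = direction, score = |effect| x 1000, capped."""
    with open(path, "w") as fh:
        for d in truth.domains:
            score = min(1000, round(abs(d.effect) * 1000))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t{score}\t{d.strand}\n")


def domain_bed_name(domain: TranscriptDomain, cls: Optional[DomainClass] = None) -> str:
    parts = [domain.direction]
    if cls is not None:
        if cls.intergenic:
            parts.append("intergenic")
        if cls.sense:
            parts.append("sense")
        if cls.antisense:
            parts.append("antisense")
        if cls.is_vlinc:
            parts.append("vlinc")
    return ";".join(parts)


def write_domains_bed(
    domains: Sequence[TranscriptDomain],
    path,
    classes: Optional[Sequence[Optional[DomainClass]]] = None,
) -> None:
    """Domains as BED6; name encodes direction and classes, score = min(1000,
    round(|mean_ratio| x 1000))."""
    if classes is None:
        classes = [None] * len(domains)
    with open(path, "w") as fh:
        for dom, cls in zip(domains, classes):
            score = min(1000, round(abs(dom.mean_ratio) * 1000))
            fh.write(
                f"{dom.chrom}\t{dom.start}\t{dom.end}\t{domain_bed_name(dom, cls)}\t{score}\t{dom.strand}\n"
            )


def read_domains_bed(path) -> List[dict]:
    """Read a domains BED back as dicts (chrom, start, end, strand, direction).

    Only the genomic span and direction survive a BED round trip; probe
    indices do not, so the result is a plain record, not a TranscriptDomain.
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{ln}: BED6 requires 6 columns")
            chrom, start, end, name, score, strand = fields[:6]
            direction = name.split(";")[0]
            records.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "direction": direction,
                    "score": int(score),
                }
            )
    return records
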