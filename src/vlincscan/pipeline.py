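"""End-to-end orchestration: tracks -> segmentation -> significance ->
classification -> summaries -> activation-bias test.

The two strands are processed as fully independent datasets (the array
design measures them independently); results are pooled only for the
summary tables.  Every run writes a machine-readable manifest recording the
resolved parameters, the seed, and the headline counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from . import io as vio
from .classification import (
    antisense_concordance,
    classify_domain,
    summarize_genes,
    summarize_table1,
)
from .segmentation import run_segmentation
from .significance import assign_pvalues, filter_significant
from .stats import ChiSquareResult, activation_bias_test
from .types import (
    ACTIVATED,
    ParameterSet,
    RatioTrack,
    TranscriptDomain,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved inputs and knobs for one pipeline run.

    ``track_paths`` maps strand ('+'/'-') to the list of per-replicate ratio
    track TSVs for that strand (>= 2 per strand).
    """

    track_paths: Dict[str, List[str]]
    annotation_path: Optional[str] = None
    params: ParameterSet = field(default_factory=ParameterSet)
    n_randomizations: int = 199
    seed: int = 0
    randomization: str = "shuffle"
    probe_length: int = 25
    outdir: Optional[str] = None

    def validate(self) -> None:
        if not self.track_paths:
            raise ValidationError("config lists no ratio tracks")
        for strand, paths in self.track_paths.items():
            if strand not in ("+", "-"):
                raise ValidationError(f"bad strand key {strand!r}")
            if len(paths) < 2:
                raise ValidationError(f"strand {strand}: segmentation needs >= 2 replicates")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = ParameterSet(**raw.get("params", {}))
        return PipelineConfig(
            track_paths={str(k): list(v) for k, v in raw.get("tracks", {}).items()},
            annotation_path=raw.get("annotation"),
            params=params,
            n_randomizations=int(raw.get("n_randomizations", 199)),
            seed=int(raw.get("seed", 0)),
            randomization=raw.get("randomization", "shuffle"),
            probe_length=int(raw.get("probe_length", 25)),
            outdir=raw.get("outdir"),
        )


@dataclass
class PipelineResult:
    domains: List[TranscriptDomain]
    classes: list
    table1: "object"  # pandas DataFrame
    gene_summary: Optional[object]
    table2: Optional[object]
    concordance: Optional[Dict[str, int]]
    chisq: Optional[ChiSquareResult]
    manifest: dict


def _load_strand_tracks(paths: Sequence[str], strand: str, probe_length: int):
    """Read replicate files for one strand; returns {chrom: [track per replicate]}."""
    per_rep = []
    for p in paths:
        try:
            per_rep.append(vio.read_ratio_track(p, strand, probe_length))
        except FileNotFoundError as exc:
            raise ValidationError(f"input stage: missing replicate file {p}") from exc
    chroms = set(per_rep[0])
    for rep in per_rep[1:]:
        if set(rep) != chroms:
            raise ValidationError("input stage: replicates cover different chromosomes")
    return {chrom: [rep[chrom] for rep in per_rep] for chrom in sorted(chroms)}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Segmentation and randomization P-values are computed per (chromosome,
    strand); significant domains from all units are pooled for
    classification, the two summary tables, antisense concordance, and the
    vlinc activation-bias chi-square test.
    """
    config.validate()
    params = config.params
    all_domains: List[TranscriptDomain] = []
    unit_index = 0
    for strand in sorted(config.track_paths):
        by_chrom = _load_strand_tracks(config.track_paths[strand], strand, config.probe_length)
        for chrom, tracks in by_chrom.items():
            domains = run_segmentation(tracks, params)
            domains = assign_pvalues(
                domains,
                tracks,
                params,
                n_randomizations=config.n_randomizations,
                # decorrelate the null streams of independent (chrom, strand) units
                seed=config.seed + unit_index,
                method=config.randomization,
            )
            all_domains.extend(filter_significant(domains, params.alpha))
            unit_index += 1
    all_domains.sort(key=lambda d: (d.chrom, d.start, d.strand))

    catalog = vio.read_gene_catalog(config.annotation_path) if config.annotation_path else []
    classes = [classify_domain(d, catalog, params) for d in all_domains]
    table1 = summarize_table1(all_domains, catalog, params)

    gene_summary = table2 = concordance = None
    if catalog:
        gene_summary = summarize_genes(all_domains, catalog)
        table2 = gene_summary.counts()
        concordance = antisense_concordance(gene_summary)

    chisq = None
    n_total = len(all_domains)
    n_act = sum(1 for d in all_domains if d.direction == ACTIVATED)
    n_vlinc = sum(1 for c in classes if c.is_vlinc)
    n_vlinc_act = sum(
        1 for d, c in zip(all_domains, classes) if c.is_vlinc and d.direction == ACTIVATED
    )
    if n_vlinc > 0 and n_total > 0:
        chisq = activation_bias_test(n_vlinc_act, n_vlinc, n_act, n_total)
    else:
        logger.info("chi-square activation-bias test skipped: no vlinc domains called")

    manifest = {
        "params": dataclasses.asdict(params),
        "seed": config.seed,
        "n_randomizations": config.n_randomizations,
        "randomization": config.randomization,
        "counts": {
            "domains": n_total,
            "activated": n_act,
            "repressed": n_total - n_act,
            "vlincs": n_vlinc,
            "vlincs_activated": n_vlinc_act,
            "genes_in_catalog": len(catalog),
        },
    }
    result = PipelineResult(
        domains=all_domains,
        classes=classes,
        table1=table1,
        gene_summary=gene_summary,
        table2=table2,
        concordance=concordance,
        chisq=chisq,
        manifest=manifest,
    )
    if config.outdir:
        write_outputs(result, config.outdir)
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vio.write_domains_bed(result.domains, out / "domains.bed", result.classes)
    result.table1.to_csv(out / "table1.tsv", sep="\t")
    if result.table2 is not None:
        result.table2.to_csv(out / "table2.tsv", sep="\t")
    if result.concordance is not None:
        (out / "concordance.json").write_text(json.dumps(result.concordance, indent=2) + "\n")
    if result.chisq is not None:
        (out / "chisq.json").write_text(
            json.dumps(
                {
                    "statistic": result.chisq.statistic,
                    "df": result.chisq.df,
                    "p_value": result.chisq.p_value,
                    "observed": list(result.chisq.observed),
                    "expected": list(result.chisq.expected),
                },
                indent=2,
            )
            + "\n"
        )
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")
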