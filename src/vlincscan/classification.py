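"""Classify called domains against a gene catalogue.

Categories follow the strand-aware scheme: a domain is *sense* to a gene it
overlaps (>= 1 bp) on the same strand, *antisense* to a gene it overlaps on
the opposite strand, *intergenic* if it overlaps no gene on either strand,
and a *vlinc* (very long intergenic non-coding RNA candidate) if at least
50 kb of its span is not covered by same-strand annotation.  Only
same-strand gene spans count as "annotated" coverage for the vlinc rule:
an RNA antisense to a gene is itself unannotated, and antisense vlincRNAs
are a real and important class.  Overlap is measured against whole gene
spans (pre-mRNA), not exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import pandas as pd
from intervaltree import IntervalTree

from .types import (
    ACTIVATED,
    REPRESSED,
    GeneModel,
    ParameterSet,
    TranscriptDomain,
    ValidationError,
)

TABLE1_CATEGORIES = ("Total", "Intergenic", "Genes", "Sense", "Antisense", "Vlincs")
_DIR_ROWS = (REPRESSED, ACTIVATED, "total")


@dataclass(frozen=True)
class DomainClass:
    """Strand-aware annotation flags for one domain."""

    overlaps_gene: bool
    sense: bool
    antisense: bool
    intergenic: bool
    unannotated_bp: int
    is_vlinc: bool


@dataclass
class GeneSummary:
    """Per-gene hit states plus aggregate counts over the catalogue.

    ``sense_hits`` / ``antisense_hits`` map gene name -> set of directions of
    the domains overlapping it on the same / opposite strand.
    """

    catalog_size: int
    sense_hits: Dict[str, Set[str]] = field(default_factory=dict)
    antisense_hits: Dict[str, Set[str]] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        """Table of gene counts: rows repressed/activated/total, columns Sense/Antisense.

        A gene hit by both directions counts once per direction row; the
        total row counts distinct genes hit at least once.
        """
        rows = {}
        for direction in (REPRESSED, ACTIVATED):
            rows[direction] = {
                "Sense": sum(1 for dirs in self.sense_hits.values() if direction in dirs),
                "Antisense": sum(1 for dirs in self.antisense_hits.values() if direction in dirs),
            }
        rows["total"] = {
            "Sense": len(self.sense_hits),
            "Antisense": len(self.antisense_hits),
        }
        return pd.DataFrame.from_dict(rows, orient="index")[["Sense", "Antisense"]]


def _gene_trees(catalog: Sequence[GeneModel]) -> Dict[tuple, IntervalTree]:
    trees: Dict[tuple, IntervalTree] = {}
    for g in catalog:
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g)
    return trees


def _covered_bp(domain: TranscriptDomain, tree: IntervalTree) -> int:
    """bp of the domain span covered by the union of tree intervals."""
    hits = sorted(
        (max(iv.begin, domain.start), min(iv.end, domain.end))
        for iv in tree.overlap(domain.start, domain.end)
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in hits:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def unannotated_span(domain: TranscriptDomain, catalog: Sequence[GeneModel]) -> int:
    """bp of the domain not covered by any same-strand gene span."""
    tree = _gene_trees(catalog).get((domain.chrom, domain.strand))
    span = domain.end - domain.start
    if tree is None:
        return span
    return span - _covered_bp(domain, tree)


def classify_domain(
    domain: TranscriptDomain,
    catalog: Sequence[GeneModel],
    params: ParameterSet = ParameterSet(),
) -> DomainClass:
    """Flag a domain as sense/antisense/intergenic and test the vlinc rule."""
    trees = _gene_trees(catalog)
    opposite_strand = "-" if domain.strand == "+" else "+"
    same = trees.get((domain.chrom, domain.strand), IntervalTree())
    opp = trees.get((domain.chrom, opposite_strand), IntervalTree())
    sense = bool(same.overlap(domain.start, domain.end))
    antisense = bool(opp.overlap(domain.start, domain.end))
    unannot = (domain.end - domain.start) - (_covered_bp(domain, same) if sense else 0)
    return DomainClass(
        overlaps_gene=sense or antisense,
        sense=sense,
        antisense=antisense,
        intergenic=not (sense or antisense),
        unannotated_bp=unannot,
        is_vlinc=unannot >= params.vlinc_min_unannotated,
    )


def summarize_table1(
    domains: Sequence[TranscriptDomain],
    catalog: Sequence[GeneModel],
    params: ParameterSet = ParameterSet(),
) -> pd.DataFrame:
    """Count domains per direction x category.

    Rows: repressed, activated, total.  Columns: Total, Intergenic, Genes,
    Sense, Antisense, Vlincs.  A domain may count in both Sense and
    Antisense, so Genes <= Sense + Antisense.
    """
    counts = {row: {cat: 0 for cat in TABLE1_CATEGORIES} for row in _DIR_ROWS}
    for dom in domains:
        cls = classify_domain(dom, catalog, params)
        for row in (dom.direction, "total"):
            counts[row]["Total"] += 1
            counts[row]["Intergenic"] += int(cls.intergenic)
            counts[row]["Genes"] += int(cls.overlaps_gene)
            counts[row]["Sense"] += int(cls.sense)
            counts[row]["Antisense"] += int(cls.antisense)
            counts[row]["Vlincs"] += int(cls.is_vlinc)
    return pd.DataFrame.from_dict(counts, orient="index")[list(TABLE1_CATEGORIES)]


def summarize_genes(
    domains: Sequence[TranscriptDomain], catalog: Sequence[GeneModel]
) -> GeneSummary:
    """Per-gene sense/antisense hit states against the called domains.

    A gene is sense-hit in direction d when >= 1 bp of a direction-d domain
    overlaps it on the same strand; antisense-hit likewise on the opposite
    strand.  Percentages are computed against the full catalogue size.
    """
    if not catalog:
        raise ValidationError("gene catalogue is empty; proportions are undefined")
    summary = GeneSummary(catalog_size=len(catalog))
    trees = _gene_trees(catalog)
    for dom in domains:
        opposite_strand = "-" if dom.strand == "+" else "+"
        for iv in trees.get((dom.chrom, dom.strand), IntervalTree()).overlap(dom.start, dom.end):
            summary.sense_hits.setdefault(iv.data.name, set()).add(dom.direction)
        for iv in trees.get((dom.chrom, opposite_strand), IntervalTree()).overlap(dom.start, dom.end):
            summary.antisense_hits.setdefault(iv.data.name, set()).add(dom.direction)
    return summary


def antisense_concordance(gene_summary: GeneSummary) -> Dict[str, int]:
    """Partition antisense-hit genes by their sense-strand behaviour.

    ``antisense_only``: no sense-strand change; ``concordant``: sense and
    antisense changes share one direction; ``opposite``: directions differ
    (genes carrying both directions on a strand are counted as opposite).
    The three counts sum to the number of antisense-hit genes.
    """
    counts = {"antisense_only": 0, "concordant": 0, "opposite": 0}
    for gene, anti_dirs in gene_summary.antisense_hits.items():
        sense_dirs = gene_summary.sense_hits.get(gene)
        if not sense_dirs:
            counts["antisense_only"] += 1
        elif len(sense_dirs) == 1 and sense_dirs == anti_dirs:
            counts["concordant"] += 1
        else:
            counts["opposite"] += 1
    return counts
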