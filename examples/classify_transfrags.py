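"""Classify called transfrags against a gene catalogue.

Three hand-built domains illustrate the strand-aware categories: a short
intergenic call, a sense call inside a gene, and a 200-kb call antisense to
a gene — the latter carries >= 50 kb of unannotated sequence on its own
strand and is therefore an antisense vlincRNA.  The summary table counts
domains per direction and category (a domain may be both sense and
antisense); the gene-level summary and concordance partition ask, for each
gene, what happened on each strand.
"""

import vlincscan as v
from vlincscan.types import TranscriptDomain


def domain(chrom, strand, start, end, direction, mean):
    n = (end - start) // 25
    return TranscriptDomain(
        chrom=chrom, strand=strand, first_probe=0, last_probe=n - 1,
        start=start, end=end, direction=direction, mean_ratio=mean, n_probes=n,
    )


catalog = [
    v.GeneModel("chr1", "+", 100_000, 160_000, "GENE_A"),
    v.GeneModel("chr1", "+", 500_000, 560_000, "GENE_B"),
]
domains = [
    domain("chr1", "+", 20_000, 30_000, "repressed", -0.5),    # intergenic
    domain("chr1", "+", 110_000, 140_000, "repressed", -0.6),  # sense to GENE_A
    domain("chr1", "-", 450_000, 650_000, "activated", +0.7),  # antisense vlinc over GENE_B
]

for d in domains:
    cls = v.classify_domain(d, catalog)
    kinds = [k for k in ("intergenic", "sense", "antisense") if getattr(cls, k)]
    if cls.is_vlinc:
        kinds.append("vlinc")
    print(f"{d.chrom}:{d.start:,}-{d.end:,} ({d.strand}) {d.direction:>9}: "
          f"{'+'.join(kinds)}  unannotated={cls.unannotated_bp:,} bp")

print("\nDomain summary (counts per direction and category):")
print(v.summarize_table1(domains, catalog))

genes = v.summarize_genes(domains, catalog)
print("\nGene-level hits (of", genes.catalog_size, "genes):")
print(genes.counts())

print("\nAntisense concordance partition:", v.antisense_concordance(genes))
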