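"""Gene-level editing scores and genomic-element classification.

Plants three clusters inside one annotated gene and one cluster in another,
scans de novo, then (1) classifies each detected region as exon/UTR, intron
or intergenic against the annotation and (2) ranks the genes by their
editing score Delta(sum RTF) — the sum of RTF_exact over all target-type
(AG, TC) regions overlapping the gene (no knockout here, so the corrective
term is omitted).
"""

import tempfile

from tsscan import (ClusterSpec, Gene, ScanParams, SimConfig, denovo_scan,
                    gene_scores, intersect_features, simulate_dataset)
from tsscan.annot import GeneInterval

genes = [Gene("geneA", "c1", 10_000, 40_000, "+"),
         Gene("geneB", "c1", 60_000, 80_000, "-")]
exons = [GeneInterval("geneA", "c1", 10_000, 12_000, "+"),
         GeneInterval("geneA", "c1", 38_000, 40_000, "+"),
         GeneInterval("geneB", "c1", 60_000, 62_000, "-")]
clusters = [ClusterSpec("c1", s, s + 150, t, 10, editing_freq=0.3)
            for s, t in ((11_000, "AG"), (20_000, "AG"), (30_000, "TC"),
                         (70_000, "AG"))]

cfg = SimConfig(seed=5, contigs={"c1": 100_000}, coverage=30.0,
                error_rate=0.0, clusters=clusters, genes=genes, exons=exons)

with tempfile.TemporaryDirectory() as tmp:
    data = simulate_dataset(cfg, tmp)
    results = denovo_scan(data.bam_path, data.fasta_path, ScanParams())

regions = [r for v in results.values() for r in v]
print("element classification of detected regions:")
for a in intersect_features(regions, genes, exons):
    print(f"  {a.contig}:{a.span[0]}-{a.span[1]} {a.ts_type} -> "
          f"{a.element_class} (genes: {', '.join(a.gene_ids) or 'none'})")

print("\ngene editing scores (Delta sum RTF over AG+TC regions, "
      "no KO term):")
for s in sorted(gene_scores(regions, None, genes),
                key=lambda s: -s.delta_sum_rtf):
    print(f"  {s.gene_id}: delta_sum_rtf={s.delta_sum_rtf:.4f} "
          f"delta_sum_ts_sites={s.delta_sum_ts_sites} "
          f"n_regions={s.n_regions}")
print("\ngeneA hosts three planted clusters and ranks first; the cluster at "
      "11,000 falls in an exon, the others in introns.")
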