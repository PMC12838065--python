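"""Wild-type vs knockout differential filtering.

Simulates a WT sample with four editing clusters and an ADAR-deficient (KO)
counterpart sharing two of them (same genome, same read placement, editing
frequencies zeroed for the other two), then runs the full differential
pipeline: de novo scan on both samples, 100-nt distance merge, removal of
WT regions >= 50% covered by matching KO regions, re-quantification of the
retained regions in both samples (Regio mode, minCov 8), TsSiteCount >= 5
filter, and the confidence indicator CI = (RTF_wt - RTF_ko) / RTF_wt with
CI >= 0.85.
"""

import tempfile

from tsscan import (ClusterSpec, ScanParams, SimConfig, confidence_pipeline,
                    denovo_scan, knockout_config, merge_within,
                    regio_quantify, simulate_dataset, subtract_overlapping)

clusters = [ClusterSpec("c1", 20_000 + 40_000 * i, 20_150 + 40_000 * i,
                        "AG" if i % 2 == 0 else "TC", 10, editing_freq=0.3)
            for i in range(4)]
wt_cfg = SimConfig(seed=11, contigs={"c1": 200_000}, coverage=30.0,
                   error_rate=0.0, clusters=clusters)
ko_cfg = knockout_config(wt_cfg, keep_clusters=(1, 3))  # clusters 1,3 shared

with tempfile.TemporaryDirectory() as tmp:
    wt = simulate_dataset(wt_cfg, f"{tmp}/wt", "wt")
    ko = simulate_dataset(ko_cfg, f"{tmp}/ko", "ko")

    params = ScanParams()
    wt_regions = [r for v in denovo_scan(wt.bam_path, wt.fasta_path,
                                         params).values() for r in v]
    ko_regions = [r for v in denovo_scan(ko.bam_path, ko.fasta_path,
                                         params).values() for r in v]
    print(f"deNovo: {len(wt_regions)} WT regions, {len(ko_regions)} KO regions")

    retained = subtract_overlapping(merge_within(wt_regions),
                                    merge_within(ko_regions))
    print(f"after merge + 50%-overlap subtraction: {len(retained)} WT regions")

    regio_params = ScanParams.for_regio()
    wt_q = regio_quantify(wt.bam_path, wt.fasta_path, retained, regio_params)
    ko_q = regio_quantify(ko.bam_path, ko.fasta_path, retained, regio_params)
    survivors = confidence_pipeline(wt_q, ko_q, min_ts_sites=5, min_ci=0.85)

print("\nsurviving differential regions (WT-specific editing):")
for s in survivors:
    print(f"  {s.contig}:{s.span[0]}-{s.span[1]} {s.ts_type} "
          f"rtf_wt={s.rtf_exact_wt:.4f} rtf_ko={s.rtf_exact_ko:.4f} "
          f"sites_wt={s.ts_site_count_wt} CI={s.ci:.2f}")
print("\nCI == 1.00 means editing fully abolished in the knockout; the two "
      "clusters planted in both samples were removed by the subtraction "
      "step and do not appear.")
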