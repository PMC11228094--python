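"""Merge two marker panels genotyped on the same reference genome.

Extracts each platform's observed dosage matrix (with its own missing
rate), merges them by physical position, reports the overlap, and
applies the MAF filter used before association analysis.
"""

import pedigen as pg

cfg = pg.SimConfig(seed=1)
truth, pedigree, design = pg.simulate_population(cfg)

array_panel = pg.apply_platform(truth, 0)    # incumbent array (A)
amplicon_panel = pg.apply_platform(truth, 1)  # new amplicon assay (B)
print(f"platform A: {array_panel.n_markers} markers, "
      f"missing rate {array_panel.missing_rate():.4f}")
print(f"platform B: {amplicon_panel.n_markers} markers, "
      f"missing rate {amplicon_panel.missing_rate():.4f}")

merged, report = pg.merge_platforms(array_panel, amplicon_panel)
print(f"merged: {merged.n_markers} markers "
      f"({report.n_overlap} overlaps, genotype consistency "
      f"{report.mean_consistency:.3f}, duplicate copies dropped from "
      f"platform {report.dropped_platform})")

filtered = pg.filter_maf(merged, 0.025)
print(f"after MAF >= 0.025 filter: {filtered.n_markers} markers")
print("consistency is the share of agreeing non-missing calls on the")
print("overlap markers; it gauges cross-platform compatibility.")
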