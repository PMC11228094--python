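"""Simulate a pedigreed breeding population with two genotyping platforms.

Builds the default desk-scale population — founders crossed repeatedly
into a parental population, plus full-sib F1 families — and prints its
dimensions and the rise of inbreeding across generations, the pattern
that motivates modelling an inbreeding effect in prediction.
"""

import pedigen as pg

cfg = pg.SimConfig(seed=1)
truth, pedigree, design = pg.simulate_population(cfg)

f = truth.true_inbreeding()
offspring = [i for i in pedigree.individuals
             if i not in set(design.parental_ids)]

print(f"individuals: {len(truth.individuals)} "
      f"({len(design.parental_ids)} parents, {len(offspring)} F1)")
print(f"families: {len(design.families)} "
      f"({len(design.dual_families)} dual-genotyped)")
print(f"markers: {truth.n_markers} on "
      f"{truth.marker_map['chrom'].nunique()} chromosomes")
print(f"mean true inbreeding F — founders: "
      f"{f[pedigree.founders].mean():.3f}, parents: "
      f"{f[design.parental_ids].mean():.3f}, F1: {f[offspring].mean():.3f}")
print("F rises because a few elite parents are reused each generation;")
print("true F here is the fraction of markers autozygous by descent.")
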