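"""Heterochromatin overlap: enrichment, direction split, biotype make-up.

Tests whether differential regions concentrate in H3K9me3-like domains far
beyond the domains' genome coverage, whether domain-interior DARs are
predominantly upregulated, and what biotypes dominate top-ranked genes.
"""

import numpy as np
import pandas as pd

import chromaging as cg

cfg = cg.SimConfig(seed=4, n_background_dars=5000,
                   domain_dar_enrichment=15.0, domain_dars_up_fraction=0.85)
layout, domains, _, genes = cg.simulate_genome(cfg)
dars = cg.simulate_dars(layout, domains, cfg)

regions = cg.RegionSet(dars[["chrom", "start", "end"]], layout)
enr = cg.domain_enrichment(regions, domains, layout, n_permutations=1000, seed=4)
print(f"{enr.n_overlapping}/{enr.n_total} DARs overlap domains "
      f"({100 * enr.observed_fraction:.1f}%) vs "
      f"{100 * enr.genome_coverage_fraction:.1f}% genome coverage")
print(f"enrichment ratio {enr.enrichment_ratio:.1f}x; "
      f"binomial p = {enr.binomial_p:.3g}, permutation p = {enr.permutation_p:.4f}")

split = cg.direction_split(dars, domains, by=None)
print(f"\nup-fraction inside domains:  {split.loc[0, 'up_fraction_in']:.2f}")
print(f"up-fraction outside domains: {split.loc[0, 'up_fraction_out']:.2f}")
print(f"exact 2x2 association p = {split.loc[0, 'fisher_p']:.3g}")

# biotype composition of a ranked gene list with planted lncRNA excess on top
rng = np.random.default_rng(4)
ranked = pd.DataFrame({
    "gene_id": genes["gene_id"],
    "log2_fold_change": rng.normal(0, 1, len(genes)),
    "adjusted_p": rng.uniform(0, 0.05, len(genes)),
})
comp = cg.biotype_top_composition(
    ranked, genes.set_index("gene_id")["biotype"], top_n=100)
print(f"\nlncRNA+pseudogene share of top 100 upregulated genes: "
      f"{cg.target_fraction(comp, 'up'):.2f}")
print("Domain-interior DARs were planted 85% upregulated at 15x density, the")
print("pattern expected when repressive heterochromatin erodes with age.")
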