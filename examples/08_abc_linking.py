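"""Activity-By-Contact links between candidate elements and genes.

Candidate elements are peaks whose midpoint lies within 5 Mb of a gene's
TSS; each link scores A*C normalized over the gene's candidates, so scores
per gene sum to one.
"""

import numpy as np
import pandas as pd

import chromaging as cg

cfg = cg.SimConfig(seed=8, n_genes=50, n_peaks=500)
layout, _, _, genes = cg.simulate_genome(cfg)
peaks = cg.simulate_peaks(layout, cfg)

candidates = cg.candidate_elements(peaks, genes, window_bp=5_000_000)
rng = np.random.default_rng(8)
activities = pd.Series(rng.gamma(2.0, 1.0, len(peaks)),
                       index=peaks.df["name"]).to_dict()
contacts = pd.DataFrame([
    (e, g, float(rng.exponential(0.5)))
    for g, elems in candidates.items() for e in elems],
    columns=["element_id", "gene_id", "contact"])

links = cg.abc_scores(activities, contacts, candidates, threshold=0.02)
n_cand = int(np.mean([len(v) for v in candidates.values()]))
print(f"{len(genes)} genes, mean {n_cand} candidate elements within 5 Mb of the TSS")
print(f"{len(links)} links with ABC score >= 0.02")
top = links.groupby("gene_id").head(1).sort_values("abc_score", ascending=False).head(5)
print("\nstrongest element-gene links:")
print(top.to_string(index=False))
print("\nabc_score is the element's share of total activity-by-contact mass")
print("for that gene: a score of 0.3 means the element accounts for 30% of")
print("the gene's predicted regulatory input.")
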