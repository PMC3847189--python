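"""Seed-site conservation and the normalized divergence-rate statistic.

Simulates multi-species 3'UTR alignments with planted seed sites whose
site bases substitute faster than their flanks, labels each site as
conserved or reference-specific against a species panel, and measures the
normalized divergence rate (site substitution rate minus flank rate) of
every planted site.
"""

import numpy as np

from mirdiverge.synthetic_data import gen_mirna_catalog, gen_utr_alignment_set
from mirdiverge.targeting import (TargetSiteCall, classify_site_conservation,
                                  normalized_site_divergence)

catalog, _ = gen_mirna_catalog(2, 1, 0.0, 0.0, rng_seed=5)
blocks, truth = gen_utr_alignment_set(
    n_genes=300, species_list=["cow", "human", "mouse"], catalog=catalog,
    site_plant_spec=(1.0, 0.6),     # all genes get a site; 60% retained/species
    site_sub_rate=0.25, flank_sub_rate=0.08, indel_rate=0.01,
    utr_len=150, rng_seed=6)
by_gene = {b.gene_id: b for b in blocks}

labels, norm = [], []
for gene, mirna, site_type, start, length, _ in truth.planted_sites:
    site = TargetSiteCall(gene, mirna, site_type, start, length)
    labels.append(classify_site_conservation(site, by_gene[gene],
                                             ("human", "mouse")))
    norm.append(normalized_site_divergence(site, by_gene[gene], "human").normalized)

n = len(labels)
print(f"{n} planted sites: {labels.count('conserved')} conserved, "
      f"{labels.count('reference_specific')} reference-specific")
print(f"mean normalized divergence: {np.mean(norm):+.3f} "
      f"(site rate 0.25 - flank rate 0.08 = +0.17 expected)")
# A positive mean says site sequence evolves faster than its flanks —
# the signature of relaxed or lineage-specific target-site constraint.
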