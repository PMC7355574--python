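"""Functional characterization: hypergeometric gene-set enrichment.

Tests a 6-gene signature against two pathways inside a 91-gene panel
universe and prints overlap, enrichment ratio and p-value per set.
"""

from sigselect import GeneSetCollection, enrich, enrichment_to_frame

universe = [f"G{i:03d}" for i in range(91)]
collection = GeneSetCollection(
    sets={
        "hedgehog_like": universe[:10],       # contains most of the signature
        "unrelated_pathway": universe[40:60],
    },
    universe=universe,
)
signature = universe[:4] + universe[80:82]  # 4 of 6 genes in the first set

results = enrich(signature, collection, min_genes=3, alpha=0.05)
print(enrichment_to_frame(results).round(5).to_string(index=False))
# k of n signature genes fall in a set of K universe genes (N total).
# ratio = (k/n)/(K/N): >1 means the signature holds a larger share of the
# pathway than the universe does. p is the exact hypergeometric upper
# tail; sets with p <= 0.05 and at least 3 overlapping genes are flagged
# enriched. The unrelated pathway overlaps in <3 genes and is excluded.
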