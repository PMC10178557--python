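"""Rank genes with ReliefF and keep the top of the list.

ReliefF scores a gene by how much it differs between each sample and its
nearest neighbors of other classes (good) versus its nearest same-class
neighbors (bad); positive weights mark genes that separate the classes
locally. The filter is the cheap first stage that shrinks thousands of genes
to a pool the wrapper search can afford.
"""

from runsvm import (SyntheticSpec, generate_synthetic_dataset, minmax_normalize,
                    relieff_weights, top_m_features)

ds, truth = generate_synthetic_dataset(SyntheticSpec(seed=42))
normalized = minmax_normalize(ds)

weights = relieff_weights(normalized, k_neighbors=10)
table = weights.to_frame(ds.gene_ids)
print("top 8 genes by ReliefF weight:")
print(table.head(8).to_string(index=False))

informative = {ds.gene_ids[j] for j in truth.informative_indices}
top10 = set(table.head(10)["gene_id"])
print(f"\ninformative genes in the top 10: {len(top10 & informative)} of "
      f"{len(informative)} (rest of the top list are their redundant copies)")

filtered, kept = top_m_features(weights, 50, normalized)
print(f"filtered pool for the wrapper: {filtered.n_genes} genes")
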