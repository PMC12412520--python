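"""Rank morphological features by mutual information with the viability class.

MI is estimated in bits with equal-frequency binning plus a permutation bias
baseline; the top-k features (default 15) feed the classifier.
"""

import spheroscreen as ss

config = ss.SimConfig(seed=8)
observations, readouts, _ = ss.simulate_assay(config)
features = ss.assemble_feature_frame(observations)
labels = ss.label_readouts(readouts)
table = ss.build_feature_table(features, labels)

ranked = ss.rank_and_select(table.data, table.y, k=15,
                            feature_columns=table.feature_columns, rng=0)
print("top 10 features by mutual information with the viability class:")
for name, bits in ranked.ranking[:10]:
    print(f"  {name:<22s} {bits:.3f} bits")
print("\nDose-coupled descriptors (gray value, growth, area at 48 h) dominate;")
print("0 h features carry ~0 bits because no drug has acted yet.")
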