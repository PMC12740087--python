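"""Shortest-path node enrichment on a heterogeneous metabolic graph.

Builds the scaled-down KEGG-style graph (metabolites connected only through
reactions, enzymes, pathways and modules), plants a covarying-pair set that
routes five pairs through one rare node, and runs the three tests: path-
length enrichment, hypergeometric node enrichment, and the degree-
preserving rewiring null.
"""

import numpy as np

from climbmet import keggnet as kn
from climbmet import synthetic as syn

graph = syn.simulate_hetero_graph(syn.GraphSpec(seed=7))
print("node classes:", graph.class_counts())

index = kn.build_path_index(graph)
pairs = index.pairs
lengths = [index.pair_length(*p) for p in pairs]
print(f"{len(pairs)} mapped metabolite pairs; path lengths "
      f"{min(lengths)}-{max(lengths)} intermediate nodes, median equal-length "
      f"paths = {np.median([index.pair_path_count(*p) for p in pairs]):.0f}")

counts = index.node_pair_counts(pairs)
rare = [v for v, c in sorted(counts.items(), key=lambda kv: kv[1])
        if 15 <= c <= 60][0]
through = [p for p in pairs if index.node_on_path(rare, *p)]
others = [p for p in pairs if not index.node_on_path(rare, *p)]
rng = np.random.default_rng(0)
cov = ([through[i] for i in rng.choice(len(through), 5, replace=False)]
       + [others[i] for i in rng.choice(len(others), 24, replace=False)])

enr = kn.node_enrichment(index, cov)
row = enr[enr["node"] == rare].iloc[0]
print(f"\nfocal node {rare}: on {row['a']}/{row['n']} covarying pairs "
      f"({100 * row['a'] / row['n']:.1f}%) vs {row['A']}/{row['N']} background "
      f"({100 * row['A'] / row['N']:.2f}%), hypergeometric p = {row['p']:.2g}, "
      f"q = {row['q']:.2g}")

rw = kn.rewire_permutation(index, cov, rare, n_perm=2000, seed=1)
print(f"rewiring null (degree-preserving): observed {rw.observed} pairs "
      f"through the node vs null mean {rw.null_mean:.2f} -> empirical "
      f"p = {rw.empirical_p:.4f}")
print("(small p: the node's enrichment reflects which metabolites are paired,")
print(" not merely which metabolites appear in the network)")

ple = kn.path_length_enrichment(index, cov)
print(f"path-length enrichment of the covarying set: chi2 = {ple['chi2']:.1f}, "
      f"df = {ple['df']}, p = {ple['p']:.3f}")
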