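"""Hypergeometric enrichment of functional annotations in a gene set.

A 40-gene background with two annotation categories; the 10-gene result
set deliberately over-samples category 'flagellum'. Categories with fewer
than 4 background members are dropped before testing; Benjamini-Hochberg
controls the FDR at 5%.
"""

import coevoscan as cs

background = [f"g{i:02d}" for i in range(40)]
annotations = {}
for g in background[:12]:
    annotations.setdefault(g, set()).add("flagellum")
for g in background[10:28]:
    annotations.setdefault(g, set()).add("metabolism")
for g in background[:3]:
    annotations.setdefault(g, set()).add("tiny_category")  # < 4 copies

gene_set = background[:8] + background[30:32]  # 8/10 flagellar

records = cs.hypergeom_enrichment(gene_set, annotations, background,
                                  min_copies=4, fdr=0.05)
print(f"{'category':<14} {'k/n':>6} {'K/N':>7} {'p':>10} {'q':>10}  sig")
for r in records:
    print(f"{r.category:<14} {r.k:>3}/{r.n} {r.K:>3}/{r.N} "
          f"{r.p_value:10.3g} {r.q_value:10.3g}  {r.significant}")
print("\n(k = category members in the set, K = in the background; p is the "
      "upper-tail hypergeometric probability of >= k hits by chance; "
      "'tiny_category' is absent because it has < 4 background copies)")
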