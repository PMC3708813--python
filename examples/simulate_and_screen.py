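"""Simulate a small truth-labelled dataset and run the association screen.

Builds a 150-taxon birth-death tree carrying one focal character (a stand-
in for the chaperone gene hsp90A/htpG) plus 8 independently evolving genes
and 3 genes mutually dependent on the focal one, then runs the replicate-
consensus likelihood-ratio screen and compares the called set against the
known truth labels.
"""

import coevoscan as cs
from coevoscan.simulate import default_screen_spec

spec = default_screen_spec(n_independent=8, n_mutual=3, n_taxa=150, seed=31)
tree, matrix, truth = cs.make_screen_dataset(spec)
print(f"simulated {tree.n_leaves} taxa, {len(matrix.characters)} characters")

results = cs.consensus_scan(
    tree, matrix, spec.focal_id, n_runs=5, agree_threshold=5, fdr=0.05, seed=1
)
print(f"\n{'gene':<10} {'truth':<12} {'2logLR':>8} {'q':>8}  associated")
for r in results:
    label = truth.loc[r.character_id, "model"]
    print(f"{r.character_id:<10} {label:<12} {r.lr_statistic:8.2f} "
          f"{r.q_value:8.3g}  {r.associated}")

called = {r.character_id for r in results if r.associated}
dependent = set(truth.index[truth["model"] != "independent"])
print(f"\nrecovered {len(called & dependent)}/{len(dependent)} dependent "
      f"genes, {len(called - dependent)} false positives")
print("(2logLR ~ chi-square with 4 df under independence; large values "
      "mean the 8-rate dependent model fits far better than the 4-rate "
      "independent one)")
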