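"""Build a cell-type expression atlas from multi-platform array data.

Simulates three nested array platform versions (461/711/837 microRNAs)
measuring 18 cell types with chip-level batch effects and missing values,
then runs the full pipeline: missing-array filter, subset quantile
normalization on the cross-platform common features, empirical Bayes
chip adjustment, and threshold expression calls.
"""

from miratlas import cluster_cells, run_pipeline
from miratlas.simulate import SimConfig, simulate_arrays, simulate_atlas_truth

cfg = SimConfig(seed=11, n_corrupt_samples=3)
truth = simulate_atlas_truth(cfg)
arrays = simulate_arrays(truth, cfg)
print("platforms:", [(m.n_samples, m.n_features) for m in arrays])

res = run_pipeline(arrays)
atlas = res.atlas
tc = truth.true_calls
calls = atlas.calls.reindex(index=tc.index, columns=tc.columns)
recovery = (calls.to_numpy() == tc.to_numpy()).mean()
print(f"planted expression calls recovered: {100 * recovery:.2f}%")

clustering = cluster_cells(atlas)
parts = clustering.cut(2)
groups = {}
for cell, g in parts.items():
    groups.setdefault(g, []).append(cell)
for g, cells in sorted(groups.items()):
    print(f"cluster {g}: {sorted(cells)}")
print()
print("The two flat clusters separate the hematopoietic (hema_*) from the")
print("non-hematopoietic (nonhema_*) lineages, driven by their shared")
print("signature microRNAs — the same split real cell collections show.")
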