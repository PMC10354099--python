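"""Single-cell CSC gating and nucleus-mitochondria coordination scoring.

Simulates droplet-like counts with a 20% CSC subpopulation that co-activates
pluripotency and mitochondrial programs through a shared latent intensity,
gates cells on CSC markers, scores the programs per cell by ssGSEA, and
tests CSC vs non-CSC differences.
"""

import numpy as np

from tmescreen import synthetic
from tmescreen.singlecell import GatingRule, compare_groups, gate_cells, score_cells

truth = synthetic.make_single_cells(n_cells=1000, csc_fraction=0.2, seed=3)
rule = GatingRule(clauses=[(g, "positive") for g in truth.marker_genes], name="CSC")
labels = gate_cells(truth.matrix, rule)
recall = (labels[truth.labels == "CSC"] == "CSC").mean()
print(f"marker gate: {int((labels == 'CSC').sum())} CSCs called, recall {recall:.2f}")

table = score_cells(truth.matrix, truth.programs, labels=labels)
csc = table[table["label"] == "CSC"]
r = np.corrcoef(csc["pluripotency"], csc["mitochondrial"])[0, 1]
print(f"pluripotency-mitochondrial score correlation in CSCs: r = {r:.3f}")

for program in ("esc", "pluripotency", "mitochondrial"):
    t, p, means = compare_groups(table, program)
    print(
        f"{program}: CSC mean {means['CSC']:.2f} vs non-CSC {means['non-CSC']:.2f}, "
        f"Welch t = {t:.1f}, p = {p:.2e}"
    )
# coordinated activation shows up as a positive cross-program correlation
# within CSCs and higher program scores in CSCs than in the bulk.
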