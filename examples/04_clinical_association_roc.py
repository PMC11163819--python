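"""Hub-hormone correlation, cis editing-expression correlation, and ROC.

The synthetic cohort ties the hub editing block to LH (and through LH/FSH
to the derived ratio); the example computes the hub x hormone Pearson grid,
a cis correlation between one hub event and its host gene's expression, and
single/combined diagnostic ROC curves for the top differential events.
"""

import numpy as np

from edscan.calling import call_editing
from edscan.clinical import (cis_correlation, hub_clinical_correlation,
                             roc_combined, roc_single)
from edscan.counts import groups_dict, metadata_frame
from edscan.differential import dre_test
from edscan.simulate import SimulationConfig, simulate_all

# cis_strength raised from the default weak coupling so the editing ->
# host-gene expression relationship is visible at n = 22
bundle = simulate_all(SimulationConfig(cis_strength=8.0), seed=1)
matrix = call_editing(bundle.counts, bundle.genome)
groups = groups_dict(bundle.metadata)
traits = metadata_frame(bundle.metadata).loc[list(matrix.levels.columns)]

dre = dre_test(matrix, bundle.counts, groups)
top = list(dre[dre["significant"].fillna(False)]
           .sort_values("p_glm").head(5).index)

grid = hub_clinical_correlation(matrix.levels, top, traits)
best = grid[grid["testable"]].sort_values("p").head(5)
print("strongest event x hormone correlations:")
print(best[["event_id", "feature", "r", "p"]].round(4).to_string(index=False))

# cis coupling is planted on the hub block's host genes, so probe a hub site
t = bundle.truth.table
hub_keys = {(r.contig, int(r.pos)) for r in t[t.is_hub].itertuples()}
event = next(eid for eid, r in matrix.events.iterrows()
             if (r.contig, int(r.pos)) in hub_keys)
gene = matrix.events.loc[event, "gene_id"]
cis = cis_correlation(matrix.levels.loc[event],
                      bundle.expression.loc[gene].astype(float),
                      event_id=event, gene_id=gene)
print(f"\ncis correlation {event} vs {gene} expression: "
      f"r = {cis.r:.2f} (P = {cis.p:.1e})")
# positive r: more-edited samples express the host gene more highly

labels = traits["group"]
single = roc_single(matrix.levels.loc[event].to_numpy(),
                    labels.to_numpy(), marker=event)
print(f"\nsingle-marker AUC ({event}): {single.auc:.4f}")
combined = roc_combined(matrix.levels.loc[top].T, labels)
print(f"combined five-marker AUC (in-sample logistic score): "
      f"{combined.auc:.4f}")
print("combination coefficients:",
      {k: round(v, 2) for k, v in combined.coefficients.items()})
if combined.ridge_stabilized:
    print("note: fit was ridge-stabilized (perfect separation at this n)")
# AUC is the probability a random case scores above a random control;
# the in-sample combined AUC is optimistic at n = 22.
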