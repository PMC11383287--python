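"""What makes a cell divide fast?  Initial-state PCA of Gen-1 mothers.

Control mothers' initial states are decomposed with standardized PCA; the
component that stratifies progeny division counts is inspected, and a
trametinib-treated population is projected onto the control components.
"""

import numpy as np

from lineagesim import (attach_drug, build_demo_model, builtin_drug_specs,
                        fit_pca, growth_media, initial_state_matrix, project,
                        run_population, top_loadings)
from lineagesim.heterogeneity import component_correlations
from lineagesim.lineage import categorize_division_counts

model = build_demo_model()
control = run_population(model, 100, growth_media(), exp_time=72.0, seed=17)
matrix, counts = initial_state_matrix(control)
cats = categorize_division_counts(counts)
print("control division-count phenotypes:",
      {c: cats.count(c) for c in ("low", "moderate", "high")})

transform, scores = fit_pca(matrix)
corr = component_correlations(scores, counts)
best = int(np.argmax(np.abs(corr)))
print(f"PC{best + 1} correlates with progeny division count "
      f"(r = {corr[best]:.2f}); top loadings:")
print(top_loadings(transform, component=best + 1, k=8).to_string(index=False))
print("-> fluctuations that raise ERK-pathway capacity mark the rapidly "
      "dividing phenotype.")

# project a drug-treated population onto the control components
tram = attach_drug(model, builtin_drug_specs()["trametinib"])
treated = run_population(tram, 60,
                         growth_media(drug="trametinib", dose=0.000032),
                         exp_time=72.0, seed=23)
t_matrix, t_counts = initial_state_matrix(treated)
t_scores = project(transform, t_matrix)
fast = t_counts >= np.percentile(t_counts, 80)
print(f"\ntrametinib 0.032 nM, projected onto control components: "
      f"fast dividers sit at PC{best + 1} = "
      f"{t_scores[fast, best].mean():+.2f} vs {t_scores[~fast, best].mean():+.2f} "
      "for the rest (the same ERK-capacity axis predicts persistence under "
      "MEK inhibition).")
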