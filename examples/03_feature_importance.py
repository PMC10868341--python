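"""Recover the planted informative features from a fitted cascade.

Importance credits each feature with the OOB MCC x between-class centroid
separation of the surviving first-layer classifiers containing it; with
known ground truth we can measure precision of the top-50 ranking.
"""

from deepcentroid import RunConfig, SimScenario, fit_cascade, rank_important_features, simulate

sim = simulate(SimScenario(seed=3))
model = fit_cascade(sim.train_X, sim.train_y, RunConfig(seed=3))

top = rank_important_features(model, top_k=50)
print(top.head(10).to_string(index=False))

hits = len(set(top.feature_name) & set(sim.truth))
print(f"\nprecision@50 against the 50 planted informative features: {hits / 50:.2f}")
# A high precision means the ranking concentrates on the features that truly
# carry class signal — the analogue of biologically meaningful gene lists.
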