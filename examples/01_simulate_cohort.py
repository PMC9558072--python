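"""Draw a synthetic cohort with planted gene-pair structure.

The generator builds a two-cluster patient population: informative immune
genes are up-shifted in cluster A, each has a designated partner gene sitting
midway between its two cluster means (the planted pairs), survival hazard
rises with the planted pair score, and a logistic model ties the response
label to the same score.
"""

import reoscore as rs

cfg = rs.SimulationConfig(n_samples=200, seed=42)
expr, clinical, truth = rs.simulate_cohort(cfg)

print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(f"clinical table: {len(clinical)} patients, covariates {clinical.covariate_names}")
print(f"cluster sizes: {truth.cluster_label.value_counts().to_dict()}")
print(f"planted pairs: {[str(p) for p in truth.planted_pairs[:3]]} ... ({len(truth.planted_pairs)} total)")
print(f"events observed: {int(clinical.event.sum())} of {len(clinical)}")
print(f"responders: {(clinical.response == 'responder').sum()}")
# The planted score (fraction of planted pairs scoring 1) is the latent
# quantity that drives both survival and response in this cohort.
print(f"mean planted score, cluster A: {truth.planted_score[truth.cluster_label == 'A'].mean():.2f}")
print(f"mean planted score, cluster B: {truth.planted_score[truth.cluster_label == 'B'].mean():.2f}")
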