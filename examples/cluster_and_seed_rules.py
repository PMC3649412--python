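"""Seed a Sugeno rule base from training features by subtractive clustering.

Each cluster center found in the 8-dimensional RMS feature space becomes one
fuzzy rule whose Gaussian premises are centered on it; the consequents are
then fitted by least squares during hybrid training.
"""

import numpy as np

from myoanfis import ClusterConfig, build_initial_fis, cluster, featurize, generate_session

recording, schedule = generate_session(seed=42)
features = featurize(recording, schedule)
X = np.vstack([fv.rms for fv in features])

result = cluster(X, ClusterConfig(ra=0.5, max_clusters=60))
fis = build_initial_fis(result, order="first", data=X,
                        input_names=features[0].channel_ids)

print(f"training points:   {len(X)} (35 movement executions x 8 channels)")
print(f"clusters found:    {result.n_clusters}")
print(f"selection densities (non-increasing): {result.densities.round(2)}")
print(f"rules in the FIS:  {fis.n_rules}, premises per rule: {fis.n_inputs}")
# With seven well-separated movement classes the density peaks sit one per
# class, so the cap of 60 rules is rarely reached on clean synthetic data.
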