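"""Cluster time-course profiles into waves of coordinated expression.

Plants ten profile archetypes at 10x noise separation, clusters with
k-means (k = 10), and prints the agreement with the planted partition plus
each cluster's size and peak time -- the analogue of reading mean cluster
profiles off a time-series panel.
"""

from sklearn.metrics import adjusted_rand_score

from cagedyn import kmeans_profiles, mean_cluster_profiles
from cagedyn.simulate import simulate_profile_archetypes

matrix, truth = simulate_profile_archetypes(
    n_per_cluster=30, k=10, n_timepoints=10, separation=1.0, noise_sd=0.1, seed=3
)
result = kmeans_profiles(matrix, k=10, seed=3)
means, sizes = mean_cluster_profiles(result, matrix)

ari = adjusted_rand_score(truth, result.assignments)
print(f"{len(matrix)} profiles, k = {result.k}, inertia = {result.inertia:.1f}")
print(f"adjusted Rand index vs planted archetypes: {ari:.3f}")
print("\ncluster  members  peak_slot")
for c in means.index:
    print(f"{c:7d}  {sizes[c]:7d}  {means.loc[c].idxmax():9}")
# ARI = 1.0 means the planted partition was recovered exactly; clusters are
# numbered by the time slot where their mean profile peaks.
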