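"""Cluster a phantom into magnitude-ordered habitats and score recovery.

k-means (k = 3) on the z-scored combined [SNR_Pyr + k_PL] features,
followed by magnitude sorting so habitat 3 is always the highest-signal
region; the adjusted Rand index compares the result to the planted
ground-truth habitats.
"""

from sklearn.metrics import adjusted_rand_score

from hphabitat import cluster_habitats, generate_phantom
from hphabitat.phantom import recovery_phantom_spec

for noise in (0.0, 0.25):
    phantom = generate_phantom(recovery_phantom_spec(seed=3, noise_fraction=noise))
    habitats = cluster_habitats(
        [phantom.maps["SNR_Pyr"], phantom.maps["k_PL"]], phantom.roi, k=3, seed=9
    )
    sel = habitats.labels > 0
    ari = adjusted_rand_score(phantom.truth_labels[sel], habitats.labels[sel])
    sizes = [int((habitats.labels == i).sum()) for i in (1, 2, 3)]
    print(f"noise {noise:.0%} of inter-habitat contrast: "
          f"habitat sizes {sizes}, ARI vs truth = {ari:.3f}")
# ARI = 1.0 means the planted partition is recovered exactly (up to the
# magnitude-ordered relabelling); >0.9 under noise indicates that habitat
# boundaries survive a realistic noise level.
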