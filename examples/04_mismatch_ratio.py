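"""Quantify perfusion/metabolism mismatch per habitat.

Normalized habitat means (tumour mean = 1) of SNR_Pyr and k_PL give a
dimensionless k_PL/SNR_Pyr ratio per habitat; a ratio well above 1
marks low substrate delivery with high metabolic conversion, the
signature of the aggressive mismatch region. Cross-habitat differences
are tested with the normality-gated omnibus + pairwise machinery.
"""

from hphabitat import (
    cluster_habitats,
    cluster_summaries,
    compare_across_clusters,
    generate_phantom,
)
from hphabitat.phantom import default_phantom_spec

phantom = generate_phantom(default_phantom_spec(seed=12))
habitats = cluster_habitats(
    [phantom.maps["SNR_Pyr"], phantom.maps["k_PL"]], phantom.roi, seed=4
)

print("habitat  n_px  norm_SNR  norm_kPL  kPL/SNR ratio")
for s in cluster_summaries(habitats, phantom.maps["SNR_Pyr"], phantom.maps["k_PL"]):
    print(f"{s.label:^7d}  {s.n_pixels:4d}  {s.norm_mean_snr:8.2f}  "
          f"{s.norm_mean_kpl:8.2f}  {s.mismatch_ratio:8.2f}")

groups = [
    phantom.maps["k_PL"].values[habitats.labels == lab] for lab in (1, 2, 3)
]
res = compare_across_clusters(groups)
print(f"\nk_PL across habitats: {res.method}, omnibus p = {res.omnibus_p:.2e}")
for pair in res.pairwise:
    a, b = pair["groups"]
    print(f"  habitat {a + 1} vs {b + 1}: adjusted p = {pair['p_adj']:.3g}")
# The medium habitat's ratio >> 1 identifies the planted mismatch region;
# pairwise p-values show which habitats differ in conversion rate.
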