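# hphabitat

Intratumoral habitat analysis of hyperpolarised [1-¹³C]pyruvate MRI in
renal tumours: k-means clustering of co-registered perfusion and
metabolism parameter maps, magnitude-ordered habitat labelling, a
perfusion/metabolism mismatch statistic, biopsy-to-habitat
co-registration, and per-habitat diagnostic performance for detecting
the highest WHO/ISUP grade within a tumour.

## The problem

Clear cell renal cell carcinoma (ccRCC) is metabolically heterogeneous:
a single post-surgical grade misses the most aggressive region inside a
tumour, and biopsies can be taken from the wrong place. Hyperpolarised
¹³C-MRI measures two complementary quantities per voxel:

- **SNR_Pyr** — pyruvate signal-to-noise ratio, a surrogate for
  substrate delivery / perfusion;
- **k_PL** (s⁻¹) — the apparent pyruvate→lactate conversion rate,
  estimated from dynamic signals under a two-site exchange model
  (dP/dt = −(k_PL + r_P)·P, dL/dt = k_PL·P − r_L·L);

plus **%NG**, the percentage nephrographic enhancement
100·(post − pre)/pre from Gd-contrast T1-weighted imaging, a vascular
permeability measure.

`hphabitat` partitions the in-tumour pixels of these maps into *k* = 3
**habitats** with k-means (greedy k-means++ seeding, Lloyd iterations,
Hartigan–Wong single-point refinement, multiple restarts), relabels the
clusters so habitat 1→*k* ascends with mean signal magnitude
(low/medium/high), and computes per-habitat normalized means whose
**k_PL/SNR_Pyr ratio** flags perfusion/metabolism mismatch — low
delivery with high conversion, a signature of aggressive, putatively
hypoxic tumour. Graded biopsy points are assigned to habitats and each
habitat is scored as a binary test for "highest grade within the
tumour" (sensitivity, specificity, PPV, NPV pooled across patients).

Because the underlying patient data are not public, the package ships a
first-class synthetic-data module: tumour phantoms with planted
habitats (including a designed mismatch habitat), Gaussian map noise,
two-site dynamic curves, and biopsies whose grades are drawn
conditionally on habitat identity — every stage is testable end-to-end
offline.

## Worked example

```bash
python examples/04_mismatch_ratio.py
```

```
habitat  n_px  norm_SNR  norm_kPL  kPL/SNR ratio
   1      310      0.62      0.39      0.63
   2      224      0.61      1.41      2.32
   3      241      1.85      1.40      0.76

k_PL across habitats: anova+holm-sidak, omnibus p = 0.00e+00
  habitat 1 vs 2: adjusted p = 9.89e-283
  habitat 1 vs 3: adjusted p = 3.91e-286
  habitat 2 vs 3: adjusted p = 0.45
```

Habitat means are normalized so the tumour mean is 1; habitat 2 (the
medium-magnitude cluster) has near-average metabolism relative to the
tumour (norm k_PL 1.41) but low delivery (norm SNR 0.61), giving a
mismatch ratio of 2.32 — far above the other habitats — and correctly
identifying the planted mismatch region. The pairwise tests show its
conversion rate is indistinguishable from the high habitat (p = 0.45)
while both differ sharply from the low habitat: k_PL alone cannot
isolate it, which is exactly why the combined [SNR_Pyr + k_PL]
clustering is needed.

Other examples: `01_phantom_and_png.py` (phantom generation and %NG),
`02_kinetics_round_trip.py` (two-site model and k_PL fitting),
`03_habitat_clustering.py` (habitat recovery scored with the adjusted
Rand index), `05_diagnostic_performance.py` (full cohort evaluation
table). A thin CLI mirrors the library:
`habitat simulate | png | cluster | summarize | evaluate | run`.

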