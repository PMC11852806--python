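# Methods

## Parameter maps and %NG

All analysis operates on co-registered 2-D maps on a common pixel grid
with a boolean whole-tumour ROI (cystic/necrotic areas are assumed
already excluded from the ROI, as they would be at drawing time). The
percentage nephrographic enhancement is defined per pixel as

    %NG = 100 · (S_post − S_pre) / S_pre

inside the ROI, where S_pre is the non-enhanced T1-weighted signal and
S_post the nephrographic-phase contrast-enhanced signal. Although the
quantity is sometimes described loosely as a subtraction, a pure
difference has no percent scale; division by the baseline is the
standard dynamic-contrast enhancement convention and makes %NG
invariant to a common rescaling of both phases. Pixels with S_pre ≤ 0
inside the ROI are excluded (set to background) rather than failing the
slice; a slice with no valid pixel is an error.

Registration is out of scope: only the *application* of a user-supplied
2-D affine is provided (`apply_transform`, pull-back convention, nearest
or linear interpolation; identity returns the input bit-exactly;
label images must use nearest).

## Two-site exchange kinetics

k_PL maps are given mechanistic provenance through the minimal
unidirectional two-site model

    dP/dt = −(k_PL + r_P) P,   dL/dt = k_PL P − r_L L,   P(0)=p0, L(0)=0,

with relaxation and RF losses lumped into the effective decay rates r_P
and r_L (defaults 1/30 s⁻¹, a typical effective ¹³C T1 scale in vivo).
The closed form is

    P(t) = p0 e^{−(k_PL+r_P)t},
    L(t) = p0 k_PL/(r_L−k_PL−r_P) (e^{−(k_PL+r_P)t} − e^{−r_L t}),

with the continuous limit L(t) = p0 k_PL t e^{−r_L t} when
r_L = k_PL + r_P (switched at |r_L − a| < 1e−12 s⁻¹). `fit_kpl`
recovers k_PL (and p0) by bounded nonlinear least squares on both
curves with the decay rates held fixed; on noiseless curves the
recovery error is far below 1e−4 s⁻¹. No input function, flip-angle
schedule or B1 correction is modelled — the model is a deliberately
minimal, testable stand-in for a full acquisition-aware fit.

## Habitat clustering

Features are the in-ROI pixels of one map (single-parameter clustering)
or two maps (combined [SNR_Pyr + k_PL]); each intensity channel is
z-scored over the retained pixels so channels with different units
contribute equally. Pixels with SNR_Pyr below `snr_floor` (default 5)
are matched to background before clustering, emulating the exclusion of
voxels indistinguishable from noise. Spatial position can be appended
as (row, col)·`spatial_weight`; the default weight is 0
(intensity-only) because no principled weight is available and the
habitats in the data regime modelled here are already spatially
coherent through their intensities.

k-means is implemented in full rather than delegated: greedy k-means++
seeding (several D²-weighted candidates per step, keeping the one that
most reduces the potential), Lloyd iterations with empty-cluster repair
(reseed on the point farthest from its centroid), and a Hartigan–Wong
single-point refinement pass alternated with Lloyd until neither
improves. The Hartigan step moves a point from cluster a to b when
n_b/(n_b+1)·‖x−c_b‖² < n_a/(n_a−1)·‖x−c_a‖², which escapes Lloyd fixed
points that are not partition-local minima; centroids are recomputed
exactly from the labels at every step so floating-point drift cannot
produce improvement cycles, and a cluster is never emptied. With the
default 20 restarts this attains the exhaustive-enumeration global
optimum on every tiny instance tested (n ≤ 10, k ≤ 3) and matches
scikit-learn's objective on larger ones. Defaults: n_restarts = 20,
max_iter = 300, tol = 1e−8 relative objective change; deterministic
under a fixed seed; best restart by final objective, ties to the
earliest.

Clusters are then sorted: the magnitude of a pixel is the sum of its
z-scored intensity channels (spatial columns excluded); clusters are
relabelled 1..k in ascending order of mean magnitude, ties broken by
the smaller original label. Sorting is a pure permutation — the
partition is never changed — so the highest-numbered habitat always
corresponds to the highest signal. Clustering is performed per slice;
cross-slice pooling for multi-slice tumours is possible by clustering a
stacked feature matrix but is not wired as a default.

## Mismatch statistics

Maps are normalized by their mean over all clustered (non-background)
pixels of the slice, making 1.0 the neutral value; the pixel-weighted
average of habitat means is then exactly 1 (conservation). Each habitat
gets norm_mean_snr, norm_mean_kpl, their average as the combined
metric, and the mismatch ratio norm_mean_kpl / norm_mean_snr. The ratio
is invariant to rescaling either map by a positive constant. Ratios
well above 1 mark low-delivery/high-conversion tissue.

Cross-habitat comparisons are normality-gated, mirroring common
biomedical practice: Shapiro–Wilk per group (groups with n < 3 or zero
range are treated as non-normal); if all pass, one-way ANOVA with
Holm–Šidák-adjusted pairwise t-tests; otherwise Kruskal–Wallis with
Dunn's rank-based pairwise z-tests using the tie-corrected pooled
variance N(N+1)/12 − Σ(t³−t)/(12(N−1)), adjusted by the number of
comparisons (capped at 1). Two groups degrade to an unpaired t-test or
Mann–Whitney U. The gate can be overridden with `route=` since the
normality decision on small samples is fragile. Significance threshold
0.05.

## Biopsy evaluation

A biopsy is assigned the habitat label of its containing pixel; if that
pixel is background the nearest habitat pixel within a rescue radius
(default 1 px, ties row-major) is used, else the biopsy is excluded
with a warning. Within each patient, biopsies failing the >75%
cellularity criterion are dropped, and a biopsy is *positive* iff its
grade equals the maximum grade among that patient's included biopsies
("highest grade within the tumour"; a patient whose biopsies are all
one grade makes every biopsy positive — accepted, since dropping such
patients would discard real data). Each habitat is scored as a binary
test (in-habitat = test-positive) on one 2×2 table pooled across
patients: sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV
tp/(tp+fp), NPV tn/(tn+fn); a metric with zero denominator is reported
as undefined, never 0. Report output rounds half-up to whole percent.
The AUC of a single binary operating point is (sensitivity +
specificity)/2 — the trapezoid through (0,0), (1−spec, sens), (1,1);
published AUCs computed by unstated ROC constructions are not
reproducible from a 2×2 table and are not targeted.

## Synthetic phantoms — what they emulate and what they do not

A phantom is one patient slice: a 64×64 grid (1 mm pixels) whose tumour
mask is the union of 2–4 disjoint elliptical/polygonal habitats, each
with planted mean SNR_Pyr, k_PL and %NG, plus additive Gaussian noise
per map kind. T1-weighted phases are generated as a baseline of 100
(pre) and 100·(1+%NG/100) (ng) so the %NG computation is exercised
end-to-end. SNR_Pyr is planted directly by default; a curve-derived
mode computes it as time-summed pyruvate / noise SD from simulated
dynamics with p0 scaled to the planted value. Biopsies are uniform over
distinct in-mask pixels with grades drawn from a per-habitat
distribution. Everything is bit-reproducible under the PhantomSpec seed.

Two canonical specs define the study conditions:

- **Cohort phantom** (`default_phantom_spec`): habitats with
  (SNR_Pyr, k_PL, %NG) = (20, 0.010, 30), (20, 0.035, 25),
  (60, 0.035, 90). Habitat 2 is the mismatch region and is *structurally
  ambiguous in every single channel* — it shares SNR_Pyr with habitat 1
  and k_PL with habitat 3 — so only the combined 2-D feature space
  isolates it, the regime the combined clustering exists for. Noise SDs
  are realistic clinical values (SNR 4, k_PL 0.004 s⁻¹, T1w 2 on a
  baseline of 100). Grade rule: habitat 2 carries WHO/ISUP grade 4 with
  probability 0.9; habitats 1 and 3 are mostly grade 2–3. The default
  cohort has 6 patients with (8,7,7,8,7,7) = 44 biopsies, two flagged
  low-cellularity, leaving 42 in the evaluation.
- **Recovery phantom** (`recovery_phantom_spec`): three distinct levels
  per channel (SNR 25/10/40; k_PL 0.010/0.025/0.035 s⁻¹) so every
  habitat pair differs in both channels; `noise_fraction` scales the
  per-channel noise SD as a fraction of the inter-habitat contrast (the
  smallest between-mean difference per channel: 15 SNR units,
  0.010 s⁻¹). This is the instrument for recovery studies: noiseless
  phantoms are recovered with ARI = 1, and at 25% contrast noise the
  ARI exceeds 0.9 in essentially all seeds.

What the phantoms do *not* model: Rician noise (the high-SNR Gaussian
regime is assumed), partial-volume mixing at habitat borders, k-space
or acquisition effects, B1/flip-angle variation, misregistration
between the ¹H and ¹³C frames, 3-D structure (the analysis is 2-D by
design), and within-habitat biological gradients. Passing tests
therefore demonstrate the correctness and stability of the *pipeline*
under its stated assumptions, not clinical performance on patient data;
in particular the patient-level mismatch ratio (≈1.4 in vivo) and
patient AUCs depend on unavailable data and are not reproduction
targets.

## Numerical choices and degenerate inputs

Constant feature channels, empty ROIs, fewer in-mask pixels than k, and
non-positive normalization means raise typed errors rather than
propagating NaNs. Tie-breaks are deterministic everywhere (sorting by
smaller original label; biopsy rescue row-major; restart ties to the
earliest). Problem sizes in the test and acceptance studies — 64×64
grids (~775 tumour pixels), 100-seed Monte Carlo repeats, 200
brute-force k-means instances with n ≤ 10 — were chosen so each study
completes in seconds while keeping the Monte Carlo margins wide.

## Known limitations

- The two-site model is a stand-in; real k_PL estimation involves input
  functions and flip-angle corrections not modelled here.
- Dunn's adjustment multiplies raw p-values by the number of
  comparisons; software differs in this choice and exact agreement with
  other implementations is not guaranteed beyond the documented form.
- Per-slice clustering treats multi-slice tumours independently.
- The CLI covers the common paths only; the library API is the primary
  surface.
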