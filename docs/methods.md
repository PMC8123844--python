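# Methods

This note documents the models, defaults and numerical choices behind
`nucleoprofile`, and what the synthetic-data validation does and does not
demonstrate about real microscope data.

## Image model and segmentation

All computation is on 8-bit grayscale pixel grids; intensity is read as
chromatin density (0 = no chromatin, 255 = highly condensed) in the DNA
channel and as marker activity in the immunofluorescence channel.  Areas
are pixel counts; a nominal 0.1 µm/px pitch is carried as metadata only.

**Nucleus.**  Global Otsu threshold on the chromatin channel, hole
filling, largest 8-connected component; a minimum area (default 500 px)
guards against empty fields.  On synthetic nuclei this recovers the
planted mask at Jaccard ≥ 0.95.

**Nucleolus.**  The nucleolus is DNA-stain-dark.  Within the nucleus
eroded by 3 px, pixels below the 20th percentile of intra-nucleus
intensity are candidates; after a 1-px opening the largest hole-filled
component survives if it reaches 50 px, otherwise the mask is empty (a
valid outcome — some nuclei show no resolvable nucleolus).  The
percentile rule makes the threshold per-nucleus, not global: staining
intensity varies nucleus to nucleus, and a global cut would need manual
tuning per slide.

**Heterochromatin.**  Otsu split of intra-nucleus intensities, with two
robustness measures.  (i) The dark nucleolus — dilated by 2 px to cover
boundary pixels the nucleolus segmentation may miss — is excluded from
the histogram, so the bimodal split separates heterochromatin from
nucleoplasm rather than nucleolus from everything else.  (ii) If the
"bright" class still exceeds 60% of the domain, the split isolated a dark
minority instead of the bright heterochromatin; Otsu is then re-run on
the upper class alone.  A minimum inter-class contrast (default 30
intensity units) declares near-unimodal histograms heterochromatin-free,
and speckles under 4 px are removed.  A fixed user threshold can replace
the automatic rule for parity with manual ImageJ workflows.
`HC% = 100 · HC area / nucleus area`.

## Focus detection

Foci are connected bright components of the marker channel inside the
nucleus.  The threshold is

```
median(intra-nucleus marker) + max(k · 1.4826 · MAD, Δ_min)
```

with `k = 3` and `Δ_min = 40` by default, both configurable.  The robust
floor-plus-spread term adapts to noise; the minimum rise `Δ_min` exists
because a diffusely fluorescent ("light") nucleolus elevates a large
contiguous region by a few tens of intensity units, and without a floor
on the rise that region would segment as one giant false focus.
Components use 8-connectivity (merged heterochromatin-associated clusters
flow into each other) and must reach 3 px.  Focus intensity is recorded
both as component mean (used for profile features) and maximum.
Positions are summarized by centroid and by signed Euclidean distance to
the nucleolus boundary (negative inside).

## Profile classification

Features per labeled nucleus: fraction of foci with centroids inside the
nucleolus; a ring score (fraction of 12 equal angular sectors around the
nucleolus centroid whose perinucleolar annulus holds ≥ 1 focus centroid);
the annulus focus count and the annulus-to-overall mean-intensity ratio;
the fraction of total focus area in "large" components (≥ 5× a singleton
reference area); and the nucleolus-to-nucleoplasm marker brightness ratio
(the light/dark nucleolus distinction — a marker-channel property kept
deliberately separate from the DNA-channel nucleolus segmentation).

The perinucleolar annulus has width `max(3 px, 0.15 · r_eq)` where `r_eq`
is the equivalent nucleolus radius.  The singleton reference for cluster
detection is the population median focus area when available; within a
single nucleus the lower-quartile focus area stands in, because merged
clusters can make up half the components of a cluster-rich nucleus and
would inflate a plain median.

Classification applies ordered rules — T3 (cluster fraction ≥ 0.5), then
T2A (ring score ≥ 0.5 and ≥ 4 ring foci and ring intensity ratio ≥ 1),
then T1 (nucleolar fraction ≥ 0.9), then T2 (nucleolar fraction ≤ 0.05
and dark nucleolus, brightness ratio < 1.2), else T2B.  Cluster
morphology and the ring are the most distinctive signatures, hence their
precedence.  Every threshold is a config key; the decision path is logged
per nucleus.  Nuclei without a resolvable nucleolus can only receive T3,
T2 or T2B and are flagged.  A nucleus with no detected foci is UNLABELED;
type distributions are reported over labeled nuclei with the unlabeled
share alongside.

## DNA-content mixture and EM fitter

The phase model is a Dean–Jett–Fox-style univariate mixture: Gaussian G1
at mean μ with shared coefficient of variation `cv`; Gaussian G2/M at
`r·μ` (same cv, so sd scales with the mean); S as ten equal-weight
Gaussians with sd `cv·μ` whose means are the midpoints of ten equal cells
tiling `(μ, r·μ)`.  The midpoint grid covers the whole S support without
colliding with the G1/G2M means — components placed exactly at μ or r·μ
would be indistinguishable from the phase peaks and make the weights
unidentifiable, while a grid inset from the ends leaves coverage gaps
near the peaks whose S mass the G1/G2M components then absorb
(2–5 percentage points of S in trials).  The shared cv and the fixed
grid size are identifiability choices.

Fitting is expectation–maximization.  The weight update is the exact
M-step.  The shape parameters (μ, r, cv) use a generalized M-step: a
moment-based candidate plus a periodic L-BFGS-B refinement of the
expected complete-data log-likelihood, accepted only when it improves
that objective materially — so the observed log-likelihood is
non-decreasing (asserted in tests) and numerical-noise oscillation is
excluded.  μ initializes at the dominant histogram mode, r at 2.0, cv at
a robust local spread estimate; bounds keep r in [1.5, 2.5] and cv in
[0.005, 0.3].

Near its optimum this EM crawls along a flat likelihood ridge: the
log-likelihood plateaus thousands of iterations before the weights stop
moving.  Convergence is therefore judged once per 50-iteration cycle —
both the log-likelihood and the weights must be unchanged since the
previous cycle — and the densities are cached between shape updates so
the weight-only iterations reduce to one matrix–vector product each.
Difficult samples converge in a few thousand iterations (a few seconds at
n = 10,000).  On simulations at the study conditions (n = 10,000,
cv = 0.05) the fitted S fraction lands within ±2 percentage points of
truth, and the fitted G2/G1 ratio within [1.8, 2.2].

The simulator draws each event's phase from a recorded multinomial
(ground truth per event), then G1 ~ `N(μ, cv·μ)`,
G2M ~ `N(rμ, cv·rμ)`, S ~ `U(μ, rμ) + N(0, cv·μ)`, resampling
non-positive draws.  Debris/doublet gating is out of scope: the module
consumes already-gated samples and the simulator produces clean ones.
M is recorded separately in ground truth but fitted only as combined G2M.

## Synthetic nucleus generator

One nucleus per 256×256 image.  Nucleus and nucleolus are ellipses
(default semi-axes 85×65 and 24×19 px) with ≤ 20° orientation jitter; the
nucleolus is placed strictly inside the eroded nucleus.  Heterochromatin
is planted as random disks (rejection-sampled outside the nucleolus)
until the HC pixel fraction is within 0.01 of its target, trimming the
last blob from the outside in; running out of attempts raises an error
rather than silently undershooting.  Channel levels default to
background 8, nucleoplasm 120, HC 200, nucleolus 60; a "light" nucleolus
adds +30 to the marker channel inside the nucleolus.  Sensor noise is
Gaussian, truncated at ±3.9 sd — clipping only the 1e-4 tail while giving
every rendered channel a hard guarantee that no pixel strays more than
4 sd from its noiseless value, which the background-floor checks rely on.

Foci are isotropic Gaussian spots (sd = radius/2) whose centroid pixel
reaches the planted peak.  Placement encodes the five profiles: T1 inside
the nucleolus; T2/T2A outside it (T2A adds ring foci at boundary + half
the annulus width, spread around the full circle, peaks ×1.5); T2B
anywhere in the nucleus; T3 grows each cluster as a connected chain
(steps of 1.2 focus radii) inside a span-limited disk so the cluster
renders as one merged component, plus ~20% singletons.  Optional linear
formations place 2–5 collinear near-touching foci.  Singleton placements
keep centers ≥ 3 focus radii apart because detected footprints extend
~1.5× the nominal radius.

Condition effects, as directions with configurable magnitudes (the source
observations are qualitative): HU multiplies focus count by 0.4 and peak
intensity by 0.6, PCC by 0.6 and 0.8; HU lowers the HC target fraction
(0.20 → 0.12) and scales the nucleus axes ×1.12; PCC reverts both near
control (0.19, ×1.02) and loosens T3 clusters so singular foci stay
distinguishable (member separation ≥ 2.5 radii).  Default labeled
fractions are 0.895 (control), 0.352 (HU) and — with no measured value to
adopt — 0.60 for PCC, an intermediate value reflecting partial
reactivation after checkpoint override.  Default per-condition profile
mixtures preserve the reported orderings (ring profile T2A rising from
8% through 15% to 22%; cluster profile T3 falling 20% → 13% → 8%;
nucleolus-active T1/T2B rising after PCC).  Profile-specific focus counts
(5–34) and radii (~3 px) are free parameters chosen to look realistic at
this image scale.  Exactly `round(labeled_fraction · N)` nuclei of a
population carry foci; which ones is a seeded permutation.

Reproducibility: a single integer seed; each nucleus draws from an
independent RNG stream derived from `(seed, nucleus_index)`, so
populations are bit-identical under any generation order.

### What the synthetic validation does and does not show

The generator reproduces the morphological vocabulary of the real data —
elliptical DAPI-bright nuclei, dark nucleoli, blob-like heterochromatin,
profile-specific focus placement, condition-dependent dimming — and every
recovery test (segmentation overlap, HC% round trip within 2 points,
focus counts within 10%, ≥ 95% per-type classification accuracy on clean
images, labeling-index equality) is against planted truth.  It does not
model out-of-focus light, illumination gradients, touching nuclei,
mitotic figures, photobleaching, or a realistic PSF; spots are ideal
Gaussians and noise is pixel-independent.  Passing tests therefore
demonstrate the correctness and internal consistency of the measurement
chain, not its robustness to every real acquisition artifact — on real
slides the configurable thresholds (detection rise, HC contrast,
classifier cut-offs) are the knobs to revisit.

## Statistics

Pearson `r` and `r²` for scatter relations (count vs total area, etc.);
one-way ANOVA (with a guard clamping the numerically negative F of
literally identical groups to zero) followed by Tukey HSD pairwise tests,
significance at p < 0.05.  Tukey handles multiplicity within a variable;
no additional correction is applied across variables.  Under a null
simulation the ANOVA type-I error is calibrated (0.03–0.07 at α = 0.05,
1,000 replicates).  Condition summaries are mean ± SD and are
recomputable from the per-nucleus CSV alone; every run writes a manifest
with the seed and a configuration hash, and rerunning with the same seed
reproduces all CSVs byte for byte.

## Problem sizes used in the validation suite

Recovery checks use 200-nucleus populations for labeling-index tests,
100 nuclei per profile type for classifier accuracy, 25 nuclei per level
for the HC round trip, 100 nuclei per condition for the directional
orderings, and 10,000-event samples for the cell-cycle fits — sizes at
which the binomial/EM noise floor sits well inside the asserted
tolerances.

## Known limitations

* The five-profile classifier is rule-based with hand-set thresholds; no
  intermediate or mixed types, no mitotic figures.
* M-phase cannot be separated from G2 by DNA content; endoreduplication
  peaks beyond 4C (common in plants) are not modelled.
* 2-D only; no z-stacks, no watershed splitting of touching nuclei.
* The heatmap export (flame gradient, luminance-monotone) is pure
  visualization; no analysis output depends on it.
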