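# Methods

This note documents the models implemented in `t1qc`, the choices made
where the design was genuinely open, and what the synthetic phantoms do
and do not establish about behaviour on real data.

## Synthetic phantom model

The phantom is a nested-ellipsoid head: a WM core inside a GM shell
inside a CSF shell, in a zero background.  Shell radii are solved from
the target intracranial volume fractions — for concentric similar
ellipsoids volume scales as $r^3$, so the WM and GM boundaries sit at
$r_{WM}=\sqrt[3]{f_{WM}}$ and $r_{GM}=\sqrt[3]{f_{WM}+f_{GM}}$.  The
default fractions are the normative (CSF, GM, WM) = (0.20, 0.35, 0.45).
Partial volumes are realized by supersampling the class indicator 3×
per axis and box-averaging, which makes the ground-truth maps exact to
the supersampling resolution.

Default tissue means are (200, 500, 700) in arbitrary units — the T1w
ordering CSF < GM < WM — and the default noise channel is σ = 10, i.e.
SNR 20 for the dimmest tissue (CSF) and 70 for WM.  Noise is applied as
the modulus of two independent Gaussian channels, so tissue intensities
are Rician and the air background is Rayleigh — the noise family the
background-referenced SNR and the QI2 fit assume.  An optional
multiplicative bias field is `exp(amplitude · P)` for a random
polynomial `P` (seeded, normalized to max |P| = 1); ghosting adds a
circularly shifted replica along the phase-encoding axis; wrap-around
folds the leading slab of the FOV onto the trailing slab.

The cohort writer emulates a multi-site study: per-site intensity and
noise scalings, "exclude" subjects drawn at a per-site prevalence
(default 0.31, a realistic exclusion rate for heterogeneous multi-site
data) and given a visible artifact — ghost intensity ≥ 0.25, noise ≥ 3×
base, or a strong bias field — and manifest labels flipped at a
configurable rate to emulate rater class-noise.  The severity cutoffs
are a stand-in for rater behaviour, not a claim about it.

**What the phantom does not emulate:** anatomy (gyri, skull, scalp,
vessels), k-space acquisition, motion trajectories, multi-coil noise
correlation.  Consequences worth knowing:

- there is no tissue brighter than WM, so the full-image 95th
  percentile sits inside WM and `wm2max` comes out near 1.0 rather than
  in the real-data interval [0.6, 0.8]; the metric's response to bright
  fat-like structure is tested by injecting one explicitly;
- the union-of-tissues simple SNR and the CSF-shell simple SNR have
  spreads dominated by tissue contrast and boundary partial volume
  rather than noise, so only the thick-region (GM, WM) simple SNRs and
  all background-referenced SNRs are meaningful noise monotones here;
- passing tests demonstrates correctness of the estimators under the
  stated statistical model, not robustness to clinical heterogeneity.

## Preprocessing

**Head mask.** Otsu threshold computed on log-intensities (with a
max-proportional offset so the mask is invariant to global intensity
scaling), morphological closing with a radius-3 ball, largest connected
component, hole filling.  The log domain matters: on a T1w histogram
dominated by dim air, a raw-intensity Otsu cut lands between CSF and GM
and truncates the dark CSF shell.  Masks that come out empty or cover
more than 60% of the FOV raise a mask-failure error (a pure-noise image
percolates into a near-full mask).

**Air and hat masks.** Air = complement of the head dilated by 4
voxels, minus a 2-voxel border rind.  The hat mask restricts air to
slices superior to a cutoff plane at 40% of the head bounding-box
extent above its inferior edge — a reproducible geometric proxy for the
nasio-cerebellar plane (configurable `hat_fraction`).

**INU field.** A polynomial (default total order 3, valid range 2–4) is
fitted to log-intensities within an eroded head mask.  A naive
least-squares fit would absorb tissue structure (the concentric
geometry is itself a radial intensity pattern), so each of 3 iterations
first groups the current residuals into three classes by 1D k-medians,
subtracts the class medians, trims voxels beyond 3 robust SDs of their
class (partial-volume and rim voxels are spatially structured outliers)
and fits the polynomial to what remains.  The field is exp of the fit,
renormalized to mean 1 over the head; a global intensity scale is a
log-offset absorbed by the class centres.  On bias-free phantoms the
fitted field's p95−p05 spread is < 0.02; with a planted amplitude-0.2
quadratic field the estimate correlates with truth above 0.95.

**Segmentation.** A 3-component 1D Gaussian mixture is fitted by EM to
in-head intensities of the bias-corrected image (initialized at the
1/6, 3/6, 5/6 intensity quantiles; ≤ 100 iterations; tolerance 1e-6;
components relabelled by ascending mean to CSF/GM/WM; a component
weight below 1e-4 raises a segmentation error).  Raw posteriors are
near-binary at tissue boundaries, which cannot represent graded partial
volume, so the returned maps resolve mixels explicitly: class centres
are re-estimated as medians of hard-assigned voxels, a voxel within a
per-class gate (2 robust SDs, floored at 2% of the class mean, capped
at 45% of the adjacent inter-class gap) is pure, and remaining voxels
interpolate linearly between neighbouring class means with a
zero-intensity background anchor below CSF (the unit budget's remainder
is background).  Maps are evaluated on a one-voxel dilation of the head
so the fractional rim is recovered.  Identifiability caveat: a voxel
mixing three classes (GM|CSF|background) is not resolvable from
intensity alone; with the default geometry this limits CSF recovery on
64³ grids (shell ≈ 1.6 voxels thick), which is why the
segmentation-recovery tests use 96³ grids (shell ≈ 2.4 voxels), where
per-class fuzzy Dice exceeds 0.95 at SNR 20 and fitted class means are
within 2% of truth.

## The 64-feature contract

The canonical enumeration is: 10 scalars (cjv, cnr, efc, fber, qi1,
qi2, wm2max, inu_med, inu_p05, inu_p95) + 8 SNRs (snr/snrd ×
csf/gm/wm/total, "total" = union of tissues) + 4 FWHM + 3 ICV + 3 rPVE
+ 4 overlaps (csf/gm/wm/head) + 32 summary statistics (4 regions × 8
stats: mean, median, stdv, mad, p05, p95, Fisher kurtosis, region
fraction).  Kurtosis of regions under 8 voxels is NaN; FWHM axes whose
variance-ratio argument is out of domain are NaN and excluded from the
average; the 4 overlap entries are NaN when no pre-aligned reference
maps are supplied (the phantom's truth maps serve as the reference —
spatial normalization to a template is deliberately out of scope).
Downstream learning imputes NaN with training-fold medians.

Numerical conventions: percentiles are linear-interpolation order
statistics; "energy" in FBER is the mean squared intensity; EFC is
normalized so a uniform image scores exactly 1; the QI1 detector
thresholds the grey-opened image (the structure that *survives* a
radius-3 opening) at 1 SD of the hat intensities — thresholding the
opening residual instead would flag most of an honest noise floor; QI2
fits a chi distribution (default 2 degrees of freedom = Rayleigh,
configurable) by maximum likelihood with the location fixed at zero and
reports the mean absolute difference between fitted density and the
100-bin histogram up to the 99.9th percentile.

## Learning framework

Labels binarize as {accept, doubtful} → accept, exclude → positive.
The preprocessing chain inside a model is: median imputation → per-site
median/IQR normalization (center and scale independently switchable;
zero IQR falls back to scale 1) → site-predictability elimination →
noise-probe selection → classifier.  All switches are hyper-parameters.

- *Unseen-site normalization* uses the new site's own median/IQR
  (unsupervised, no labels needed); sites with fewer than 5 samples
  fall back to training-global statistics.
- *Site elimination* iteratively fits extremely-randomized trees to
  predict the site and removes the top-importance feature, stopping at
  `max_removed` (default 14) or when cross-validated site-prediction
  accuracy falls to chance + 0.05.
- *Noise-probe selection* appends 5 standard-normal probe columns and
  drops real features whose importance does not beat the best probe,
  for up to 3 rounds.  Five probes rather than one: against a single
  probe another noise feature wins a coin flip, so the filter would
  pass pure noise half the time.
- *Models*: random forest (scores = vote fractions) and linear/RBF SVC
  (scores = Platt-calibrated probabilities); class weights inverse to
  class frequency when enabled.  Decision threshold defaults to 0.5,
  ties breaking toward "accept".

Evaluation uses leave-one-site-out folds (every site is the test set
exactly once; site-disjointness is asserted structurally) or stratified
k-fold.  Nested cross-validation draws up to 50 candidates uniformly
from the grid for the inner loop, selects by mean inner AUC, refits the
winner per outer-train and scores AUC/ACC on the outer test; a
single-class outer fold reports accuracy only (AUC = NaN, excluded from
means).  The shipped default grid has 24 points; the full expansion of
the same axes (3 families × hyper-parameters × 5 preprocessing
switches) has 512.  The permutation test shuffles training and test
labels independently, refits, and reports
p = (1 + #{perm ≥ observed}) / (1 + N), so the smallest attainable p
with 1000 permutations is 1/1001 ≈ 0.001.  Label-independent
preprocessing is computed once across permutations (it cannot change
under label shuffling) unless the label-driven noise-probe filter is
active.  Feature ranking reports the median per-tree Gini importance of
a fitted forest.

### Why k-fold looks better than LoSo on multi-site data

In the synthetic cohorts, sites differ both in feature shifts and in
exclude prevalence.  Under k-fold, every test fold contains samples
from sites seen in training, so a model can exploit the site signature
as a proxy for the site's label prior; under LoSo that shortcut
generalizes to nothing.  The test suite verifies the resulting optimism
ordering (mean outer k-fold AUC ≥ mean outer LoSo AUC over 5 seeds)
with non-normalizing models — per-site normalization removes the very
signature whose exploitation the experiment measures.  With equalized
prevalences the ordering disappears, which is itself informative: batch
effects inflate k-fold estimates only insofar as site identity carries
label information.

## Problem sizes and determinism

Default test-time problem sizes: 64³ phantoms for extraction and
artifact sensitivity (three seeds, paired comparisons), 96³ for
segmentation recovery, 4 sites × 50 subjects for the cross-validation
design experiments, 200 repetitions × 99 permutations for the
permutation-calibration check, and 10⁵ samples for distribution-moment
recoveries.  All generators and fits are deterministic given their
seeds; identical spec + seed reproduces bit-identical phantoms and
identical feature vectors.

## Known limitations

- Ellipsoid phantoms validate estimator correctness, not clinical
  robustness; no claim is made about classifier accuracy on real
  multi-site cohorts.
- The INU estimator assumes a log-polynomial field of order ≤ 4 and
  three dominant tissue classes; pathology or strong wrap-around can
  violate both.
- The hat-plane proxy (40% of bounding-box height) approximates the
  nasio-cerebellar axis only for roughly centred, roughly upright
  heads; `axis_meaning` must declare the superior–inferior axis.
- SVC score calibration uses the standard Platt procedure on training
  folds; vote-fraction and calibrated-probability scales are not
  directly comparable across model families.
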