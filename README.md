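# t1qc

No-reference image quality metrics (IQMs) and cross-site quality
classification for T1-weighted structural brain MRI — with a synthetic
phantom generator so the whole pipeline can be validated end to end
without downloading any imaging data.

## Who this is for

Neuroimaging studies routinely pool T1w scans from many scanners.
Visual quality rating does not scale, raters disagree, and acquisition
differences between sites leak into any quantitative quality measure as
a *batch effect* that lets a naive classifier learn the scanner instead
of the quality.  `t1qc` addresses both halves of the problem:

1. **Extraction** — a minimal preprocessing workflow (head/air/"hat"
   masks, polynomial intensity-non-uniformity estimation, EM tissue
   segmentation) feeding 14 metric families that spawn a canonical
   **64-element named feature vector** per image.
2. **Classification** — a batch-effect-robust supervised framework:
   site-wise robust normalization (median/IQR), elimination of features
   predictive of the acquisition site, Winnow-style noise-probe feature
   selection, random-forest and SVM classifiers, **leave-one-site-out
   (LoSo)** nested cross-validation, permutation testing and Gini
   feature ranking.

## The metrics

Let $\mu_t,\sigma_t$ be the mean/SD of intensities in tissue $t$ and
$\sigma_{\text{air}}$ the background SD.  The core measures include

- **CJV** $=(\sigma_{WM}+\sigma_{GM})/|\mu_{WM}-\mu_{GM}|$ — rises with
  motion and bias fields;
- **CNR** $=|\mu_{WM}-\mu_{GM}|/\sqrt{\sigma_{\text{air}}^2+\sigma_{WM}^2+\sigma_{GM}^2}$;
- **SNR** per tissue, both within-region ($\mu_t/\sigma_t$) and
  background-referenced: the air SD is mapped to the noise-channel
  $\sigma$ under the Rayleigh law, $\hat\sigma=\mathrm{SD}_{\text{air}}\sqrt{2/(4-\pi)}$;
- **EFC** — Shannon entropy of the $\ell_2$-normalized intensities,
  scaled so a uniform image scores 1 (ghosting/blur raise it);
- **FBER** — mean squared intensity in the head over that in the air;
- **QI1/QI2** — the fraction of background voxels above the
  nasio-cerebellar plane carrying artifactual structure (grey-opening
  detector), and the misfit of a Rayleigh/chi law to the remaining
  clean background;
- **INU** summaries (median, p05, p95 of the estimated bias field),
  **WM2MAX**, per-axis **FWHM** smoothness, intracranial volume
  fractions, residual partial-volume effects, fuzzy-Dice overlaps with
  reference tissue maps, and 8 summary statistics for each of
  background/CSF/GM/WM — 64 named values in a fixed canonical order.

## Worked example

```python
from t1qc import PhantomSpec, generate_phantom, extract_iqms
from t1qc.phantom import GhostSpec

vol, truth = generate_phantom(PhantomSpec(seed=42))   # 64^3 T1w-like head
vec, _ = extract_iqms(vol, reference=truth.tissue_maps(), seed=0)
for k in ("cjv", "cnr", "efc", "qi1", "snrd_wm", "icv_csf", "overlap_wm"):
    print(f"{k:10s} {vec[k]:8.4f}")
```

prints

```
cjv          0.2837
cnr          4.6416
efc          0.4081
qi1          0.0000
snrd_wm     67.6183
icv_csf      0.2170
overlap_wm   0.9944
```

— a clean phantom: no background artifacts (`qi1` 0), background-derived
WM SNR ≈ 68 (tissue mean 700 over the planted noise channel σ=10 gives
70), a CSF volume fraction near the normative 20%, and WM maps
overlapping the ground truth at Dice 0.994.  Re-rendering the same
phantom with a half-FOV ghost at 40% intensity moves exactly the
artifact-sensitive metrics:

```python
spec = PhantomSpec(seed=42, ghost=GhostSpec(axis=1, offset_frac=0.5, intensity=0.4))
```

```
qi1    0.0000 -> 0.0035     # ghost structure appears in the background
efc    0.4081 -> 0.5456     # intensity entropy rises
cjv    0.2837 -> 0.7067     # tissue distributions smear together
```

## Command line

```bash
t1qc simulate cohort/ --sites siteA,siteB --subjects-per-site 4 --seed 1
t1qc extract cohort/ iqms/                  # per-image JSON + group TSV
t1qc group-report iqms/group_iqms.tsv report.html
t1qc fit iqms/group_iqms.tsv labels.csv model.pkl --family rfc
t1qc evaluate features.tsv labels.csv cv.json --outer loso --inner kfold5
t1qc predict model.pkl features.tsv predictions.tsv --threshold 0.5
```

Every command writes a provenance JSON (inputs, config hash, seed,
version).  `evaluate` supports `--outer {loso,kfold10}` ×
`--inner {loso,kfold5}` to compare split designs; on synthetic
batch-effect cohorts the k-fold outer estimate is systematically more
optimistic than LoSo, which is the motivation for site-aware
validation.

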