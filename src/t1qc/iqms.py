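"""No-reference image quality metrics (IQMs) for T1-weighted volumes.

Fourteen metric families spawn a canonical 64-element named feature
vector per image:

* noise-based: coefficient of joint variation (cjv), contrast-to-noise
  ratio (cnr), signal-to-noise per tissue both within-region (snr_*) and
  against the Rayleigh air background (snrd_*), and the background
  chi-square goodness-of-fit index (qi2);
* information-theoretic: entropy-focus criterion (efc),
  foreground-background energy ratio (fber);
* artifact-specific: bias-field location/spread (inu_*), artifactual
  background intensities above the nasio-cerebellar plane (qi1),
  white-matter-to-maximum ratio (wm2max);
* other: per-axis image smoothness (fwhm_*), intracranial volume
  fractions (icv_*), residual partial-volume effects (rpve_*), overlap
  with reference tissue maps (overlap_*), and 8 summary statistics for
  each of background/CSF/GM/WM (summary_*).

Every metric is a plain function of arrays so it can be checked against
brute-force re-computation; :func:`extract_iqms` is the driver that runs
the preprocessing workflow and assembles the full vector.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import ball

from .errors import InvalidSpecError, UndefinedMetricError
from .preprocess import (
    BiasField,
    MaskSet,
    TissueMaps,
    Volume,
    run_preprocessing,
)

_SUMMARY_STATS = ("mean", "median", "stdv", "mad", "p05", "p95", "kurtosis", "n")
_SUMMARY_REGIONS = ("bg", "csf", "gm", "wm")

#: Canonical ordering of the 64 named features.
IQM_NAMES: tuple[str, ...] = tuple(
    ["cjv", "cnr", "efc", "fber", "qi1", "qi2", "wm2max",
     "inu_med", "inu_p05", "inu_p95"]
    + [f"snr_{t}" for t in ("csf", "gm", "wm", "total")]
    + [f"snrd_{t}" for t in ("csf", "gm", "wm", "total")]
    + [f"fwhm_{a}" for a in ("x", "y", "z", "avg")]
    + [f"icv_{t}" for t in ("csf", "gm", "wm")]
    + [f"rpve_{t}" for t in ("csf", "gm", "wm")]
    + [f"overlap_{t}" for t in ("csf", "gm", "wm", "head")]
    + [f"summary_{r}_{s}" for r in _SUMMARY_REGIONS for s in _SUMMARY_STATS]
)
assert len(IQM_NAMES) == 64

# Rayleigh moments: mean = sigma*sqrt(pi/2), SD = sigma*sqrt(2 - pi/2).
# The factor below maps an observed air SD back to the Gaussian channel
# sigma of the magnitude-reconstruction noise model.
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 / (4.0 - math.pi))


def cjv(mu_gm: float, sigma_gm: float, mu_wm: float, sigma_wm: float) -> float:
    """Coefficient of joint variation of GM and WM: (s_WM+s_GM)/|m_WM-m_GM|.

    Rises with head motion and strong intensity non-uniformity.
    """
    if mu_wm == mu_gm:
        raise UndefinedMetricError("cjv undefined: equal GM and WM means")
    return (sigma_wm + sigma_gm) / abs(mu_wm - mu_gm)


def cnr(mu_gm: float, sigma_gm: float, mu_wm: float, sigma_wm: float,
        sigma_air: float) -> float:
    """Contrast-to-noise ratio: |m_WM-m_GM| / sqrt(s_air^2+s_WM^2+s_GM^2)."""
    denom = math.sqrt(sigma_air**2 + sigma_wm**2 + sigma_gm**2)
    if denom == 0.0:
        raise UndefinedMetricError("cnr undefined: all variances zero")
    return abs(mu_wm - mu_gm) / denom


def snr_simple(mu: float, sigma: float) -> float:
    """Within-region SNR: mean over SD of the region intensities."""
    if sigma == 0.0:
        raise UndefinedMetricError("snr undefined: zero region SD")
    return mu / sigma


def snr_dietrich(mu: float, air_values: np.ndarray) -> float:
    """Background-referenced SNR.

    The air SD is mapped back to the Gaussian channel sigma under the
    Rayleigh background law (SD_air = sigma*sqrt(2-pi/2)), so the result
    estimates mu/sigma of the underlying noise channel.
    """
    air_values = np.asarray(air_values)
    if air_values.size == 0:
        raise UndefinedMetricError("snr_dietrich undefined: empty air sample")
    sd = float(np.std(air_values))
    if sd == 0.0:
        raise UndefinedMetricError("snr_dietrich undefined: zero air SD")
    return mu / (sd * RAYLEIGH_SD_FACTOR)


def efc(data: np.ndarray) -> float:
    """Entropy-focus criterion: Shannon entropy of the L2-normalized
    intensities, scaled so a uniform image scores exactly 1.

    Ghosting and motion blur spread energy over many voxels and raise it;
    lower is better.
    """
    x = np.clip(np.asarray(data, dtype=float).ravel(), 0.0, None)
    norm = np.linalg.norm(x)
    if norm == 0.0:
        raise UndefinedMetricError("efc undefined: all-zero image")
    p = x / norm
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    n = x.size
    # Uniform image: p_j = 1/sqrt(N) for all j -> E_max = sqrt(N)*ln(sqrt(N)).
    e_max = math.sqrt(n) * math.log(math.sqrt(n))
    return entropy / e_max


def fber(data: np.ndarray, head: np.ndarray, air: np.ndarray) -> float:
    """Foreground-background energy ratio: mean squared intensity in the
    head over mean squared intensity in the air; +inf when the air is
    exactly zero."""
    if not head.any() or not air.any():
        raise UndefinedMetricError("fber undefined: empty mask")
    fg = float(np.mean(data[head] ** 2))
    bg = float(np.mean(data[air] ** 2))
    if bg == 0.0:
        return float("inf")
    return fg / bg


def qi1(data: np.ndarray, hat: np.ndarray, threshold_sds: float = 1.0,
        opening_radius: int = 3) -> np.ndarray | float:
    """Fraction of "hat" background voxels carrying artifactual structure.

    Grey-level opening with a radius-``opening_radius`` ball suppresses
    point noise but preserves extended structures (ghost replicas, spill-
    over); hat voxels where the opened image still exceeds
    ``threshold_sds`` times the hat intensity SD are counted as artifact.
    """
    if not hat.any():
        raise UndefinedMetricError("qi1 undefined: empty hat mask")
    opened = ndimage.grey_opening(data, footprint=ball(opening_radius))
    sd = float(np.std(data[hat]))
    artifact = hat & (opened > threshold_sds * sd)
    return float(artifact.sum() / hat.sum())


def qi1_artifact_mask(data: np.ndarray, hat: np.ndarray,
                      threshold_sds: float = 1.0,
                      opening_radius: int = 3) -> np.ndarray:
    """Boolean mask of the artifact voxels detected by :func:`qi1`."""
    if not hat.any():
        raise UndefinedMetricError("qi1 undefined: empty hat mask")
    opened = ndimage.grey_opening(data, footprint=ball(opening_radius))
    sd = float(np.std(data[hat]))
    return hat & (opened > threshold_sds * sd)


def qi2(data: np.ndarray, hat: np.ndarray,
        artifact_mask: np.ndarray | None = None,
        dof: float = 2.0, n_bins: int = 100,
        min_voxels: int = 500) -> float:
    """Goodness-of-fit of a central chi-family law to the clean background.

    Artifact voxels (as detected for qi1) are removed, a chi distribution
    with ``dof`` degrees of freedom (``dof=2`` is Rayleigh, the magnitude
    noise law) is fitted to the remaining hat intensities by maximum
    likelihood, and the statistic is the mean absolute difference between
    the fitted density and the observed normalized histogram up to the
    99.9th percentile.  Lower is better.
    """
    if artifact_mask is None:
        artifact_mask = qi1_artifact_mask(data, hat)
    clean = data[hat & ~artifact_mask]
    clean = clean[clean > 0]
    if clean.size < min_voxels:
        raise UndefinedMetricError(
            f"qi2 needs >= {min_voxels} clean hat voxels, got {clean.size}"
        )
    hi = float(np.percentile(clean, 99.9))
    scale = stats.chi.fit(clean, f0=dof, floc=0.0)[2]
    edges = np.linspace(0.0, hi, n_bins + 1)
    observed, _ = np.histogram(clean, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fitted = stats.chi.pdf(centers, dof, loc=0.0, scale=scale)
    return float(np.mean(np.abs(fitted - observed)))


def wm2max(data: np.ndarray, p_wm: np.ndarray) -> float:
    """Median WM intensity over the 95th percentile of the whole image.

    Long bright tails (fat, carotid vessels) depress it; values around
    [0.6, 0.8] are typical of clean T1w contrast.
    """
    wm_mask = p_wm > 0.5
    if not wm_mask.any():
        raise UndefinedMetricError("wm2max undefined: empty WM mask")
    p95 = float(np.percentile(data, 95))
    if p95 == 0.0:
        raise UndefinedMetricError("wm2max undefined: zero 95th percentile")
    return float(np.median(data[wm_mask])) / p95


def fwhm_estimate(vol: Volume, head: np.ndarray) -> tuple[float, float, float, float]:
    """Image smoothness per axis as a Gaussian-equivalent FWHM in mm.

    Uses the classic variance-of-differences estimator: with s2 the
    in-mask intensity variance and sd2 the variance of first differences
    along an axis, FWHM = dx * sqrt(-2 ln 2 / ln(1 - sd2/(2 s2))).  For
    unsmoothed noise the log argument is non-positive and the axis value
    is NaN; the average is taken over finite axes only.
    """
    if not head.any():
        raise UndefinedMetricError("fwhm undefined: empty head mask")
    x = vol.data - vol.data[head].mean()
    s2 = float(np.var(x[head]))
    if s2 == 0.0:
        raise UndefinedMetricError("fwhm undefined: constant in-mask signal")
    out = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(0, -1)
        pair = head[tuple(sl_a)] & head[tuple(sl_b)]
        if pair.sum() < 2:
            raise UndefinedMetricError(f"fwhm axis {axis}: too few neighbor pairs")
        d = x[tuple(sl_a)][pair] - x[tuple(sl_b)][pair]
        sd2 = float(np.var(d))
        arg = 1.0 - sd2 / (2.0 * s2)
        if arg <= 0.0:
            out.append(float("nan"))
        else:
            out.append(vol.voxel_mm[axis] * math.sqrt(-2.0 * math.log(2.0) / math.log(arg)))
    finite = [v for v in out if np.isfinite(v)]
    avg = float(np.mean(finite)) if finite else float("nan")
    return out[0], out[1], out[2], avg


def icv_fractions(tissue: TissueMaps) -> tuple[float, float, float]:
    """Intracranial volume fractions (CSF, GM, WM); they sum to 1."""
    vols = [float(m.sum()) for m in (tissue.p_csf, tissue.p_gm, tissue.p_wm)]
    total = sum(vols)
    if total == 0.0:
        raise UndefinedMetricError("icv undefined: all-zero tissue maps")
    return tuple(v / total for v in vols)  # type: ignore[return-value]


def rpve(p: np.ndarray, lo: float = 0.05, hi: float = 0.95) -> float:
    """Residual partial-volume effect of one tissue map: the share of the
    map's total volume held in voxels with fractional content in
    (lo, hi).  Smaller is better (sharper boundaries)."""
    total = float(p.sum())
    if total == 0.0:
        raise UndefinedMetricError("rpve undefined: empty map")
    partial = p[(p > lo) & (p < hi)]
    return float(partial.sum()) / total


def summary_stats(data: np.ndarray, region: np.ndarray) -> dict[str, float]:
    """Eight summary statistics of the intensities in a region.

    ``region`` is boolean or a probability map (thresholded at 0.5).
    ``n`` is the region voxel count as a fraction of the grid; kurtosis is
    Fisher (excess) and set to NaN for regions under 8 voxels.
    """
    mask = region if region.dtype == bool else region > 0.5
    x = data[mask]
    if x.size == 0:
        raise UndefinedMetricError("summary stats undefined: empty region")
    med = float(np.median(x))
    return {
        "mean": float(np.mean(x)),
        "median": med,
        "stdv": float(np.std(x)),
        "mad": float(np.median(np.abs(x - med))),
        "p05": float(np.percentile(x, 5)),
        "p95": float(np.percentile(x, 95)),
        "kurtosis": float(stats.kurtosis(x, fisher=True)) if x.size >= 8 else float("nan"),
        "n": x.size / data.size,
    }


def fuzzy_dice(p: np.ndarray, q: np.ndarray) -> float:
    """Fuzzy Dice overlap of two probability maps: 2*sum(min)/(sum p + sum q)."""
    denom = float(p.sum() + q.sum())
    if denom == 0.0:
        return 0.0
    return 2.0 * float(np.minimum(p, q).sum()) / denom


def tpm_overlap(estimated: TissueMaps, reference: TissueMaps) -> tuple[float, float, float, float]:
    """Fuzzy Dice per class plus the union ("head") overlap against
    reference tissue maps supplied on the same grid."""
    if estimated.p_csf.shape != reference.p_csf.shape:
        raise InvalidSpecError("tissue map grids do not match")
    o = tuple(
        fuzzy_dice(getattr(estimated, f"p_{t}"), getattr(reference, f"p_{t}"))
        for t in ("csf", "gm", "wm")
    )
    est_head = estimated.p_csf + estimated.p_gm + estimated.p_wm
    ref_head = reference.p_csf + reference.p_gm + reference.p_wm
    return o[0], o[1], o[2], fuzzy_dice(est_head, ref_head)


def inu_summary(bias: BiasField, head: np.ndarray) -> tuple[float, float, float]:
    """Median and 5th/95th percentiles of the bias field within the head.

    Spreads tight around 1.0 indicate a homogeneous acquisition.
    """
    if not head.any():
        raise UndefinedMetricError("inu summary undefined: empty head")
    vals = bias.field[head]
    return (
        float(np.median(vals)),
        float(np.percentile(vals, 5)),
        float(np.percentile(vals, 95)),
    )


def assemble_feature_vector(components: dict[str, float]) -> dict[str, float]:
    """Order the computed metrics into the canonical 64-name vector."""
    missing = [n for n in IQM_NAMES if n not in components]
    if missing:
        raise InvalidSpecError(f"missing IQM components: {missing}")
    return {name: float(components[name]) for name in IQM_NAMES}


def extract_iqms(
    vol: Volume,
    reference: TissueMaps | None = None,
    seed: int = 0,
    inu_order: int = 3,
    hat_fraction: float = 0.4,
) -> tuple[dict[str, float], dict]:
    """Run the minimal preprocessing workflow and compute all 64 IQMs.

    Tissue and intensity statistics are taken on the INU-corrected image;
    region membership is posterior probability > 0.5 for tissues and the
    air mask for background.  ``reference`` supplies pre-aligned tissue
    maps for the overlap metrics; without one those four entries are NaN.

    Returns the ordered feature dict plus the intermediate artifacts
    (corrected volume, masks, bias field, tissue maps) for reporting.
    """
    corrected, masks, bias, tissues = run_preprocessing(
        vol, inu_order=inu_order, hat_fraction=hat_fraction, seed=seed
    )
    data = corrected.data
    comp: dict[str, float] = {}

    regions = {
        "csf": tissues.p_csf > 0.5,
        "gm": tissues.p_gm > 0.5,
        "wm": tissues.p_wm > 0.5,
    }
    regions["total"] = regions["csf"] | regions["gm"] | regions["wm"]
    mu = {k: float(data[m].mean()) if m.any() else float("nan") for k, m in regions.items()}
    sd = {k: float(data[m].std()) if m.any() else float("nan") for k, m in regions.items()}
    air_vals = data[masks.air]

    comp["cjv"] = cjv(mu["gm"], sd["gm"], mu["wm"], sd["wm"])
    comp["cnr"] = cnr(mu["gm"], sd["gm"], mu["wm"], sd["wm"], float(air_vals.std()))
    comp["efc"] = efc(data)
    comp["fber"] = fber(data, masks.head, masks.air)
    artifact = qi1_artifact_mask(data, masks.hat)
    comp["qi1"] = float(artifact.sum() / masks.hat.sum())
    comp["qi2"] = qi2(data, masks.hat, artifact_mask=artifact)
    comp["wm2max"] = wm2max(data, tissues.p_wm)
    comp["inu_med"], comp["inu_p05"], comp["inu_p95"] = inu_summary(bias, masks.head)
    for t in ("csf", "gm", "wm", "total"):
        comp[f"snr_{t}"] = snr_simple(mu[t], sd[t])
        comp[f"snrd_{t}"] = snr_dietrich(mu[t], air_vals)
    fx, fy, fz, favg = fwhm_estimate(corrected, masks.head)
    comp["fwhm_x"], comp["fwhm_y"], comp["fwhm_z"], comp["fwhm_avg"] = fx, fy, fz, favg
    comp["icv_csf"], comp["icv_gm"], comp["icv_wm"] = icv_fractions(tissues)
    for t in ("csf", "gm", "wm"):
        comp[f"rpve_{t}"] = rpve(getattr(tissues, f"p_{t}"))
    if reference is not None:
        o = tpm_overlap(tissues, reference)
    else:
        o = (float("nan"),) * 4
    comp["overlap_csf"], comp["overlap_gm"], comp["overlap_wm"], comp["overlap_head"] = o
    region_masks = {"bg": masks.air, **{t: regions[t] for t in ("csf", "gm", "wm")}}
    for rname, rmask in region_masks.items():
        for sname, val in summary_stats(data, rmask).items():
            comp[f"summary_{rname}_{sname}"] = val

    vector = assemble_feature_vector(comp)
    artifacts = {
        "corrected": corrected,
        "masks": masks,
        "bias": bias,
        "tissues": tissues,
    }
    return vector, artifacts
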