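"""Minimal preprocessing workflow for T1-weighted volumes.

Produces the corrected image, masks and tissue probability maps that the
quality metrics consume: Otsu-based head mask, background (air) and "hat"
masks, a polynomial intensity-non-uniformity (INU) field fitted to
log-intensities, and a three-class Gaussian-mixture tissue segmentation
(CSF, GM, WM by ascending mean, the T1w contrast ordering).

All masks and maps are voxel-indexed boolean/float arrays on the input
grid.  The workflow is deliberately self-contained: the metric
definitions, not any particular upstream toolbox, are the point.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from sklearn.mixture import GaussianMixture

from .errors import (
    FitError,
    InvalidSpecError,
    MaskFailureError,
    SegmentationError,
)

DEFAULT_AXIS_MEANING = {"superior_inferior": 2, "phase_encoding": 1}


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    ``axis_meaning`` declares which array axis runs superior–inferior
    (needed by the hat mask) and which is the phase-encoding axis
    (informational, used by the artifact simulators).
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_meaning: dict = field(default_factory=lambda: dict(DEFAULT_AXIS_MEANING))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise InvalidSpecError("Volume.data must be 3-dimensional")
        if any(v <= 0 for v in self.voxel_mm):
            raise InvalidSpecError(f"voxel_mm must be positive, got {self.voxel_mm}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidSpecError("Volume.data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.voxel_mm, dict(self.axis_meaning))

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_mm) + [1.0])

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_mm)
        return img

    @classmethod
    def from_nifti(cls, path, axis_meaning: dict | None = None) -> "Volume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, zooms, dict(axis_meaning or DEFAULT_AXIS_MEANING))


@dataclass
class MaskSet:
    """Head / air / hat boolean masks on a common grid.

    Invariants: head and air are disjoint; hat is a subset of air.
    """

    head: np.ndarray
    air: np.ndarray
    hat: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.head & self.air):
            raise InvalidSpecError("head and air masks overlap")
        if np.any(self.hat & ~self.air):
            raise InvalidSpecError("hat mask is not contained in the air mask")


@dataclass
class BiasField:
    """Multiplicative intensity-non-uniformity field, mean 1 within head."""

    field: np.ndarray
    params: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise InvalidSpecError("bias field must be strictly positive")


@dataclass
class TissueMaps:
    """Per-class probability / partial-volume maps (CSF, GM, WM)."""

    p_csf: np.ndarray
    p_gm: np.ndarray
    p_wm: np.ndarray
    class_means: tuple[float, float, float] = (0.0, 0.5, 1.0)

    def __post_init__(self) -> None:
        total = self.p_csf + self.p_gm + self.p_wm
        if np.any(total > 1.0 + 1e-6):
            raise InvalidSpecError("tissue probabilities exceed 1 per voxel")
        m = self.class_means
        if not (m[0] < m[1] < m[2]):
            raise InvalidSpecError(f"class means not ordered CSF<GM<WM: {m}")

    def stacked(self) -> np.ndarray:
        return np.stack([self.p_csf, self.p_gm, self.p_wm])


def compute_head_mask(vol: Volume) -> np.ndarray:
    """Binary head mask: Otsu threshold, morphological closing (radius-3
    ball), largest connected component, hole filling.

    Raises :class:`MaskFailureError` on constant images and on masks that
    are empty or implausibly large (a structureless noise image percolates
    into a mask covering most of the field of view).
    """
    data = vol.data
    if np.ptp(data) == 0:
        raise MaskFailureError("constant image: cannot threshold")
    # Threshold log-intensities: the air/tissue split dominates there even
    # though the tissue histogram is multimodal (a raw-intensity Otsu can
    # land between CSF and GM and truncate the dark CSF shell).  The
    # max-proportional offset keeps the mask invariant to global scaling.
    logd = np.log(np.clip(data, 0.0, None) + 1e-4 * data.max())
    thresh = threshold_otsu(logd)
    mask = logd > thresh
    mask = ndimage.binary_closing(mask, structure=ball(3))
    labels, nlab = ndimage.label(mask)
    if nlab == 0:
        raise MaskFailureError("empty mask after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    frac = mask.mean()
    if frac == 0.0:
        raise MaskFailureError("empty head mask")
    if frac > 0.6:
        raise MaskFailureError(
            f"head mask covers {frac:.0%} of the FOV; input looks like pure noise"
        )
    return mask


def compute_air_mask(
    head: np.ndarray,
    vol: Volume,
    dilation_voxels: int = 4,
    border_voxels: int = 2,
) -> np.ndarray:
    """Air (background) mask: complement of the head dilated by
    ``dilation_voxels``, excluding a ``border_voxels``-wide image-border
    rind where padding effects live."""
    if dilation_voxels > 0:
        dilated = ndimage.binary_dilation(head, structure=ball(dilation_voxels))
    else:
        dilated = head
    air = ~dilated
    if border_voxels > 0:
        b = border_voxels
        interior = np.zeros_like(air)
        interior[b:-b, b:-b, b:-b] = True
        air &= interior
    if not air.any():
        raise MaskFailureError("air mask empty: head fills the field of view")
    return air


def hat_cutoff_index(head: np.ndarray, si_axis: int, fraction: float = 0.4) -> int:
    """Slice index of the hat-mask cutoff plane.

    The cutoff sits ``fraction`` of the head bounding-box extent above the
    inferior (low-index) head boundary along the superior–inferior axis.
    """
    other = tuple(a for a in range(head.ndim) if a != si_axis)
    profile = head.any(axis=other)
    idx = np.flatnonzero(profile)
    if idx.size == 0:
        raise MaskFailureError("empty head mask: no bounding box")
    imin, imax = int(idx[0]), int(idx[-1])
    return int(round(imin + fraction * (imax - imin)))


def compute_hat_mask(
    air: np.ndarray,
    head: np.ndarray,
    vol: Volume,
    fraction: float = 0.4,
) -> np.ndarray:
    """Hat mask: air restricted to slices superior to the cutoff plane.

    "Superior" is the increasing-index direction of the declared
    superior–inferior axis; a geometric proxy for the nasio-cerebellar
    plane used by the artifact-sensitive quality indices.
    """
    si = vol.axis_meaning.get("superior_inferior")
    if si is None:
        raise InvalidSpecError("axis_meaning lacks 'superior_inferior'")
    cutoff = hat_cutoff_index(head, si, fraction)
    hat = air.copy()
    sl = [slice(None)] * air.ndim
    sl[si] = slice(0, cutoff)
    hat[tuple(sl)] = False
    if not hat.any():
        raise MaskFailureError("hat mask empty")
    return hat


def _poly_design(shape: tuple[int, ...], order: int, mask: np.ndarray) -> np.ndarray:
    """Monomial design matrix (total degree <= order) at masked voxels,
    on coordinates normalized to [-1, 1] per axis."""
    coords = np.nonzero(mask)
    cols = []
    axes = [2.0 * c / max(n - 1, 1) - 1.0 for c, n in zip(coords, shape)]
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(axes[0] ** i * axes[1] ** j * axes[2] ** k)
    return np.column_stack(cols)


def estimate_inu_field(
    vol: Volume,
    head: np.ndarray,
    order: int = 3,
    n_iter: int = 3,
) -> BiasField:
    """Estimate the multiplicative INU field by polynomial regression on
    log-intensities within the head.

    Tissue structure would dominate a naive fit, so each iteration first
    groups the (current) corrected log-intensities into three classes by
    1D k-means and removes the class means; the polynomial is fitted to
    the class-centred residual, which isolates the smooth spatial trend.
    The field is exp of the fitted polynomial, renormalized to mean 1 over
    the head, and is invariant to global intensity scaling (a scale is a
    log-offset absorbed by the class means).
    """
    if not 2 <= order <= 4:
        raise InvalidSpecError(f"INU polynomial order must be in 2..4, got {order}")
    # Partial-volume and mask-rim voxels sit on shell surfaces — spatially
    # structured — and would masquerade as a bias trend; erode the mask and
    # trim per-class residual outliers before fitting.
    core = ndimage.binary_erosion(head, structure=ball(2))
    usable = (core if core.sum() >= 50 else head) & (vol.data > 0)
    if usable.sum() < 50:
        raise FitError(f"only {int(usable.sum())} usable voxels for INU fit")
    logi = np.log(vol.data[usable])
    X = _poly_design(vol.shape, order, usable)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        resid = logi - X @ beta
        centers = np.quantile(resid, [1 / 6, 3 / 6, 5 / 6])
        for _ in range(25):
            assign = np.argmin(np.abs(resid[:, None] - centers[None, :]), axis=1)
            # median centres: robust to the partial-volume continuum that
            # would otherwise shift class means radially
            new = np.array(
                [np.median(resid[assign == c]) if np.any(assign == c) else centers[c]
                 for c in range(3)]
            )
            if np.allclose(new, centers, atol=1e-8):
                break
            centers = new
        centred = resid - centers[assign]
        sigma = np.ones(3)
        for c in range(3):
            if np.any(assign == c):
                sigma[c] = 1.4826 * np.median(np.abs(centred[assign == c]))
        keep = np.abs(centred) <= 3.0 * sigma[assign]
        if keep.sum() < max(50, X.shape[1] * 3):
            keep = np.ones_like(keep)
        beta = beta + np.linalg.lstsq(X[keep], centred[keep], rcond=None)[0]
    full = np.ones(vol.shape, dtype=bool)
    log_field = (_poly_design(vol.shape, order, full) @ beta).reshape(vol.shape)
    fld = np.exp(log_field - log_field[head].mean())
    fld /= fld[head].mean()
    return BiasField(field=fld, params=beta)


def segment_tissues(
    vol_corrected: Volume,
    head: np.ndarray,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> TissueMaps:
    """Three-class EM Gaussian-mixture segmentation of in-head intensities.

    Components are initialized at the 1/6, 3/6, 5/6 intensity quantiles
    and relabelled by ascending fitted mean to (CSF, GM, WM); posterior
    probabilities are returned as maps on the input grid (zero outside the
    head).  The relabelling makes the result invariant to initialization
    order.
    """
    x = vol_corrected.data[head].reshape(-1, 1)
    if x.size < 3:
        raise SegmentationError("head mask too small to segment")
    init = np.quantile(x, [1 / 6, 3 / 6, 5 / 6]).reshape(3, 1)
    reg = max(1e-6 * float(np.var(x)), 1e-12)
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        means_init=init,
        max_iter=max_iter,
        tol=tol,
        reg_covar=reg,
        random_state=seed,
    )
    gmm.fit(x)
    if np.min(gmm.weights_) < 1e-4:
        raise SegmentationError(
            f"degenerate mixture component (weights {gmm.weights_})"
        )
    order_idx = np.argsort(gmm.means_.ravel())
    post = gmm.predict_proba(x)[:, order_idx]
    # Robust class centres: the EM means are dragged by the partial-volume
    # continuum between classes, so re-centre each class on the median of
    # its hard-assigned voxels.
    assign = np.argmax(post, axis=1)
    t = x.ravel()
    means = np.empty(3)
    gates = np.empty(3)
    for c in range(3):
        sel = t[assign == c]
        if sel.size == 0:
            raise SegmentationError(f"empty tissue class {c} after EM")
        means[c] = np.median(sel)
        mad = 1.4826 * np.median(np.abs(sel - means[c]))
        gates[c] = max(2.0 * mad, 0.02 * abs(means[c]))
    if not (means[0] < means[1] < means[2]):
        raise SegmentationError(f"class means not separable: {means}")
    gaps = np.diff(means)
    gates[0] = min(gates[0], 0.45 * gaps[0])
    gates[1] = min(gates[1], 0.45 * min(gaps))
    gates[2] = min(gates[2], 0.45 * gaps[1])
    # Mixel-style partial-volume resolution: voxels within a class gate
    # are pure; the rest interpolate linearly between the neighbouring
    # class means, with a zero-intensity background anchor below CSF
    # (remainder of the unit budget is background).  The maps are
    # evaluated on a one-voxel dilation of the head so the fractional rim
    # at the head boundary is recovered; the mixture itself is fitted on
    # the tight mask only, keeping air out of the intensity model.
    map_mask = ndimage.binary_dilation(head)
    t = np.clip(vol_corrected.data[map_mask], 0.0, None)
    dist = np.abs(t[:, None] - means[None, :])
    frac = np.zeros((t.size, 3))
    anchors = np.concatenate([[0.0], means])  # bg, csf, gm, wm
    pure = np.full(t.size, -1)
    nearest = np.argmin(dist, axis=1)
    in_gate = dist[np.arange(t.size), nearest] <= gates[nearest]
    pure[in_gate] = nearest[in_gate]
    for c in range(3):
        frac[pure == c, c] = 1.0
    mix = pure < 0
    tm = np.clip(t[mix], 0.0, None)
    seg = np.clip(np.searchsorted(anchors, tm, side="right") - 1, 0, 2)
    lo, hi = anchors[seg], anchors[seg + 1]
    w = np.clip((tm - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0, 1.0)
    above = tm >= anchors[-1]
    w[above] = 1.0
    seg[above] = 2
    rows = np.flatnonzero(mix)
    frac[rows, seg] += w
    lower = seg - 1  # class index of the lower anchor; -1 means background
    has_lower = lower >= 0
    frac[rows[has_lower], lower[has_lower]] += 1.0 - w[has_lower]
    maps = []
    for c in range(3):
        m = np.zeros(vol_corrected.shape)
        m[map_mask] = frac[:, c]
        maps.append(m)
    return TissueMaps(
        p_csf=maps[0], p_gm=maps[1], p_wm=maps[2],
        class_means=tuple(float(m) for m in means),
    )


def run_preprocessing(
    vol: Volume,
    inu_order: int = 3,
    hat_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[Volume, MaskSet, BiasField, TissueMaps]:
    """Full minimal workflow: masks, INU field, corrected image, segmentation."""
    head = compute_head_mask(vol)
    air = compute_air_mask(head, vol)
    hat = compute_hat_mask(air, head, vol, fraction=hat_fraction)
    bias = estimate_inu_field(vol, head, order=inu_order)
    corrected = vol.with_data(vol.data / bias.field)
    tissues = segment_tissues(corrected, head, seed=seed)
    return corrected, MaskSet(head=head, air=air, hat=hat), bias, tissues
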