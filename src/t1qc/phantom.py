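"""Synthetic T1w brain phantoms and multi-site feature tables.

The phantom is a nested-ellipsoid "head": a WM core inside a GM shell
inside a CSF shell, surrounded by background.  Shell radii are solved from
the target intracranial volume fractions, so ground-truth partial-volume
maps are exact by construction (the class indicator is supersampled 3x
per axis and box-averaged).  Intensities follow the T1w contrast ordering
CSF < GM < WM; an optional smooth multiplicative bias field, ghosting and
wrap-around artifacts can be applied, and magnitude noise is realized by
taking the modulus of two independent Gaussian channels — Rician in
tissue, Rayleigh in the air background, the noise family the
background-based quality indices assume.

The cohort writer lays subjects out BIDS-style
(``sub-XXX/anat/sub-XXX_T1w.nii.gz``) with per-site acquisition shifts,
and ``synth_iqm_table`` draws multi-site feature tables with controlled
class signal and site batch effects for exercising the learning stack
without any image processing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DegenerateArtifactError, GeometryError, InvalidSpecError
from .preprocess import Volume

# Head semi-axes as a fraction of each grid axis extent; leaves enough
# air margin for the 4-voxel head dilation plus the 2-voxel border rind.
_SEMIAXIS_FRAC = (0.32, 0.38, 0.35)
_SUPERSAMPLE = 3


@dataclass
class BiasSpec:
    """Multiplicative bias-field descriptor: exp(amplitude * P(x,y,z))
    for a random polynomial P of the given total order, normalized to
    max |P| = 1 over the grid."""

    order: int = 2
    amplitude: float = 0.0


@dataclass
class GhostSpec:
    axis: int = 1
    offset_frac: float = 0.5
    intensity: float = 0.0


@dataclass
class WrapSpec:
    axis: int = 1
    fold_frac: float = 0.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic T1w volume.

    ``tissue_means`` are (CSF, GM, WM) in arbitrary units and must be
    strictly increasing; ``tissue_fractions_target`` are the intended
    intracranial volume fractions in the same order (defaults to the
    normative 20% CSF / 35% GM / 45% WM split).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: tuple[float, float, float] = (200.0, 500.0, 700.0)
    tissue_fractions_target: tuple[float, float, float] = (0.20, 0.35, 0.45)
    noise_sigma: float = 10.0
    bias: BiasSpec = dc_field(default_factory=BiasSpec)
    ghost: GhostSpec = dc_field(default_factory=GhostSpec)
    wrap: WrapSpec = dc_field(default_factory=WrapSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_mm):
            raise InvalidSpecError(f"voxel_mm must be positive, got {self.voxel_mm}")
        m = self.tissue_means
        if not (m[0] < m[1] < m[2]):
            raise InvalidSpecError(f"tissue_means must satisfy CSF<GM<WM, got {m}")
        if abs(sum(self.tissue_fractions_target) - 1.0) > 1e-6:
            raise InvalidSpecError("tissue_fractions_target must sum to 1")
        if any(f <= 0 for f in self.tissue_fractions_target):
            raise InvalidSpecError("tissue fractions must be positive")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        if not 0.0 <= self.ghost.intensity <= 1.0:
            raise InvalidSpecError("ghost intensity must be in [0, 1]")
        if any(n < 32 for n in self.grid_shape):
            raise GeometryError(
                f"grid_shape {self.grid_shape} too small; need >= 32 per axis"
            )


@dataclass
class PhantomTruth:
    """Exact ground truth for one phantom (all maps pre-noise)."""

    pv_maps: dict[str, np.ndarray]
    head_mask_true: np.ndarray
    bias_field_true: np.ndarray
    applied_artifacts: dict

    def tissue_maps(self):
        from .preprocess import TissueMaps

        return TissueMaps(
            p_csf=self.pv_maps["csf"],
            p_gm=self.pv_maps["gm"],
            p_wm=self.pv_maps["wm"],
            class_means=(0.0, 0.5, 1.0),
        )


@dataclass
class SiteEffectSpec:
    """Per-site acquisition effects.

    ``feature_shift``/``feature_scale`` act on synthetic feature tables;
    ``intensity_scale``/``noise_scale`` act on rendered images.
    """

    site_id: str
    n_subjects: int = 10
    feature_shift: float | np.ndarray = 0.0
    feature_scale: float | np.ndarray = 1.0
    intensity_scale: float = 1.0
    noise_scale: float = 1.0
    exclude_prevalence: float = 0.31
    label_noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.feature_scale) <= 0):
            raise InvalidSpecError("feature_scale must be > 0 elementwise")
        for name in ("exclude_prevalence", "label_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")


def _shell_radii(fractions: tuple[float, float, float]) -> tuple[float, float]:
    """Normalized radii of the WM core and GM shell boundaries.

    For concentric similar ellipsoids volume scales with r^3, so the
    boundary radii are cube roots of the cumulative (inner-out) fractions.
    """
    f_csf, f_gm, f_wm = fractions
    return float(np.cbrt(f_wm)), float(np.cbrt(f_wm + f_gm))


def _partial_volume_maps(spec: PhantomSpec) -> dict[str, np.ndarray]:
    s = _SUPERSAMPLE
    shape = spec.grid_shape
    r_wm, r_gm = _shell_radii(spec.tissue_fractions_target)
    centers = [(n - 1) / 2.0 for n in shape]
    semi = [f * n for f, n in zip(_SEMIAXIS_FRAC, shape)]
    if min(semi) < 6.0:
        raise GeometryError("grid too small to hold three tissue shells")
    # Normalized coordinates of supersampled subvoxel centres, one 1D
    # array per axis; rho2 built by broadcasting keeps memory modest.
    ax = []
    for n, c, a in zip(shape, centers, semi):
        fine = (np.arange(n * s) + 0.5) / s - 0.5
        ax.append(((fine - c) / a).astype(np.float32) ** 2)
    rho2 = (
        ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
    )
    pv = {}
    bounds = {"wm": (0.0, r_wm), "gm": (r_wm, r_gm), "csf": (r_gm, 1.0)}
    for name, (lo, hi) in bounds.items():
        ind = ((rho2 >= lo * lo) & (rho2 < hi * hi)).astype(np.float32)
        coarse = ind.reshape(shape[0], s, shape[1], s, shape[2], s).mean(axis=(1, 3, 5))
        pv[name] = coarse.astype(np.float64)
    # single-precision box averaging can overshoot the unit budget by ~1e-8
    total = pv["csf"] + pv["gm"] + pv["wm"]
    excess = np.maximum(total, 1.0)
    for name in pv:
        pv[name] /= excess
    return pv


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth positive multiplicative field, deterministic in the spec seed."""
    b = spec.bias
    if b.amplitude == 0.0:
        return np.ones(spec.grid_shape)
    rng = np.random.default_rng(spec.seed + 10_007)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in spec.grid_shape], indexing="ij"
    )
    poly = np.zeros(spec.grid_shape)
    for i in range(b.order + 1):
        for j in range(b.order + 1 - i):
            for k in range(b.order + 1 - i - j):
                if i == j == k == 0:
                    continue
                poly += rng.normal() * grids[0] ** i * grids[1] ** j * grids[2] ** k
    poly /= np.max(np.abs(poly))
    return np.exp(b.amplitude * poly)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Render one phantom volume together with its exact ground truth.

    Order of operations: partial-volume mixing of tissue means, then the
    multiplicative bias field, then ghost/wrap artifacts, then magnitude
    noise (modulus of signal+N(0,s) and N(0,s)).  Truth maps describe the
    pre-noise image.
    """
    pv = _partial_volume_maps(spec)
    signal = sum(pv[t] * m for t, m in zip(("csf", "gm", "wm"), spec.tissue_means))
    bias = _bias_field(spec)
    signal = signal * bias
    applied: dict = {}
    vol = Volume(signal, spec.voxel_mm)
    if spec.ghost.intensity > 0.0:
        vol = add_ghost(vol, spec.ghost.axis, spec.ghost.offset_frac, spec.ghost.intensity)
        applied["ghost"] = vars(spec.ghost).copy()
    if spec.wrap.fold_frac > 0.0:
        vol = add_wraparound(vol, spec.wrap.axis, spec.wrap.fold_frac)
        applied["wrap"] = vars(spec.wrap).copy()
    if spec.bias.amplitude > 0.0:
        applied["bias"] = vars(spec.bias).copy()
    data = vol.data
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        n1 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
        n2 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
        data = np.hypot(data + n1, n2)
        applied["noise_sigma"] = spec.noise_sigma
    truth = PhantomTruth(
        pv_maps=pv,
        head_mask_true=(pv["csf"] + pv["gm"] + pv["wm"]) > 0.5,
        bias_field_true=bias,
        applied_artifacts=applied,
    )
    return Volume(data, spec.voxel_mm), truth


def add_ghost(vol: Volume, axis: int, offset_frac: float, intensity: float) -> Volume:
    """Add a shifted replica along the phase-encoding axis.

    output = input + intensity * roll(input, round(offset_frac * N), axis)
    """
    if not 0.0 < offset_frac < 1.0:
        raise InvalidSpecError(f"offset_frac must be in (0,1), got {offset_frac}")
    n = vol.shape[axis]
    shift = int(round(offset_frac * n))
    if shift == 0:
        raise DegenerateArtifactError("ghost offset rounds to 0 voxels")
    out = vol.data + intensity * np.roll(vol.data, shift, axis=axis)
    return vol.with_data(out)


def add_wraparound(vol: Volume, axis: int, fold_frac: float) -> Volume:
    """Fold the leading ``fold_frac`` slab of the field of view onto the
    trailing slab, then crop the leading slab to background (zero)."""
    if not 0.0 < fold_frac < 0.5:
        raise InvalidSpecError(f"fold_frac must be in (0, 0.5), got {fold_frac}")
    n = vol.shape[axis]
    nfold = max(int(round(fold_frac * n)), 1)
    if nfold >= n // 2:
        raise GeometryError(f"fold of {nfold} slices exceeds half the FOV")
    out = vol.data.copy()
    lead = [slice(None)] * 3
    trail = [slice(None)] * 3
    lead[axis] = slice(0, nfold)
    trail[axis] = slice(n - nfold, n)
    out[tuple(trail)] += out[tuple(lead)]
    out[tuple(lead)] = 0.0
    return vol.with_data(out)


@dataclass
class CohortManifest:
    table: pd.DataFrame
    tsv_path: Path
    sidecar_path: Path


def render_cohort(
    sites: list[SiteEffectSpec],
    base_spec: PhantomSpec,
    out_dir,
    seed: int = 0,
    write_truth: bool = True,
) -> CohortManifest:
    """Write a BIDS-style multi-site cohort of phantom images.

    "Exclude" subjects receive a visible artifact (ghost at intensity
    >= 0.25, noise at >= 3x the base level, or a strong bias field) drawn
    at each site's ``exclude_prevalence``; the manifest label is flipped
    at ``label_noise_rate`` to emulate rater class-noise.  When
    ``write_truth`` is set, the exact tissue maps are saved alongside each
    image as ``*_label-{CSF,GM,WM}_probseg.nii.gz`` so the map-overlap
    metrics have a reference.
    """
    if not sites:
        raise InvalidSpecError("need at least one site")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for site in sites:
        for j in range(site.n_subjects):
            sub = f"{site.site_id}{j:03d}"
            sub_dir = out_dir / f"sub-{sub}" / "anat"
            if sub_dir.exists():
                raise FileExistsError(f"subject directory already exists: {sub_dir}")
            sub_dir.mkdir(parents=True)
            spec = PhantomSpec(
                grid_shape=base_spec.grid_shape,
                voxel_mm=base_spec.voxel_mm,
                tissue_means=tuple(
                    m * site.intensity_scale for m in base_spec.tissue_means
                ),
                tissue_fractions_target=base_spec.tissue_fractions_target,
                noise_sigma=base_spec.noise_sigma * site.noise_scale,
                seed=int(rng.integers(2**31)),
            )
            is_exclude = bool(rng.random() < site.exclude_prevalence)
            artifact = "none"
            if is_exclude:
                artifact = rng.choice(["ghost", "noise", "bias"])
                if artifact == "ghost":
                    spec.ghost = GhostSpec(
                        axis=1, offset_frac=0.5,
                        intensity=float(rng.uniform(0.25, 0.5)),
                    )
                elif artifact == "noise":
                    spec.noise_sigma = base_spec.noise_sigma * float(
                        rng.uniform(3.0, 4.0)
                    )
                else:
                    spec.bias = BiasSpec(order=2, amplitude=float(rng.uniform(0.4, 0.6)))
            vol, truth = generate_phantom(spec)
            vol.to_nifti().to_filename(str(sub_dir / f"sub-{sub}_T1w.nii.gz"))
            if write_truth:
                for cls in ("csf", "gm", "wm"):
                    img = nib.Nifti1Image(
                        truth.pv_maps[cls].astype(np.float32), vol.affine
                    )
                    img.to_filename(
                        str(sub_dir / f"sub-{sub}_label-{cls.upper()}_probseg.nii.gz")
                    )
            label = "exclude" if is_exclude else "accept"
            if site.label_noise_rate > 0 and rng.random() < site.label_noise_rate:
                label = "accept" if label == "exclude" else "exclude"
            rows.append(
                {
                    "subject_id": sub,
                    "site": site.site_id,
                    "label": label,
                    "artifact": artifact,
                }
            )
    manifest = pd.DataFrame(rows)
    tsv_path = out_dir / "participants.tsv"
    manifest.to_csv(tsv_path, sep="\t", index=False)
    sidecar = {
        "seed": seed,
        "base_spec": {
            "grid_shape": list(base_spec.grid_shape),
            "voxel_mm": list(base_spec.voxel_mm),
            "tissue_means": list(base_spec.tissue_means),
            "noise_sigma": base_spec.noise_sigma,
        },
        "sites": [
            {
                "site_id": s.site_id,
                "n_subjects": s.n_subjects,
                "exclude_prevalence": s.exclude_prevalence,
                "label_noise_rate": s.label_noise_rate,
                "intensity_scale": s.intensity_scale,
                "noise_scale": s.noise_scale,
            }
            for s in sites
        ],
    }
    sidecar_path = out_dir / "participants.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return CohortManifest(table=manifest, tsv_path=tsv_path, sidecar_path=sidecar_path)


def synth_iqm_table(
    sites: list[SiteEffectSpec],
    n_features: int = 10,
    class_effect: float | np.ndarray = 0.0,
    seed: int = 0,
    require_both_classes: bool = False,
) -> pd.DataFrame:
    """Draw a multi-site feature table with class signal and batch effects.

    Features are class-conditional Gaussians: N(0,1) for "accept" rows and
    N(class_effect, 1) (per feature, in SD units) for "exclude" rows; a
    scalar ``class_effect`` is broadcast.  Per-site additive shifts and
    multiplicative scales are then applied to every feature, emulating the
    acquisition batch effect that lets rows be clustered by site.
    """
    if n_features < 2:
        raise InvalidSpecError("need at least 2 features")
    effect = np.broadcast_to(np.asarray(class_effect, dtype=float), (n_features,))
    rng = np.random.default_rng(seed)
    frames = []
    for site in sites:
        n = site.n_subjects
        y = (rng.random(n) < site.exclude_prevalence).astype(int)
        if require_both_classes and len(np.unique(y)) < 2:
            raise InvalidSpecError(
                f"site {site.site_id} drew a single class; cannot stratify"
            )
        X = rng.normal(size=(n, n_features)) + y[:, None] * effect[None, :]
        X = X * np.asarray(site.feature_scale) + np.asarray(site.feature_shift)
        if site.label_noise_rate > 0:
            flip = rng.random(n) < site.label_noise_rate
            y = np.where(flip, 1 - y, y)
        df = pd.DataFrame(X, columns=[f"iqm_{k:02d}" for k in range(n_features)])
        df.insert(0, "label", np.where(y == 1, "exclude", "accept"))
        df.insert(0, "site", site.site_id)
        df.insert(0, "subject_id", [f"{site.site_id}{j:03d}" for j in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
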