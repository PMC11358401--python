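"""Synthetic MRI generation from label maps.

The training images for a contrast- and resolution-agnostic segmenter
are never real scans: each one is sampled from a label map by (i) a
random geometric augmentation (affine + smooth elastic deformation) of
the labels, (ii) drawing a random Gaussian intensity model per label
(mean and standard deviation sampled uniformly from configured ranges)
and sampling every voxel conditionally independently, and (iii)
simulating an acquisition at lower, possibly anisotropic resolution by
blurring and down/up-sampling.  Randomizing contrast and resolution at
every draw is what removes the domain gap at test time.

The drawn per-label (mu, sigma) and the normalization constants are
returned alongside each image so statistical properties of the
generator can be verified directly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .core import LabelMap, Volume

__all__ = [
    "SynthConfig",
    "GmmDraw",
    "augment_labels",
    "apply_deformation",
    "sample_gmm_image",
    "simulate_resolution",
    "generate_training_pair",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class SynthConfig:
    mean_range: tuple[float, float] = (25.0, 225.0)
    std_range: tuple[float, float] = (5.0, 25.0)
    rotation_range: float = 15.0        # degrees, per axis, symmetric
    scale_range: tuple[float, float] = (0.85, 1.15)
    shear_range: float = 0.012          # off-diagonal affine terms, symmetric
    translation_range: float = 10.0     # mm, per axis, symmetric
    elastic_scale: float = 3.0          # mm, std of the displacement field
    elastic_fwhm: float = 20.0          # mm, smoothness of the field
    thickness_range: tuple[float, float] = (1.0, 9.0)  # mm simulated slices
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_range", "std_range", "scale_range", "thickness_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy lower <= upper")
        if self.std_range[0] <= 0:
            raise ValueError("std_range lower bound must be positive")


@dataclasses.dataclass
class GmmDraw:
    """The random intensity model drawn for one synthetic image."""

    means: dict[int, float]
    stds: dict[int, float]
    norm_min: float    # min-max normalization applied after sampling:
    norm_scale: float  # normalized = (raw - norm_min) / norm_scale

    def unnormalize(self, data: np.ndarray) -> np.ndarray:
        return data * self.norm_scale + self.norm_min


def _random_affine_index_map(
    lm: LabelMap, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Inverse world-space augmentation affine expressed in index coords."""
    ang = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range, 3))
    scale = rng.uniform(cfg.scale_range[0], cfg.scale_range[1], 3)
    shear = rng.uniform(-cfg.shear_range, cfg.shear_range, 3)
    trans = rng.uniform(-cfg.translation_range, cfg.translation_range, 3)
    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    sh = np.eye(3)
    sh[0, 1], sh[0, 2], sh[1, 2] = shear
    m = rx @ ry @ rz @ sh @ np.diag(scale)
    centre = lm.world_coordinates(
        (np.asarray(lm.shape, dtype=float) - 1) / 2.0
    ).ravel()
    aug = np.eye(4)
    aug[:3, :3] = m
    aug[:3, 3] = centre - m @ centre + trans
    # source_world = aug^{-1} @ out_world ; express in index coordinates
    return np.linalg.inv(lm.affine) @ np.linalg.inv(aug) @ lm.affine


def _elastic_field(
    shape, spacing, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement, in voxel units, shape (3, *shape)."""
    sigma_vox = cfg.elastic_fwhm * FWHM_TO_SIGMA / np.asarray(spacing)
    field = np.empty((3,) + tuple(shape))
    for a in range(3):
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        sd = smooth.std()
        amp_vox = cfg.elastic_scale / spacing[a]
        field[a] = smooth * (amp_vox / sd) if sd > 0 else 0.0
    return field


def _build_deformation(
    lm: LabelMap, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Source-index sampling field, shape (3, *shape): out(v) = in(field[:, v])."""
    shape = lm.shape
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    m = _random_affine_index_map(lm, cfg, rng)
    src = np.stack(
        [
            m[a, 0] * grids[0] + m[a, 1] * grids[1] + m[a, 2] * grids[2] + m[a, 3]
            for a in range(3)
        ]
    )
    if cfg.elastic_scale > 0:
        src += _elastic_field(shape, lm.spacing, cfg, rng)
    return src


def apply_deformation(lm: LabelMap, deformation: np.ndarray) -> LabelMap:
    """Resample labels (nearest-neighbour) through a stored sampling field."""
    out = ndimage.map_coordinates(
        np.asarray(lm.data, dtype=np.float32),
        deformation,
        order=0,
        mode="constant",
        cval=0.0,
    )
    return LabelMap(np.rint(out).astype(np.int32), lm.affine.copy(), dict(lm.label_table))


def augment_labels(
    lm: LabelMap,
    cfg: SynthConfig | None = None,
    seed: int = 0,
    return_deformation: bool = False,
):
    """Random affine + elastic deformation of a label map (nearest-neighbour).

    Output ids are always a subset of the input ids; a fixed seed gives
    identical output.  With ``return_deformation`` the sampling field is
    returned too, so the identical warp can be re-applied to another map
    on the same grid.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    deformation = _build_deformation(lm, cfg, rng)
    out = apply_deformation(lm, deformation)
    if return_deformation:
        return out, deformation
    return out


def sample_gmm_image(
    lm: LabelMap, cfg: SynthConfig | None = None, seed: int = 0
) -> tuple[Volume, GmmDraw]:
    """Sample a random-contrast image conditioned on a label map.

    Per label id l: mu_l ~ U(mean_range), sigma_l ~ U(std_range); voxel
    intensities are independent N(mu_l, sigma_l^2) draws.  The image is
    min-max normalized to [0, 1]; the draw (including the normalization
    constants) is returned for inspection.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    ids = [int(i) for i in lm.ids()]
    means = {l: float(rng.uniform(*cfg.mean_range)) for l in ids}
    stds = {l: float(rng.uniform(*cfg.std_range)) for l in ids}
    data = np.zeros(lm.shape, dtype=np.float64)
    for l in ids:
        where = lm.data == l
        n = int(where.sum())
        data[where] = rng.normal(means[l], stds[l], size=n)
    lo = float(data.min())
    scale = float(data.max() - lo)
    if scale == 0:
        scale = 1.0
    draw = GmmDraw(means=means, stds=stds, norm_min=lo, norm_scale=scale)
    return Volume((data - lo) / scale, lm.affine.copy()), draw


def simulate_resolution(
    v: Volume, thickness, seed: int = 0
) -> Volume:
    """Emulate acquisition at a lower (possibly anisotropic) resolution.

    Per axis: Gaussian blur whose standard deviation follows
    0.85 * thickness / (2 * spacing) voxels, with the native-resolution
    baseline removed in quadrature so thickness == spacing is an exact
    identity; then linear downsampling to the simulated spacing and
    linear resampling back to the native grid.
    """
    thick = np.broadcast_to(np.asarray(thickness, dtype=float), (3,)).copy()
    spacing = v.spacing
    if np.any(thick < spacing - 1e-9):
        raise ValueError("simulated thickness must be >= native spacing on each axis")
    ratio = thick / spacing
    base = 0.85 / 2.0
    sigma_vox = np.sqrt(np.maximum(0.0, (base * ratio) ** 2 - base**2))
    data = np.asarray(v.data, dtype=np.float64)
    if np.any(sigma_vox > 0):
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if np.any(ratio > 1 + 1e-9):
        n = np.asarray(v.shape)
        n_low = np.maximum(1, np.round(n / ratio)).astype(int)
        # centre-aligned linear down- then up-sampling
        down = np.meshgrid(
            *[(np.arange(m) + 0.5) * n[a] / m - 0.5 for a, m in enumerate(n_low)],
            indexing="ij",
        )
        low = ndimage.map_coordinates(data, down, order=1, mode="nearest")
        up = np.meshgrid(
            *[(np.arange(n[a]) + 0.5) * n_low[a] / n[a] - 0.5 for a in range(3)],
            indexing="ij",
        )
        data = ndimage.map_coordinates(low, up, order=1, mode="nearest")
    return Volume(data, v.affine.copy())


def generate_training_pair(
    lm: LabelMap, cfg: SynthConfig | None = None, seed: int = 0
) -> tuple[Volume, LabelMap]:
    """One (synthetic image, segmentation target) pair from a full-brain map.

    The same random deformation warps both the synthesis labels and the
    target; the image additionally goes through GMM intensity sampling
    and resolution simulation.  The target keeps only ids 0-10 (context
    classes collapse to background -- they are synthesis scaffolding,
    never segmentation targets).
    """
    cfg = cfg or SynthConfig()
    ids = set(int(i) for i in lm.ids())
    if not set(range(1, 11)) <= ids:
        warnings.warn(
            "label map is missing some subregion ids 1-10; targets will be partial",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    aug_seed = int(rng.integers(0, 2**31 - 1))
    gmm_seed = int(rng.integers(0, 2**31 - 1))
    aug = augment_labels(lm, cfg, seed=aug_seed)
    image, _ = sample_gmm_image(aug, cfg, seed=gmm_seed)
    thick = rng.uniform(cfg.thickness_range[0], cfg.thickness_range[1], 3)
    thick = np.maximum(thick, image.spacing)
    image = simulate_resolution(image, thick)
    target = aug.data.copy()
    target[target > 10] = 0
    return image, LabelMap(target, aug.affine.copy())
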