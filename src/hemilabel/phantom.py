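"""Deterministic hemisphere phantoms for exercising the whole pipeline.

Real inputs are ultra-high-resolution ex vivo scans of single brain
hemispheres with a manually traced 5-subregion hypothalamus.  The
phantom stands in for them with known ground truth: a half-ellipsoid
"hemisphere" sitting entirely on one side of the mid-sagittal plane
x = 0, flat medial face toward the plane, filled with concentric
constant-intensity shells (the analog of tissue classes), plus optional
Gaussian noise and a multiplicative bias gradient.  A 5-label block
abuts the medial face, laid out like the hypothalamic subregions:
anterior / tuberal / posterior along the antero-posterior axis, with
the anterior and tuberal parts split into superior and inferior halves
(ids 1 anterior-sup, 2 anterior-inf, 3 tuberal-sup, 4 tuberal-inf,
5 posterior).

Phantoms are geometric, not anatomically realistic: their job is to
give every stage a verifiable ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import LabelMap, Volume, left_right_flip

__all__ = ["PhantomSpec", "make_phantom_hemisphere", "make_phantom_cohort"]

SHELL_MEAN_LO = 40.0
SHELL_MEAN_HI = 210.0


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 0.3             # mm, isotropic
    n_shells: int = 4                # concentric intensity shells (4..9)
    hemisphere_side: str = "left"    # "left" (x<0) or "right" (x>0)
    subregion_extent: tuple[float, float, float] = (4.5, 9.0, 6.0)  # mm box
    noise_sigma: float = 2.0         # additive Gaussian intensity noise
    bias_gradient: tuple[float, float] = (1.0, 1.0)  # multiplicative range
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("phantom shape must be >= 32 per axis")
        if not (4 <= self.n_shells <= 9):
            raise ValueError("n_shells must be in [4, 9]")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.hemisphere_side not in ("left", "right"):
            raise ValueError("hemisphere_side must be 'left' or 'right'")


def shell_means(n_shells: int) -> np.ndarray:
    """Well-separated shell intensities, darkest innermost."""
    return np.linspace(SHELL_MEAN_LO, SHELL_MEAN_HI, n_shells)


def make_phantom_hemisphere(spec: PhantomSpec | None = None) -> tuple[Volume, LabelMap]:
    """One hemisphere-like volume plus its 5-subregion manual-label analog.

    The left-sided phantom occupies world x < 0 with its flat medial
    face on the voxel plane nearest x = 0; a right-sided phantom is its
    exact mirror (all anatomy at x > 0).  Same seed, same output.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    s = spec.spacing
    # voxel centres: x in [-(nx-0.5)s, -0.5s] -- strictly negative world x
    affine = np.diag([s, s, s, 1.0])
    affine[0, 3] = -(nx - 0.5) * s
    affine[1, 3] = -(ny / 2.0) * s
    affine[2, 3] = -(nz / 2.0) * s
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    x = ii * s + affine[0, 3]
    y = jj * s + affine[1, 3]
    z = kk * s + affine[2, 3]

    extent = np.array(spec.shape) * s
    centre = np.array([-0.5 * s, affine[1, 3] + extent[1] / 2.0,
                       affine[2, 3] + extent[2] / 2.0])
    semi = np.array([0.9 * extent[0], 0.42 * extent[1], 0.42 * extent[2]])
    rho = np.sqrt(
        ((x - centre[0]) / semi[0]) ** 2
        + ((y - centre[1]) / semi[1]) ** 2
        + ((z - centre[2]) / semi[2]) ** 2
    )
    hemi = rho <= 1.0

    means = shell_means(spec.n_shells)
    shell_idx = np.minimum((rho * spec.n_shells).astype(int), spec.n_shells - 1)
    data = np.where(hemi, means[shell_idx], 0.0)
    if spec.noise_sigma > 0:
        data = np.where(hemi, data + rng.normal(0.0, spec.noise_sigma, data.shape), 0.0)
    lo, hi = spec.bias_gradient
    if hi != lo:
        # smooth multiplicative gradient along the x+y diagonal of the FOV
        ramp = (x - x.min()) / np.ptp(x) + (y - y.min()) / np.ptp(y)
        ramp = ramp / 2.0
        data = np.where(hemi, data * (lo + (hi - lo) * ramp), 0.0)

    # 5-subregion block abutting the medial face
    ex, ey, ez = spec.subregion_extent
    box = (
        (x >= -0.5 * s - ex)
        & (x <= -0.4 * s)
        & (np.abs(y - centre[1]) <= ey / 2.0)
        & (np.abs(z - centre[2]) <= ez / 2.0)
    )
    if not np.all(hemi[box]):
        raise ValueError("subregion extent exceeds the hemisphere bounds")
    labels = np.zeros(spec.shape, dtype=np.int32)
    y0 = centre[1] - ey / 2.0
    anterior = box & (y >= y0 + 2.0 * ey / 3.0)      # most anterior third
    tuberal = box & (y >= y0 + ey / 3.0) & ~anterior
    posterior = box & ~anterior & ~tuberal           # most posterior third
    superior = z >= centre[2]
    labels[anterior & superior] = 1   # anterior superior
    labels[anterior & ~superior] = 2  # anterior inferior
    labels[tuberal & superior] = 3    # tuberal superior
    labels[tuberal & ~superior] = 4   # tuberal inferior
    labels[posterior] = 5             # posterior (full height)

    vol = Volume(data, affine)
    lm = LabelMap(labels, affine.copy())
    if spec.hemisphere_side == "right":
        vol = left_right_flip(vol)
        lm = left_right_flip(lm)
    return vol, lm


def make_phantom_cohort(
    n: int = 10, base_seed: int = 0, spec: PhantomSpec | None = None
) -> list[tuple[Volume, LabelMap]]:
    """A cohort of phantoms with varied seeds and sides.

    Every third member is right-sided so the left-right flip path is
    exercised; seeds derive from ``base_seed`` so the whole cohort is
    reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    cohort = []
    for i in range(n):
        member = dataclasses.replace(
            spec,
            seed=base_seed + i,
            hemisphere_side="right" if i % 3 == 2 else "left",
        )
        cohort.append(make_phantom_hemisphere(member))
    return cohort
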