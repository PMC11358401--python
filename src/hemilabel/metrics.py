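"""Segmentation agreement metrics: Dice coefficient and Average Hausdorff Distance.

Dice is 2|A∩B| / (|A|+|B|) over voxel sets; two empty sets agree
perfectly (Dice 1.0), an empty against a non-empty set scores 0.0.

The Average Hausdorff Distance is the symmetric mean of nearest-
neighbour distances between the two voxel sets, Euclidean in world mm
through each grid's affine.  It is computed over all labeled voxels
(not only surface voxels) -- tools that use surface point sets will
report different values.  AHD is undefined when either set is empty.

``intra_rater_report`` groups the five hypothalamic subregions the way
reliability studies report them: Whole (1-5), Anterior (superior +
inferior, ids 1-2), Tuberal (ids 3-4), Posterior (id 5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import LabelMap

__all__ = [
    "dice_coefficient",
    "average_hausdorff_distance",
    "intra_rater_report",
    "REPORT_GROUPS",
]

# reliability-report label groups over subregion ids
# 1 anterior superior, 2 anterior inferior, 3 tuberal superior,
# 4 tuberal inferior, 5 posterior
REPORT_GROUPS: dict[str, tuple[int, ...]] = {
    "Whole": (1, 2, 3, 4, 5),
    "Anterior": (1, 2),
    "Tuberal": (3, 4),
    "Posterior": (5,),
}


def _check_same_grid(a: LabelMap, b: LabelMap, tol_mm: float = 1e-4) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"grid mismatch: shapes {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.affine, b.affine, atol=tol_mm):
        raise ValueError("grid mismatch: affines differ beyond tolerance")


def dice_coefficient(a: LabelMap, b: LabelMap, ids) -> float:
    """Overlap agreement in [0, 1] for the voxel sets carrying any id in ``ids``."""
    _check_same_grid(a, b)
    ma = a.mask(ids)
    mb = b.mask(ids)
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def average_hausdorff_distance(a: LabelMap, b: LabelMap, ids) -> float:
    """Symmetric mean nearest-neighbour distance in world mm.

    0.0 iff the two voxel sets are identical; raises if either is empty.
    """
    _check_same_grid(a, b)
    pa = a.world_coordinates(np.argwhere(a.mask(ids)))
    pb = b.world_coordinates(np.argwhere(b.mask(ids)))
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("average Hausdorff distance is undefined for empty sets")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def intra_rater_report(seg1: LabelMap, seg2: LabelMap) -> pd.DataFrame:
    """Agreement table between two delineations of the same subject.

    One row per group (Whole, Anterior, Tuberal, Posterior) with Dice
    and AHD (mm).  A group absent from both raters is reported as
    missing (NaN), never as zero.
    """
    _check_same_grid(seg1, seg2)
    rows = []
    for group, ids in REPORT_GROUPS.items():
        present = bool(seg1.mask(ids).any() or seg2.mask(ids).any())
        if not present:
            rows.append({"group": group, "dice": np.nan, "ahd_mm": np.nan})
            continue
        dice = dice_coefficient(seg1, seg2, ids)
        try:
            ahd = average_hausdorff_distance(seg1, seg2, ids)
        except ValueError:  # one rater missed the group entirely
            ahd = np.nan
        rows.append({"group": group, "dice": dice, "ahd_mm": ahd})
    return pd.DataFrame(rows, columns=["group", "dice", "ahd_mm"])
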