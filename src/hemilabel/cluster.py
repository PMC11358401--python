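"""Unsupervised "context" labeling of the brain by k-means on intensities.

The non-hypothalamic tissue does not need anatomically meaningful
labels: its only job is to condition synthetic image contrast.  A 1-D
k-means over the bias-corrected grayscale levels inside the brain mask
therefore suffices.  To increase the variability of the generated label
maps, clustering is run for every k in a configured range (default
4..9, i.e. 6 context maps per volume and 60 for a 10-subject cohort).

Cluster ids are made stable by sorting clusters by ascending mean
intensity and offsetting them (default offset 100) so they can never
collide with the hypothalamic subregion ids 1-10.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.cluster import KMeans

from .core import LabelMap, Volume

__all__ = ["ContextSetConfig", "cluster_intensities", "generate_context_set"]


@dataclasses.dataclass
class ContextSetConfig:
    k_min: int = 4
    k_max: int = 9
    seed: int = 0
    context_id_offset: int = 100

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.context_id_offset <= 10:
            raise ValueError("context_id_offset must exceed all subregion ids (1-10)")


def cluster_intensities(
    v: Volume,
    mask: LabelMap,
    k: int,
    seed: int = 0,
    offset: int = 100,
) -> LabelMap:
    """Partition in-mask voxels into k intensity clusters.

    Ids are ``offset+1 .. offset+k`` in ascending order of cluster mean
    intensity (offset+1 = darkest); out-of-mask voxels are 0.  Fixed
    seed gives identical output (k-means++ initialization, seeded).
    """
    m = mask.data > 0
    if not m.any():
        raise ValueError("empty mask")
    if k < 2:
        raise ValueError("k must be >= 2")
    values = np.asarray(v.data, dtype=float)[m]
    n_distinct = np.unique(values).size
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct in-mask intensities"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=3, random_state=seed)
    assign = km.fit_predict(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    rank = np.empty(k, dtype=np.int32)
    rank[order] = np.arange(k, dtype=np.int32)
    out = np.zeros(v.data.shape, dtype=np.int32)
    out[m] = offset + 1 + rank[assign]
    return LabelMap(out, v.affine.copy())


def generate_context_set(
    v: Volume, mask: LabelMap, cfg: ContextSetConfig | None = None
) -> list[LabelMap]:
    """One context map per k in [k_min, k_max], ascending.

    Each map is clustered with its own derived seed (``cfg.seed + k``) so
    the whole set is reproducible from a single seed.
    """
    cfg = cfg or ContextSetConfig()
    return [
        cluster_intensities(
            v, mask, k, seed=cfg.seed + k, offset=cfg.context_id_offset
        )
        for k in range(cfg.k_min, cfg.k_max + 1)
    ]
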