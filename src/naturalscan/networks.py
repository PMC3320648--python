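"""Spatial thresholding, cluster labeling and network comparison.

Statistic volumes are binarized, connected components are labeled under the
18-neighbourhood (voxels sharing a face or an edge, not only a vertex) and
small clusters discarded; ICA and voxel-wise result masks are compared
voxel-by-voxel into overlap categories; functional connectivity between
cluster mean time courses is assessed with a max-correlation circular-shift
permutation null; and per-time-point snapshot maps threshold the
across-subject mean of standardized signals against the sampling
distribution of a mean of standard normals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ClusterSet",
    "ConnectivityNull",
    "OVERLAP_CATEGORIES",
    "threshold_map",
    "label_clusters",
    "classify_overlap",
    "roi_connectivity_threshold",
    "snapshot_map",
]

#: category codes written by classify_overlap
OVERLAP_CATEGORIES = {
    "none": 0,
    "voxel_only": 1,
    "ic1_only": 2,
    "ic2_only": 3,
    "voxel_ic1": 4,
    "voxel_ic2": 5,
    "ic1_ic2": 6,
    "voxel_ic1_ic2": 7,
}


@dataclass
class ClusterSet:
    """Labeled suprathreshold clusters of one statistic volume."""

    labels: np.ndarray  # int volume, 0 = background, clusters 1..n
    sizes: np.ndarray  # voxels per retained cluster
    mean_timecourses: np.ndarray | None = None  # clusters x time
    provenance: list[str] | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def threshold_map(volume: np.ndarray, rule: float = 3.0, absolute: bool = True) -> np.ndarray:
    """Binarize a statistic volume.

    With ``absolute`` the default rule keeps voxels with |value| >= rule
    (suitable for z-scored component maps, and invariant to component sign
    flips); otherwise a one-sided value > rule is applied (suitable for
    correlation maps against a permutation threshold).
    """
    import warnings

    volume = np.asarray(volume, dtype=float)
    mask = (np.abs(volume) >= rule) if absolute else (volume > rule)
    if not mask.any():
        warnings.warn("threshold produced an empty mask", stacklevel=2)
    return mask


_STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)  # faces + edges


def label_clusters(
    mask: np.ndarray,
    connectivity: int = 18,
    min_cluster_size: int = 125,
) -> ClusterSet:
    """Connected-component labeling with a minimum cluster size.

    Components are connected under the requested 3-D neighbourhood (6, 18
    or 26); clusters of ``min_cluster_size`` voxels or fewer are discarded
    (the size criterion is strict: a 125-voxel cluster is dropped at the
    default).  Retained clusters are relabeled contiguously from 1 in
    decreasing size order.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: _STRUCTURE_18,
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    lab, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(lab.ravel())[1:]  # skip background
    keep = np.flatnonzero(sizes > min_cluster_size) + 1
    keep = keep[np.argsort(sizes[keep - 1])[::-1]]
    out = np.zeros_like(lab)
    out_sizes = []
    for new, old in enumerate(keep, start=1):
        out[lab == old] = new
        out_sizes.append(int(sizes[old - 1]))
    return ClusterSet(out, np.array(out_sizes, dtype=int))


def cluster_mean_timecourses(clusters: ClusterSet, dataset) -> np.ndarray:
    """Mean time course per cluster from a masked BoldDataset."""
    vols = dataset.to_volume()  # x, y, z, t
    out = np.empty((clusters.n_clusters, vols.shape[-1]))
    for c in range(1, clusters.n_clusters + 1):
        out[c - 1] = vols[clusters.labels == c].mean(axis=0)
    return out


def classify_overlap(
    voxelwise_mask: np.ndarray,
    ic_masks: Sequence[np.ndarray],
) -> np.ndarray:
    """Label each voxel by which result masks cover it.

    Compares the voxel-wise GLM mask with two IC masks, producing the
    category codes of :data:`OVERLAP_CATEGORIES` (only-voxelwise, only one
    IC, pairwise and triple overlaps).
    """
    if len(ic_masks) != 2:
        raise ValueError("exactly two IC masks expected")
    v = np.asarray(voxelwise_mask).astype(bool)
    a, b = (np.asarray(m).astype(bool) for m in ic_masks)
    if v.shape != a.shape or v.shape != b.shape:
        raise ValueError("mask shapes differ")
    code = np.zeros(v.shape, dtype=int)
    code[v & ~a & ~b] = OVERLAP_CATEGORIES["voxel_only"]
    code[~v & a & ~b] = OVERLAP_CATEGORIES["ic1_only"]
    code[~v & ~a & b] = OVERLAP_CATEGORIES["ic2_only"]
    code[v & a & ~b] = OVERLAP_CATEGORIES["voxel_ic1"]
    code[v & ~a & b] = OVERLAP_CATEGORIES["voxel_ic2"]
    code[~v & a & b] = OVERLAP_CATEGORIES["ic1_ic2"]
    code[v & a & b] = OVERLAP_CATEGORIES["voxel_ic1_ic2"]
    return code


@dataclass
class ConnectivityNull:
    """Max-correlation permutation null for ROI functional connectivity."""

    max_r: np.ndarray
    n_permutations: int
    min_shift: int
    monte_carlo_se: float
    shifts: np.ndarray | None = None  # permutation log

    def threshold_at(self, p: float) -> float:
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        return float(np.quantile(self.max_r, 1.0 - p))


def roi_connectivity_threshold(
    mean_timecourses: np.ndarray,
    n_permutations: int = 100_000,
    min_shift: int = 5,
    p: float = 0.001,
    seed: int = 0,
    signed: bool = True,
) -> tuple[ConnectivityNull, list[tuple[int, int, float]]]:
    """Permutation threshold for between-cluster time-course correlations.

    Each permutation picks a seed cluster uniformly, rotates its time
    course by a random shift of at least ``min_shift`` samples (in either
    direction), correlates it with every other cluster and records the
    maximum (signed by default).  Observed pairs exceeding the null's
    ``1 - p`` quantile are returned as significant.
    """
    Y = np.atleast_2d(np.asarray(mean_timecourses, dtype=float))
    R, T = Y.shape
    if R < 2:
        raise ValueError("need at least two clusters")
    if T <= 2 * min_shift:
        raise ValueError("series too short for the minimum shift")
    Z = Y - Y.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(Z, axis=1)
    Zn = Z / np.where(nrm == 0, 1.0, nrm)[:, None]

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, R, n_permutations)
    shifts = rng.integers(min_shift, T - min_shift + 1, n_permutations)
    max_r = np.empty(n_permutations)
    # group permutations by seed region so each group is one matrix product
    for region in range(R):
        sel = np.flatnonzero(seeds == region)
        if not len(sel):
            continue
        idx = (np.arange(T)[None, :] + shifts[sel][:, None]) % T
        shifted = Zn[region][idx]  # (n_sel, T)
        others = np.delete(np.arange(R), region)
        corr = shifted @ Zn[others].T  # (n_sel, R-1)
        max_r[sel] = corr.max(axis=1) if signed else np.abs(corr).max(axis=1)

    thr = float(np.quantile(max_r, 1.0 - p))
    se = float(np.std(max_r) / np.sqrt(n_permutations))
    null = ConnectivityNull(np.sort(max_r), n_permutations, min_shift, se, shifts=shifts)
    obs = Zn @ Zn.T
    pairs = [
        (i, j, float(obs[i, j]))
        for i in range(R)
        for j in range(i + 1, R)
        if (obs[i, j] if signed else abs(obs[i, j])) > thr
    ]
    return null, pairs


def snapshot_map(
    volumes_at_t: np.ndarray,
    p: float = 0.05,
    two_sided: bool = False,
) -> tuple[np.ndarray, float]:
    """Across-subject mean activity at one time point, normal-theory thresholded.

    ``volumes_at_t`` stacks the standardized per-subject signals at one
    volume (subjects first axis).  Under the null the mean of n standard
    normals has SD 1/sqrt(n), so the one-sided threshold is
    z_(1-p)/sqrt(n); the returned map zeroes subthreshold voxels.
    """
    V = np.asarray(volumes_at_t, dtype=float)
    n = V.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = V.mean(axis=0)
    q = 1.0 - p / 2.0 if two_sided else 1.0 - p
    thr = float(stats.norm.ppf(q) / np.sqrt(n))
    keep = (np.abs(mean) >= thr) if two_sided else (mean >= thr)
    return np.where(keep, mean, 0.0), thr
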