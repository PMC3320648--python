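"""Temporal-concatenation group spatial ICA with stability selection.

The group decomposition follows the GIFT/ICASSO recipe: optional per-subject
PCA, temporal concatenation, group PCA to the target dimensionality, many
ICA runs with random initialisation (and optional bootstrap resampling),
agglomerative clustering of the pooled spatial maps on 1 - |spatial
correlation|, a per-cluster stability index (mean intra-cluster |rho|) with
centrotype representatives, and subject-level back-reconstruction of
component time courses as spatial-map-weighted averages of voxel time
courses.

The per-run unmixing is delegated to a fixed-point maximal-non-Gaussianity
estimator (FastICA); everything around it — reduction, bootstrap, stability
clustering, selection, back-reconstruction — lives here.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .design import BoldDataset

__all__ = [
    "IcaConfig",
    "ComponentSet",
    "Reduction",
    "Decomposition",
    "concat_and_reduce",
    "run_ica_once",
    "icasso_cluster",
    "select_stable",
    "back_reconstruct",
    "run_group_ica",
    "stability_sweep",
]


@dataclass
class IcaConfig:
    """Group-ICA settings.

    ``n_components`` is the reduced dimensionality (the reference study used
    40 at full scale); ``n_runs`` repeated decompositions feed the stability
    clustering; components are retained downstream only when they appear in
    all runs (``require_all_runs``) with mean intra-cluster spatial
    similarity above ``stability_min``.
    """

    n_components: int = 4
    n_runs: int = 100
    bootstrap: bool = True
    subject_pca_dim: int | None = None
    random_seed: int = 0
    stability_min: float = 0.9
    require_all_runs: bool = True
    max_iter: int = 1000
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 < self.stability_min <= 1.0:
            raise ValueError("stability_min must lie in (0, 1]")
        if self.n_components < 1 or self.n_runs < 1:
            raise ValueError("n_components and n_runs must be positive")


@dataclass
class Reduction:
    """Operators of the concatenation + PCA step, kept for back-projection."""

    basis: np.ndarray  # (total_time, n_components) orthonormal
    col_mean: np.ndarray  # per-voxel mean over concatenated time
    singular_values: np.ndarray
    explained_variance_ratio: float
    reduced: np.ndarray  # (n_components, n_voxels)
    subject_slices: list[slice]
    subject_bases: list[np.ndarray] | None


@dataclass
class Decomposition:
    """One ICA run: spatial maps and the reduced-space mixing matrix."""

    maps: np.ndarray  # (n_components, n_voxels)
    mixing: np.ndarray  # (n_reduced, n_components)
    seed: int
    converged: bool
    bootstrap: bool


@dataclass
class ComponentSet:
    """Group components after stability clustering.

    ``spatial_maps`` are z-scored over voxels; ``group_timecourses`` live on
    the concatenated time axis; ``subject_timecourses`` (subjects x
    components x time) are filled by :func:`back_reconstruct`.
    """

    spatial_maps: np.ndarray
    group_timecourses: np.ndarray
    stability_index: np.ndarray
    run_count: np.ndarray
    subject_timecourses: np.ndarray | None = None
    cluster_sizes: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    def subset(self, idx) -> "ComponentSet":
        idx = np.asarray(idx)
        return ComponentSet(
            self.spatial_maps[idx],
            self.group_timecourses[idx],
            self.stability_index[idx],
            self.run_count[idx],
            None if self.subject_timecourses is None else self.subject_timecourses[:, idx],
            None if self.cluster_sizes is None else self.cluster_sizes[idx],
        )


def concat_and_reduce(
    datasets: Sequence[BoldDataset], config: IcaConfig
) -> Reduction:
    """Temporally concatenate subjects and PCA-reduce to ``n_components``.

    Optional per-subject PCA (to ``subject_pca_dim`` temporal dimensions)
    precedes concatenation.  The returned orthonormal basis maps reduced
    rows back to concatenated time points for time-course reconstruction.
    """
    if not datasets:
        raise ValueError("no datasets")
    V = datasets[0].n_voxels
    if any(d.n_voxels != V for d in datasets):
        raise ValueError("datasets differ in voxel count")

    blocks, slices, bases = [], [], []
    row0 = 0
    for d in datasets:
        X = d.data - d.data.mean(axis=0)
        if config.subject_pca_dim is not None:
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            k = config.subject_pca_dim
            if k > len(s):
                raise ValueError("subject_pca_dim exceeds subject rank")
            B = U[:, :k]  # time x k
            X = (s[:k, None] * Vt[:k])  # k x voxels
            bases.append(B)
        blocks.append(X)
        slices.append(slice(row0, row0 + X.shape[0]))
        row0 += X.shape[0]
    X = np.vstack(blocks)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = config.n_components
    rank = int(np.sum(s > s[0] * 1e-10))
    if k > rank:
        raise ValueError(f"n_components={k} exceeds data rank {rank}")
    evr = float(np.sum(s[:k] ** 2) / np.sum(s**2))
    reduced = s[:k, None] * Vt[:k]  # k x voxels
    return Reduction(
        basis=U[:, :k],
        col_mean=X.mean(axis=0),
        singular_values=s[:k],
        explained_variance_ratio=evr,
        reduced=reduced,
        subject_slices=slices,
        subject_bases=bases or None,
    )


def run_ica_once(
    reduced: np.ndarray,
    seed: int,
    bootstrap: bool = False,
    max_iter: int = 1000,
    tol: float = 1e-7,
) -> Decomposition:
    """One spatial-ICA decomposition of the reduced matrix.

    Rows of the returned source matrix are spatial maps; mixing columns are
    the corresponding reduced-space time courses.  With ``bootstrap`` the
    ICA samples (voxels, the observations of spatial ICA) are resampled with
    replacement before estimation and the learned unmixing is applied to the
    full matrix.  Non-convergence is flagged, not raised.
    """
    reduced = np.asarray(reduced, dtype=float)
    if not np.all(np.isfinite(reduced)):
        raise ValueError("reduced matrix contains non-finite values")
    k, V = reduced.shape
    X = reduced.T  # voxels x k: voxels are the i.i.d. samples of spatial ICA
    rng = np.random.default_rng(seed)
    fit_X = X[rng.integers(0, V, V)] if bootstrap else X
    ica = FastICA(
        n_components=k,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**32),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica.fit(fit_X)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica.fit(fit_X)
    maps = ica.transform(X).T  # k x voxels
    return Decomposition(maps, ica.mixing_, seed, converged, bootstrap)


def _signed_map_correlation(pool: np.ndarray) -> np.ndarray:
    sd = pool.std(axis=1)
    Z = (pool - pool.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    return (Z @ Z.T) / pool.shape[1]


def icasso_cluster(
    decompositions: Sequence[Decomposition],
    config: IcaConfig,
    reduction: Reduction,
    refine: bool = True,
) -> ComponentSet:
    """Cluster pooled maps from repeated runs into stable group components.

    Pooled spatial maps are agglomeratively clustered (average linkage) on
    the dissimilarity 1 - |spatial Pearson rho| into ``n_components``
    clusters.  Per cluster the stability index is the mean pairwise
    intra-cluster |rho|, the run count the number of distinct runs
    represented, and the representative map the sign-aligned cluster mean
    around the centrotype (the member with maximal summed similarity).
    With ``refine`` a one-pass reassignment of every map to its nearest
    centrotype follows the agglomerative cut, correcting borderline
    assignments of bootstrap-perturbed estimates.  Components are ordered by
    decreasing stability.
    """
    if len(decompositions) < 2:
        raise ValueError("stability clustering needs at least two decompositions")
    k = config.n_components
    pool = np.vstack([d.maps for d in decompositions])
    run_of = np.repeat(np.arange(len(decompositions)), [d.maps.shape[0] for d in decompositions])
    C = _signed_map_correlation(pool)
    S = np.minimum(np.abs(C), 1.0)
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    labels = fcluster(linkage(squareform(D, checks=False), method="average"),
                      t=k, criterion="maxclust")
    if len(np.unique(labels)) < k:
        raise ValueError("clustering produced an empty cluster; check n_components")
    if refine:
        centros = np.array([
            np.flatnonzero(labels == lab)[
                int(np.argmax(S[np.ix_(labels == lab, labels == lab)].sum(axis=1)))
            ]
            for lab in np.unique(labels)
        ])
        new = np.unique(labels)[np.argmax(S[:, centros], axis=1)]
        if len(np.unique(new)) == k:  # keep the cut if refinement empties a cluster
            labels = new

    maps, tcs, stab, runs, sizes = [], [], [], [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = S[np.ix_(idx, idx)]
        if len(idx) == 1:
            stability = 1.0
        else:
            stability = float((sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1)))
        centro = idx[int(np.argmax(sub.sum(axis=1)))]
        signs = np.sign(C[idx, centro])
        signs[signs == 0] = 1.0
        mean_map = (signs[:, None] * pool[idx]).mean(axis=0)
        mean_map = (mean_map - mean_map.mean()) / mean_map.std()
        # member time course on the concatenated axis = basis @ mixing column
        member_tcs = []
        for j, sgn in zip(idx, signs):
            d = decompositions[run_of[j]]
            col = j - int(np.flatnonzero(run_of == run_of[j])[0])
            member_tcs.append(sgn * (reduction.basis @ d.mixing[:, col]))
        maps.append(mean_map)
        tcs.append(np.mean(member_tcs, axis=0))
        stab.append(stability)
        runs.append(len(np.unique(run_of[idx])))
        sizes.append(len(idx))

    order = np.argsort(stab)[::-1]
    return ComponentSet(
        spatial_maps=np.array(maps)[order],
        group_timecourses=np.array(tcs)[order],
        stability_index=np.array(stab)[order],
        run_count=np.array(runs)[order],
        cluster_sizes=np.array(sizes)[order],
    )


def select_stable(components: ComponentSet, config: IcaConfig) -> ComponentSet:
    """Keep components found in every run with stability above the floor."""
    keep = components.stability_index > config.stability_min
    if config.require_all_runs:
        keep &= components.run_count == config.n_runs
    return components.subset(np.flatnonzero(keep))


def back_reconstruct(
    components: ComponentSet,
    datasets: Sequence[BoldDataset],
    reduction: Reduction | None = None,
) -> ComponentSet:
    """Subject-level component time courses from group spatial maps.

    Each subject's data matrix is projected onto the pseudo-inverse of the
    spatial-map matrix — for orthonormal maps this is exactly the
    spatial-map-weighted average of the voxel time courses.
    """
    M = components.spatial_maps
    if np.linalg.matrix_rank(M) < M.shape[0]:
        warnings.warn("rank-deficient spatial map matrix; least-squares projection used",
                      stacklevel=2)
    P = np.linalg.pinv(M)  # voxels x k
    out = np.stack([( (d.data - d.data.mean(axis=0)) @ P ).T for d in datasets])
    return dataclasses.replace(components, subject_timecourses=out)


def run_group_ica(
    datasets: Sequence[BoldDataset],
    config: IcaConfig | None = None,
    select: bool = False,
) -> tuple[ComponentSet, Reduction]:
    """Full group decomposition: reduce, repeat ICA, cluster, back-reconstruct."""
    config = config or IcaConfig()
    reduction = concat_and_reduce(datasets, config)
    seeds = np.random.SeedSequence(config.random_seed).generate_state(config.n_runs)
    decomps = [
        run_ica_once(reduction.reduced, int(s) % (2**31), config.bootstrap,
                     config.max_iter, config.tol)
        for s in seeds
    ]
    components = icasso_cluster(decomps, config, reduction)
    if select:
        components = select_stable(components, config)
    components = back_reconstruct(components, datasets, reduction)
    return components, reduction


def stability_sweep(
    datasets: Sequence[BoldDataset],
    dimensionalities: Sequence[int],
    config: IcaConfig | None = None,
) -> dict[int, np.ndarray]:
    """Exploratory stability-vs-dimensionality sweep.

    Reruns the bootstrap/clustering at each candidate dimensionality and
    returns the per-component stability indices, supporting a post-hoc
    choice of model order.
    """
    config = config or IcaConfig()
    out = {}
    for k in dimensionalities:
        cfg = dataclasses.replace(config, n_components=int(k))
        red = concat_and_reduce(datasets, cfg)
        seeds = np.random.SeedSequence(cfg.random_seed).generate_state(cfg.n_runs)
        decomps = [
            run_ica_once(red.reduced, int(s) % (2**31), cfg.bootstrap, cfg.max_iter, cfg.tol)
            for s in seeds
        ]
        out[int(k)] = icasso_cluster(decomps, cfg, red).stability_index
    return out
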