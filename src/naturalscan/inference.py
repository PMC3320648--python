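"""Annotation-GLM fitting, ISC screening and circular-shift permutation tests.

Stimulus models (collections of HRF-convolved annotation regressors) are fit
to component or voxel time courses by ordinary least squares; the quality of
fit is summarised by the Pearson correlation r between the fitted sum of
annotations and the observed series.  Significance thresholds for r come
from a circular-shift permutation scheme that rotates the fMRI series
through every distinct shift, preserving autocorrelation while destroying
stimulus alignment; the pooled null is tabulated into 100 bins with linear
interpolation between bin centres.  Inter-subject correlation (mean pairwise
Pearson r, averaged in Fisher-z space) screens components for consistent
timing across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .group_ica import ComponentSet, IcaConfig, select_stable
from .stimulus_features import AnnotationSet

__all__ = [
    "ModelFit",
    "IscResult",
    "PermutationNull",
    "fit_annotation_model",
    "single_feature_fits",
    "weight_tests",
    "isc_mean",
    "circular_null",
    "single_annotation_null",
    "modality_threshold",
    "annotation_correlation_matrix",
    "select_components",
]


@dataclass
class ModelFit:
    """OLS fit of one stimulus model to one observed time course.

    ``normalized_weights`` are the betas divided by the largest |beta| so
    the main explanatory variable receives weight +/-1; the intercept is
    fitted but not reported among the weights.
    """

    feature_names: list[str]
    betas: np.ndarray
    intercept: float
    normalized_weights: np.ndarray
    fitted: np.ndarray
    r: float
    r_squared: float


@dataclass
class IscResult:
    """Inter-subject correlation of one component's time courses."""

    pairwise_r: np.ndarray
    mean_r: float
    dispersion: float  # variance of pairwise r
    dispersion_sd: float  # SD of pairwise r
    p_value: float


@dataclass
class PermutationNull:
    """Empirical null of model-fit correlations from circular shifts.

    The distribution is tabulated into ``n_bins`` equal-width bins; bin
    probabilities are observed frequencies assigned to bin centres and
    ``threshold_at(p)`` linearly interpolates the upper-tail probability
    curve between centres.
    """

    model_id: str
    r_samples: np.ndarray  # sorted
    bin_centers: np.ndarray
    bin_probabilities: np.ndarray
    n_series: int
    n_shifts: int

    @property
    def n_realizations(self) -> int:
        return len(self.r_samples)

    def threshold_at(self, p: float) -> float:
        """Correlation value whose upper-tail probability is ``p``."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        # tail[i] = probability mass at or above bin i
        tail = self.bin_probabilities[::-1].cumsum()[::-1]
        lo, hi = tail[-1], tail[0]
        if p <= lo:
            return float(self.bin_centers[-1])
        if p >= hi:
            return float(self.bin_centers[0])
        return float(np.interp(p, tail[::-1], self.bin_centers[::-1]))


def _as_matrix(X: DesignMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        return X.matrix, X.feature_names
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(M: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # name columns involved in the linear dependence via QR pivots
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"design matrix is rank deficient; dependent column(s): {bad}")


def fit_annotation_model(X: DesignMatrix | np.ndarray, y: np.ndarray) -> ModelFit:
    """Fit a stimulus model to an observed series by OLS with intercept.

    Returns betas, the fitted sum of annotations, the Pearson correlation r
    of fitted vs observed, R^2 = r^2, and weights normalised so that the
    feature with the largest |beta| receives weight 1 (sign preserved).
    """
    M, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) != M.shape[0]:
        raise ValueError("length of y must equal design matrix rows")
    _check_rank(M, names)
    A = np.column_stack([np.ones(len(y)), M])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    intercept, betas = coef[0], coef[1:]
    fitted = A @ coef
    if fitted.std() == 0 or y.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    scale = np.max(np.abs(betas))
    normalized = betas / scale if scale > 0 else betas.copy()
    return ModelFit(names, betas, float(intercept), normalized, fitted, r, r * r)


def single_feature_fits(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-subject slope of a single regressor (plus intercept) fit.

    ``Y`` is (subjects, time); returns one beta per subject.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != len(x):
        raise ValueError("regressor and series lengths differ")
    xc = x - x.mean()
    denom = xc @ xc
    if denom == 0:
        raise ValueError("constant regressor")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    return Yc @ xc / denom


def weight_tests(
    betas_c1: np.ndarray,
    betas_c2: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-sample and paired t-tests on per-subject single-feature betas.

    ``betas_c1``/``betas_c2`` are (subjects, features) for the two
    components under comparison.  Per feature: two-sided one-sample t vs 0
    within each component, and a paired t between the components.  Zero
    variance of the pairwise differences leaves the paired p undefined
    (NaN, flagged).
    """
    b1 = np.atleast_2d(np.asarray(betas_c1, dtype=float))
    b2 = np.atleast_2d(np.asarray(betas_c2, dtype=float))
    if b1.shape != b2.shape:
        raise ValueError("beta matrices must have identical shape")
    if b1.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(b1.shape[1])
    ]

    def _onesample(b):
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_1samp(b, 0.0, axis=0)
        # all-zero values: no effect and no variance -> t = 0, p = 1;
        # constant nonzero values leave p undefined (flagged via NaN)
        zero_var = b.std(axis=0) == 0
        exact_zero = zero_var & (b.mean(axis=0) == 0)
        t = np.where(exact_zero, 0.0, np.where(zero_var, np.nan, t))
        p = np.where(exact_zero, 1.0, np.where(zero_var, np.nan, p))
        return t, p

    t1, p1 = _onesample(b1)
    t2, p2 = _onesample(b2)
    tp, pp = _onesample(b1 - b2)
    degenerate = ~np.isfinite(pp)
    return pd.DataFrame(
        dict(feature=names, t_c1=t1, p_c1=p1, t_c2=t2, p_c2=p2,
             t_paired=tp, p_paired=pp, degenerate=degenerate)
    )


# ---------------------------------------------------------------------------
# inter-subject correlation
# ---------------------------------------------------------------------------

_CLIP = 1.0 - 1e-12


def _fisher_mean(r: np.ndarray) -> float:
    return float(np.tanh(np.mean(np.arctanh(np.clip(r, -_CLIP, _CLIP)))))


def isc_mean(
    subject_timecourses: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> IscResult:
    """Mean pairwise inter-subject correlation with a circular-shift p-value.

    All subject pairs are correlated, coefficients are clipped away from
    +/-1, averaged in Fisher-z space and back-transformed.  The p-value
    compares the observed Fisher-z mean with a null in which one member of
    each pair is circularly shifted by a random nonzero rotation.
    """
    Y = np.atleast_2d(np.asarray(subject_timecourses, dtype=float))
    S, T = Y.shape
    if S < 2:
        raise ValueError("ISC needs at least 2 subjects")
    pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    Z = (Y - Y.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(Z, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    Zn = Z / norms[:, None]
    obs_r = np.array([Zn[i] @ Zn[j] for i, j in pairs])
    obs_r = np.clip(obs_r, -_CLIP, _CLIP)
    obs_stat = np.mean(np.arctanh(obs_r))

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        zs = 0.0
        for i, j in pairs:
            s = int(rng.integers(1, T))
            r = Zn[i] @ np.roll(Zn[j], s)
            zs += np.arctanh(np.clip(r, -_CLIP, _CLIP))
        null[b] = zs / len(pairs)
    p = float((1 + np.sum(null >= obs_stat)) / (n_permutations + 1))
    return IscResult(
        pairwise_r=obs_r,
        mean_r=_fisher_mean(obs_r),
        dispersion=float(np.var(obs_r)),
        dispersion_sd=float(np.std(obs_r)),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# circular-shift permutation nulls
# ---------------------------------------------------------------------------


def _binned_null(
    samples: np.ndarray, model_id: str, n_series: int, n_shifts: int, n_bins: int = 100
) -> PermutationNull:
    samples = np.sort(samples)
    lo, hi = samples[0], samples[-1]
    if hi == lo:
        hi = lo + 1e-12
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    probs = counts / counts.sum()
    return PermutationNull(model_id, samples, centers, probs, n_series, n_shifts)


def circular_null(
    X: DesignMatrix | np.ndarray,
    Y: np.ndarray,
    step: int = 1,
    n_bins: int = 100,
    model_id: str | None = None,
) -> PermutationNull:
    """Null distribution of model-fit r over all circular shifts.

    Every series in ``Y`` is rotated through every ``step``-th shift
    (identity included) and the GLM is refit at each rotation; the model-fit
    correlation r of each refit enters the null, giving
    ``ceil(T / step) * n_series`` realizations.
    """
    import warnings as _warnings

    M, names = _as_matrix(X)
    if isinstance(X, DesignMatrix) and model_id is None:
        model_id = X.model_id
    _check_rank(M, names)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    T = Y.shape[1]
    if T != M.shape[0]:
        raise ValueError("series length must equal design matrix rows")
    if T < 50:
        _warnings.warn("series shorter than 50 samples: permutation threshold unstable",
                       stacklevel=2)
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    shifts = np.arange(0, T, step)
    idx = (np.arange(T)[None, :] + shifts[:, None]) % T  # (n_shifts, T)
    out = np.empty((Y.shape[0], len(shifts)))
    for i, y in enumerate(Y):
        yc = y - y.mean()
        nrm = np.linalg.norm(yc)
        if nrm == 0:
            out[i] = 0.0
            continue
        C = yc[idx] @ Q
        out[i] = np.sqrt((C**2).sum(axis=1)) / nrm
    return _binned_null(out.ravel(), model_id or "custom", Y.shape[0], len(shifts), n_bins)


def single_annotation_null(
    x: np.ndarray,
    Y: np.ndarray,
    step: int = 2,
    n_bins: int = 100,
    model_id: str = "single",
) -> PermutationNull:
    """Circular-shift null of the plain Pearson correlation with one regressor.

    No GLM fitting: the signed correlation of the regressor with each
    rotation of each series is recorded.  Shifts advance in two-sample
    increments by default, sampling half of the distribution.
    """
    x = np.asarray(getattr(x, "values", x), dtype=float).ravel()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    T = Y.shape[1]
    if T != len(x):
        raise ValueError("series length must equal regressor length")
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    if xn == 0:
        raise ValueError("constant regressor")
    shifts = np.arange(0, T, step)
    idx = (np.arange(T)[None, :] + shifts[:, None]) % T
    out = np.empty((Y.shape[0], len(shifts)))
    for i, y in enumerate(Y):
        yc = y - y.mean()
        nrm = np.linalg.norm(yc)
        out[i] = (yc[idx] @ xc) / (nrm * xn) if nrm > 0 else 0.0
    return _binned_null(out.ravel(), model_id, Y.shape[0], len(shifts), n_bins)


def modality_threshold(nulls: Sequence[PermutationNull], p: float) -> float:
    """Single visualization threshold: mean of the individual annotation thresholds."""
    return float(np.mean([n.threshold_at(p) for n in nulls]))


def annotation_correlation_matrix(
    tracks: AnnotationSet | np.ndarray,
    n_hist_bins: int = 20,
) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Pairwise Pearson correlations of the annotation tracks.

    Returns the symmetric unit-diagonal matrix as a DataFrame (NaN rows/
    columns for constant tracks) and a histogram (counts, edges) of the
    off-diagonal values.
    """
    if isinstance(tracks, AnnotationSet):
        names = tracks.names
        data = np.stack([tracks[n].values for n in names])
    else:
        data = np.atleast_2d(np.asarray(tracks, dtype=float))
        names = [f"t{i}" for i in range(data.shape[0])]
    sd = data.std(axis=1)
    constant = sd == 0
    Z = (data - data.mean(axis=1, keepdims=True)) / np.where(constant, 1.0, sd)[:, None]
    R = (Z @ Z.T) / data.shape[1]
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    np.fill_diagonal(R, 1.0)
    off = R[np.triu_indices_from(R, k=1)]
    off = off[np.isfinite(off)]
    hist = np.histogram(off, bins=n_hist_bins, range=(-1, 1))
    return pd.DataFrame(R, index=names, columns=names), hist


def select_components(
    components: ComponentSet,
    isc_results: Sequence[IscResult],
    model_fits: dict[str, Sequence[ModelFit]],
    nulls: dict[str, PermutationNull],
    config: IcaConfig,
    alpha: float = 0.001,
) -> np.ndarray:
    """Indices of components passing all three selection criteria.

    A component is kept when (a) its inter-subject correlation is
    significant at ``alpha``, (b) its time course correlates with at least
    one stimulus model above that model's own permutation threshold at
    ``alpha``, and (c) it meets the stability criteria (found in all runs,
    stability index above the floor).
    """
    n = components.n_components
    if len(isc_results) != n or any(len(v) != n for v in model_fits.values()):
        raise ValueError("per-component inputs must cover every component")
    stable_idx = set()
    keep_stab = components.stability_index > config.stability_min
    if config.require_all_runs:
        keep_stab &= components.run_count == config.n_runs
    stable_idx = set(np.flatnonzero(keep_stab))

    kept = []
    for c in range(n):
        if c not in stable_idx:
            continue
        if isc_results[c].p_value >= alpha:
            continue
        hit = any(
            model_fits[m][c].r > nulls[m].threshold_at(alpha) for m in model_fits
        )
        if hit:
            kept.append(c)
    return np.array(kept, dtype=int)
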