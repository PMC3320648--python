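"""HRF regressor construction and temporal preprocessing.

Annotation tracks sampled at 1 Hz are convolved with a canonical double-gamma
hemodynamic response function, truncated to stimulus length and resampled to
the scanner TR grid to form GLM design matrices.  The module also provides
the Gaussian-weighted running-line high-pass filter applied to BOLD series
and the standardize-then-average combination used for group-level voxel-wise
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus_features import AnnotationSet, AnnotationTrack

__all__ = [
    "HrfSpec",
    "DesignMatrix",
    "BoldDataset",
    "hrf_kernel",
    "make_regressor",
    "make_design_matrix",
    "highpass_detrend",
    "standardize_and_average",
]


@dataclass
class HrfSpec:
    """Canonical double-gamma HRF parameters (all in seconds).

    The kernel is the difference of two gamma densities, the positive lobe
    peaking at ``peak_delay`` and the undershoot at ``undershoot_delay``,
    scaled by ``undershoot_ratio``.  Gamma shapes are chosen so that the
    *mode* of each lobe sits exactly at its delay, honouring the canonical
    six-second peak lag.  The kernel is normalised to unit peak amplitude.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "kernel_length",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")
        if self.dt > self.kernel_length:
            raise ValueError("dt must not exceed kernel_length")


def hrf_kernel(spec: HrfSpec | None = None) -> np.ndarray:
    """Sample the double-gamma HRF on ``t = 0, dt, ..., kernel_length``."""
    spec = spec or HrfSpec()
    t = np.arange(0.0, spec.kernel_length + 0.5 * spec.dt, spec.dt)
    # shape = delay/dispersion + 1 puts the gamma mode at the delay
    peak = stats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion + 1.0, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion + 1.0,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.undershoot_ratio * under
    return h / np.max(h)


def make_regressor(
    track: AnnotationTrack | np.ndarray,
    spec: HrfSpec | None = None,
    tr: float = 2.0,
    n_timepoints: int | None = None,
    resample: Literal["decimate", "linear"] = "decimate",
) -> np.ndarray:
    """HRF-convolve a 1-Hz track and resample it to the TR grid.

    Causal convolution at 1 Hz is truncated to the stimulus length, then
    sampled at t = 0, TR, 2 TR, ...; ``decimate`` picks the nearest 1-Hz
    sample at each grid point (exact for integer TR), ``linear``
    interpolates.
    """
    spec = spec or HrfSpec()
    values = np.asarray(getattr(track, "values", track), dtype=float)
    kernel = hrf_kernel(spec)
    conv = np.convolve(values, kernel)[: len(values)]
    if n_timepoints is None:
        n_timepoints = int(len(values) // tr)
    times = np.arange(n_timepoints) * tr
    if times[-1] > len(values) - 1:
        raise ValueError(
            f"track of {len(values)} s too short for {n_timepoints} volumes at TR={tr}"
        )
    if resample == "decimate":
        idx = np.round(times).astype(int)
        return conv[idx]
    return np.interp(times, np.arange(len(values)), conv)


@dataclass
class DesignMatrix:
    """TR-sampled regressor collection for one stimulus model."""

    model_id: str
    feature_names: list[str]
    matrix: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix must be time x features")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite entries")
        if np.any(np.ptp(self.matrix, axis=0) == 0):
            bad = [n for n, c in zip(self.feature_names, self.matrix.T) if np.ptp(c) == 0]
            raise ValueError(f"constant/all-zero regressor column(s): {bad}")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.feature_names)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, model_id: str = "custom", tr: float = 2.0) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(model_id, list(df.columns), df.to_numpy(float), tr)


def make_design_matrix(
    annotations: AnnotationSet,
    model_id: str,
    tr: float,
    n_timepoints: int,
    spec: HrfSpec | None = None,
    names: Sequence[str] | None = None,
    resample: Literal["decimate", "linear"] = "decimate",
) -> DesignMatrix:
    """Build a model's design matrix from a set of annotation tracks."""
    names = list(names) if names is not None else annotations.names
    cols = [
        make_regressor(annotations[n], spec, tr, n_timepoints, resample) for n in names
    ]
    return DesignMatrix(model_id, names, np.column_stack(cols), tr)


def highpass_detrend(series: np.ndarray, sigma: float = 100.0, tr: float = 2.0) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter.

    At every time point a straight line is fitted to the whole series by
    least squares with Gaussian weights (SD ``sigma`` seconds) centred there,
    and the fitted value is subtracted; the global mean is restored.  Accepts
    a 1-D series or a (time, voxels) matrix.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    T = y.shape[0]
    if T < 5:
        raise ValueError("series too short to detrend")
    t = np.arange(T) * tr
    W = np.exp(-0.5 * ((t[None, :] - t[:, None]) / sigma) ** 2)  # (center, sample)
    s0 = W.sum(axis=1)
    s1 = W @ t
    s2 = W @ t**2
    sy = W @ y
    sty = W @ (t[:, None] * y)
    denom = s0 * s2 - s1**2
    slope = (s0[:, None] * sty - s1[:, None] * sy) / denom[:, None]
    intercept = (sy - slope * s1[:, None]) / s0[:, None]
    fitted = intercept + slope * t[:, None]
    out = y - fitted + y.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


@dataclass
class BoldDataset:
    """One subject's masked BOLD data as a (time, voxels) matrix.

    Voxel columns follow the mask's linear order with the x index varying
    fastest, so data round-trip losslessly through 4-D volumes.
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""
    flagged_voxels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be (time, voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("column count does not match mask voxel count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_volume(self) -> np.ndarray:
        """Unmask into a 4-D (x, y, z, t) array, zeros outside the mask."""
        flat = np.zeros((int(np.prod(self.mask.shape)), self.n_timepoints))
        flat[self.mask.ravel(order="F")] = self.data.T
        return flat.reshape(self.mask.shape + (self.n_timepoints,), order="F")

    def unmask_map(self, values: np.ndarray) -> np.ndarray:
        """Scatter one value per voxel back into a 3-D volume."""
        flat = np.zeros(int(np.prod(self.mask.shape)))
        flat[self.mask.ravel(order="F")] = values
        return flat.reshape(self.mask.shape, order="F")


def standardize_and_average(datasets: Sequence[BoldDataset]) -> BoldDataset:
    """Z-score every voxel time course per subject, then average across subjects.

    Voxels with zero temporal variance in any subject are set to 0 there and
    recorded in ``flagged_voxels`` of the result.
    """
    if not datasets:
        raise ValueError("no datasets given")
    ref = datasets[0]
    for d in datasets[1:]:
        if d.data.shape != ref.data.shape or not np.array_equal(d.mask, ref.mask):
            raise ValueError("datasets must share time length and mask")
    acc = np.zeros_like(ref.data)
    flagged = np.zeros(ref.n_voxels, dtype=bool)
    for d in datasets:
        mu = d.data.mean(axis=0)
        sd = d.data.std(axis=0)
        zero = sd == 0
        flagged |= zero
        sd = np.where(zero, 1.0, sd)
        z = (d.data - mu) / sd
        z[:, zero] = 0.0
        acc += z
    acc /= len(datasets)
    return BoldDataset(
        acc, ref.mask, ref.tr, ref.affine, subject_id="group-mean", flagged_voxels=flagged
    )
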