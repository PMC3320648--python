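"""Stimulus annotation tracks for naturalistic audiovisual experiments.

Audio descriptors (zero-crossing rate, RMS energy, spectral spread, spectral
entropy) are computed in non-overlapping 1-s windows; visual complexity is
quantified as the mean absolute intensity of DCT high-pass filtered frames;
object motion is scored on an ordinal 0-4 scale combining on-screen size and
speed, either from manual sub-scores or from object-tracking tables.

All extractors emit :class:`AnnotationTrack` objects sampled at 1 Hz, the
common currency consumed by the design-matrix builder.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.fft import dctn, idctn, rfft, rfftfreq

__all__ = [
    "AnnotationTrack",
    "AnnotationSet",
    "EdgeFilterSpec",
    "MotionScoringSpec",
    "ObjectTrack",
    "MOTION_CATEGORIES",
    "extract_audio_features",
    "substitute_silence",
    "edge_density",
    "score_motion_manual",
    "score_motion_tracks",
    "compare_annotation_pair",
]

#: object categories recognised by the track scorer
MOTION_CATEGORIES = ("body", "head", "hand", "mechanical")


@dataclass
class AnnotationTrack:
    """One named stimulus feature sampled at 1 Hz.

    ``kind`` determines the value constraints: ``boxcar`` tracks are binary
    presence indicators, ``ordinal`` tracks take integer scores 0-4 (motion
    strength), and ``continuous`` tracks are unconstrained non-negative
    descriptors.
    """

    name: str
    modality: Literal["auditory", "visual"]
    kind: Literal["boxcar", "continuous", "ordinal"]
    values: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.kind == "boxcar":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError(f"boxcar track {self.name!r} has values outside {{0,1}}")
        elif self.kind == "ordinal":
            if not np.all(np.isin(self.values, np.arange(5.0))):
                raise ValueError(f"ordinal track {self.name!r} has values outside 0..4")

    def __len__(self) -> int:
        return len(self.values)


class AnnotationSet:
    """Ordered collection of equal-length annotation tracks."""

    def __init__(self, tracks: Sequence[AnnotationTrack]):
        lengths = {len(t) for t in tracks}
        if len(lengths) > 1:
            raise ValueError(f"tracks have unequal lengths: {sorted(lengths)}")
        self._tracks = {t.name: t for t in tracks}
        if len(self._tracks) != len(tracks):
            raise ValueError("duplicate track names")

    def __getitem__(self, name: str) -> AnnotationTrack:
        return self._tracks[name]

    def __iter__(self):
        return iter(self._tracks.values())

    def __len__(self) -> int:
        return len(self._tracks)

    def __contains__(self, name: str) -> bool:
        return name in self._tracks

    @property
    def names(self) -> list[str]:
        return list(self._tracks)

    def subset(self, names: Sequence[str]) -> "AnnotationSet":
        return AnnotationSet([self._tracks[n] for n in names])

    def by_modality(self, modality: str) -> "AnnotationSet":
        return AnnotationSet([t for t in self if t.modality == modality])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``time_s``, ``name``, ``value``."""
        rows = []
        for t in self:
            rows.append(
                pd.DataFrame(
                    {"time_s": np.arange(len(t)) / t.rate, "name": t.name, "value": t.values}
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class EdgeFilterSpec:
    """High-pass filter used to quantify sharp contrast edges.

    ``cutoff`` is a spatial frequency in rad/pixel; DCT coefficients below it
    are zeroed.  The default 2*pi/16 retains only fine image structure.
    ``mask_geometry`` selects a radial (isotropic) threshold on
    sqrt(wx^2 + wy^2) or a separable per-axis threshold.
    """

    cutoff: float = 2.0 * np.pi / 16.0
    mask_geometry: Literal["radial", "separable"] = "radial"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < np.pi:
            raise ValueError("cutoff must lie in (0, pi) rad/pixel")


@dataclass
class MotionScoringSpec:
    """Thresholds mapping object size and speed to ordinal sub-scores.

    ``area_breaks`` are fractions of the frame area: below the first break
    scores 0, between the breaks (inclusive) 1, above the second 2.
    ``speed_breaks`` are in pixels/second with the same convention.
    ``zero_when_static`` forces the combined score to 0 whenever the speed
    sub-score is 0, mirroring the manual rule that a motionless object scores
    0 regardless of its size.
    """

    area_breaks: tuple[float, float] = (1.0 / 10.0, 1.0 / 6.0)
    speed_breaks: tuple[float, float] = (15.0, 50.0)
    window: float = 1.0
    zero_when_static: bool = True

    def __post_init__(self) -> None:
        if not (self.area_breaks[0] < self.area_breaks[1]):
            raise ValueError("area_breaks must be strictly increasing")
        if not (self.speed_breaks[0] < self.speed_breaks[1]):
            raise ValueError("speed_breaks must be strictly increasing")


@dataclass
class ObjectTrack:
    """Per-frame bounding boxes of one tracked object.

    ``boxes`` holds (x0, y0, x1, y1) pixel corners per frame (exclusive upper
    corner), ``frames`` the frame indices (consecutive within a shot).
    Centroids are derived from the boxes unless given explicitly.
    """

    object_id: str
    category: str
    fps: float
    frames: np.ndarray
    boxes: np.ndarray
    centroids: np.ndarray | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.boxes.shape != (len(self.frames), 4):
            raise ValueError("boxes must be (n_frames, 4)")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be consecutive")
        if self.centroids is None:
            self.centroids = 0.5 * (self.boxes[:, :2] + self.boxes[:, 2:])
        else:
            self.centroids = np.asarray(self.centroids, dtype=float)

    @property
    def areas(self) -> np.ndarray:
        """Box area per frame in px^2."""
        w = self.boxes[:, 2] - self.boxes[:, 0]
        h = self.boxes[:, 3] - self.boxes[:, 1]
        return w * h

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "object_id": self.object_id,
                "category": self.category,
                "x0": self.boxes[:, 0],
                "y0": self.boxes[:, 1],
                "x1": self.boxes[:, 2],
                "y1": self.boxes[:, 3],
            }
        )


# ---------------------------------------------------------------------------
# audio features
# ---------------------------------------------------------------------------


def _window_view(x: np.ndarray, n: int) -> np.ndarray:
    """Reshape signal into floor(len/n) non-overlapping windows of n samples."""
    k = len(x) // n
    return x[: k * n].reshape(k, n)


def _zcr_window(w: np.ndarray) -> float:
    # samples lying exactly on zero sit on the crossing; drop them so a
    # +,0,- transition counts once
    s = np.sign(w)
    s = s[s != 0]
    if len(s) < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(s)))


def _spectral_moments(w: np.ndarray, sample_rate: float, taper: str) -> tuple[float, float]:
    """(spread_hz, normalized_entropy) of the magnitude spectrum of one window."""
    if taper == "hann":
        w = w * np.hanning(len(w))
    mag = np.abs(rfft(w))
    freqs = rfftfreq(len(w), d=1.0 / sample_rate)
    total = mag.sum()
    if total <= 0.0:
        return np.nan, np.nan
    p = mag / total
    mu = float(p @ freqs)
    spread = float(np.sqrt(p @ (freqs - mu) ** 2))
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
    return spread, entropy


def extract_audio_features(
    waveform: np.ndarray,
    sample_rate: float,
    taper: Literal["none", "hann"] = "none",
    silence_substitution: bool = True,
) -> AnnotationSet:
    """Compute the four acoustic annotation tracks from a mono waveform.

    Per non-overlapping 1-s window: ``zcr`` counts sign changes per second,
    ``rms`` is the root-mean-square amplitude, ``spectral_spread`` the
    standard deviation (Hz) of the magnitude-spectrum distribution and
    ``entropy`` the Shannon entropy of the normalised magnitude spectrum
    divided by log(bin count), so a flat spectrum maps to 1.  Entropy is
    undefined in silent windows; those entries are filled per
    :func:`substitute_silence` when ``silence_substitution`` is on.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("stereo/multichannel input: downmix to mono first")
    n = int(round(sample_rate))
    if len(waveform) < n:
        raise ValueError("waveform shorter than one 1-s analysis window")
    wins = _window_view(waveform, n)

    zcr = np.array([_zcr_window(w) for w in wins])
    rms = np.sqrt(np.mean(wins**2, axis=1))
    spread = np.empty(len(wins))
    entropy = np.empty(len(wins))
    for i, w in enumerate(wins):
        spread[i], entropy[i] = _spectral_moments(w, sample_rate, taper)
    spread = np.nan_to_num(spread, nan=0.0)

    mk = lambda name, v: AnnotationTrack(name, "auditory", "continuous", v)
    entropy_track = mk("entropy", entropy)
    rms_track = mk("rms", rms)
    if silence_substitution and np.any(~np.isfinite(entropy)):
        entropy_track = substitute_silence(entropy_track, rms_track)
    return AnnotationSet(
        [mk("zcr", zcr), mk("spectral_spread", spread), entropy_track, rms_track]
    )


def substitute_silence(
    entropy_track: AnnotationTrack,
    rms_track: AnnotationTrack,
    floor: float = 1e-6,
) -> AnnotationTrack:
    """Fill entropy values of silent windows.

    Windows whose RMS falls below ``floor`` times the track maximum receive
    the entropy of the quietest *non-silent* window (ties broken by the
    earlier window), the value the spectrum converges to as the signal fades.
    """
    ent = np.asarray(entropy_track.values, dtype=float)
    rms = np.asarray(rms_track.values, dtype=float)
    if len(ent) != len(rms):
        raise ValueError("entropy and rms tracks are not aligned")
    silent = (rms < floor * rms.max()) | ~np.isfinite(ent)
    if silent.all():
        raise ValueError("all windows are silent; entropy undefined everywhere")
    if not silent.any():
        return entropy_track
    candidates = np.where(~silent, rms, np.inf)
    donor = int(np.argmin(candidates))  # argmin returns the earliest tie
    out = ent.copy()
    out[silent] = ent[donor]
    return dataclasses.replace(entropy_track, values=out)


# ---------------------------------------------------------------------------
# visual features
# ---------------------------------------------------------------------------


def _dct_highpass_mask(shape: tuple[int, int], spec: EdgeFilterSpec) -> np.ndarray:
    h, w = shape
    wy = np.pi * np.arange(h) / h
    wx = np.pi * np.arange(w) / w
    if spec.mask_geometry == "radial":
        rad = np.sqrt(wy[:, None] ** 2 + wx[None, :] ** 2)
        return rad >= spec.cutoff
    # separable: keep a coefficient if either axis frequency reaches cutoff
    return (wy[:, None] >= spec.cutoff) | (wx[None, :] >= spec.cutoff)


def edge_density(
    frames: np.ndarray,
    spec: EdgeFilterSpec | None = None,
    fps: float = 25.0,
) -> AnnotationTrack:
    """Mean absolute intensity of DCT high-pass filtered frames, per second.

    Each frame (intensities in [0, 1]) is 2-D DCT transformed, coefficients
    below the cutoff spatial frequency are zeroed (the DC term always is, so
    the measure is invariant to global brightness shifts), the inverse DCT is
    rectified and averaged over pixels; frame values are then averaged within
    1-s windows.
    """
    spec = spec or EdgeFilterSpec()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n_frames, height, width) stack")
    mask = _dct_highpass_mask(frames.shape[1:], spec)
    per_frame = np.empty(len(frames))
    for i, fr in enumerate(frames):
        coef = dctn(fr, norm="ortho")
        coef[~mask] = 0.0
        per_frame[i] = np.mean(np.abs(idctn(coef, norm="ortho")))
    n = int(round(fps))
    win = _window_view(per_frame, n).mean(axis=1)
    return AnnotationTrack("edges", "visual", "continuous", win)


# ---------------------------------------------------------------------------
# motion scoring
# ---------------------------------------------------------------------------


def score_motion_manual(size_score: int, strength_score: int) -> int:
    """Combine manual shot-size (0-2) and motion-strength (0-2) sub-scores.

    A motionless object scores 0 regardless of its on-screen size; otherwise
    the overall score is the sum of the two sub-scores.
    """
    if size_score not in (0, 1, 2) or strength_score not in (0, 1, 2):
        raise ValueError("sub-scores must be integers in 0..2")
    if strength_score == 0:
        return 0
    return size_score + strength_score


def _break_score(value: float, breaks: tuple[float, float]) -> int:
    lo, hi = breaks
    if value < lo:
        return 0
    if value <= hi:
        return 1
    return 2


def score_motion_tracks(
    tracks: Sequence[ObjectTrack],
    frame_area: float,
    spec: MotionScoringSpec | None = None,
    n_windows: int | None = None,
) -> AnnotationSet:
    """Ordinal 0-4 motion tracks per object category from tracking tables.

    Per object and 1-s window, the on-screen size measure is the maximum box
    area fraction over the window's frames and the speed measure is the sum
    of instantaneous centroid displacements (pixels traversed in the window).
    Both are thresholded to 0-2 sub-scores; per category the maxima of the
    two sub-scores over objects are summed.  When ``zero_when_static`` is set
    the category score is forced to 0 if no object moved, matching the
    manual convention.
    """
    spec = spec or MotionScoringSpec()
    for tr in tracks:
        if tr.category not in MOTION_CATEGORIES:
            raise ValueError(f"unknown object category {tr.category!r}")
    if n_windows is None:
        if not tracks:
            raise ValueError("n_windows required when no tracks given")
        n_windows = max(int(tr.frames[-1] // tr.fps) + 1 for tr in tracks)

    area_scores = {c: np.zeros(n_windows, dtype=int) for c in MOTION_CATEGORIES}
    speed_scores = {c: np.zeros(n_windows, dtype=int) for c in MOTION_CATEGORIES}
    for tr in tracks:
        n_per = int(round(tr.fps * spec.window))
        areas = tr.areas
        disp = np.linalg.norm(np.diff(tr.centroids, axis=0), axis=1)
        for w in range(n_windows):
            lo, hi = w * n_per, (w + 1) * n_per
            sel = (tr.frames >= lo) & (tr.frames < hi)
            if not sel.any():
                continue
            a_frac = float(areas[sel].max()) / frame_area
            # displacement between consecutive frame pairs inside the window
            idx = np.flatnonzero(sel[:-1] & sel[1:])
            speed = float(disp[idx].sum()) / spec.window if len(idx) else 0.0
            a_sc = _break_score(a_frac, spec.area_breaks)
            s_sc = _break_score(speed, spec.speed_breaks)
            cat = tr.category
            area_scores[cat][w] = max(area_scores[cat][w], a_sc)
            speed_scores[cat][w] = max(speed_scores[cat][w], s_sc)

    out = []
    for cat in MOTION_CATEGORIES:
        total = area_scores[cat] + speed_scores[cat]
        if spec.zero_when_static:
            total = np.where(speed_scores[cat] == 0, 0, total)
        out.append(AnnotationTrack(f"motion_{cat}", "visual", "ordinal", total.astype(float)))
    return AnnotationSet(out)


def compare_annotation_pair(track_a, track_b) -> float:
    """Pearson correlation of two aligned annotation tracks (or plain arrays)."""
    a = np.asarray(getattr(track_a, "values", track_a), dtype=float)
    b = np.asarray(getattr(track_b, "values", track_b), dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("tracks must be equal-length 1-D with length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance track")
    return float(np.corrcoef(a, b)[0, 1])
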