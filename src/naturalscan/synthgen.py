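"""Synthetic naturalistic-fMRI study generator.

Builds every input the analysis pipeline consumes — 1-Hz stimulus
annotations, toy audio and video with analytic ground truth, object-tracking
tables, and multi-subject BOLD-like datasets containing planted spatial
networks — so the full chain (feature extraction, design, group ICA,
inference, network comparison) can be exercised against known truth.

The emulated study geometry is a 10-subject free-viewing experiment with
TR = 2 s and 679 retained volumes; the desk-scale default is 5 subjects,
300 volumes, 2000 voxels and 4 planted components, with the full geometry
reachable through :class:`SynthConfig`.

Planted component time courses are linear combinations of HRF-convolved
annotations plus a shared AR(1) signal common to all subjects and an
idiosyncratic AR(1) perturbation per subject, so inter-subject correlation
is controlled by ``subject_noise_sd``.  Spatial networks are Gaussian blobs
separated on a lattice, keeping pairwise spatial correlation low and ICA
recovery well-posed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .design import BoldDataset, DesignMatrix, HrfSpec, make_design_matrix
from .stimulus_features import AnnotationSet, AnnotationTrack, ObjectTrack

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "FEATURE_NAMES",
    "AUDITORY_FEATURES",
    "VISUAL_FEATURES",
    "default_weight_matrix",
    "gen_annotations",
    "gen_audio",
    "gen_video_tracks",
    "gen_bold",
    "synth_study",
]

BOXCAR_NAMES = ("speech", "music", "lead_singing", "background_singing")
ACOUSTIC_NAMES = ("zcr", "spectral_spread", "entropy", "rms")
MOTION_NAMES = (
    "motion_mechanical",
    "motion_hand",
    "motion_head",
    "motion_body",
    "motion_global",
    "motion_inferred",
)
AUDITORY_FEATURES = BOXCAR_NAMES + ACOUSTIC_NAMES
VISUAL_FEATURES = ("edges",) + MOTION_NAMES
#: canonical feature order: 8 auditory then 7 visual
FEATURE_NAMES = AUDITORY_FEATURES + VISUAL_FEATURES


def default_weight_matrix(n_components: int = 4) -> np.ndarray:
    """Generating weights mapping the 15 features to planted components.

    The four default components mimic the functional networks a naturalistic
    study recovers: a core auditory network (speech + music + loudness), a
    speech-selective network, an early-visual network driven by contrast
    edges and large-scale motion, and a dorsal hand/mechanical-motion
    network.
    """
    W = np.zeros((4, len(FEATURE_NAMES)))
    names = list(FEATURE_NAMES)

    def put(row, **kv):
        for k, v in kv.items():
            W[row, names.index(k)] = v

    put(0, speech=1.0, music=0.7, rms=0.5, lead_singing=0.4)
    put(1, speech=1.0, spectral_spread=0.4, entropy=0.3)
    put(2, edges=1.0, motion_global=0.6, motion_body=0.4)
    put(3, motion_hand=1.0, motion_mechanical=0.6)
    if n_components <= 4:
        return W[:n_components]
    # extra components beyond the four stimulus-locked defaults carry no
    # stimulus weights (pure shared-noise networks)
    return np.vstack([W, np.zeros((n_components - 4, len(FEATURE_NAMES)))])


@dataclass
class SynthConfig:
    """Ground-truth parameters of one synthetic study.

    Noise SDs are stationary standard deviations of AR(1) processes with
    common coefficient ``ar1_phi``; ``shared_noise_sd`` perturbs component
    time courses identically in every subject, ``subject_noise_sd``
    idiosyncratically, and ``voxel_noise_sd`` is added per voxel.  The clean
    stimulus-driven part of each component time course is scaled to unit
    variance, so the SDs read directly as noise-to-signal ratios.
    """

    n_subjects: int = 5
    n_timepoints: int = 300
    tr: float = 2.0
    n_voxels: int = 2000
    mask_shape: tuple[int, int, int] = (20, 10, 10)
    n_components: int = 4
    weight_matrix: np.ndarray | None = None
    shared_noise_sd: float = 0.3
    subject_noise_sd: float = 0.3
    voxel_noise_sd: float = 0.5
    ar1_phi: float = 0.3
    seed: int = 0
    # annotation generation
    boxcar_density: float = 0.18
    boxcar_overlap: float = 0.0
    motion_density: float = 0.2
    hrf: HrfSpec = field(default_factory=HrfSpec)

    def __post_init__(self) -> None:
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if int(np.prod(self.mask_shape)) < self.n_voxels:
            raise ValueError("mask_shape too small for n_voxels")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        for name in ("shared_noise_sd", "subject_noise_sd", "voxel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.weight_matrix is None:
            self.weight_matrix = default_weight_matrix(self.n_components)
        self.weight_matrix = np.asarray(self.weight_matrix, dtype=float)
        if self.weight_matrix.shape[0] != self.n_components:
            raise ValueError("weight_matrix row count must equal n_components")

    @property
    def duration_s(self) -> int:
        return int(self.n_timepoints * self.tr)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spatial_maps: np.ndarray  # components x voxels
    component_timecourses: np.ndarray  # subjects x components x time
    generating_betas: np.ndarray  # components x features
    track_tables: list[ObjectTrack]
    stimulus_locked: np.ndarray  # bool per component (any nonzero weight)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _place_segments(
    T: int,
    n_active: int,
    mean_len: float,
    rng: np.random.Generator,
    occupied: np.ndarray,
) -> np.ndarray:
    """Mark ``n_active`` bins active in segments of ~mean_len, avoiding ``occupied``."""
    out = np.zeros(T, dtype=bool)
    placed = 0
    while placed < n_active:
        L = int(min(n_active - placed, 1 + rng.poisson(max(mean_len - 1.0, 0.0))))
        free = ~(occupied | out)
        # valid starts: L consecutive free bins
        csum = np.concatenate(([0], np.cumsum(free)))
        while L >= 1:
            starts = np.flatnonzero(csum[L:] - csum[:-L] == L)
            if len(starts):
                break
            L -= 1
        if L < 1:
            break  # no room left anywhere
        s = int(rng.choice(starts))
        out[s : s + L] = True
        placed += L
    return out


def gen_annotations(config: SynthConfig) -> AnnotationSet:
    """Generate the 15 annotation tracks of one synthetic stimulus.

    Four boxcar sound categories with configurable active density and
    overlap (``boxcar_overlap = 0`` places them disjointly), four continuous
    acoustic features as smoothed Gaussian noise clipped to be non-negative,
    one edge-density track, and six ordinal motion-category tracks whose
    segment scores are drawn from the manual size/strength scoring rule.
    """
    T = config.duration_s
    if T < 10:
        raise ValueError("stimulus duration must be at least 10 s")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    tracks: list[AnnotationTrack] = []

    n_active = int(round(config.boxcar_density * T))
    global_occ = np.zeros(T, dtype=bool)
    for name in BOXCAR_NAMES:
        if config.boxcar_overlap <= 0.0:
            occ = global_occ
        else:
            occ = np.zeros(T, dtype=bool)
        seg = _place_segments(T, n_active, 8.0, rng, occ)
        global_occ |= seg
        tracks.append(AnnotationTrack(name, "auditory", "boxcar", seg.astype(float)))

    for name in ACOUSTIC_NAMES:
        x = gaussian_filter1d(rng.standard_normal(T), 3.0)
        tracks.append(
            AnnotationTrack(name, "auditory", "continuous", np.clip(x + 1.0, 0.0, None))
        )

    x = gaussian_filter1d(rng.standard_normal(T), 3.0)
    tracks.append(AnnotationTrack("edges", "visual", "continuous", np.clip(x + 1.0, 0.0, None)))

    n_motion = int(round(config.motion_density * T))
    for name in MOTION_NAMES:
        seg = _place_segments(T, n_motion, 6.0, rng, np.zeros(T, dtype=bool))
        vals = np.zeros(T)
        # constant ordinal score per contiguous event, from the manual rule
        edges = np.flatnonzero(np.diff(np.concatenate(([0], seg.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            size, strength = int(rng.integers(0, 3)), int(rng.integers(1, 3))
            vals[s:e] = min(4, size + strength)
        tracks.append(AnnotationTrack(name, "visual", "ordinal", vals))
    return AnnotationSet(tracks)


# ---------------------------------------------------------------------------
# toy media
# ---------------------------------------------------------------------------


def gen_audio(
    config: SynthConfig,
    sample_rate: int = 8000,
    n_seconds: int = 16,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenated 1-s audio segments with an analytic per-second truth table.

    Segment kinds cycle silence / pure tone / two-tone chord / white noise.
    The truth table lists RMS, ZCR and spectral spread where closed forms
    exist (NaN elsewhere): a tone of amplitude A has RMS A/sqrt(2) and ZCR
    2f; an equal-amplitude chord has spread |f2 - f1| / 2.
    """
    if sample_rate < 2000:
        raise ValueError("sample_rate must be >= 2 kHz")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    t = np.arange(sample_rate) / sample_rate
    pieces, rows = [], []
    freqs = np.arange(200, 1001, 50)
    for i in range(n_seconds):
        kind = ("silence", "tone", "chord", "noise")[i % 4]
        amp = float(rng.uniform(0.2, 0.9))
        if kind == "silence":
            pieces.append(np.zeros(sample_rate))
            rows.append(dict(segment=i, kind=kind, f1=np.nan, f2=np.nan, amplitude=0.0,
                             rms=0.0, zcr=0.0, spread=np.nan))
        elif kind == "tone":
            f = float(rng.choice(freqs))
            pieces.append(amp * np.sin(2 * np.pi * f * t + 0.1))
            rows.append(dict(segment=i, kind=kind, f1=f, f2=np.nan, amplitude=amp,
                             rms=amp / np.sqrt(2), zcr=2 * f, spread=0.0))
        elif kind == "chord":
            f1, f2 = sorted(rng.choice(freqs, size=2, replace=False).astype(float))
            pieces.append(
                0.5 * amp * (np.sin(2 * np.pi * f1 * t + 0.1) + np.sin(2 * np.pi * f2 * t + 0.2))
            )
            rows.append(dict(segment=i, kind=kind, f1=f1, f2=f2, amplitude=amp,
                             rms=0.5 * amp, zcr=np.nan, spread=(f2 - f1) / 2))
        else:
            x = rng.standard_normal(sample_rate)
            x *= amp / np.sqrt(np.mean(x**2))  # exact window RMS
            pieces.append(x)
            rows.append(dict(segment=i, kind=kind, f1=np.nan, f2=np.nan, amplitude=amp,
                             rms=amp, zcr=np.nan, spread=np.nan))
    return np.concatenate(pieces), pd.DataFrame(rows)


def gen_video_tracks(
    config: SynthConfig,
    fps: int = 25,
    n_seconds: int = 8,
    frame_shape: tuple[int, int] = (48, 64),
    background: float = 0.5,
    objects: Sequence[dict] | None = None,
) -> tuple[np.ndarray, list[ObjectTrack]]:
    """Moving rectangles on a uniform background plus exact tracking tables.

    Each object moves with constant velocity; its emitted track holds the
    exact per-frame bounding box and centroid so motion scoring is
    verifiable.  A track is truncated and flagged when the object would
    leave the frame.  ``objects`` overrides the random draw with explicit
    dicts of ``x, y, w, h, vx, vy, category``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    H, W = frame_shape
    n_frames = fps * n_seconds
    frames = np.full((n_frames, H, W), background)
    tracks: list[ObjectTrack] = []
    cats = ("body", "head", "hand", "mechanical")
    if objects is None:
        objects = []
        for k in range(3):
            w = int(rng.integers(6, 14))
            h = int(rng.integers(6, 14))
            objects.append(dict(
                w=w, h=h,
                x=float(rng.integers(2, W - w - 2)),
                y=float(rng.integers(2, H - h - 2)),
                vx=float(rng.uniform(-1.5, 1.5)),
                vy=float(rng.uniform(-1.0, 1.0)),
                category=cats[k % len(cats)],
            ))
    for k, obj in enumerate(objects):
        w, h = int(obj["w"]), int(obj["h"])
        x, y = float(obj["x"]), float(obj["y"])
        vx, vy = float(obj.get("vx", 0.0)), float(obj.get("vy", 0.0))
        category = obj.get("category", cats[k % len(cats)])
        boxes, fidx = [], []
        truncated = False
        for f in range(n_frames):
            xf, yf = x + vx * f, y + vy * f
            if xf < 0 or yf < 0 or xf + w > W or yf + h > H:
                truncated = True
                break
            boxes.append((xf, yf, xf + w, yf + h))
            fidx.append(f)
            frames[f, int(round(yf)) : int(round(yf)) + h, int(round(xf)) : int(round(xf)) + w] = 1.0
        if boxes:
            tracks.append(
                ObjectTrack(f"obj{k}", category, float(fps),
                            np.array(fidx), np.array(boxes), truncated=truncated)
            )
    return frames, tracks


# ---------------------------------------------------------------------------
# BOLD data
# ---------------------------------------------------------------------------


def _ar1(rng: np.random.Generator, sd: float, phi: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` along the first axis."""
    if sd == 0.0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape) * sd * np.sqrt(1.0 - phi**2)
    eps[0] = rng.standard_normal(shape[1:]) * sd if len(shape) > 1 else rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -phi], eps, axis=0) if phi != 0.0 else eps


def _blob_maps(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-blob spatial maps on the mask lattice, one blob per component."""
    shape = config.mask_shape
    mask_flat = np.zeros(int(np.prod(shape)), dtype=bool)
    mask_flat[: config.n_voxels] = True  # x-fastest linear order
    mask = mask_flat.reshape(shape, order="F")
    xs, ys, zs = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack([xs.ravel(order="F"), ys.ravel(order="F"), zs.ravel(order="F")], axis=1)
    coords = coords[mask_flat].astype(float)
    # one blob per cell of a lattice partition of the volume: split axes
    # greedily (largest cell extent first) until there are >= K cells, which
    # guarantees a minimum center separation relative to blob width
    K = config.n_components
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    extent = hi - lo + 1.0
    splits = np.ones(3, dtype=int)
    while int(np.prod(splits)) < K:
        ax = int(np.argmax(extent / splits))
        splits[ax] += 1
    cell = extent / splits
    grid = [lo[a] + cell[a] * (np.arange(splits[a]) + 0.5) for a in range(3)]
    cx, cy, cz = np.meshgrid(*grid, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)[:K]
    sigma = max(1.0, float(cell.min()) / 5.0)
    maps = np.exp(-0.5 * np.sum((coords[None] - centers[:, None]) ** 2, axis=2) / sigma**2)
    maps[maps < 1e-8] = 0.0
    return maps, mask


def gen_bold(
    config: SynthConfig, design: DesignMatrix
) -> tuple[list[BoldDataset], GroundTruth]:
    """Plant stimulus-driven spatial networks in multi-subject BOLD data.

    Per subject, ``data = timecourses @ spatial_maps + voxel AR(1) noise``
    where each component time course is the unit-variance combination of the
    design columns given by the weight matrix, plus a shared AR(1) signal
    (common to all subjects) and an idiosyncratic AR(1) perturbation.  A
    weight row of zeros yields a pure shared-noise network (a warning is
    emitted: such a component carries no stimulus information).
    """
    if design.n_timepoints != config.n_timepoints:
        raise ValueError("design matrix length must equal n_timepoints")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    T, K = config.n_timepoints, config.n_components
    W = config.weight_matrix

    X = design.matrix
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    locked = np.any(W != 0.0, axis=1)
    if not locked.all():
        warnings.warn(
            "weight matrix has all-zero row(s): those components are pure noise",
            stacklevel=2,
        )
    clean = np.zeros((T, K))
    for c in range(K):
        if locked[c]:
            s = Xz @ W[c]
            clean[:, c] = s / s.std()

    shared = clean + _ar1(rng, config.shared_noise_sd, config.ar1_phi, (T, K))
    maps, mask = _blob_maps(config)

    datasets, tcs = [], np.empty((config.n_subjects, K, T))
    for s in range(config.n_subjects):
        tc = shared + _ar1(rng, config.subject_noise_sd, config.ar1_phi, (T, K))
        tcs[s] = tc.T
        data = tc @ maps + _ar1(rng, config.voxel_noise_sd, config.ar1_phi, (T, config.n_voxels))
        datasets.append(BoldDataset(data, mask, config.tr, subject_id=f"sub-{s:02d}"))

    _, track_tables = gen_video_tracks(config)
    truth = GroundTruth(maps, tcs, W.copy(), track_tables, locked)
    return datasets, truth


def synth_study(
    config: SynthConfig | None = None,
) -> tuple[AnnotationSet, dict[str, DesignMatrix], list[BoldDataset], GroundTruth]:
    """One-call synthetic study: annotations, design matrices, BOLD, truth.

    Returns the annotation set, the ``auditory``/``visual``/``combined``
    design matrices on the TR grid, the per-subject datasets and the ground
    truth.  The combined design (all 15 features) is the one the generator
    used to drive the planted components.
    """
    config = config or SynthConfig()
    ann = gen_annotations(config)
    designs = {
        "auditory": make_design_matrix(
            ann, "auditory", config.tr, config.n_timepoints, config.hrf,
            names=list(AUDITORY_FEATURES),
        ),
        "visual": make_design_matrix(
            ann, "visual", config.tr, config.n_timepoints, config.hrf,
            names=list(VISUAL_FEATURES),
        ),
        "combined": make_design_matrix(
            ann, "combined", config.tr, config.n_timepoints, config.hrf,
            names=list(FEATURE_NAMES),
        ),
    }
    datasets, truth = gen_bold(config, designs["combined"])
    return ann, designs, datasets, truth
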