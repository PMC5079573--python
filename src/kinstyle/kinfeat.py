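"""Kinematic preprocessing and feature extraction for reach-to-grasp trials.

A trial is a ``T x 6 x 3`` array of marker positions (mm) sampled at a fixed
rate from six hand markers.  The processing chain is: zero-phase low-pass
filtering, velocity-threshold segmentation of the reach, computation of four
global-frame variables (wrist velocity, wrist height, wrist horizontal
trajectory, grip aperture) and twelve hand-local variables (thumb and index
coordinates, finger-plane and dorsum-plane unit normals), resampling onto a
normalized-time grid, and column z-scoring into a trials x features design
matrix.

Conventions: z is vertical, x is the horizontal transport direction.  The
hand-local frame has its origin at the wrist marker, X along the wrist to
index-metacarpal direction, Z normal to the dorsum plane and Y completing a
right-handed set; all local variables are therefore invariant to rigid
motions of the whole marker set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateFrameError,
    DegeneratePlaneError,
    InvalidArgumentError,
    NoMovementError,
    TruncatedTrialError,
)

logger = logging.getLogger(__name__)

#: Ordered marker labels; the sample array's second axis follows this order.
MARKERS = (
    "wrist_radial",
    "index_mcp",
    "index_tip",
    "little_mcp",
    "thumb_trapezium",
    "thumb_tip",
)
_MIDX = {m: i for i, m in enumerate(MARKERS)}

#: The 16 kinematic variables, in design-matrix column order.
VARIABLES = (
    "wrist_velocity",
    "wrist_height",
    "wrist_horizontal",
    "grip_aperture",
    "thumb_x", "thumb_y", "thumb_z",
    "index_x", "index_y", "index_z",
    "finger_plane_x", "finger_plane_y", "finger_plane_z",
    "dorsum_plane_x", "dorsum_plane_y", "dorsum_plane_z",
)

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_THRESHOLD_MM_S = 20.0
DEFAULT_REFRACTORY_S = 0.1
DEFAULT_N_POINTS = 10


@dataclass
class MarkerTrial:
    """One trial's marker trajectories plus metadata."""

    samples: np.ndarray          # (T, 6, 3) positions in mm
    rate_hz: float
    participant: str
    intent: str
    session: int = 1
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[1:] != (6, 3):
            raise InvalidArgumentError(
                f"samples must be (T, 6, 3), got {self.samples.shape}")
        if self.samples.shape[0] < 2:
            raise InvalidArgumentError("a trial needs at least 2 samples")
        if self.rate_hz <= 0:
            raise InvalidArgumentError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def marker(self, name: str) -> np.ndarray:
        """(T, 3) trajectory of one marker."""
        return self.samples[:, _MIDX[name], :]

    def with_samples(self, samples: np.ndarray) -> "MarkerTrial":
        return MarkerTrial(samples, self.rate_hz, self.participant,
                           self.intent, self.session, self.trial_id)


@dataclass(frozen=True)
class ReachWindow:
    """Sample-index window of the reach-to-grasp phase."""

    onset: int
    offset: int
    threshold_mm_s: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise InvalidArgumentError("onset must precede offset")

    @property
    def length(self) -> int:
        return self.offset - self.onset + 1


def lowpass_filter(trial: MarkerTrial, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                   order: int = 2) -> MarkerTrial:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The effective magnitude response is the squared single-pass response,
    and the phase is identically zero, so movement-onset times are not
    shifted by filtering.
    """
    nyquist = trial.rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise InvalidArgumentError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff_hz / nyquist, output="sos")
    flat = trial.samples.reshape(trial.n_samples, -1)
    out = signal.sosfiltfilt(sos, flat, axis=0)
    return trial.with_samples(out.reshape(trial.samples.shape))


def wrist_speed(trial: MarkerTrial) -> np.ndarray:
    """Wrist speed (mm/s) via central finite differences."""
    pos = trial.marker("wrist_radial")
    vel = np.gradient(pos, 1.0 / trial.rate_hz, axis=0)
    return np.linalg.norm(vel, axis=1)


def segment_reach(trial: MarkerTrial,
                  threshold_mm_s: float = DEFAULT_THRESHOLD_MM_S,
                  refractory_s: float = DEFAULT_REFRACTORY_S) -> ReachWindow:
    """Find the reach window from wrist-speed threshold crossings.

    Onset is the first sample with speed above the threshold that stays
    above it for at least the refractory window (rejecting isolated noise
    spikes); offset is the first later sample at or below the threshold
    that is not followed by a renewed excursion above threshold within the
    refractory window (ignoring brief sub-threshold dips).  Both guards
    share one rationale: a 20 mm/s criterion on a noisy speed estimate
    crosses spuriously, a real movement crosses sustainedly.
    """
    speed = wrist_speed(trial)
    above = speed > threshold_mm_s
    if not above.any():
        raise NoMovementError(
            f"wrist speed never exceeds {threshold_mm_s} mm/s")
    refractory = max(1, int(round(refractory_s * trial.rate_hz)))
    onset = None
    for i in np.flatnonzero(above):
        if above[i:i + refractory].all():
            onset = int(i)
            break
    if onset is None:
        raise NoMovementError(
            "wrist speed never stays above threshold; only isolated spikes")
    offset = None
    j = onset + 1
    n = len(speed)
    while j < n:
        if not above[j]:
            # candidate offset; reject if speed comes back up shortly after
            if above[j + 1:j + 1 + refractory].any():
                j += 1
                continue
            offset = j
            break
        j += 1
    if offset is None:
        raise TruncatedTrialError(
            "wrist speed never drops back below threshold after onset")
    return ReachWindow(onset, offset, threshold_mm_s)


def global_features(trial: MarkerTrial, window: ReachWindow) -> pd.DataFrame:
    """Per-sample global-frame variables over the reach window.

    wrist_velocity (mm/s), wrist_height (z, mm), wrist_horizontal (x, mm)
    and grip_aperture (thumb-tip to index-tip distance, mm).
    """
    sl = slice(window.onset, window.offset + 1)
    speed = wrist_speed(trial)[sl]
    wrist = trial.marker("wrist_radial")[sl]
    aperture = np.linalg.norm(
        trial.marker("thumb_tip")[sl] - trial.marker("index_tip")[sl], axis=1)
    return pd.DataFrame({
        "wrist_velocity": speed,
        "wrist_height": wrist[:, 2],
        "wrist_horizontal": wrist[:, 0],
        "grip_aperture": aperture,
    })


def local_frame(trial: MarkerTrial, sample_index: int,
                tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Hand-local orthonormal frame at one sample.

    Returns ``(origin, R)`` where the rows of R are the X, Y, Z axes:
    origin at the wrist marker, X toward the index metacarpal, Z along
    X x (little_mcp - wrist), Y = Z x X.
    """
    p = trial.samples[sample_index]
    origin = p[_MIDX["wrist_radial"]]
    u = p[_MIDX["index_mcp"]] - origin
    v = p[_MIDX["little_mcp"]] - origin
    nu = np.linalg.norm(u)
    if nu < tol:
        raise DegenerateFrameError("wrist and index_mcp coincide")
    x = u / nu
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < tol * max(1.0, np.linalg.norm(v)):
        raise DegenerateFrameError("frame-defining markers are collinear")
    z = z / nz
    y = np.cross(z, x)
    return origin, np.vstack([x, y, z])


def _plane_normal(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                  tol: float = 1e-9) -> np.ndarray:
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < tol:
        raise DegeneratePlaneError("plane-defining points are collinear")
    return n / norm


def local_features(trial: MarkerTrial, window: ReachWindow) -> pd.DataFrame:
    """Per-sample hand-local variables over the reach window.

    Thumb-tip and index-tip coordinates in the hand frame (6 variables),
    the unit normal of the finger plane (through thumb tip, index tip and
    the midpoint of thumb_trapezium and index_mcp) and the unit normal of
    the dorsum plane (through wrist, index_mcp, little_mcp), both expressed
    in the hand frame (6 variables).  Normal signs are fixed so the
    z-component is non-negative at onset and tracked continuously after.
    """
    rows = []
    prev_fp = None
    prev_dp = None
    for i in range(window.onset, window.offset + 1):
        origin, R = local_frame(trial, i)
        p = trial.samples[i]
        thumb = R @ (p[_MIDX["thumb_tip"]] - origin)
        index = R @ (p[_MIDX["index_tip"]] - origin)
        mid = 0.5 * (p[_MIDX["thumb_trapezium"]] + p[_MIDX["index_mcp"]])
        fp = R @ _plane_normal(p[_MIDX["thumb_tip"]],
                               p[_MIDX["index_tip"]], mid)
        dp = R @ _plane_normal(p[_MIDX["wrist_radial"]],
                               p[_MIDX["index_mcp"]], p[_MIDX["little_mcp"]])
        if prev_fp is None:
            if fp[2] < 0:
                fp = -fp
            if dp[2] < 0:
                dp = -dp
        else:
            if np.dot(fp, prev_fp) < 0:
                fp = -fp
            if np.dot(dp, prev_dp) < 0:
                dp = -dp
        prev_fp, prev_dp = fp, dp
        rows.append(np.concatenate([thumb, index, fp, dp]))
    cols = ["thumb_x", "thumb_y", "thumb_z",
            "index_x", "index_y", "index_z",
            "finger_plane_x", "finger_plane_y", "finger_plane_z",
            "dorsum_plane_x", "dorsum_plane_y", "dorsum_plane_z"]
    return pd.DataFrame(np.asarray(rows), columns=cols)


def normalize_resample(series: np.ndarray | pd.DataFrame,
                       n_points: int = DEFAULT_N_POINTS,
                       include_zero: bool = False) -> np.ndarray:
    """Resample a per-sample series onto a normalized-time grid.

    Time is mapped linearly to [0, 1] over the series and the values are
    linearly interpolated at ``n_points`` equally spaced normalized times
    (0.1, 0.2, ..., 1.0 by default; set ``include_zero`` for a grid that
    starts at 0).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 samples to resample")
    if n_points < 1:
        raise InvalidArgumentError("n_points must be >= 1")
    if include_zero:
        grid = np.linspace(0.0, 1.0, n_points)
    else:
        grid = np.linspace(1.0 / n_points, 1.0, n_points)
    t = np.linspace(0.0, 1.0, n)
    out = np.empty((n_points, arr.shape[1]))
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(grid, t, arr[:, j])
    return out if np.asarray(series).ndim > 1 else out[:, 0]


@dataclass
class FeatureMatrix:
    """Trials x (16 variables x P time points) design matrix.

    ``X`` holds the z-scored features used downstream; ``raw`` the
    unstandardized values.  ``meta`` is one row per retained trial
    (trial_id, participant, intent, session).  ``dropped`` records trials
    that failed segmentation, with the reason.
    """

    X: np.ndarray
    raw: np.ndarray
    columns: list[str]
    meta: pd.DataFrame
    col_mean: np.ndarray
    col_sd: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        data = self.X if normalized else self.raw
        df = pd.DataFrame(data, columns=self.columns)
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)

    def variable_of_column(self, col: str) -> str:
        return col.rsplit("@", 1)[0]


def extract_profile(trial: MarkerTrial,
                    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                    threshold_mm_s: float = DEFAULT_THRESHOLD_MM_S,
                    refractory_s: float = DEFAULT_REFRACTORY_S,
                    n_points: int = DEFAULT_N_POINTS,
                    include_zero: bool = False) -> np.ndarray:
    """Full single-trial chain: filter, segment, features, resample.

    Returns a flat vector of 16 * n_points values ordered variable-major
    (all time points of variable 1, then variable 2, ...).
    """
    filt = lowpass_filter(trial, cutoff_hz)
    window = segment_reach(filt, threshold_mm_s, refractory_s)
    feats = pd.concat([global_features(filt, window),
                       local_features(filt, window)], axis=1)
    feats = feats[list(VARIABLES)]
    prof = normalize_resample(feats.to_numpy(), n_points, include_zero)
    return prof.T.reshape(-1)  # variable-major


def feature_columns(n_points: int = DEFAULT_N_POINTS,
                    include_zero: bool = False) -> list[str]:
    if include_zero:
        grid = np.linspace(0.0, 1.0, n_points)
    else:
        grid = np.linspace(1.0 / n_points, 1.0, n_points)
    return [f"{var}@{int(round(100 * g))}" for var in VARIABLES for g in grid]


def build_feature_matrix(trials: Sequence[MarkerTrial],
                         cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                         threshold_mm_s: float = DEFAULT_THRESHOLD_MM_S,
                         refractory_s: float = DEFAULT_REFRACTORY_S,
                         n_points: int = DEFAULT_N_POINTS,
                         include_zero: bool = False) -> FeatureMatrix:
    """Run the per-trial chain over a trial list and z-score columns.

    Trials failing segmentation (no movement, truncated, degenerate frames)
    are dropped with a logged reason rather than aborting the batch,
    mirroring correct-trial selection in motion-capture practice.
    """
    rows, meta, dropped = [], [], []
    for trial in trials:
        try:
            rows.append(extract_profile(trial, cutoff_hz, threshold_mm_s,
                                        refractory_s, n_points, include_zero))
            meta.append({"trial_id": trial.trial_id,
                         "participant": trial.participant,
                         "intent": trial.intent,
                         "session": trial.session})
        except (NoMovementError, TruncatedTrialError, DegenerateFrameError,
                DegeneratePlaneError) as exc:
            logger.warning("dropping trial %s: %s", trial.trial_id, exc)
            dropped.append((trial.trial_id, str(exc)))
    if not rows:
        raise InvalidArgumentError("no trial survived feature extraction")
    raw = np.asarray(rows)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    # columns constant up to float rounding (e.g. a plane normal expressed
    # in its own frame) are recorded with sd 0 and left unscaled, so
    # rounding noise is not amplified into pseudo-variance
    sd = np.where(sd < 1e-9 * (1.0 + np.abs(mean)), 0.0, sd)
    sd_safe = np.where(sd > 0, sd, 1.0)
    X = (raw - mean) / sd_safe
    return FeatureMatrix(X=X, raw=raw,
                         columns=feature_columns(n_points, include_zero),
                         meta=pd.DataFrame(meta), col_mean=mean, col_sd=sd,
                         dropped=dropped)
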