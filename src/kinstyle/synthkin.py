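"""Synthetic reach-to-grasp recordings and observer choice/RT data.

The generator emulates a motion-capture study of reach-to-grasp movements
performed with three intents (pour / drink / place): six hand markers
sampled at 100 Hz, a minimum-jerk wrist transport over a 46 cm reach, a
bell-shaped grip-aperture open-close profile, and participant-specific
*movement styles* — constant offsets on the finger-plane orientation and
the peak grip aperture that persist across a participant's trials.  Because
the offsets are constant within a participant and separated across style
groups, downstream clustering has a known ground truth to recover.

Observer data are drawn from a drift-diffusion process whose drift depends
on the stimulus's style cluster, with subject-level parameters scattered
around group values, emulating a two-alternative intention-discrimination
task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import ChoiceRTDataset, DDMParams, simulate_ddm
from .errors import InvalidArgumentError
from .kinfeat import MARKERS, MarkerTrial

INTENTS = ("pour", "drink", "place")

#: Reach distance from start position to the bottle (mm).
REACH_DISTANCE_MM = 460.0
DEFAULT_RATE_HZ = 100.0
#: Movement-duration range (s) spanned by the recorded movements.
DURATION_RANGE_S = (0.72, 1.64)
#: Stationary padding before and after the movement so the speed threshold
#: is crossed strictly inside the trial.
PAD_S = 0.15
#: Within-participant trial-to-trial variability (mm) of the style-bearing
#: kinematic features (peak aperture, fingertip tilt, wrist lift) — the
#: motor execution noise that makes repeated movements differ.
DEFAULT_NOISE_SD = 2.5
#: Per-sample marker position noise (mm): optical measurement error plus
#: the soft-tissue jitter of skin-mounted hand markers.
MARKER_NOISE_SD = 0.4

# hand-template marker positions in the hand frame (mm): x distal along the
# hand, y toward the thumb, z out of the dorsum
_TEMPLATE = {
    "wrist_radial": np.array([0.0, 0.0, 0.0]),
    "index_mcp": np.array([80.0, 15.0, 0.0]),
    "little_mcp": np.array([70.0, -40.0, 5.0]),
    "thumb_trapezium": np.array([25.0, 45.0, -5.0]),
}
#: Midpoint of the thumb-tip / index-tip pair in the hand frame.
_TIP_MID = np.array([150.0, 15.0, 10.0])

# intent-level base kinematics: (wrist lift mm, peak aperture mm, roll deg)
_INTENT_BASE = {
    "pour": (70.0, 95.0, 10.0),
    "drink": (95.0, 100.0, 25.0),
    "place": (50.0, 85.0, 0.0),
}
#: Mean movement duration (s) per intent; place movements are the fastest,
#: matching the shorter end of the recorded duration range.
_INTENT_DURATION_S = {"pour": 1.15, "drink": 1.25, "place": 1.0}
#: Within-condition trial-to-trial duration scatter (s), about 8% CV.
_DURATION_SD_S = 0.09
#: Lever arm (mm) converting mm-scale style offsets into finger-tilt angles.
_TILT_LEVER_MM = 80.0


@dataclass
class StyleProfile:
    """A participant's movement style: per-intent offsets applied to the
    finger-plane tilt and the peak grip aperture, constant across trials.

    ``noise_sd`` is the participant's trial-to-trial motor variability
    (mm): every generated trial perturbs the style-bearing features by
    i.i.d. Gaussian draws of this scale, on top of per-sample marker
    measurement noise."""

    participant_id: str
    intent_offsets: dict[str, dict[str, float]]
    noise_sd: float = DEFAULT_NOISE_SD
    marker_noise_sd: float = MARKER_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.marker_noise_sd < 0:
            raise InvalidArgumentError("noise scales must be >= 0")
        for intent, off in self.intent_offsets.items():
            if not all(np.isfinite(list(off.values()))):
                raise InvalidArgumentError(
                    f"non-finite offsets for intent {intent!r}")


@dataclass
class GroundTruth:
    """Recovery-test bookkeeping: the true style group of every participant
    per intent, and the true diffusion parameters for observer data."""

    style_assignments: dict[str, dict[str, int]]  # intent -> participant -> g
    ddm_params: DDMParams | None = None
    style_features: tuple[str, ...] = ("finger_plane", "grip_aperture")

    def to_json(self, path) -> None:
        obj = {"style_assignments": self.style_assignments,
               "style_features": list(self.style_features)}
        if self.ddm_params is not None:
            v = self.ddm_params.v
            obj["ddm_params"] = {
                "v": dict(v) if isinstance(v, Mapping) else v,
                "a": self.ddm_params.a, "t": self.ddm_params.t,
                "w": self.ddm_params.w}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def gen_styles(n_participants: int,
               n_style_groups_per_intent: int | Mapping[str, int],
               separation: float, seed: int,
               noise_sd: float = DEFAULT_NOISE_SD,
               within_group_jitter: float = 0.5,
               ) -> tuple[list[StyleProfile], GroundTruth]:
    """Create participant style profiles partitioned into style groups.

    Per intent, participants are split into ``n_style_groups_per_intent``
    groups (a single count, or a mapping intent -> count) whose mean
    offsets are spaced by ``separation * noise_sd`` on both style features
    (peak aperture in mm; finger tilt as the angle subtended by the same
    length at the fingertip lever arm).  Participants within a group
    scatter around the group mean by ``within_group_jitter * noise_sd``.
    Deterministic given the seed.
    """
    if isinstance(n_style_groups_per_intent, Mapping):
        groups_by_intent = {i: int(n_style_groups_per_intent.get(i, 1))
                            for i in INTENTS}
    else:
        groups_by_intent = {i: int(n_style_groups_per_intent)
                            for i in INTENTS}
    if n_participants < 1 or min(groups_by_intent.values()) < 1:
        raise InvalidArgumentError("counts must be positive")
    if separation < 0:
        raise InvalidArgumentError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    pids = [f"P{i + 1:02d}" for i in range(n_participants)]
    assignments: dict[str, dict[str, int]] = {}
    offsets: dict[str, dict[str, dict[str, float]]] = {p: {} for p in pids}
    for intent in INTENTS:
        G = groups_by_intent[intent]
        order = rng.permutation(n_participants)
        groups = {pids[idx]: int(rank % G)
                  for rank, idx in enumerate(order)}
        assignments[intent] = groups
        spacing = separation * noise_sd
        for p in pids:
            g = groups[p]
            centered = g - (G - 1) / 2.0
            jit = within_group_jitter * noise_sd * rng.standard_normal(2)
            ap = centered * spacing + jit[0]
            tilt = np.degrees((centered * spacing + jit[1]) / _TILT_LEVER_MM)
            offsets[p][intent] = {"peak_aperture_mm": float(ap),
                                  "finger_tilt_deg": float(tilt)}
    profiles = [StyleProfile(p, offsets[p], noise_sd) for p in pids]
    return profiles, GroundTruth(style_assignments=assignments)


def _min_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position profile s(tau) and its derivative."""
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    ds = 30 * tau ** 2 - 60 * tau ** 3 + 30 * tau ** 4
    return s, ds


def _aperture_curve(tau: np.ndarray, peak_at: float = 0.7,
                    sharpness: float = 4.0) -> np.ndarray:
    """Beta-shaped open-close curve: 0 at both ends, 1 at ``peak_at``."""
    p = sharpness * peak_at
    q = sharpness * (1.0 - peak_at)
    with np.errstate(invalid="ignore"):
        g = tau ** p * (1 - tau) ** q
    g = np.nan_to_num(g)
    return g / (peak_at ** p * (1 - peak_at) ** q)


def _smooth_noise(rng: np.random.Generator, sd: float,
                  constant_weight: float = 0.35):
    """A random smooth perturbation of normalized time, pointwise scale
    ``sd``: a constant component plus low-order sinusoids."""
    c = rng.standard_normal(4)
    w1 = np.sqrt(1.0 - constant_weight ** 2)

    def f(tau):
        tau = np.clip(tau, 0.0, 1.0)
        wave = (c[1] * np.sin(np.pi * tau)
                + c[2] * np.sin(2 * np.pi * tau)
                + c[3] * np.sin(3 * np.pi * tau)) / np.sqrt(1.5)
        return sd * (constant_weight * c[0] + w1 * wave)

    return f


def _rot_x(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def gen_trial(profile: StyleProfile, intent: str,
              duration_s: float = 1.0,
              rate_hz: float = DEFAULT_RATE_HZ,
              seed: int = 0,
              session: int = 1,
              trial_id: str = "") -> MarkerTrial:
    """Generate one trial's six-marker trajectory.

    The wrist follows a minimum-jerk transport from rest to rest (so a
    20 mm/s speed threshold is crossed exactly twice), the grip aperture
    opens and closes with a peak set by intent plus style offset, and the
    fingertip assembly is tilted about the hand's long axis by the style's
    finger tilt.  Trial-to-trial motor variability (scale
    ``profile.noise_sd``) perturbs the peak aperture, the finger tilt and
    the wrist lift; i.i.d. Gaussian measurement noise is added to every
    marker coordinate sample.
    """
    if intent not in _INTENT_BASE:
        raise InvalidArgumentError(f"unknown intent {intent!r}")
    if rate_hz < 20.0:
        raise InvalidArgumentError(
            f"rate {rate_hz} Hz too low to resolve the movement")
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = np.random.default_rng(seed)
    lift, base_peak, base_roll = _INTENT_BASE[intent]
    off = profile.intent_offsets.get(intent, {})
    trial_sd = profile.noise_sd
    # Trial-to-trial motor variability: a constant offset plus a smooth
    # temporally varying perturbation (low-order sinusoids), so repeated
    # movements differ both in overall scale and in within-movement shape
    # — a constant-only perturbation would make hundreds of feature
    # columns copies of one latent variable, which real variability is not.
    peak_ap = base_peak + off.get("peak_aperture_mm", 0.0)
    tilt_deg = off.get("finger_tilt_deg", 0.0)
    ap_noise = _smooth_noise(rng, trial_sd)
    tilt_noise = _smooth_noise(rng, np.degrees(trial_sd / _TILT_LEVER_MM))
    lift_noise = _smooth_noise(rng, trial_sd)

    n_pad = int(round(PAD_S * rate_hz))
    n_move = int(round(duration_s * rate_hz)) + 1
    tau = np.concatenate([np.zeros(n_pad),
                          np.linspace(0.0, 1.0, n_move),
                          np.ones(n_pad)])
    T = len(tau)
    s, _ = _min_jerk(tau)

    # wrist transport in the global frame (x forward, z up)
    wrist = np.zeros((T, 3))
    wrist[:, 0] = REACH_DISTANCE_MM * s
    wrist[:, 2] = (lift + lift_noise(tau)) * np.sin(np.pi * tau) ** 2

    # hand-frame marker set per sample
    gcurve = _aperture_curve(tau)
    ap = 35.0 + (peak_ap - 35.0 + ap_noise(tau)) * gcurve
    tilt_series = tilt_deg + tilt_noise(tau)

    samples = np.empty((T, 6, 3))
    roll = base_roll + 15.0 * s  # progressive pronation during transport
    for i in range(T):
        R = _rot_x(float(roll[i]))
        tilt = _rot_x(float(tilt_series[i]))
        tip_mid = tilt @ _TIP_MID
        tip_axis = tilt @ np.array([0.0, 1.0, 0.0])
        local = dict(_TEMPLATE)
        local["thumb_tip"] = tip_mid + 0.5 * ap[i] * tip_axis
        local["index_tip"] = tip_mid - 0.5 * ap[i] * tip_axis
        for j, m in enumerate(MARKERS):
            samples[i, j] = wrist[i] + R @ local[m]
    samples += profile.marker_noise_sd * rng.standard_normal(samples.shape)
    return MarkerTrial(samples=samples, rate_hz=rate_hz,
                       participant=profile.participant_id, intent=intent,
                       session=session, trial_id=trial_id)


def gen_dataset(profiles: Sequence[StyleProfile],
                trials_per_intent_per_session: int = 10,
                sessions: Sequence[int] = (1, 2),
                rate_hz: float = DEFAULT_RATE_HZ,
                seed: int = 0,
                intents: Sequence[str] = INTENTS) -> list[MarkerTrial]:
    """Generate a full execution-study dataset.

    Each participant performs ``trials_per_intent_per_session`` trials per
    intent in each session.  Movement durations scatter normally around an
    intent-specific mean (about 8% coefficient of variation, as typical
    for repeated reaches within one task condition), clipped to the
    recorded overall duration range.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    trials = []
    lo, hi = DURATION_RANGE_S
    for prof in profiles:
        for session in sessions:
            for intent in intents:
                for rep in range(trials_per_intent_per_session):
                    dur = float(np.clip(
                        rng.normal(_INTENT_DURATION_S[intent],
                                   _DURATION_SD_S), lo, hi))
                    trial_seed = int(rng.integers(0, 2 ** 31))
                    tid = (f"{prof.participant_id}_s{session}_{intent}"
                           f"_{rep + 1:02d}")
                    trials.append(gen_trial(prof, intent, dur, rate_hz,
                                            trial_seed, session, tid))
    return trials


def trials_to_frame(trials: Sequence[MarkerTrial]) -> pd.DataFrame:
    """Long-format table (trial_id, participant, intent, session, time_s,
    marker, x, y, z) for CSV export."""
    frames = []
    for tr in trials:
        T = tr.n_samples
        time_s = np.arange(T) / tr.rate_hz
        for j, m in enumerate(MARKERS):
            frames.append(pd.DataFrame({
                "trial_id": tr.trial_id, "participant": tr.participant,
                "intent": tr.intent, "session": tr.session,
                "time_s": time_s, "marker": m,
                "x": tr.samples[:, j, 0], "y": tr.samples[:, j, 1],
                "z": tr.samples[:, j, 2]}))
    return pd.concat(frames, ignore_index=True)


def frame_to_trials(df: pd.DataFrame) -> list[MarkerTrial]:
    """Inverse of :func:`trials_to_frame`."""
    trials = []
    for tid, grp in df.groupby("trial_id", sort=False):
        times = np.sort(grp["time_s"].unique())
        if len(times) < 2:
            raise InvalidArgumentError(f"trial {tid} has < 2 samples")
        rate = 1.0 / float(np.median(np.diff(times)))
        T = len(times)
        samples = np.empty((T, 6, 3))
        for j, m in enumerate(MARKERS):
            sub = grp[grp["marker"] == m].sort_values("time_s")
            if len(sub) != T:
                raise InvalidArgumentError(
                    f"trial {tid}: marker {m} has missing samples")
            samples[:, j, :] = sub[["x", "y", "z"]].to_numpy()
        first = grp.iloc[0]
        trials.append(MarkerTrial(
            samples=samples, rate_hz=rate, participant=first["participant"],
            intent=first["intent"], session=int(first["session"]),
            trial_id=str(tid)))
    return trials


def gen_observer_data(truth: GroundTruth,
                      trials_per_cell: int,
                      n_subjects: int,
                      seed: int,
                      subject_sd_v: float = 0.4,
                      subject_sd_a: float = 0.1,
                      subject_sd_t: float = 0.05,
                      dt: float = 1e-3,
                      intent: str = "") -> ChoiceRTDataset:
    """Simulate a two-alternative intention-discrimination experiment.

    Each of ``n_subjects`` observers gets diffusion parameters scattered
    around the group values in ``truth.ddm_params``: the subject's drift
    deviation is a single ability offset added to every cluster's group
    drift (so equally readable clusters stay equally readable within a
    subject), with boundary and non-decision time drawn per subject.
    ``trials_per_cell`` trials per cluster are then drawn from the
    diffusion process; upper-boundary crossings are coded 'correct'.
    Censored paths (none at realistic drifts) are dropped.
    """
    if trials_per_cell < 1 or n_subjects < 1:
        raise InvalidArgumentError("counts must be positive")
    params = truth.ddm_params
    if params is None or not isinstance(params.v, Mapping):
        raise InvalidArgumentError(
            "truth.ddm_params must define a per-cluster drift mapping")
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        a_s = max(0.3, params.a + subject_sd_a * rng.standard_normal())
        t_s = max(0.05, params.t + subject_sd_t * rng.standard_normal())
        dv_s = subject_sd_v * rng.standard_normal()  # shared ability offset
        for cluster, v_c in params.v.items():
            v_s = v_c + dv_s
            sim = simulate_ddm(DDMParams(v=v_s, a=a_s, t=t_s, w=params.w),
                               trials_per_cell,
                               seed=int(rng.integers(0, 2 ** 31)), dt=dt)
            sim = sim[~sim["censored"]]
            for k, row in enumerate(sim.itertuples()):
                rows.append({
                    "subject": subject,
                    "stimulus": f"{intent}c{cluster}_{k + 1:03d}",
                    "intent": intent, "cluster": int(cluster),
                    "response": "correct" if row.choice == 1 else "error",
                    "rt_s": float(row.rt)})
    return ChoiceRTDataset(pd.DataFrame(rows))
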