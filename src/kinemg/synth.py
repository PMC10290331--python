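"""Seeded simulator of multi-subject upper-limb kinematics and surface EMG.

The generator emulates the statistical structure of a cued isotonic-movement
session: per subject, ``n_tasks`` movement tasks are each repeated
``n_repetitions`` times inside fixed instruction windows, every repetition
starting and ending in a rest pose (arm hanging).  Motion is sampled at
60 Hz (6 joint angles in degrees plus hand position and unit-quaternion
orientation from a two-segment forward-kinematics chain); raw EMG is an
amplitude-modulated Gaussian carrier at 2222 Hz whose modulating envelope is
a muscle-activation forward model driven by rectified joint velocities plus
a posture-dependent tonic term, low-pass filtered with a 60-ms time
constant.  Inter-subject variability enters through per-channel gains
(log-normal), envelope baselines, a near-identity row-stochastic crosstalk
matrix (electrode placement), sensor-noise scale and a DC electrode offset.

Trajectories between waypoints follow minimum-jerk profiles, the standard
smoothness model for voluntary reaching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

__all__ = [
    "JOINTS",
    "CHANNELS",
    "ANATOMICAL_RANGES",
    "REST_POSE",
    "ProtocolConfig",
    "SubjectProfile",
    "TaskTemplate",
    "RawRecording",
    "minimum_jerk",
    "make_task_templates",
    "synthesize_kinematics",
    "forward_kinematics",
    "forward_muscle_model",
    "generate_dataset",
]

JOINTS = (
    "shoulder_abd",
    "shoulder_flex",
    "elbow_flex",
    "elbow_rot",
    "wrist_abd",
    "wrist_flex",
)

CHANNELS = (
    "deltoid_anterior",
    "deltoid_medial",
    "deltoid_posterior",
    "biceps",
    "triceps",
    "pronator_teres",
    "flexor_carpi",
    "extensor_carpi",
)

#: antagonist channel pairs (flexor index, extensor index) sharing a joint
ANTAGONIST_PAIRS = ((0, 2), (3, 4), (6, 7))

#: editable anatomical joint-angle limits, degrees
ANATOMICAL_RANGES = {
    "shoulder_abd": (-45.0, 180.0),
    "shoulder_flex": (-60.0, 180.0),
    "elbow_flex": (0.0, 150.0),
    "elbow_rot": (-90.0, 90.0),
    "wrist_abd": (-30.0, 30.0),
    "wrist_flex": (-70.0, 80.0),
}

REST_POSE = np.zeros(len(JOINTS))

# Velocity->drive weight matrices (channels x joints), all entries >= 0.
# W_POS drives on positive joint velocity, W_NEG on negative velocity, so a
# joint's signed velocity never drives both members of an antagonist pair.
_W = 1.0 / 150.0  # deg/s -> envelope units; peak min-jerk velocities ~120 deg/s
W_POS = np.zeros((8, 6))
W_NEG = np.zeros((8, 6))
W_POS[0, 1] = _W          # deltoid anterior    <- shoulder flexion
W_POS[1, 0] = _W          # deltoid medial      <- shoulder abduction
W_NEG[2, 1] = _W          # deltoid posterior   <- shoulder extension
W_NEG[2, 0] = 0.4 * _W    #   ... assists adduction
W_POS[3, 2] = _W          # biceps              <- elbow flexion
W_POS[3, 3] = 0.3 * _W    #   ... assists supination
W_NEG[4, 2] = _W          # triceps             <- elbow extension
W_POS[5, 3] = _W          # pronator teres      <- forearm pronation
W_POS[6, 5] = _W          # flexor carpi        <- wrist flexion
W_POS[6, 4] = 0.3 * _W    #   ... assists wrist abduction
W_NEG[7, 5] = _W          # extensor carpi      <- wrist extension
W_NEG[7, 4] = 0.3 * _W    #   ... assists wrist adduction

# Posture->tonic weight matrix: anti-gravity holding activity, scaled by
# sin(angle) of the lifted segment (zero in the hanging rest pose).
U_TONIC = np.zeros((8, 6))
U_TONIC[0, 1] = 0.30      # deltoid anterior holds a flexed shoulder
U_TONIC[1, 0] = 0.30      # deltoid medial holds an abducted shoulder
U_TONIC[3, 2] = 0.20      # biceps holds a flexed elbow
U_TONIC[6, 5] = 0.08      # wrist flexor tone when flexed
U_TONIC[7, 4] = 0.05

_LOWPASS_TAU = 0.060  # s, first-order activation dynamics

UPPER_ARM_LENGTH = 0.30  # m
FOREARM_LENGTH = 0.25    # m


@dataclass(frozen=True)
class ProtocolConfig:
    """Session layout of the simulated recording protocol."""

    n_subjects: int = 5
    n_tasks: int = 20
    n_repetitions: int = 18
    motion_rate: float = 60.0
    emg_rate: float = 2222.0
    repetition_window: float = 7.5
    rest_lead: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_tasks, self.n_repetitions) < 1:
            raise ValueError("all protocol counts must be >= 1")
        if self.motion_rate <= 0 or self.emg_rate <= 0:
            raise ValueError("sampling rates must be positive")


@dataclass
class SubjectProfile:
    """Everything that makes one simulated subject's EMG look different."""

    subject_id: int
    gain: np.ndarray            # (8,) positive, log-normal across subjects
    baseline: np.ndarray        # (8,) envelope units, tonic rest level
    crosstalk: np.ndarray       # (8, 8) row-stochastic, diagonally dominant
    noise_scale: float          # additive sensor noise, mV-like
    dc_offset: np.ndarray       # (8,) raw-signal DC (electrode offset)

    def __post_init__(self):
        self.gain = np.asarray(self.gain, float)
        self.baseline = np.asarray(self.baseline, float)
        self.crosstalk = np.asarray(self.crosstalk, float)
        self.dc_offset = np.asarray(self.dc_offset, float)
        if np.any(self.gain <= 0):
            raise ValueError("channel gains must be positive")
        if not np.allclose(self.crosstalk.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("crosstalk rows must sum to 1")
        if np.any(np.diag(self.crosstalk) < 0.7):
            raise ValueError("crosstalk matrix must be diagonally dominant (diag >= 0.7)")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("gain", "baseline", "crosstalk", "dc_offset"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass(frozen=True)
class TaskTemplate:
    """A movement task as a table of joint-angle waypoints with dwell times.

    The first and last waypoints always equal the rest pose; per-repetition
    amplitude/duration jitter is applied at synthesis time.
    """

    task_id: int
    name: str
    category: str  # simple | combined | complex
    waypoints: np.ndarray = field(repr=False)   # (n_wp, 6) degrees
    dwells: np.ndarray = field(repr=False)      # (n_wp,) seconds held at waypoint
    amplitude_jitter: float = 0.10
    duration_jitter: float = 0.15

    def __post_init__(self):
        wp = np.asarray(self.waypoints, float)
        object.__setattr__(self, "waypoints", wp)
        object.__setattr__(self, "dwells", np.asarray(self.dwells, float))
        if not (np.allclose(wp[0], REST_POSE) and np.allclose(wp[-1], REST_POSE)):
            raise ValueError("first and last waypoints must equal the rest pose")
        lo = np.array([ANATOMICAL_RANGES[j][0] for j in JOINTS])
        hi = np.array([ANATOMICAL_RANGES[j][1] for j in JOINTS])
        if np.any(wp < lo - 1e-9) or np.any(wp > hi + 1e-9):
            raise ValueError(f"task {self.name}: waypoint outside anatomical range")

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "name": self.name,
            "category": self.category,
            "waypoints": self.waypoints.tolist(),
            "dwells": self.dwells.tolist(),
            "amplitude_jitter": self.amplitude_jitter,
            "duration_jitter": self.duration_jitter,
        }


@dataclass
class RawRecording:
    """One subject's raw session: 2222-Hz EMG plus 60-Hz motion frames."""

    subject_id: int
    emg: np.ndarray          # (n_samples, 8) float32, mV-like
    emg_rate: float
    motion: np.ndarray       # (n_frames, 13): 6 angles deg, hand xyz m, quat wxyz
    motion_rate: float
    cue_onsets: np.ndarray   # (n_cues,) motion-frame index of each repetition
    labels: list[tuple[int, int]]  # (task_id, repetition) per cue
    activation: np.ndarray | None = None  # (n_frames, 8) noiseless ground truth

    @property
    def angles(self) -> np.ndarray:
        return self.motion[:, :6]

    @property
    def hand_position(self) -> np.ndarray:
        return self.motion[:, 6:9]

    @property
    def hand_quaternion(self) -> np.ndarray:
        return self.motion[:, 9:13]


def minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on normalized time s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10.0 * s ** 3 - 15.0 * s ** 4 + 6.0 * s ** 5


def _wp(**angles) -> np.ndarray:
    pose = REST_POSE.copy()
    for joint, value in angles.items():
        pose[JOINTS.index(joint)] = value
    return pose


def _out_and_back(peaks: list[dict], dwell: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    wps = [REST_POSE.copy()] + [_wp(**p) for p in peaks] + [REST_POSE.copy()]
    dwells = [0.75] + [dwell] * len(peaks) + [0.75]
    return np.array(wps), np.array(dwells)


def _base_templates() -> list[tuple[str, str, np.ndarray, np.ndarray, float]]:
    """(name, category, waypoints, dwells, amplitude_jitter) definitions.

    Within each category, shoulder- and wrist-dominant tasks come first so
    that truncated task lists keep the channel imbalance of the full set.
    """
    t = []

    def simple(name, amp=0.10, **angles):
        wps, dw = _out_and_back([angles])
        t.append((name, "simple", wps, dw, amp))

    simple("shoulder_flexion", shoulder_flex=90.0)
    simple("shoulder_abduction", shoulder_abd=90.0)
    simple("wrist_flexion", wrist_flex=60.0)
    simple("wrist_extension", wrist_flex=-60.0)
    simple("shoulder_extension", shoulder_flex=-45.0)
    simple("elbow_flexion", elbow_flex=120.0)
    simple("shoulder_flexion_mix", amp=0.40, shoulder_flex=90.0)
    simple("shoulder_abduction_mix", amp=0.40, shoulder_abd=90.0)
    simple("elbow_flexion_mix", amp=0.40, elbow_flex=120.0)
    simple("elbow_flexion_supinated", elbow_flex=120.0, elbow_rot=-60.0)
    simple("wrist_pronation", elbow_rot=80.0)

    def combined(name, **angles):
        wps, dw = _out_and_back([angles])
        t.append((name, "combined", wps, dw, 0.10))

    combined("abduction_elbow_flexion", shoulder_abd=90.0, elbow_flex=100.0)
    combined("flexion_elbow_flexion", shoulder_flex=90.0, elbow_flex=100.0)
    combined("abduction_wrist_extension", shoulder_abd=90.0, wrist_flex=-50.0)

    def complex_(name, peaks, dwell=0.3):
        wps, dw = _out_and_back(peaks, dwell=dwell)
        t.append((name, "complex", wps, dw, 0.10))

    complex_("breaststroke", [
        dict(shoulder_flex=90.0, elbow_flex=60.0, elbow_rot=70.0),
        dict(shoulder_flex=80.0, shoulder_abd=70.0, elbow_rot=70.0),
    ])
    complex_("relay_handover", [dict(shoulder_flex=-40.0, elbow_rot=70.0)])
    complex_("reading_clock", [dict(elbow_flex=95.0, elbow_rot=75.0)])
    complex_("diagonal_reach", [
        dict(shoulder_flex=40.0, elbow_flex=80.0),
        dict(shoulder_flex=70.0, shoulder_abd=-20.0, elbow_flex=60.0),
    ])
    complex_("waving", [
        dict(elbow_flex=100.0, wrist_flex=35.0),
        dict(elbow_flex=100.0, wrist_flex=-35.0),
        dict(elbow_flex=100.0, wrist_flex=35.0),
    ], dwell=0.2)
    complex_("drawing_circle", [
        dict(shoulder_flex=70.0, elbow_flex=40.0),
        dict(shoulder_flex=90.0, shoulder_abd=30.0, elbow_flex=40.0),
        dict(shoulder_flex=70.0, shoulder_abd=55.0, elbow_flex=40.0),
        dict(shoulder_flex=50.0, shoulder_abd=30.0, elbow_flex=40.0),
    ], dwell=0.15)
    complex_("pointing_three_points", [
        dict(shoulder_flex=90.0, elbow_flex=20.0),
        dict(shoulder_flex=60.0, shoulder_abd=45.0, elbow_flex=30.0),
        dict(shoulder_flex=110.0, shoulder_abd=-20.0, elbow_flex=25.0),
    ])
    return t


def make_task_templates(config: ProtocolConfig) -> list[TaskTemplate]:
    """Build ``config.n_tasks`` templates spanning simple/combined/complex.

    Deterministic in the config alone.  Tasks beyond the 21 built-in
    definitions are amplitude-scaled variants of the built-ins.
    """
    if config.n_tasks < 3:
        raise ValueError("need n_tasks >= 3 to cover all three task categories")
    base = _base_templates()
    by_cat = {c: [b for b in base if b[1] == c] for c in ("simple", "combined", "complex")}
    cats = ("simple", "combined", "complex")
    # allocate task counts across categories proportionally to the built-in
    # pool sizes (largest-remainder rounding), at least one task per category
    pool_sizes = np.array([len(by_cat[c]) for c in cats], float)
    exact = config.n_tasks * pool_sizes / pool_sizes.sum()
    counts = np.maximum(np.floor(exact).astype(int), 1)
    while counts.sum() < config.n_tasks:
        counts[np.argmax(exact - counts)] += 1
    while counts.sum() > config.n_tasks:
        counts[np.argmax(counts - exact)] -= 1
    order: list[tuple] = []
    for cat, k in zip(cats, counts):
        pool = by_cat[cat]
        for i in range(k):
            name, category, wps, dwells, amp = pool[i % len(pool)]
            if i >= len(pool):  # amplitude-scaled variant of an exhausted pool
                scale = 0.8 ** (i // len(pool))
                wps = wps * scale
                name = f"{name}_v{i // len(pool)}"
            order.append((name, category, wps, dwells, amp))
    templates = [
        TaskTemplate(task_id=i, name=name, category=cat, waypoints=wps,
                     dwells=dwells, amplitude_jitter=amp)
        for i, (name, cat, wps, dwells, amp) in enumerate(order)
    ]
    return templates


def synthesize_kinematics(template: TaskTemplate, profile: SubjectProfile | None,
                          rng: np.random.Generator, n_frames: int = 450,
                          rate: float = 60.0) -> np.ndarray:
    """One repetition's joint-angle trajectory (degrees, ``n_frames`` x 6).

    Minimum-jerk interpolation between the template waypoints; amplitude and
    segment-duration jitter are drawn per call from ``rng``.  The trajectory
    starts and ends at the rest pose and is C1-smooth.
    """
    wps = template.waypoints.copy()
    n_wp = len(wps)
    if n_wp == 1:
        return np.tile(wps[0], (n_frames, 1))
    amp = 1.0 + template.amplitude_jitter * rng.uniform(-1.0, 1.0)
    wps[1:-1] = REST_POSE + amp * (wps[1:-1] - REST_POSE)
    lo = np.array([ANATOMICAL_RANGES[j][0] for j in JOINTS])
    hi = np.array([ANATOMICAL_RANGES[j][1] for j in JOINTS])
    wps = np.clip(wps, lo, hi)

    trans = np.full(n_wp - 1, 1.0)
    trans *= 1.0 + template.duration_jitter * rng.uniform(-1.0, 1.0, size=n_wp - 1)
    dwells = template.dwells.copy()
    # scale everything to exactly fill the repetition window
    total = dwells.sum() + trans.sum()
    window = n_frames / rate
    scale = window / total
    dwells *= scale
    trans *= scale

    t = np.arange(n_frames) / rate
    traj = np.empty((n_frames, 6))
    # piecewise schedule: dwell at wp0, transition, dwell at wp1, ...
    bounds = [0.0]
    for k in range(n_wp - 1):
        bounds.append(bounds[-1] + dwells[k])   # end of dwell k
        bounds.append(bounds[-1] + trans[k])    # end of transition k
    traj[:] = wps[-1]
    for k in range(n_wp - 1):
        d_end, tr_end = bounds[2 * k + 1], bounds[2 * k + 2]
        dwell_mask = (t >= bounds[2 * k]) & (t < d_end)
        traj[dwell_mask] = wps[k]
        tr_mask = (t >= d_end) & (t < tr_end)
        s = (t[tr_mask] - d_end) / (tr_end - d_end)
        traj[tr_mask] = wps[k] + minimum_jerk(s)[:, None] * (wps[k + 1] - wps[k])
    return traj


def forward_kinematics(angles_deg: np.ndarray,
                       upper_arm: float = UPPER_ARM_LENGTH,
                       forearm: float = FOREARM_LENGTH) -> tuple[np.ndarray, np.ndarray]:
    """Hand position (m) and orientation (unit quaternion wxyz) from angles.

    Two-segment chain with the shoulder at the origin and the arm hanging
    along -z in the rest pose.  Quaternion sign continuity is enforced by
    keeping each frame in the hemisphere of its predecessor.
    """
    a = np.deg2rad(np.atleast_2d(angles_deg))
    n = a.shape[0]
    r_shoulder = Rotation.from_euler("xy", np.stack([a[:, 0], a[:, 1]], axis=1))
    elbow = r_shoulder.apply(np.tile([0.0, 0.0, -upper_arm], (n, 1)))
    r_fore = r_shoulder * Rotation.from_euler(
        "yz", np.stack([a[:, 2], a[:, 3]], axis=1))
    hand = elbow + r_fore.apply(np.tile([0.0, 0.0, -forearm], (n, 1)))
    r_hand = r_fore * Rotation.from_euler(
        "xy", np.stack([a[:, 4], a[:, 5]], axis=1))
    q_xyzw = r_hand.as_quat()
    quat = np.column_stack([q_xyzw[:, 3], q_xyzw[:, :3]])  # wxyz
    # hemisphere continuity: q and -q encode the same rotation
    flips = np.cumsum(np.einsum("ij,ij->i", quat[1:], quat[:-1]) < 0) % 2
    quat[1:][flips == 1] *= -1.0
    return hand, quat


def activation_from_kinematics(joint_traj: np.ndarray, rate: float = 60.0) -> np.ndarray:
    """Noiseless, subject-independent 60-Hz muscle drive from joint angles.

    Rectified velocity terms plus posture-dependent tonic terms, low-pass
    filtered at tau = 60 ms.  This is the deterministic kinematics->activation
    oracle underlying every simulated subject.
    """
    traj = np.asarray(joint_traj, float)
    if not np.all(np.isfinite(traj)):
        raise ValueError("joint trajectory contains non-finite values")
    vel = np.empty_like(traj)
    vel[:-1] = np.diff(traj, axis=0) * rate
    vel[-1] = vel[-2] if len(traj) > 1 else 0.0
    drive = (np.maximum(vel, 0.0) @ W_POS.T
             + np.maximum(-vel, 0.0) @ W_NEG.T
             + np.sin(np.deg2rad(np.clip(traj, -90.0, 90.0))).clip(min=0.0) @ U_TONIC.T)
    dt = 1.0 / rate
    alpha = dt / (_LOWPASS_TAU + dt)
    zi = drive[:1] * (1.0 - alpha)  # start the filter settled at the first drive value
    act, _ = lfilter([alpha], [1.0, alpha - 1.0], drive, axis=0, zi=zi)
    return act


def forward_muscle_model(joint_traj: np.ndarray, profile: SubjectProfile,
                         rng: np.random.Generator, motion_rate: float = 60.0,
                         emg_rate: float = 2222.0) -> tuple[np.ndarray, np.ndarray]:
    """Map a 60-Hz joint trajectory to (60-Hz envelope, raw EMG at emg_rate).

    The envelope is the deterministic activation scaled by the subject's
    per-channel gain, mixed by the crosstalk matrix and offset by the tonic
    baseline; it stays non-negative.  The raw signal is the envelope
    (linearly upsampled) amplitude-modulating zero-mean Gaussian noise, plus
    sensor noise and a DC electrode offset, so that windowed RMS recovers
    the envelope in expectation.
    """
    act = activation_from_kinematics(joint_traj, rate=motion_rate)
    env = (act * profile.gain) @ profile.crosstalk.T + profile.baseline
    n_frames = env.shape[0]
    duration = n_frames / motion_rate
    n_samples = int(round(duration * emg_rate))
    t60 = np.arange(n_frames) / motion_rate
    ts = np.arange(n_samples) / emg_rate
    raw = np.empty((n_samples, 8), dtype=np.float32)
    for c in range(8):
        env_up = np.interp(ts, t60, env[:, c])
        carrier = rng.standard_normal(n_samples)
        noise = rng.standard_normal(n_samples)
        raw[:, c] = (env_up * carrier
                     + profile.noise_scale * noise
                     + profile.dc_offset[c]).astype(np.float32)
    return env, raw


def _draw_profile(subject_id: int, rng: np.random.Generator) -> SubjectProfile:
    gain = rng.lognormal(mean=0.0, sigma=0.35, size=8)
    baseline = rng.uniform(0.01, 0.04, size=8)
    crosstalk = np.eye(8)
    for c in range(8):
        spread = rng.uniform(0.05, 0.3)
        neighbours = [(c - 1) % 8, (c + 1) % 8]
        shares = rng.dirichlet(np.ones(len(neighbours))) * spread
        for nb, s in zip(neighbours, shares):
            crosstalk[c, nb] = s
        crosstalk[c, c] = 1.0 - spread
    noise_scale = float(rng.uniform(0.005, 0.02))
    dc_offset = rng.uniform(-0.05, 0.05, size=8)
    return SubjectProfile(subject_id=subject_id, gain=gain, baseline=baseline,
                          crosstalk=crosstalk, noise_scale=noise_scale,
                          dc_offset=dc_offset)


#: measurement noise of the recorded joint angles, degrees SD
MOTION_NOISE_DEG = 0.2


def generate_dataset(config: ProtocolConfig,
                     motion_noise_deg: float = MOTION_NOISE_DEG) -> tuple[list[RawRecording], dict]:
    """Simulate one full session per subject plus a JSON-able manifest.

    Session layout per subject: for each task, ``rest_lead`` seconds of rest
    followed by ``n_repetitions`` instruction windows of
    ``repetition_window`` seconds, each containing one rest-bracketed
    repetition; a final ``rest_lead`` rest tail closes the session.

    The muscle model is driven by the true joint trajectory; the *recorded*
    motion adds white measurement noise of ``motion_noise_deg`` degrees SD
    to the angles (hand pose is computed from the noisy angles), emulating
    IMU jitter — this is what the Savitzky-Golay stage smooths.
    """
    templates = make_task_templates(config)
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    rate = config.motion_rate
    rest_frames = int(round(config.rest_lead * rate))
    rep_frames = int(round(config.repetition_window * rate))

    recordings = []
    profiles = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        profile = _draw_profile(s + 1, rng)
        profiles.append(profile)
        blocks = []
        cue_onsets = []
        labels = []
        frame = 0
        for tpl in templates:
            blocks.append(np.tile(REST_POSE, (rest_frames, 1)))
            frame += rest_frames
            for rep in range(config.n_repetitions):
                cue_onsets.append(frame)
                labels.append((tpl.task_id, rep))
                blocks.append(synthesize_kinematics(tpl, profile, rng,
                                                    n_frames=rep_frames, rate=rate))
                frame += rep_frames
        blocks.append(np.tile(REST_POSE, (rest_frames, 1)))
        angles = np.vstack(blocks)
        env, raw = forward_muscle_model(angles, profile, rng,
                                        motion_rate=rate, emg_rate=config.emg_rate)
        measured = angles + rng.normal(0.0, motion_noise_deg, size=angles.shape)
        hand, quat = forward_kinematics(measured)
        motion = np.hstack([measured, hand, quat])
        recordings.append(RawRecording(
            subject_id=s + 1, emg=raw, emg_rate=config.emg_rate,
            motion=motion, motion_rate=rate,
            cue_onsets=np.asarray(cue_onsets, dtype=np.int64),
            labels=labels, activation=env,
        ))

    manifest = {
        "config": asdict(config),
        "templates": [tpl.to_dict() for tpl in templates],
        "profiles": [p.to_dict() for p in profiles],
        "n_cues_per_subject": config.n_tasks * config.n_repetitions,
    }
    # round-trip through JSON so equality is byte-level reproducible
    manifest = json.loads(json.dumps(manifest))
    return recordings, manifest
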