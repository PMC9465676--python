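"""Protocol-faithful synthetic cohorts: coupled ECG, respiration,
acceleration and ground-truth VO2.

The generator emulates a laboratory cardiopulmonary exercise session:

* a 17-min rest block in five postures (stand, lie, lie left, lie right,
  sit), each with normal/deep/talking/fast breathing sub-blocks
  (60/60/30/30 s) and 30 s of adjustment between postures;
* a 3-min treadmill walking warm-up;
* Bruce incremental stages of 3 min each (speeds 2.74–9.65 km/h, inclines
  10–22%), truncated at the first level whose steady-state heart rate
  reaches the exhaustion threshold (180 BPM);
* slow-walking recovery until VO2 settles back toward the warm-up level
  (capped at 20 min).

Ground-truth VO2 follows first-order on/off kinetics toward each activity's
steady state with time constant tau. Heart rate is an affine function of
VO2 plus AR(1) variability; respiration rate and breath amplitude are
affine in VO2 (with breathing-task modulation during rest); chest
acceleration is gravity plus gait harmonics at the speed-dependent step
frequency plus a slow postural-sway component whose amplitude grows with
exercise intensity (the sub-0.32 Hz content that survives the acceleration
low-pass and makes the motion-intensity feature informative). Every channel
carries calibrated measurement noise; everything is reproducible from a
single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import hr_max
from .io import ActivityInterval, Channel, Recording, SubjectInfo

__all__ = [
    "BRUCE_STAGES",
    "SimParams",
    "SubjectTruth",
    "make_schedule",
    "simulate_subject",
    "simulate_cohort",
]

#: Bruce protocol stages: (level, speed km/h, incline %), 3 min each.
BRUCE_STAGES: tuple[tuple[int, float, float], ...] = (
    (1, 2.74, 10.0),
    (2, 4.02, 12.0),
    (3, 5.47, 14.0),
    (4, 6.76, 16.0),
    (5, 8.05, 18.0),
    (6, 8.85, 20.0),
    (7, 9.65, 22.0),
)

REST_POSTURES = ("stand", "lie", "lie_left", "lie_right", "sit")
#: breathing sub-blocks within each rest posture: (mode, seconds)
REST_SUBBLOCKS = (("normal", 60.0), ("deep", 60.0), ("talking", 30.0), ("fast", 30.0))
INTER_POSTURE_REST = 30.0

#: (RR multiplier, amplitude multiplier) per breathing task
BREATHING_MODES = {
    "normal": (1.0, 1.0),
    "deep": (0.6, 1.8),
    "talking": (0.9, 0.7),
    "fast": (1.7, 0.9),  # ~24 breaths/min: near the 0.35 Hz analysis band edge
}


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the protocol simulator.

    Steady-state VO2 values are in ml/kg/min and strictly increasing across
    Bruce levels; tau is the first-order on-kinetics time constant in
    seconds. Noise levels are standard deviations in each channel's units,
    except the ECG/respiration noise which is set as a signal-to-noise
    ratio in dB.
    """

    vo2_rest: float = 3.5  # 1 MET
    vo2_walk: float = 12.0
    vo2_bruce: tuple[float, ...] = (16.0, 21.0, 28.0, 35.0, 43.0, 50.0, 55.0)
    vo2_recovery: float = 6.0  # slow walking
    tau: float = 35.0  # s

    hr_rest: float = 70.0  # BPM at resting VO2
    hr_noise_sd: float = 2.0  # AR(1) innovation sd, BPM
    hr_noise_phi: float = 0.9
    hrv_jitter_sd: float = 0.03  # multiplicative R-R jitter

    rr_rest: float = 14.0  # breaths/min at resting VO2
    rr_slope: float = 0.25  # breaths/min per ml/kg/min
    amp_rest: float = 1.0  # breath amplitude, arbitrary units
    amp_slope: float = 0.06  # per ml/kg/min

    ecg_snr_db: float = 20.0
    resp_snr_db: float = 20.0
    resp_drift_amp: float = 0.5
    resp_drift_freq: float = 0.01  # Hz
    resp_offset: float = 10.0  # belt DC offset

    acc_noise_sd: float = 0.02  # g
    gait_amp_base: float = 0.08  # g at walking speed
    gait_amp_slope: float = 0.05  # g per km/h above walk
    sway_freq: float = 0.18  # Hz, sub-cutoff postural sway
    sway_coef: float = 0.004  # g per ml/kg/min of VO2

    vo2_noise_sd: float = 0.5  # gas-analyser noise, ml/kg/min
    hr_ref_noise_sd: float = 0.5  # chest-strap noise, BPM

    exhaustion_hr: float = 180.0  # BPM
    recovery_tol: float = 0.25  # ml/kg/min settling tolerance
    recovery_max: float = 1200.0  # s

    #: per-subject spread of physiological coupling coefficients
    vo2max_range: tuple[float, float] = (42.0, 55.0)
    coef_jitter: float = 0.15

    #: Sex effect: during treadmill levels females' true VO2 sits this many
    #: ml/kg/min below what their cardiorespiratory/motion signals would
    #: indicate under the male coupling (muscle-mass / vital-capacity
    #: difference). 0 disables the effect.
    sex_vo2_offset: float = 0.0

    rest_only: bool = False

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.vo2_bruce, self.vo2_bruce[1:])):
            raise ValueError("Bruce steady-state VO2 must be strictly increasing")


@dataclass(frozen=True)
class SubjectCoefs:
    """Per-subject physiological couplings drawn once per simulation."""

    vo2max: float  # VO2 at which HR reaches the age-predicted maximum
    rr_slope_f: float  # multiplicative jitter on the RR-VO2 slope
    amp_slope_f: float
    sway_f: float
    hr_rest: float

    def hr_of_vo2(self, vo2: np.ndarray | float, age: float, p: SimParams):
        slope = (hr_max(age) - self.hr_rest) / (self.vo2max - p.vo2_rest)
        return self.hr_rest + slope * (np.asarray(vo2, dtype=float) - p.vo2_rest)


def default_coefs(subject: SubjectInfo, params: SimParams) -> SubjectCoefs:
    """Deterministic mid-range couplings (no inter-subject spread)."""
    return SubjectCoefs(
        vo2max=float(np.mean(params.vo2max_range)),
        rr_slope_f=1.0,
        amp_slope_f=1.0,
        sway_f=1.0,
        hr_rest=params.hr_rest,
    )


def _draw_coefs(subject: SubjectInfo, params: SimParams, rng: np.random.Generator) -> SubjectCoefs:
    j = params.coef_jitter
    return SubjectCoefs(
        vo2max=float(rng.uniform(*params.vo2max_range)),
        rr_slope_f=float(rng.uniform(1 - j, 1 + j)),
        amp_slope_f=float(rng.uniform(1 - j, 1 + j)),
        sway_f=float(rng.uniform(1 - j, 1 + j)),
        hr_rest=float(params.hr_rest + rng.uniform(-5.0, 5.0)),
    )


def _steady_vo2(params: SimParams, subject: SubjectInfo, level: int) -> float:
    """Steady-state VO2 for a Bruce level, with the optional sex offset."""
    v = params.vo2_bruce[level - 1]
    if subject is not None and subject.sex == "female":
        v = max(params.vo2_rest, v - params.sex_vo2_offset)
    return v


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered activity intervals plus the internal breathing-task timeline."""

    intervals: tuple[ActivityInterval, ...]
    breathing: tuple[tuple[str, float, float], ...]  # (mode, t_start, t_end)
    n_bruce_levels: int

    @property
    def duration(self) -> float:
        return self.intervals[-1].t_end


def make_schedule(
    params: SimParams,
    subject: SubjectInfo,
    coefs: SubjectCoefs | None = None,
) -> ProtocolSchedule:
    """Build the session timeline for one subject.

    The Bruce phase is truncated at the first level whose steady-state HR
    (affine in the level's steady-state VO2) reaches the exhaustion
    threshold; that level is still run, then recovery begins. Recovery
    length is the first-order settling time toward the recovery steady
    state, capped at 20 min.
    """
    coefs = coefs or default_coefs(subject, params)
    intervals: list[ActivityInterval] = []
    breathing: list[tuple[str, float, float]] = []
    t = 0.0
    for i, posture in enumerate(REST_POSTURES):
        dur = sum(d for _, d in REST_SUBBLOCKS)
        if i < len(REST_POSTURES) - 1:
            dur += INTER_POSTURE_REST  # adjustment folded into the posture
        intervals.append(ActivityInterval(posture, t, t + dur))
        tb = t
        for mode, d in REST_SUBBLOCKS:
            breathing.append((mode, tb, tb + d))
            tb += d
        if i < len(REST_POSTURES) - 1:
            breathing.append(("normal", tb, tb + INTER_POSTURE_REST))
        t += dur

    n_levels = 0
    if not params.rest_only:
        intervals.append(ActivityInterval("walk", t, t + 180.0))
        t += 180.0
        last_vo2 = params.vo2_walk
        for level, _speed, _incline in BRUCE_STAGES:
            intervals.append(ActivityInterval(f"bruce_level_{level}", t, t + 180.0))
            t += 180.0
            n_levels = level
            last_vo2 = _steady_vo2(params, subject, level)
            # exhaustion is a heart-rate rule; HR follows the effort level
            if coefs.hr_of_vo2(params.vo2_bruce[level - 1], subject.age, params) >= params.exhaustion_hr:
                break
        delta0 = max(abs(last_vo2 - params.vo2_recovery), params.recovery_tol)
        settle = params.tau * math.log(delta0 / params.recovery_tol) + 60.0
        rec_dur = min(params.recovery_max, 60.0 * math.ceil(settle / 60.0))
        intervals.append(ActivityInterval("recovery", t, t + rec_dur))
        t += rec_dur
    return ProtocolSchedule(tuple(intervals), tuple(breathing), n_levels)


@dataclass
class SubjectTruth:
    """Hidden generative state for scoring the pipeline against truth."""

    t: np.ndarray  # 1 Hz ticks, s
    vo2: np.ndarray  # noise-free instantaneous VO2, ml/kg/min
    hr: np.ndarray  # instantaneous HR incl. AR(1) variability, BPM
    rr: np.ndarray  # instantaneous respiration rate, breaths/min
    amp: np.ndarray  # breath amplitude, a.u.
    r_peak_times: np.ndarray  # s
    breath_peak_times: np.ndarray  # s
    schedule: ProtocolSchedule


def _vo2_target_fn(
    schedule: ProtocolSchedule,
    params: SimParams,
    subject: SubjectInfo,
    with_sex_offset: bool = True,
):
    """Piecewise-constant steady-state VO2 target over the session.

    With ``with_sex_offset=False`` the unshifted ("effort") trajectory is
    returned — the one the physiological signal channels follow.
    """
    edges, targets = [], []
    for iv in schedule.intervals:
        if iv.label in REST_POSTURES:
            v = params.vo2_rest
        elif iv.label == "walk":
            v = params.vo2_walk
        elif iv.label.startswith("bruce_level_"):
            level = int(iv.label.rsplit("_", 1)[1])
            v = (
                _steady_vo2(params, subject, level)
                if with_sex_offset
                else params.vo2_bruce[level - 1]
            )
        else:  # recovery
            v = params.vo2_recovery
        edges.append(iv.t_start)
        targets.append(v)
    edges = np.asarray(edges)
    targets = np.asarray(targets)

    def target(t: float) -> float:
        return float(targets[np.searchsorted(edges, t, side="right") - 1])

    return target


def _first_order(targets: np.ndarray, dt: float, tau: float, v0: float) -> np.ndarray:
    """Exact exponential relaxation toward a piecewise-constant target."""
    decay = math.exp(-dt / tau)
    out = np.empty(len(targets))
    v = v0
    for i, g in enumerate(targets):
        v = g + (v - g) * decay
        out[i] = v
    return out


def simulate_subject(
    subject: SubjectInfo,
    params: SimParams | None = None,
    seed: int = 0,
    coefs: SubjectCoefs | None = None,
) -> tuple[Recording, SubjectTruth]:
    """Simulate one full session; returns the Recording and hidden truth."""
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    coefs = coefs or _draw_coefs(subject, params, rng)
    schedule = make_schedule(params, subject, coefs)
    duration = schedule.duration
    fs_mid = 25.0
    n_mid = int(round(duration * fs_mid))
    t_mid = np.arange(n_mid) / fs_mid

    target = _vo2_target_fn(schedule, params, subject)
    targets_mid = np.array([target(t) for t in t_mid])
    vo2_mid = _first_order(targets_mid, 1.0 / fs_mid, params.tau, params.vo2_rest)
    # signal channels follow the unshifted effort trajectory (identical to
    # vo2_mid unless a sex-specific treadmill offset is configured)
    if params.sex_vo2_offset and subject.sex == "female":
        eff_target = _vo2_target_fn(schedule, params, subject, with_sex_offset=False)
        eff_mid = _first_order(
            np.array([eff_target(t) for t in t_mid]), 1.0 / fs_mid, params.tau, params.vo2_rest
        )
    else:
        eff_mid = vo2_mid

    # --- heart rate: affine in effort + AR(1) variability ----------------
    hr_clean = coefs.hr_of_vo2(eff_mid, subject.age, params)
    n_sec = int(round(duration))
    ar = np.empty(n_sec)
    e = rng.normal(0.0, params.hr_noise_sd, n_sec)
    ar[0] = e[0]
    for i in range(1, n_sec):
        ar[i] = params.hr_noise_phi * ar[i - 1] + e[i]
    hr_mid = hr_clean + np.interp(t_mid, np.arange(n_sec), ar)
    hr_mid = np.clip(hr_mid, 40.0, hr_max(subject.age) + 5.0)

    # --- ECG: Gaussian QRS pulse train at 60/HR intervals ----------------
    fs_ecg = 200.0
    beat_times = []
    t = 0.3
    while t < duration - 0.3:
        beat_times.append(t)
        hr_here = float(np.interp(t, t_mid, hr_mid))
        jitter = 1.0 + rng.normal(0.0, params.hrv_jitter_sd)
        t += max(0.25, 60.0 / hr_here * jitter)
    beat_times = np.asarray(beat_times)
    n_ecg = int(round(duration * fs_ecg))
    ecg = np.zeros(n_ecg)
    width = 0.01  # s, QRS Gaussian sd
    half = int(round(4 * width * fs_ecg))
    for bt in beat_times:
        c = int(round(bt * fs_ecg))
        lo, hi = max(0, c - half), min(n_ecg, c + half + 1)
        tt = np.arange(lo, hi) / fs_ecg - bt
        ecg[lo:hi] += np.exp(-0.5 * (tt / width) ** 2)
    sig_rms = float(np.sqrt(np.mean(ecg**2)))
    ecg_noise_sd = sig_rms * 10 ** (-params.ecg_snr_db / 20.0)
    ecg = ecg + rng.normal(0.0, ecg_noise_sd, n_ecg)
    ecg += 0.2 * np.sin(2 * np.pi * 0.3 * np.arange(n_ecg) / fs_ecg)  # wander

    # --- respiration: sinusoid at RR(VO2), amplitude A(VO2) --------------
    rr_mid = params.rr_rest + coefs.rr_slope_f * params.rr_slope * (eff_mid - params.vo2_rest)
    amp_mid = params.amp_rest + coefs.amp_slope_f * params.amp_slope * (eff_mid - params.vo2_rest)
    for mode, t0, t1 in schedule.breathing:
        rr_m, amp_m = BREATHING_MODES[mode]
        sel = (t_mid >= t0) & (t_mid < t1)
        rr_mid[sel] *= rr_m
        amp_mid[sel] *= amp_m
    # keep breathing near the 0.1-0.35 Hz analysis band; the band-pass
    # attenuates (but preserves the peaks of) rates above 21 breaths/min
    rr_mid = np.clip(rr_mid, 6.0, 32.0)
    phase = 2 * np.pi * np.cumsum(rr_mid / 60.0) / fs_mid
    resp_clean = amp_mid * np.sin(phase)
    drift = params.resp_drift_amp * np.sin(2 * np.pi * params.resp_drift_freq * t_mid)
    resp_rms = float(np.sqrt(np.mean(resp_clean**2)))
    resp_noise_sd = resp_rms * 10 ** (-params.resp_snr_db / 20.0)
    thoracic = resp_clean + drift + params.resp_offset + rng.normal(0, resp_noise_sd, n_mid)
    abdominal = 0.8 * resp_clean + 0.7 * drift + params.resp_offset + rng.normal(
        0, resp_noise_sd, n_mid
    )
    # true breath peaks: phase crossings of pi/2 (mod 2 pi)
    k = (phase - np.pi / 2) / (2 * np.pi)
    breath_peak_times = t_mid[np.nonzero(np.diff(np.floor(k)) > 0)[0] + 1]

    # --- acceleration: gravity + gait harmonics + slow sway --------------
    speed_mid = np.zeros(n_mid)
    for iv in schedule.intervals:
        sel = (t_mid >= iv.t_start) & (t_mid < iv.t_end)
        if iv.label == "walk":
            speed_mid[sel] = 3.0
        elif iv.label.startswith("bruce_level_"):
            speed_mid[sel] = BRUCE_STAGES[int(iv.label.rsplit("_", 1)[1]) - 1][1]
        elif iv.label == "recovery":
            speed_mid[sel] = 1.5
    f_step = 1.2 + 0.18 * speed_mid  # Hz
    gait_amp = np.where(
        speed_mid > 0,
        params.gait_amp_base + params.gait_amp_slope * np.maximum(speed_mid - 3.0, 0.0),
        0.0,
    )
    gait_phase = 2 * np.pi * np.cumsum(f_step) / fs_mid
    sway_amp = coefs.sway_f * params.sway_coef * eff_mid
    sway = sway_amp * np.sin(2 * np.pi * params.sway_freq * t_mid)
    acc_x = 0.05 + gait_amp * np.sin(gait_phase) + rng.normal(0, params.acc_noise_sd, n_mid)
    acc_y = -0.03 + 0.6 * gait_amp * np.sin(2 * gait_phase) + rng.normal(
        0, params.acc_noise_sd, n_mid
    )
    acc_z = 1.0 + 0.8 * gait_amp * np.cos(gait_phase) + sway + rng.normal(
        0, params.acc_noise_sd, n_mid
    )

    # --- 1 Hz references -------------------------------------------------
    t_1hz = np.arange(n_sec, dtype=float)
    vo2_1hz = np.interp(t_1hz, t_mid, vo2_mid)
    hr_1hz = np.interp(t_1hz, t_mid, hr_mid)
    vo2_ref = np.maximum(vo2_1hz + rng.normal(0, params.vo2_noise_sd, n_sec), 0.1)
    hr_ref = np.maximum(hr_1hz + rng.normal(0, params.hr_ref_noise_sd, n_sec), 30.0)

    channels = {
        "ecg": Channel("ecg", fs_ecg, ecg),
        "resp_thoracic": Channel("resp_thoracic", fs_mid, thoracic),
        "resp_abdominal": Channel("resp_abdominal", fs_mid, abdominal),
        "acc_x": Channel("acc_x", fs_mid, acc_x),
        "acc_y": Channel("acc_y", fs_mid, acc_y),
        "acc_z": Channel("acc_z", fs_mid, acc_z),
        "vo2_ref": Channel("vo2_ref", 1.0, vo2_ref),
        "hr_ref": Channel("hr_ref", 1.0, hr_ref),
    }
    rec = Recording(subject=subject, channels=channels, activities=list(schedule.intervals))
    truth = SubjectTruth(
        t=t_1hz,
        vo2=vo2_1hz,
        hr=hr_1hz,
        rr=np.interp(t_1hz, t_mid, rr_mid),
        amp=np.interp(t_1hz, t_mid, amp_mid),
        r_peak_times=beat_times,
        breath_peak_times=breath_peak_times,
        schedule=schedule,
    )
    return rec, truth


def simulate_cohort(
    n: int,
    params: SimParams | None = None,
    seed: int = 0,
    age_range: tuple[int, int] = (20, 30),
    bmi_range: tuple[float, float] = (18.0, 25.0),
    n_male: int | None = None,
) -> list[tuple[Recording, SubjectTruth]]:
    """Simulate a cohort of n subjects with reproducible demographics.

    Demographics are drawn uniformly within the given ranges (defaults
    bracket a young-adult cohort); sexes alternate unless ``n_male`` fixes
    the male count. Per-subject seeds derive deterministically from the
    cohort seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    params = params or SimParams()
    ss = np.random.SeedSequence(seed)
    demo_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n + 1)[1:]]

    if n_male is None:
        sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]
    else:
        if not 0 <= n_male <= n:
            raise ValueError("n_male out of range")
        sexes = ["male"] * n_male + ["female"] * (n - n_male)

    out = []
    for i in range(n):
        sex = sexes[i]
        age = int(demo_rng.integers(age_range[0], age_range[1] + 1))
        height = float(
            demo_rng.uniform(165, 185) if sex == "male" else demo_rng.uniform(155, 175)
        )
        bmi = float(demo_rng.uniform(*bmi_range))
        weight = round(bmi * (height / 100.0) ** 2, 1)
        subject = SubjectInfo(
            subject_id=f"S{i + 1:03d}",
            age=age,
            sex=sex,
            height_cm=round(height, 1),
            weight_kg=weight,
        )
        out.append(simulate_subject(subject, params, seed=child_seeds[i]))
    return out
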