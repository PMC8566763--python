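"""Synthetic gaze/scotoma cohort generator with known ground truth.

The generator emulates the free-viewing study design: observers watch clips
whose salient content is summarized as a piecewise-constant *salience track*
(the single most conspicuous screen location at each moment, jumping at
Poisson times).  Control observers follow the track with high probability,
giving the consistent, center-biased scanpaths seen in normal-sighted
cohorts.  Patient observers carry a parametric sensitivity field (archetypes:
normal, peripheral loss, nasal arc, tunnel vision, central loss, blind);
their probability of detecting the salient target is attenuated by the dB
sensitivity at the target's gaze-relative location, so without compensation
they miss — and therefore under-saccade toward — damaged parts of the field.
An optional compensation gain instead biases relocation saccades toward the
damaged field regions.

Everything downstream consumes the same event schema as real data, and every
simulated trial carries its ground-truth event log, so the simulator doubles
as the oracle for event detection (when emitting raw 1,000 Hz samples) and
for mechanism-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .events import EventTrial, Fixation, Saccade
from .geometry import MONOCULAR_SCREEN, ScreenGeometry
from .perimetry import SensitivityField, hfa_locations, merge_ivf

__all__ = [
    "ARCHETYPES",
    "SalienceTrack",
    "ObserverModel",
    "CohortConfig",
    "CohortBundle",
    "make_field",
    "make_track",
    "simulate_trial",
    "make_cohort",
]

ARCHETYPES = ("normal", "peripheral", "nasal_arc", "tunnel", "central", "blind")

_BASELINE_DB = 30.0

# Detection slope/midpoint solve logistic(30 dB) ~ 0.98 and logistic(10 dB) ~ 0.3
_DETECTION_SLOPE = (np.log(0.98 / 0.02) - np.log(0.3 / 0.7)) / 20.0
_DETECTION_MID = 30.0 - np.log(0.98 / 0.02) / _DETECTION_SLOPE


@dataclass(frozen=True)
class SalienceTrack:
    """Piecewise-constant salient-target track for one clip."""

    clip: str
    duration_s: float
    jump_times_s: np.ndarray   # ascending, within (0, duration)
    positions: np.ndarray      # (n_segments, 2) deg, screen-centered

    def target_at(self, t_ms) -> np.ndarray:
        """Target position (deg) at time(s) t_ms."""
        t_s = np.atleast_1d(np.asarray(t_ms, dtype=float)) / 1000.0
        seg = np.searchsorted(self.jump_times_s, t_s, side="right")
        return self.positions[seg]


@dataclass(frozen=True)
class ObserverModel:
    """Generative scanpath parameters for one simulated observer.

    ``p_follow``: probability a detected salient target is saccaded to.
    ``center_bias_weight``/``center_bias_sd``: relocation saccades (made when
    the target is not followed) are small exploratory steps forming an AR(1)
    pull toward screen center — gaze' = w * gaze + noise — with stationary
    SD ``center_bias_sd`` deg; a high weight keeps individual relocation
    steps short, as undirected exploratory saccades are.  ``compensation_gain``: probability
    that a relocation is instead aimed at a damaged field region (top-down
    compensation).  Fixation durations are log-normal (median
    ``fix_median_ms``, log-SD ``fix_sigma``); saccade landing noise is
    isotropic Gaussian; peak velocity follows the main sequence
    ``vmax * (1 - exp(-amplitude / amp_scale))``.
    """

    p_follow: float = 0.8
    center_bias_weight: float = 0.9
    center_bias_sd: float = 6.0
    fix_median_ms: float = 280.0
    fix_sigma: float = 0.4
    landing_noise_sd: float = 1.0
    min_saccade_amp: float = 0.5   # smaller relocations merge into the fixation
    vmax: float = 500.0
    amp_scale: float = 5.0
    compensation_gain: float = 0.0
    detection_slope: float = _DETECTION_SLOPE
    detection_mid: float = _DETECTION_MID

    def __post_init__(self) -> None:
        if not (0 <= self.p_follow <= 1 and 0 <= self.compensation_gain <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.center_bias_sd, self.fix_sigma, self.landing_noise_sd) <= 0:
            raise ValueError("all spreads must be positive")

    def p_detect(self, sensitivity_db) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(
            -self.detection_slope * (np.asarray(sensitivity_db, float) - self.detection_mid)
        ))


def make_field(
    archetype: str,
    severity: float,
    layout: str = "hfa24_2",
    seed: int = 0,
    noise_sd: float = 1.0,
    tunnel_radius: float = 10.0,
) -> SensitivityField:
    """Synthesize a perimetry field of a given defect archetype.

    Baseline 30 dB plus measurement noise; the archetype's region is
    attenuated multiplicatively by ``severity`` in [0, 1] (1 = down to 0 dB).
    ``tunnel`` spares a central island of ``tunnel_radius`` deg.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    locs = hfa_locations(layout)
    ecc = np.hypot(locs[:, 0], locs[:, 1])
    if archetype == "normal":
        region = np.zeros(len(locs), dtype=bool)
    elif archetype == "peripheral":
        # partial peripheral scotoma: a 180-deg sector beyond 10 deg, at a
        # seed-chosen orientation (distinct from tunnel = full annulus)
        theta = rng.uniform(0.0, 360.0)
        ang = (np.degrees(np.arctan2(locs[:, 1], locs[:, 0])) - theta) % 360.0
        region = (ecc > 10.0) & (ang < 180.0)
    elif archetype == "nasal_arc":
        # arcuate nasal defect (nasal field = negative x in right-eye charts)
        region = (locs[:, 0] <= -9.0) & (ecc >= 9.0)
    elif archetype == "tunnel":
        region = ecc > tunnel_radius
    elif archetype == "central":
        region = ecc <= 10.0
    else:  # blind
        region = np.ones(len(locs), dtype=bool)
    base = _BASELINE_DB + (rng.normal(0.0, noise_sd, len(locs)) if noise_sd > 0 else 0.0)
    sens = np.clip(base, 0.0, 40.0) * (1.0 - severity * region)
    sens = np.clip(sens, 0.0, 40.0)
    fld = SensitivityField(layout=layout, locations=locs, sensitivity=sens,
                           eye="right", md=float(np.mean(sens) - _BASELINE_DB))
    return fld


def make_track(
    duration_s: float,
    jump_rate_per_s: float = 0.5,
    spread_deg: tuple[float, float] = (16.0, 10.0),
    seed: int = 0,
    clip: str = "clip",
) -> SalienceTrack:
    """Poisson-jumping salient target, uniform within a margin-inset box."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_jumps = rng.poisson(jump_rate_per_s * duration_s)
    jump_times = np.sort(rng.uniform(0.0, duration_s, n_jumps))
    positions = rng.uniform(
        [-spread_deg[0], -spread_deg[1]], [spread_deg[0], spread_deg[1]],
        size=(n_jumps + 1, 2),
    )
    return SalienceTrack(clip=clip, duration_s=duration_s,
                         jump_times_s=jump_times, positions=positions)


def _main_sequence_duration_ms(amplitude: float) -> float:
    # classic linear amplitude-duration relation
    return 2.2 * amplitude + 21.0


def simulate_trial(
    track: SalienceTrack,
    fld: SensitivityField,
    model: ObserverModel,
    rng: np.random.Generator,
    participant: str = "sim",
    geometry: ScreenGeometry = MONOCULAR_SCREEN,
) -> EventTrial:
    """Generate one trial's fixations and saccades.

    The loop alternates fixation (log-normal duration) and saccade.  At each
    fixation end the salient target's gaze-relative location is tested
    against the observer's sensitivity field; a detected-and-followed target
    draws a saccade to it (plus landing noise), otherwise the gaze relocates
    with center bias or, with probability ``compensation_gain``, toward a
    damaged field region.  Peak velocity and duration come from the main
    sequence.  The trial's events ARE the ground truth.
    """
    half_w, half_h = (s / 2 for s in geometry.subtense_deg)
    damaged = fld.locations[fld.sensitivity < 20.0]
    trial = EventTrial(participant=participant, clip=track.clip)
    t = 0.0
    gaze = np.zeros(2)
    end_ms = track.duration_s * 1000.0
    w = model.center_bias_weight
    reloc_sd = model.center_bias_sd * np.sqrt(max(1.0 - w**2, 1e-9))
    fix_start = 0.0
    while t < end_ms:
        dur = rng.lognormal(np.log(model.fix_median_ms), model.fix_sigma)
        fix_off = min(t + dur, end_ms)
        if fix_off >= end_ms:
            t = end_ms
            break
        target = track.target_at(fix_off)[0]
        rel = target - gaze
        sens = float(fld.sensitivity_at(rel[0], rel[1])[0])
        detected = rng.random() < model.p_detect(sens)
        if detected and rng.random() < model.p_follow:
            dest = target + rng.normal(0.0, model.landing_noise_sd, 2)
        elif len(damaged) and rng.random() < model.compensation_gain:
            dest = gaze + damaged[rng.integers(len(damaged))] \
                + rng.normal(0.0, model.landing_noise_sd, 2)
        else:
            dest = w * gaze + rng.normal(0.0, reloc_sd, 2)
        dest = np.clip(dest, [-half_w, -half_h], [half_w, half_h])
        amp = float(np.hypot(*(dest - gaze)))
        if amp < model.min_saccade_amp:
            # sub-detectable relocation: the fixation simply continues
            t = fix_off
            continue
        trial.fixations.append(Fixation(fix_start, fix_off, gaze[0], gaze[1],
                                        participant, track.clip))
        sdur = _main_sequence_duration_ms(amp)
        sac_off = min(fix_off + sdur, end_ms)
        if sac_off >= end_ms:
            t = end_ms
            fix_start = end_ms
            break
        pv = model.vmax * (1.0 - np.exp(-amp / model.amp_scale))
        trial.saccades.append(Saccade.from_endpoints(
            fix_off, sac_off, gaze[0], gaze[1], dest[0], dest[1],
            peak_velocity=pv, participant=participant, clip=track.clip,
        ))
        gaze = dest
        t = sac_off
        fix_start = sac_off
    if t > fix_start:
        trial.fixations.append(Fixation(fix_start, t, gaze[0], gaze[1],
                                        participant, track.clip))
    return trial


def emit_samples(trial: EventTrial, rate_hz: float = 1000.0,
                 jitter_sd_deg: float = 0.0,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Render a trial as a uniformly sampled gaze trace.

    Fixations hold position (plus optional jitter); saccades follow a
    raised-cosine position profile between their endpoints, which gives the
    bell-shaped velocity course of real saccades.  Used to exercise event
    detection against the trial's own ground truth.
    """
    events = sorted(trial.fixations + trial.saccades, key=lambda e: e.onset)
    if not events:
        return pd.DataFrame(columns=["t_ms", "x_deg", "y_deg"])
    dt = 1000.0 / rate_hz
    t0 = events[0].onset
    t1 = events[-1].offset
    ts = t0 + dt * np.arange(int(np.floor((t1 - t0) / dt)) + 1)
    onsets = np.array([e.onset for e in events])
    idx = np.clip(np.searchsorted(onsets, ts, side="right") - 1, 0, len(events) - 1)
    xs = np.empty(len(ts))
    ys = np.empty(len(ts))
    rng = rng or np.random.default_rng(0)
    for k, ev in enumerate(events):
        sel = idx == k
        if not sel.any():
            continue
        if isinstance(ev, Fixation):
            xs[sel] = ev.x
            ys[sel] = ev.y
            if jitter_sd_deg > 0:
                xs[sel] += rng.normal(0, jitter_sd_deg, sel.sum())
                ys[sel] += rng.normal(0, jitter_sd_deg, sel.sum())
        else:
            phase = np.clip((ts[sel] - ev.onset) / (ev.offset - ev.onset), 0, 1)
            s = 0.5 * (1 - np.cos(np.pi * phase))  # 0 -> 1, bell velocity
            xs[sel] = ev.x0 + (ev.x1 - ev.x0) * s
            ys[sel] = ev.y0 + (ev.y1 - ev.y0) * s
    return pd.DataFrame({"t_ms": ts, "x_deg": xs, "y_deg": ys})


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of a simulated cohort.

    Defaults emulate the monocular free-viewing regime at a desk-scale size;
    ``binocular=True`` switches observers to their best-location integrated
    field (the binocular regime), which for asymmetric two-eye defects
    largely restores normal detection.
    """

    n_controls: int = 12
    n_patients: int = 12
    n_clips: int = 6
    clip_duration_s: float = 30.0
    jump_rate_per_s: float = 0.5
    archetype_mix: tuple = ("tunnel", "peripheral", "central", "nasal_arc")
    severity: float = 1.0
    covered_eye_severity_factor: float = 0.5  # asymmetric bilateral loss:
    # the covered eye carries the same defect at half severity, so its
    # damaged regions still fall below the 20 dB penalty threshold
    binocular: bool = False
    compensation_gain: float = 0.0
    field_noise_sd: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be >= 0")


@dataclass
class CohortBundle:
    """Everything a study consumes, with ground truth attached."""

    config: CohortConfig
    tracks: list[SalienceTrack]
    trials: list[EventTrial]                      # all participants x clips
    groups: dict[str, str]                        # participant -> control|patient
    fields: dict[str, dict]                       # participant -> tested/covered/effective
    archetypes: dict[str, str]

    def trials_of(self, participant: str) -> list[EventTrial]:
        return [t for t in self.trials if t.participant == participant]

    def control_trials(self) -> list[EventTrial]:
        return [t for t in self.trials
                if self.groups[t.participant] == "control"]

    def participants(self, group: str | None = None) -> list[str]:
        pids = sorted(self.groups)
        if group is None:
            return pids
        return [p for p in pids if self.groups[p] == group]


def make_cohort(config: CohortConfig = CohortConfig()) -> CohortBundle:
    """Simulate a full cohort, deterministic per master seed.

    Controls carry intact fields; patients cycle through
    ``config.archetype_mix`` with severity ``config.severity`` in the tested
    eye and ``severity * covered_eye_severity_factor`` in the covered eye.
    Monocular regime drives the observer with the tested-eye field; the
    binocular regime with the best-location merge of both eyes.
    """
    root = np.random.SeedSequence(config.master_seed)
    track_ss, obs_ss, field_ss = root.spawn(3)
    n_obs = config.n_controls + config.n_patients
    field_seeds = field_ss.generate_state(2 * max(n_obs, 1)) % (2**31)
    track_seeds = track_ss.generate_state(config.n_clips)
    tracks = [
        make_track(config.clip_duration_s, config.jump_rate_per_s,
                   seed=int(s % (2**31)), clip=f"clip{i:02d}")
        for i, s in enumerate(track_seeds)
    ]
    trials: list[EventTrial] = []
    groups: dict[str, str] = {}
    fields: dict[str, dict] = {}
    archetypes: dict[str, str] = {}
    obs_children = obs_ss.spawn(config.n_controls + config.n_patients)

    def run_observer(pid: str, fld: SensitivityField, model: ObserverModel,
                     ss: np.random.SeedSequence) -> None:
        rng = np.random.default_rng(ss)
        for track in tracks:
            trials.append(simulate_trial(track, fld, model, rng, participant=pid))

    idx = 0
    for i in range(config.n_controls):
        pid = f"C{i:03d}"
        groups[pid] = "control"
        archetypes[pid] = "normal"
        tested = make_field("normal", 0.0, seed=int(field_seeds[2 * idx]),
                            noise_sd=config.field_noise_sd)
        covered = make_field("normal", 0.0, seed=int(field_seeds[2 * idx + 1]),
                             noise_sd=config.field_noise_sd)
        effective = merge_ivf(tested, covered) if config.binocular else tested
        fields[pid] = {"tested": tested, "covered": covered, "effective": effective}
        run_observer(pid, effective, ObserverModel(), obs_children[idx])
        idx += 1
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        groups[pid] = "patient"
        arch = config.archetype_mix[i % len(config.archetype_mix)]
        archetypes[pid] = arch
        tested = make_field(arch, config.severity, seed=int(field_seeds[2 * idx]),
                            noise_sd=config.field_noise_sd)
        covered = make_field(
            arch, config.severity * config.covered_eye_severity_factor,
            seed=int(field_seeds[2 * idx + 1]), noise_sd=config.field_noise_sd,
        )
        effective = merge_ivf(tested, covered) if config.binocular else tested
        fields[pid] = {"tested": tested, "covered": covered, "effective": effective}
        model = ObserverModel(compensation_gain=config.compensation_gain)
        run_observer(pid, effective, model, obs_children[idx])
        idx += 1
    return CohortBundle(config=config, tracks=tracks, trials=trials,
                        groups=groups, fields=fields, archetypes=archetypes)
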