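"""Synthetic IMU cohort generator for the one-minute dual-task 360° turning test.

The generator emulates the signal content the sensor metrics are built on:

* shin accelerometers (AP/ML, in g) carry a stepping oscillation inside the
  0.5-3 Hz locomotion band while the subject turns;
* trembling freezing superimposes a 3-8 Hz leg-oscillation burst and
  suppresses the stepping component;
* akinetic freezing attenuates all deterministic motion toward the sensor
  noise floor;
* the lumbar gyroscope yaw channel (deg/s) rotates in alternating directions
  — direction flips after each completed 360° — and pauses during episodes,
  so freezers complete fewer turns.

Signals are sums of sinusoids with slow frequency jitter plus white Gaussian
sensor noise; episode boundaries are snapped to the sample grid so the
sample-mask %TF and the annotation %TF agree exactly.  Everything is driven
by :class:`numpy.random.Generator` streams spawned from a single seed, so a
cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .annotations import (
    AnnotationSummary,
    SubjectRecord,
    assign_subgroup,
    percent_time_frozen,
)
from .io import Episode, FogAnnotation, IMUTrial

FREEZE_BAND = (3.0, 8.0)
LOCOMOTION_BAND = (0.5, 3.0)


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-subject generative parameters.

    Attributes
    ----------
    is_freezer : bool
        Ground-truth freezer status; non-freezers get no episodes.
    awareness_prob : float
        Probability a freezer self-reports freezing on the questionnaire
        (freezers are frequently unaware of their own episodes).
    episode_rate : float
        Expected episodes per minute (>= 0).
    mean_episode_dur_s : float
        Mean episode duration in seconds (> 0).
    trembling_fraction : float
        Probability an episode is trembling-type (else akinetic).
    trembling_freq_hz : float
        Leg-oscillation frequency during trembling episodes; must lie in the
        3-8 Hz freeze band.
    akinetic_suppression : float
        Amplitude multiplier in [0, 1) applied to all deterministic shin
        motion during akinetic episodes (residual is sensor noise).
    cadence_hz : float
        Stepping frequency during turning, inside the 0.5-3 Hz locomotion band.
    turn_rate_dps : float
        Mean yaw speed while turning, deg/s (> 0).
    turn_overshoot_deg : float
        Rotation past the full 360° before the direction flips; subjects do
        not reverse on the exact degree, and the margin keeps a completed
        turn unambiguous under low-pass filtering.
    """

    is_freezer: bool = False
    awareness_prob: float = 0.2115  # 22 aware of 104 expert-rated freezers
    episode_rate: float = 0.0
    mean_episode_dur_s: float = 5.0
    trembling_fraction: float = 0.31  # 43 trembling of 140 annotated episodes
    trembling_freq_hz: float = 5.0
    akinetic_suppression: float = 0.05
    cadence_hz: float = 1.8
    turn_rate_dps: float = 70.0
    turn_overshoot_deg: float = 20.0
    # signal amplitudes (g) and noise levels; the trembling amplitude is the
    # spectral effect size separating freezers from non-freezers
    loco_amp_ap_g: float = 0.30
    loco_amp_ml_g: float = 0.22
    tremble_amp_g: float = 0.25
    tremble_loco_suppression: float = 0.2
    noise_g: float = 0.02
    gyro_noise_dps: float = 2.0
    yaw_osc_dps: float = 20.0
    # freezing normally halts the rotation; disable to isolate the purely
    # spectral freezer/non-freezer contrast
    pause_turning_during_episodes: bool = True

    def validate(self) -> "PhenotypeParams":
        for name in ("awareness_prob", "trembling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        if self.mean_episode_dur_s <= 0:
            raise ValueError("mean_episode_dur_s must be > 0")
        if not FREEZE_BAND[0] <= self.trembling_freq_hz <= FREEZE_BAND[1]:
            raise ValueError(
                f"trembling_freq_hz={self.trembling_freq_hz} outside the "
                f"{FREEZE_BAND} Hz freeze band"
            )
        if not 0.0 <= self.akinetic_suppression < 1.0:
            raise ValueError("akinetic_suppression must be in [0, 1)")
        if not LOCOMOTION_BAND[0] <= self.cadence_hz <= LOCOMOTION_BAND[1]:
            raise ValueError(
                f"cadence_hz={self.cadence_hz} outside the {LOCOMOTION_BAND} Hz "
                "locomotion band"
            )
        if self.turn_rate_dps <= 0:
            raise ValueError("turn_rate_dps must be > 0")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Exact episode intervals and labels the generator injected."""

    episodes: tuple[Episode, ...]
    true_subgroup: str
    self_report: bool

    def annotation(self, trial_duration_s: float, rater_id: str = "ground_truth") -> FogAnnotation:
        return FogAnnotation(
            rater_id=rater_id,
            episodes=list(self.episodes),
            trial_duration_s=trial_duration_s,
        ).validate()


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of the synthetic cohort.

    Defaults reproduce the group structure of the validation cohort: 63.4%
    expert-rated freezers, 21.2% of whom self-report, and a 10% chance that a
    subject without observable episodes self-reports (a "possible" freezer).
    """

    n_subjects: int = 164
    freezer_prevalence: float = 104 / 164
    possible_freezer_prob: float = 0.10
    trial_duration_s: float = 60.0
    sample_rate_hz: float = 128.0
    seed: int = 0
    # (mean, sd) per drawn phenotype parameter; sd 0 means fixed
    phenotype_distributions: dict = field(
        default_factory=lambda: {
            "episode_rate": (1.35, 0.6),
            "mean_episode_dur_s": (5.0, 2.0),
            "trembling_freq_hz": (5.0, 1.0),
            "akinetic_suppression": (0.05, 0.02),
            "cadence_hz": (1.8, 0.25),
            "turn_rate_dps": (70.0, 20.0),
            "tremble_amp_g": (0.25, 0.05),
        }
    )
    base_phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)

    def validate(self) -> "CohortConfig":
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be > 0")
        if self.sample_rate_hz <= 2 * FREEZE_BAND[1]:
            raise ValueError(
                f"sample_rate_hz={self.sample_rate_hz} must exceed twice the "
                f"{FREEZE_BAND[1]} Hz upper freeze-band edge"
            )
        if not 0.0 <= self.freezer_prevalence <= 1.0:
            raise ValueError("freezer_prevalence must be in [0, 1]")
        return self


_PARAM_CLIPS = {
    "episode_rate": (0.2, 6.0),
    "mean_episode_dur_s": (1.0, 20.0),
    "trembling_freq_hz": (3.2, 7.8),
    "akinetic_suppression": (0.0, 0.3),
    "cadence_hz": (0.8, 2.8),
    "turn_rate_dps": (20.0, 200.0),
    "tremble_amp_g": (0.0, 0.6),
}


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, tau_s: float = 1.0) -> np.ndarray:
    """Unit-variance noise low-passed by a Hann kernel of width ``tau_s``."""
    z = rng.standard_normal(n)
    k = np.hanning(max(3, int(round(tau_s * fs))))
    k /= k.sum()
    out = np.convolve(z, k, mode="same")
    sd = out.std()
    return out / sd if sd > 0 else out


def _place_episodes(
    rng: np.random.Generator,
    params: PhenotypeParams,
    duration_s: float,
    sample_rate_hz: float,
    min_gap_s: float = 1.0,
) -> list[Episode]:
    """Draw non-overlapping episodes with >= 1 s gaps, snapped to the sample grid."""
    if not params.is_freezer or params.episode_rate == 0:
        return []
    n_target = max(1, rng.poisson(params.episode_rate * duration_s / 60.0))
    while n_target >= 1:
        durations = rng.gamma(shape=2.0, scale=params.mean_episode_dur_s / 2.0, size=n_target)
        durations = np.clip(durations, 1.0, duration_s / 2.0)
        placed: list[tuple[float, float]] = []
        ok = True
        for dur in durations:
            for _attempt in range(200):
                start = rng.uniform(0.0, duration_s - dur)
                end = start + dur
                if all(
                    end + min_gap_s <= s or e + min_gap_s <= start for s, e in placed
                ):
                    placed.append((start, end))
                    break
            else:
                ok = False
                break
        if ok:
            break
        n_target -= 1  # infeasible packing: retry with fewer episodes
    else:
        return []
    placed.sort()
    dt = 1.0 / sample_rate_hz
    episodes = []
    for start, end in placed:
        s = round(start / dt) * dt
        e = round(end / dt) * dt
        ep_type = "trembling" if rng.random() < params.trembling_fraction else "akinetic"
        episodes.append(Episode(s, e, ep_type))
    return episodes


def _oscillation(rng, n, fs, freq_hz, jitter=0.03):
    """Unit-amplitude sinusoid with slow multiplicative frequency jitter."""
    f_inst = freq_hz * (1.0 + jitter * _smooth_noise(rng, n, fs, tau_s=2.0))
    phase = 2.0 * np.pi * cumulative_trapezoid(f_inst, dx=1.0 / fs, initial=0.0)
    phase0 = rng.uniform(0, 2 * np.pi)
    return np.sin(phase + phase0), phase + phase0


def simulate_trial(
    params: PhenotypeParams,
    duration_s: float = 60.0,
    sample_rate_hz: float = 128.0,
    seed: int | np.random.SeedSequence | None = 0,
    subject_id: str = "synthetic",
    self_report: bool | None = None,
    episodes: list[Episode] | None = None,
) -> tuple[IMUTrial, GroundTruth]:
    """Simulate one subject's turning trial and its exact ground truth.

    Returns the multi-sensor recording and a :class:`GroundTruth` whose
    episode list is exact (the video gold standard is emulated by construction,
    not re-detected).  Pass ``episodes`` to inject a fixed episode layout
    instead of drawing one.
    """
    params.validate()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate_hz <= 2 * FREEZE_BAND[1]:
        raise ValueError(
            f"sample_rate_hz={sample_rate_hz} is below Nyquist for the "
            f"{FREEZE_BAND[1]} Hz freeze-band edge"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    if episodes is None:
        episodes = _place_episodes(rng, params, duration_s, sample_rate_hz)
    else:
        episodes = sorted(episodes, key=lambda e: e.start_s)
    tremble_mask = np.zeros(n, dtype=bool)
    akinetic_mask = np.zeros(n, dtype=bool)
    for ep in episodes:
        i0 = int(round(ep.start_s * sample_rate_hz))
        i1 = int(round(ep.end_s * sample_rate_hz))
        (tremble_mask if ep.type == "trembling" else akinetic_mask)[i0:i1] = True
    episode_mask = tremble_mask | akinetic_mask

    # locomotion (stepping) oscillation; left/right legs in antiphase
    step, _ = _oscillation(rng, n, sample_rate_hz, params.cadence_hz)
    step_r = -step
    loco_env = np.ones(n)
    loco_env[tremble_mask] = params.tremble_loco_suppression
    loco_env[akinetic_mask] = params.akinetic_suppression

    tremble, _ = _oscillation(rng, n, sample_rate_hz, params.trembling_freq_hz, jitter=0.02)
    tremble_env = np.where(tremble_mask, 1.0, 0.0)

    def shin(step_sig, tremble_sign):
        amp_mod = 1.0 + 0.1 * _smooth_noise(rng, n, sample_rate_hz, tau_s=2.0)
        ap = (
            params.loco_amp_ap_g * amp_mod * loco_env * step_sig
            + params.tremble_amp_g * tremble_env * tremble * tremble_sign
            + params.noise_g * rng.standard_normal(n)
        )
        ml = (
            params.loco_amp_ml_g * amp_mod * loco_env * step_sig
            + 0.8 * params.tremble_amp_g * tremble_env * tremble * tremble_sign
            + params.noise_g * rng.standard_normal(n)
        )
        v = (
            1.0
            + 0.1 * params.loco_amp_ap_g * loco_env * np.abs(step_sig)
            + params.noise_g * rng.standard_normal(n)
        )
        return {"AP": ap, "ML": ml, "V": v}

    shin_left = shin(step, 1.0)
    shin_right = shin(step_r, -1.0)

    # lumbar yaw: alternating-direction rotation, paused during episodes
    dt = 1.0 / sample_rate_hz
    yaw = np.zeros(n)
    direction = 1.0 if rng.random() < 0.5 else -1.0
    seg_angle = 0.0
    pause = episode_mask if params.pause_turning_during_episodes else np.zeros(n, dtype=bool)
    for i in range(n):
        rate = 0.0 if pause[i] else direction * params.turn_rate_dps
        yaw[i] = rate
        seg_angle += abs(rate) * dt
        if seg_angle >= 360.0 + params.turn_overshoot_deg:
            direction = -direction
            seg_angle = 0.0
    yaw = yaw + params.yaw_osc_dps * np.where(pause, 0.0, step) * np.sign(yaw + 1e-12)
    yaw = yaw + params.gyro_noise_dps * rng.standard_normal(n) if params.gyro_noise_dps > 0 else yaw
    pitch = params.gyro_noise_dps * rng.standard_normal(n) + 5.0 * loco_env * step
    roll = params.gyro_noise_dps * rng.standard_normal(n) + 5.0 * loco_env * step_r

    trial = IMUTrial(
        subject_id=subject_id,
        sample_rate_hz=sample_rate_hz,
        duration_s=duration_s,
        shin_left=shin_left,
        shin_right=shin_right,
        lumbar_gyro={"yaw": yaw, "pitch": pitch, "roll": roll},
    ).validate()

    expert = len(episodes) > 0
    if self_report is None:
        self_report = bool(rng.random() < params.awareness_prob) if params.is_freezer else False
    truth = GroundTruth(
        episodes=tuple(episodes),
        true_subgroup=assign_subgroup(self_report, expert),
        self_report=bool(self_report),
    )
    return trial, truth


def _draw_phenotype(
    rng: np.random.Generator, config: CohortConfig, is_freezer: bool
) -> PhenotypeParams:
    drawn = {}
    for name, (mean, sd) in config.phenotype_distributions.items():
        v = rng.normal(mean, sd) if sd > 0 else mean
        lo, hi = _PARAM_CLIPS.get(name, (-np.inf, np.inf))
        drawn[name] = float(np.clip(v, lo, hi))
    if not is_freezer:
        drawn["episode_rate"] = 0.0
    return replace(config.base_phenotype, is_freezer=is_freezer, **drawn).validate()


def simulate_cohort(
    config: CohortConfig,
) -> list[tuple[SubjectRecord, IMUTrial, GroundTruth]]:
    """Simulate a full cohort: records, recordings and exact ground truth.

    Freezer status is Bernoulli(freezer_prevalence); freezers self-report
    with ``awareness_prob``; episode-free subjects self-report with
    ``possible_freezer_prob`` (the "possible freezer" phenomenon).  The
    subject's record derives its subgroup and %TF summary from the generated
    episodes exactly as the analysis pipeline would from expert annotations.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_subjects + 1)
    cohort_rng = np.random.default_rng(streams[0])
    out = []
    for i in range(config.n_subjects):
        is_freezer = bool(cohort_rng.random() < config.freezer_prevalence)
        params = _draw_phenotype(cohort_rng, config, is_freezer)
        if is_freezer:
            self_report = bool(cohort_rng.random() < params.awareness_prob)
        else:
            self_report = bool(cohort_rng.random() < config.possible_freezer_prob)
        if self_report:
            nfogq = int(np.clip(round(cohort_rng.normal(13.5, 6.7)), 1, 28))
        else:
            nfogq = 0
        subject_id = f"S{i:04d}"
        trial, truth = simulate_trial(
            params,
            duration_s=config.trial_duration_s,
            sample_rate_hz=config.sample_rate_hz,
            seed=streams[i + 1],
            subject_id=subject_id,
            self_report=self_report,
        )
        summary = percent_time_frozen(truth.annotation(config.trial_duration_s))
        expert = len(truth.episodes) > 0
        record = SubjectRecord(
            subject_id=subject_id,
            self_report_fog=self_report,
            nfogq_total=nfogq,
            expert_freezer=expert,
            subgroup=assign_subgroup(self_report, expert),
            annotation_summary=summary,
            covariates={"is_freezer": is_freezer, **{k: getattr(params, k) for k in _PARAM_CLIPS}},
        )
        out.append((record, trial, truth))
    return out


def cohort_table(cohort: list[tuple[SubjectRecord, IMUTrial, GroundTruth]]) -> pd.DataFrame:
    """Flatten a simulated cohort into the cohort-table CSV layout."""
    rows = []
    for record, _trial, truth in cohort:
        summ = record.annotation_summary
        rows.append(
            {
                "subject_id": record.subject_id,
                "self_report": int(record.self_report_fog),
                "nfogq_total": record.nfogq_total,
                "expert_freezer": int(record.expert_freezer),
                "subgroup": record.subgroup,
                "tf_total_pct": summ.tf_total_pct if summ else np.nan,
                "tf_trembling_pct": summ.tf_trembling_pct if summ else np.nan,
                "tf_akinetic_pct": summ.tf_akinetic_pct if summ else np.nan,
                **record.covariates,
            }
        )
    return pd.DataFrame(rows)
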