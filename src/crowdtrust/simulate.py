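"""Synthetic videos, classifier and worker cohorts.

The study's raw worker data are not deposited, so this module generates
datasets that emulate the task mechanics end to end: a balanced set of
videos, each with a latent "ideal" answer vector that the ground-truth
logistic classifier scores confidently for the correct class; a worker
population spanning diligent raters, noisy raters and lazy (copy-paste)
raters; a minimum-time warning with optional revisions; and a re-rating
of the same videos at a second administration.

Worker behavior model
---------------------
Each worker carries a diligence level d in [0, 1] and a habitual
"default" answer vector. On each question the worker answers near the
video's ideal vector with probability d (the ideal code plus rounded,
clipped Gaussian noise) and otherwise falls back on their default answer.
Lazy workers always emit their default vector. This anchoring mechanism
reproduces the key empirical pattern the metrics are built to detect:
workers whose answers collapse onto one vector have both a low mean
pairwise internal L1 distance and a mean PCC near chance, so the
generator-implied correlation between MPIL1 and mean PCC is positive.

With ``couple_quality=False`` the generator switches to a null mode: no
lazy workers, and rating speed, revision effort and revision moves are
drawn independently of diligence, so the time-based trust signals carry
no information about performance. This makes negative findings (the
penalized-time c-sweep) testable as well as positive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import ClassifierSpec, pcc, predict_probability
from .config import StudyConfig
from .data_model import AUTISM, NEUROTYPICAL, VideoRecord, WorkerResponse
from .exceptions import GenerationError


@dataclass(frozen=True)
class WorkerProfile:
    """Latent behavioral parameters of one simulated worker."""

    worker_id: str
    diligence: float
    answer_noise_sd: float
    retest_drift_sd: float
    time_rate_s: float
    lazy: bool
    revise_effort: float
    default_answers: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.diligence <= 1.0:
            raise ValueError("diligence must lie in [0, 1]")
        if not 0.0 <= self.revise_effort <= 1.0:
            raise ValueError("revise_effort must lie in [0, 1]")
        if self.answer_noise_sd < 0 or self.retest_drift_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.time_rate_s <= 0:
            raise ValueError("time_rate_s must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults emulate the study conditions: 24 videos balanced between the
    two classes, 60 workers, 13 questions with 4 ordinal levels each, a
    120 s warning threshold, and a second administration of every video.
    """

    n_videos: int = 24
    n_workers: int = 60
    class_balance: float = 0.5
    M: int = 13
    levels: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    T_s: float = 120.0
    seed: int = 0
    retest: bool = True
    couple_quality: bool = True
    lazy_fraction: float = 0.15
    answer_noise_sd: float = 0.8
    retest_drift_sd: float = 0.5
    skip_retest_scale: float = 0.5
    ideal_min_pcc: float = 0.8

    def __post_init__(self) -> None:
        if self.levels is None:
            object.__setattr__(self, "levels", (4,) * self.M)
        else:
            object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))
        if self.n_videos < 2 or self.n_workers < 1:
            raise ValueError("need n_videos >= 2 and n_workers >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie strictly in (0, 1)")
        if len(self.levels) != self.M:
            raise ValueError("levels length must equal M")
        if not 0.5 <= self.ideal_min_pcc < 1.0:
            raise ValueError("ideal_min_pcc must lie in [0.5, 1)")


@dataclass(frozen=True)
class SimulatedStudy:
    """Everything one simulated study produces, latent truth included."""

    videos: list[VideoRecord]
    ideal_answers: dict[str, tuple[int, ...]]
    classifier: ClassifierSpec
    profiles: list[WorkerProfile]
    responses: list[WorkerResponse]
    sim_config: SimulationConfig
    study_config: StudyConfig


def study_config_for(sim: SimulationConfig, **overrides) -> StudyConfig:
    """StudyConfig matching a simulation's task mechanics."""
    kwargs = dict(T_s=sim.T_s, M=sim.M, levels=sim.levels, seed=sim.seed)
    kwargs.update(overrides)
    return StudyConfig(**kwargs)


def simulate_ground_truth_classifier(
    config: SimulationConfig, rng: np.random.Generator
) -> ClassifierSpec:
    """Draw ground-truth logistic weights, calibrated at the neutral vector.

    Weights are standard-normal (symmetric, at least one nonzero); the
    intercept is set so the mid-scale "neutral" answer vector scores
    exactly 0.5, anchoring the probability scale.
    """
    for _ in range(100):
        w = rng.normal(0.0, 1.0, size=config.M)
        if np.max(np.abs(w)) > 1e-8:
            break
    else:  # pragma: no cover - probability ~0
        raise GenerationError("could not draw nonzero classifier weights")
    neutral = (np.asarray(config.levels, dtype=float) - 1.0) / 2.0
    intercept = -float(w @ neutral)
    return ClassifierSpec(weights=tuple(w), intercept=intercept, positive_class=AUTISM)


def simulate_videos(
    config: SimulationConfig,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    id_prefix: str = "v",
) -> tuple[list[VideoRecord], dict[str, tuple[int, ...]]]:
    """Generate videos with latent ideal answer vectors.

    Class counts match ``class_balance`` exactly (deterministic rounding).
    Each ideal vector is drawn so the ground-truth classifier assigns the
    correct class a probability of at least ``ideal_min_pcc``: per
    question, with growing strength across retries, the answer is pushed
    to the class-consistent extreme of its scale, remaining uniform
    otherwise so ideal vectors vary within a class.
    """
    n_autism = round(config.n_videos * config.class_balance)
    labels = [AUTISM] * n_autism + [NEUROTYPICAL] * (config.n_videos - n_autism)
    levels = np.asarray(config.levels)
    w = np.asarray(spec.weights)

    videos: list[VideoRecord] = []
    ideals: dict[str, tuple[int, ...]] = {}
    width = len(str(config.n_videos))
    for i, label in enumerate(labels, start=1):
        sign = 1.0 if label == AUTISM else -1.0
        extreme = np.where(sign * w > 0, levels - 1, 0)
        vec = None
        for strength in np.linspace(0.7, 1.0, 40):
            keep = rng.random(config.M) < strength
            cand = np.where(keep, extreme, rng.integers(0, levels))
            p = predict_probability(cand, spec)
            if pcc(p, label) >= config.ideal_min_pcc:
                vec = cand
                break
        if vec is None:
            raise GenerationError(
                f"could not place an ideal vector for a {label} video with "
                f"PCC >= {config.ideal_min_pcc}"
            )
        vid = f"{id_prefix}{i:0{width}d}"
        videos.append(
            VideoRecord(
                video_id=vid, true_class=label, duration_s=float(rng.uniform(20, 90))
            )
        )
        ideals[vid] = tuple(int(a) for a in vec)
    return videos, ideals


def simulate_worker_profiles(
    config: SimulationConfig, rng: np.random.Generator, id_prefix: str = "w"
) -> list[WorkerProfile]:
    """Draw a worker population.

    Diligence is Beta(2, 2). In coupled mode a ``lazy_fraction`` of
    workers are copy-paste raters (their diligence is forced low and they
    rate fast), rating speed rises with diligence, and revision effort
    equals diligence; in null mode speed and revision effort are drawn
    independently of diligence and nobody is lazy.
    """
    levels = np.asarray(config.levels)
    out: list[WorkerProfile] = []
    width = len(str(config.n_workers))
    for i in range(1, config.n_workers + 1):
        diligence = float(rng.beta(2.0, 2.0))
        lazy = bool(config.couple_quality and rng.random() < config.lazy_fraction)
        if lazy:
            diligence = min(diligence, float(rng.uniform(0.05, 0.3)))
        if config.couple_quality:
            if lazy:
                time_rate = float(rng.uniform(40.0, 140.0))
            else:
                time_rate = float(
                    np.clip(90.0 + 120.0 * diligence + rng.normal(0.0, 15.0), 30.0, None)
                )
            revise_effort = diligence
        else:
            time_rate = float(rng.uniform(90.0, 210.0))
            revise_effort = float(rng.uniform(0.0, 1.0))
        out.append(
            WorkerProfile(
                worker_id=f"{id_prefix}{i:0{width}d}",
                diligence=diligence,
                answer_noise_sd=config.answer_noise_sd,
                retest_drift_sd=config.retest_drift_sd,
                time_rate_s=time_rate,
                lazy=lazy,
                revise_effort=revise_effort,
                default_answers=tuple(int(a) for a in rng.integers(0, levels)),
            )
        )
    return out


def _draw_answers(
    ideal: np.ndarray,
    profile: WorkerProfile,
    levels: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    if profile.lazy:
        return profile.default_answers
    default = np.asarray(profile.default_answers)
    near_ideal = np.rint(ideal + rng.normal(0.0, noise_sd, size=ideal.size))
    near_ideal = np.clip(near_ideal, 0, levels - 1)
    use_ideal = rng.random(ideal.size) < profile.diligence
    return tuple(int(a) for a in np.where(use_ideal, near_ideal, default))


def simulate_responses(
    profiles: Sequence[WorkerProfile],
    videos: Sequence[VideoRecord],
    ideal_answers: dict[str, tuple[int, ...]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[WorkerResponse]:
    """Generate rating events for every worker x video.

    Initial time is log-normal around the worker's rate; a rating faster
    than ``T_s`` is warned. Warned ratings are revised with probability
    rising in revision effort: in coupled mode the revision moves answers
    toward the ideal vector proportionally to effort, in null mode it is
    an undirected unit perturbation. The second administration (when
    enabled) re-runs the first-attempt process with retest drift added to
    the answer noise; workers may skip it entirely, preferentially the
    less diligent ones in coupled mode.
    """
    levels = np.asarray(config.levels)
    out: list[WorkerResponse] = []
    for profile in profiles:
        noise1 = profile.answer_noise_sd
        noise2 = float(np.hypot(profile.answer_noise_sd, profile.retest_drift_sd))
        if config.couple_quality:
            skip_p = float(
                np.clip(config.skip_retest_scale * (1.3 - 1.6 * profile.diligence), 0.0, 0.9)
            )
        else:
            skip_p = 0.25 if config.retest else 1.0
        skip_retest = (not config.retest) or (rng.random() < skip_p)
        for attempt, noise_sd in ((1, noise1), (2, noise2)):
            if attempt == 2 and skip_retest:
                continue
            for video in videos:
                ideal = np.asarray(ideal_answers[video.video_id], dtype=float)
                answers = _draw_answers(ideal, profile, levels, noise_sd, rng)
                t1 = float(max(5.0, profile.time_rate_s * rng.lognormal(0.0, 0.25)))
                warned = t1 < config.T_s
                revised = None
                t2 = None
                if warned:
                    p_revise = 0.25 + 0.7 * profile.revise_effort
                    if rng.random() < p_revise:
                        a = np.asarray(answers, dtype=float)
                        if config.couple_quality:
                            moved = np.rint(a + profile.revise_effort * (ideal - a))
                        else:
                            moved = a + rng.integers(-1, 2, size=a.size)
                        revised = tuple(
                            int(v) for v in np.clip(moved, 0, levels - 1)
                        )
                        t2 = float(
                            (20.0 + 150.0 * profile.revise_effort)
                            * rng.lognormal(0.0, 0.3)
                        )
                out.append(
                    WorkerResponse(
                        worker_id=profile.worker_id,
                        video_id=video.video_id,
                        attempt=attempt,
                        answers=answers,
                        t1_s=t1,
                        warned=warned,
                        revised_answers=revised,
                        t2_s=t2,
                    )
                )
    return out


def simulate_study(
    config: SimulationConfig,
    worker_prefix: str = "w",
    video_prefix: str = "v",
) -> SimulatedStudy:
    """Run the full generator under one master seed.

    Independent substreams (classifier, videos, workers, responses) are
    spawned from the master seed, so the same seed reproduces the study
    bit for bit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_clf, rng_vid, rng_wrk, rng_resp = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    spec = simulate_ground_truth_classifier(config, rng_clf)
    videos, ideals = simulate_videos(config, spec, rng_vid, id_prefix=video_prefix)
    profiles = simulate_worker_profiles(config, rng_wrk, id_prefix=worker_prefix)
    responses = simulate_responses(profiles, videos, ideals, config, rng_resp)
    return SimulatedStudy(
        videos=videos,
        ideal_answers=ideals,
        classifier=spec,
        profiles=profiles,
        responses=responses,
        sim_config=config,
        study_config=study_config_for(config),
    )


def make_cohort_pair(
    config: SimulationConfig,
) -> tuple[SimulatedStudy, SimulatedStudy]:
    """Two studies with disjoint worker and video ids, same parameters.

    Both cohorts share the generative settings (and nothing else); sub
    seeds derive from the master seed, so the pair is reproducible. Use
    for cross-cohort generalization: fit the metric regression on cohort
    A, evaluate on cohort B.
    """
    ss = np.random.SeedSequence(config.seed).spawn(2)
    seed_a = int(ss[0].generate_state(1)[0] % (2**31))
    seed_b = int(ss[1].generate_state(1)[0] % (2**31))
    cfg_a = SimulationConfig(**{**_public_fields(config), "seed": seed_a})
    cfg_b = SimulationConfig(**{**_public_fields(config), "seed": seed_b})
    study_a = simulate_study(cfg_a, worker_prefix="A_w", video_prefix="A_v")
    study_b = simulate_study(cfg_b, worker_prefix="B_w", video_prefix="B_v")
    return study_a, study_b


def _public_fields(config: SimulationConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["levels"] = tuple(d["levels"])
    return d
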