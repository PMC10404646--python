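"""Synthetic participants and cohorts with known ground-truth learning.

The simulator produces complete datasets (streams, keypress logs, 2-AFC
responses, participant metadata) in the same schemas the scoring pipeline
consumes, so parameter recovery, power, and type-I behavior of every
downstream stage can be checked without any real data.

Behavior model
--------------
Target detection: on each target occurrence ``t`` (1..T) the participant
responds with probability ``hit_prob``.  Response latency is linear in the
occurrence index — the estimand of the RT-slope analysis — plus Gaussian
noise, truncated to the task's accept window.  ``true_rt_slope`` is defined
on the *post z-normalization* scale (z units per target occurrence): the
millisecond-scale trend is back-computed so that the expected z-normed OLS
slope equals the declared value (see :func:`calibrated_trend_ms`).  With
probability ``anticipation_prob`` a response is anticipatory (uniform in
the negative part of the window).  Each non-target stimulus triggers a
false alarm with probability ``fa_rate_per_nontarget``, uniform within its
SOA interval.

2-AFC: each test trial is answered correctly with probability
``afc_accuracy_prob``, independently.

Cohorts: group × domain effect maps set the mean true slope and mean 2-AFC
accuracy; individual parameters scatter around them, partially driven by a
shared per-child ability factor (which also yields the cross-task
correlations and the sentence-recall coupling seen in real cohorts).
Default cohort parameters emulate a two-group school-age sample: 50 TD /
55 ASD children aged 6–12.6, ~12% stopping after three of the four tasks,
and sentence-recall scores for roughly two thirds of each group.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import DatasetBundle
from .errors import SpecError
from .task_design import (
    DEFAULT_TASKS,
    Stream,
    build_foils,
    build_triplet_inventory,
    generate_familiarization_stream,
    generate_test_phase,
)
from .util import as_rng, child_seeds

__all__ = [
    "ParticipantParams",
    "CohortSpec",
    "calibrated_trend_ms",
    "simulate_keypresses",
    "simulate_afc",
    "simulate_cohort",
]

#: largest |z-scale slope| the linear-trend model can represent at T = 48
#: (the trend's share of variance must stay below the total); cohort draws
#: are clipped here.
MAX_ABS_SLOPE = 0.06


@dataclass
class ParticipantParams:
    """Ground-truth behavioral parameters of one simulated child."""

    participant_id: str
    group: str  # 'TD' | 'ASD'
    age_years: float
    sex: str  # 'F' | 'M'
    baseline_rt_ms: dict  # task -> ms
    true_rt_slope: dict  # task -> z units per target occurrence
    afc_accuracy_prob: dict  # task -> probability
    rt_noise_sd_ms: float = 150.0
    hit_prob: float = 0.85
    anticipation_prob: float = 0.03
    fa_rate_per_nontarget: float = 0.015
    language_level: str | None = None  # 'at_above' | 'below' (ASD only)
    sentence_recall_raw: int | None = None  # 0..32

    def __post_init__(self):
        for name in ("hit_prob", "anticipation_prob", "fa_rate_per_nontarget"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name}={v} outside [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.afc_accuracy_prob.values()):
            raise SpecError("afc_accuracy_prob outside [0, 1]")
        if self.rt_noise_sd_ms <= 0:
            raise SpecError("rt_noise_sd_ms must be positive")


def calibrated_trend_ms(slope_z: float, noise_sd_ms: float, n_targets: int) -> float:
    """Millisecond trend per occurrence matching a post-z-norm slope.

    z-norming each participant's latencies fixes their SD to 1, so a linear
    trend β·t + N(0, σ) over t = 1..T yields an expected z-scale slope of
    β / sqrt(β²·S̄ + σ²) with S̄ = T(T+1)/12.  Inverting gives
    β = s·σ / sqrt(1 − s²·S̄), defined only while the requested slope's
    trend variance stays below the unit total (|s|·sqrt(S̄) < 1).
    """
    sbar = n_targets * (n_targets + 1) / 12.0
    disc = 1.0 - slope_z**2 * sbar
    if disc <= 0:
        raise SpecError(
            f"|true_rt_slope|={abs(slope_z):.4f} is not representable with {n_targets} targets"
        )
    return slope_z * noise_sd_ms / np.sqrt(disc)


def simulate_keypresses(stream: Stream, params: ParticipantParams, seed=None) -> np.ndarray:
    """Simulate a sorted keypress timestamp log (ms) for one stream."""
    rng = as_rng(seed)
    cfg = stream.config
    task = cfg.task_name
    lo, hi = cfg.hit_window_ms
    t_on = stream.target_onsets
    occ = stream.target_occurrence_index[stream.is_target].astype(float)
    T = len(t_on)

    slope = params.true_rt_slope.get(task, 0.0)
    noise = params.rt_noise_sd_ms
    beta = calibrated_trend_ms(slope, noise, T) if slope else 0.0
    responded = rng.random(T) < params.hit_prob
    lat = params.baseline_rt_ms.get(task, 450.0) + beta * occ + rng.normal(0.0, noise, T)
    anticipate = rng.random(T) < params.anticipation_prob
    lat = np.where(anticipate, rng.uniform(lo, 0.0, T), lat)
    lat = np.clip(lat, lo + 1.0, hi - 1.0)
    hit_times = t_on[responded] + lat[responded]

    nt_on = stream.onset_ms[~stream.is_target]
    fa_mask = rng.random(len(nt_on)) < params.fa_rate_per_nontarget
    fa_times = nt_on[fa_mask] + rng.uniform(0.0, cfg.soa_ms, int(fa_mask.sum()))

    return np.sort(np.concatenate([hit_times, fa_times]))


def simulate_afc(test_trials, params, task: str | None = None, seed=None) -> pd.DataFrame:
    """Simulate a 2-AFC response table for one participant × task.

    ``params`` is a :class:`ParticipantParams` (with ``task`` naming which
    accuracy to use) or a plain probability.
    """
    rng = as_rng(seed)
    if isinstance(params, ParticipantParams):
        p = params.afc_accuracy_prob[task]
    else:
        p = float(params)
        if not 0.0 <= p <= 1.0:
            raise SpecError(f"accuracy probability {p} outside [0, 1]")
    n = len(test_trials)
    correct = (rng.random(n) < p).astype(np.int8)
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in test_trials],
            "item_id": [f"{task or 'task'}:{t.target_triplet_id}|{t.foil_id}" for t in test_trials],
            "presentation_order": [t.presentation_order for t in test_trials],
            "correct": correct,
            "chosen": [
                t.target_triplet_id if c else t.foil_id for t, c in zip(test_trials, correct)
            ],
        }
    )


def _default_effects() -> dict:
    # (mean true RT slope in z/occurrence, mean 2-AFC accuracy) per group x domain;
    # emulates robust linguistic online learning in TD, above-chance offline
    # learning in TD everywhere, and an ASD disadvantage specific to the
    # linguistic domain.
    return {
        ("TD", "linguistic"): (-0.020, 0.66),
        ("TD", "nonlinguistic"): (-0.004, 0.66),
        ("ASD", "linguistic"): (-0.008, 0.55),
        ("ASD", "nonlinguistic"): (-0.004, 0.63),
    }


@dataclass
class CohortSpec:
    """Generative description of a simulated two-group cohort."""

    n_per_group: dict = field(default_factory=lambda: {"TD": 50, "ASD": 55})
    effects: dict = field(default_factory=_default_effects)
    slope_sd: float = 0.02  # between-participant SD of true slope (per task)
    acc_sd: float = 0.12  # between-participant SD of true 2-AFC accuracy
    ability_share: float = 0.35  # variance share of the common ability factor
    age_mean: dict = field(default_factory=lambda: {"TD": 8.63, "ASD": 8.28})
    age_sd: dict = field(default_factory=lambda: {"TD": 1.89, "ASD": 1.20})
    age_range: tuple = (6.0, 12.6)
    female_prob: dict = field(default_factory=lambda: {"TD": 0.56, "ASD": 0.18})
    missing_task_prob: float = 0.12  # chance a child stops after 3 of 4 tasks
    below_age_language_prob: float = 0.565  # ASD parent-rated language level
    recall_prob: float = 0.64  # chance the optional sentence-recall task was done
    recall_mean: dict = field(default_factory=lambda: {"TD": 27.26, "ASD": 19.91})
    recall_sd: dict = field(default_factory=lambda: {"TD": 4.61, "ASD": 8.18})
    recall_ability_share: float = 0.30
    hit_prob_mean: float = 0.85
    hit_prob_sd: float = 0.08
    anticipation_prob: float = 0.03
    fa_rate_per_nontarget: float = 0.015
    rt_noise_sd_ms: float = 150.0
    baseline_rt_ms: dict = field(default_factory=lambda: {"visual": 550.0, "auditory": 450.0})
    baseline_rt_sd_ms: float = 80.0
    tasks: tuple = ("image", "letter", "tone", "syllable")
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n < 2:
                raise SpecError(f"n_per_group[{g!r}]={n}; need at least 2")
        for key, (s, a) in self.effects.items():
            if not 0.0 <= a <= 1.0:
                raise SpecError(f"effects[{key}]: mean accuracy {a} outside [0, 1]")
            if abs(s) > MAX_ABS_SLOPE:
                raise SpecError(f"effects[{key}]: |mean slope| {abs(s)} exceeds {MAX_ABS_SLOPE}")
        if not 0.0 <= self.ability_share <= 1.0:
            raise SpecError("ability_share must lie in [0, 1]")


def _draw_participant(spec: CohortSpec, configs, group: str, pid: str, rng) -> ParticipantParams:
    age = float(
        np.clip(rng.normal(spec.age_mean[group], spec.age_sd[group]), *spec.age_range)
    )
    sex = "F" if rng.random() < spec.female_prob[group] else "M"
    g_ability = rng.normal()
    rho = spec.ability_share

    slopes, accs, baselines = {}, {}, {}
    for task in spec.tasks:
        cfg = configs[task]
        mu_s, mu_a = spec.effects[(group, cfg.domain)]
        eps_s, eps_a = rng.normal(size=2)
        s = mu_s + spec.slope_sd * (np.sqrt(rho) * -g_ability + np.sqrt(1 - rho) * eps_s)
        a = mu_a + spec.acc_sd * (np.sqrt(rho) * g_ability + np.sqrt(1 - rho) * eps_a)
        slopes[task] = float(np.clip(s, -MAX_ABS_SLOPE, MAX_ABS_SLOPE))
        accs[task] = float(np.clip(a, 0.0, 1.0))
        baselines[task] = float(
            rng.normal(spec.baseline_rt_ms[cfg.modality], spec.baseline_rt_sd_ms)
        )

    language_level = None
    if group == "ASD":
        language_level = "below" if rng.random() < spec.below_age_language_prob else "at_above"
    recall = None
    if rng.random() < spec.recall_prob:
        kappa = spec.recall_ability_share
        raw = spec.recall_mean[group] + spec.recall_sd[group] * (
            np.sqrt(kappa) * g_ability + np.sqrt(1 - kappa) * rng.normal()
        )
        recall = int(np.clip(round(raw), 0, 32))

    return ParticipantParams(
        participant_id=pid,
        group=group,
        age_years=round(age, 2),
        sex=sex,
        baseline_rt_ms=baselines,
        true_rt_slope=slopes,
        afc_accuracy_prob=accs,
        rt_noise_sd_ms=spec.rt_noise_sd_ms,
        hit_prob=float(np.clip(rng.normal(spec.hit_prob_mean, spec.hit_prob_sd), 0.4, 0.98)),
        anticipation_prob=spec.anticipation_prob,
        fa_rate_per_nontarget=spec.fa_rate_per_nontarget,
        language_level=language_level,
        sentence_recall_raw=recall,
    )


def simulate_cohort(spec: CohortSpec, seed=None, configs: dict | None = None) -> DatasetBundle:
    """Simulate a complete dataset bundle for a two-group cohort.

    Deterministic given ``seed`` (defaults to ``spec.seed``).  Every
    participant gets a fresh randomized design (inventory, stream, foils,
    test order) per task, as in the experiment.
    """
    if configs is None:
        configs = {t: DEFAULT_TASKS[t] for t in spec.tasks}
    master = spec.seed if seed is None else seed
    groups = sorted(spec.n_per_group)  # deterministic order: ASD, TD
    total = sum(spec.n_per_group.values())
    seeds = child_seeds(master, total + 1)
    top_rng = as_rng(seeds[0])

    part_rows, truth_rows = [], []
    streams = {}
    kp_pid, kp_task, kp_time = [], [], []
    afc_cols = {k: [] for k in ("participant_id", "task", "trial_id", "item_id", "presentation_order", "correct", "chosen")}

    i = 0
    for group in groups:
        for k in range(spec.n_per_group[group]):
            pid = f"{group}_{k + 1:03d}"
            rng = as_rng(seeds[i + 1])
            i += 1
            params = _draw_participant(spec, configs, group, pid, rng)

            done = list(spec.tasks)
            if len(done) > 1 and rng.random() < spec.missing_task_prob:
                done.remove(done[rng.integers(len(done))])

            for task in done:
                cfg = configs[task]
                stim_ids = [f"{task}_s{j:02d}" for j in range(1, cfg.n_stimuli + 1)]
                inventory = build_triplet_inventory(stim_ids, rng)
                stream = generate_familiarization_stream(inventory, cfg, rng)
                foils = build_foils(inventory, rng)
                trials = generate_test_phase(inventory, foils, cfg, rng)

                kp = simulate_keypresses(stream, params, rng)
                streams[(pid, task)] = stream
                kp_pid.extend([pid] * len(kp))
                kp_task.extend([task] * len(kp))
                kp_time.append(kp)

                p_acc = params.afc_accuracy_prob[task]
                correct = rng.random(len(trials)) < p_acc
                afc_cols["participant_id"].extend([pid] * len(trials))
                afc_cols["task"].extend([task] * len(trials))
                afc_cols["trial_id"].extend(t.trial_id for t in trials)
                afc_cols["item_id"].extend(
                    f"{task}:{t.target_triplet_id}|{t.foil_id}" for t in trials
                )
                afc_cols["presentation_order"].extend(t.presentation_order for t in trials)
                afc_cols["correct"].extend(np.asarray(correct, dtype=np.int8))
                afc_cols["chosen"].extend(
                    t.target_triplet_id if c else t.foil_id for t, c in zip(trials, correct)
                )

                truth_rows.append(
                    {
                        "participant_id": pid,
                        "task": task,
                        "true_rt_slope": params.true_rt_slope[task],
                        "afc_accuracy_prob": params.afc_accuracy_prob[task],
                        "baseline_rt_ms": params.baseline_rt_ms[task],
                        "hit_prob": params.hit_prob,
                    }
                )

            part_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "age_years": params.age_years,
                    "sex": params.sex,
                    "language_level": params.language_level,
                    "sentence_recall_raw": params.sentence_recall_raw,
                    "n_tasks_completed": len(done),
                }
            )

    participants = pd.DataFrame(part_rows)
    keypresses = pd.DataFrame(
        {
            "participant_id": kp_pid,
            "task": kp_task,
            "time_ms": np.concatenate(kp_time) if kp_time else np.empty(0),
        }
    )
    afc_responses = pd.DataFrame(afc_cols)
    afc_responses["correct"] = afc_responses["correct"].astype(np.int8)
    provenance = {"seed": int(master) if np.isscalar(master) else None, "generator": "behavior_sim.simulate_cohort"}
    return DatasetBundle(
        participants=participants,
        streams=streams,
        keypresses=keypresses,
        afc_responses=afc_responses,
        configs=configs,
        provenance=provenance,
        truth=pd.DataFrame(truth_rows),
    )
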