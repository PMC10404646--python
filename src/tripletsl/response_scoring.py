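"""Score target-detection keypress logs: hits, false alarms, A′, exclusions.

A keypress counts toward a target if it falls in the accept window of one
stimulus before to two stimuli after the target onset (−SOA to +2·SOA, i.e.
−480..+960 ms for auditory and −1000..+2000 ms for visual tasks), so both
anticipatory and delayed responses are captured.  Each target claims at
most one keypress and vice versa; keypresses matched to no target are false
alarms attributed to the stimulus event whose onset interval contains them.

Sensitivity is Grier's nonparametric A′ from hit and false-alarm rates.
Participants are dropped from the RT analysis of a task (never from the
2-AFC analysis) when they have fewer than ``min_hits`` valid keypresses or
when their A′ falls more than 3 SDs below their diagnostic group's mean for
that task.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ScoringError
from .task_design import Stream, TaskConfig

__all__ = [
    "accept_window",
    "assign_keypresses",
    "AssignmentResult",
    "compute_a_prime",
    "summarize_detection",
    "apply_exclusions",
    "score_bundle",
    "ScoredData",
]

#: exclusion reasons
REASON_NONE = "none"
REASON_TOO_FEW = "too_few_keypresses"
REASON_APRIME = "a_prime_outlier"


def accept_window(config: TaskConfig) -> tuple[float, float]:
    """Keypress accept window (lower, upper) in ms relative to target onset.

    One stimulus before to two after the target onset: (−SOA, +2·SOA).
    """
    if config.modality not in ("visual", "auditory"):
        raise ScoringError(f"unknown modality {config.modality!r}")
    return config.hit_window_ms


@dataclass
class AssignmentResult:
    """Outcome of matching a keypress log against a stream's targets."""

    hits: pd.DataFrame  # columns: target_occurrence_index, latency_ms, keypress_ms
    false_alarms: pd.DataFrame  # columns: keypress_ms, event_index (1-based)
    n_targets: int

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def n_false_alarms(self) -> int:
        return len(self.false_alarms)


def _match_lsa(kp: np.ndarray, t_on: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """One-to-one keypress→target matching maximizing matches, then
    minimizing total |latency|, ties broken toward earlier targets.

    Returns an int array per keypress: matched target index or −1.
    """
    nk, nt = len(kp), len(t_on)
    lat = kp[:, None] - t_on[None, :]
    valid = (lat >= lo) & (lat <= hi)
    BIG = 1e12
    # tiny earlier-target bias implements the tie rule without perturbing
    # genuinely different totals (latencies are O(1e3) ms)
    cost = np.where(valid, np.abs(lat) + 1e-7 * np.arange(nt)[None, :], BIG)
    rows, cols = linear_sum_assignment(cost)
    out = np.full(nk, -1, dtype=np.int64)
    for r, c in zip(rows, cols):
        if valid[r, c]:
            out[r] = c
    return out


def _match_disjoint(kp: np.ndarray, t_on: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fast path when no keypress falls in two target windows.

    Each target then independently claims its minimum-|latency| keypress
    (earlier keypress on ties), which is the global optimum.
    Returns matched target index per keypress or −1; caller must have
    verified disjointness.
    """
    nk = len(kp)
    out = np.full(nk, -1, dtype=np.int64)
    # candidate target per keypress: the unique j with lo <= kp - t_on[j] <= hi
    j = np.searchsorted(t_on, kp - hi)  # first target with t_on >= kp - hi
    j = np.clip(j, 0, len(t_on) - 1)
    lat = kp - t_on[j]
    cand = (lat >= lo) & (lat <= hi)
    order = np.argsort(np.abs(lat), kind="stable")  # stable => earlier keypress wins ties
    claimed = np.zeros(len(t_on), dtype=bool)
    for r in order:
        if cand[r] and not claimed[j[r]]:
            claimed[j[r]] = True
            out[r] = j[r]
    return out


def _assign_arrays(stream: Stream, kp: np.ndarray, lo: float, hi: float):
    """Array core of keypress→target matching.

    Returns (hit_occurrence, hit_latency, hit_time, fa_time, fa_event_index);
    ``kp`` must already be validated and sorted.
    """
    t_on = stream.target_onsets
    occ = stream.target_occurrence_index[stream.is_target]
    if len(kp) == 0 or len(t_on) == 0:
        matched = np.full(len(kp), -1, dtype=np.int64)
    else:
        left = np.searchsorted(t_on, kp - hi, side="left")
        right = np.searchsorted(t_on, kp - lo, side="right")
        if np.max(right - left) <= 1:
            matched = _match_disjoint(kp, t_on, lo, hi)
        else:
            matched = _match_lsa(kp, t_on, lo, hi)
    is_hit = matched >= 0
    hit_occ = occ[matched[is_hit]].astype(np.int64)
    hit_lat = kp[is_hit] - t_on[matched[is_hit]]
    hit_time = kp[is_hit]
    order = np.argsort(hit_occ, kind="stable")
    fa_time = kp[~is_hit]
    # attribute each false alarm to the event whose [onset, onset + SOA) holds it
    ev = np.searchsorted(stream.onset_ms, fa_time, side="right")  # 1-based event index
    ev = np.clip(ev, 1, len(stream)).astype(np.int64)
    return hit_occ[order], hit_lat[order], hit_time[order], fa_time, ev


def _check_keypresses(stream: Stream, keypresses, window) -> tuple[np.ndarray, float, float]:
    kp = np.asarray(keypresses, dtype=float)
    if kp.ndim != 1:
        raise ScoringError("keypresses must be a 1-D sequence of times")
    if np.any(np.diff(kp) < 0):
        raise ScoringError("keypress log must be sorted ascending")
    lo, hi = accept_window(stream.config) if window is None else window
    if len(kp) and (kp[0] < 0 or kp[-1] > stream.duration_ms + hi):
        raise ScoringError("keypress outside the stream duration (+ window upper bound)")
    return kp, lo, hi


def assign_keypresses(
    stream: Stream,
    keypresses,
    window: tuple[float, float] | None = None,
) -> AssignmentResult:
    """Match a sorted keypress log to the stream's targets.

    Overlapping accept windows are arbitrated by a one-to-one matching that
    maximizes the number of hits and then minimizes total |latency|, with
    ties resolved toward the earlier target.  Unmatched keypresses are
    false alarms attributed to the containing stimulus event.
    """
    kp, lo, hi = _check_keypresses(stream, keypresses, window)
    hit_occ, hit_lat, hit_time, fa_time, fa_ev = _assign_arrays(stream, kp, lo, hi)
    hits = pd.DataFrame(
        {"target_occurrence_index": hit_occ, "latency_ms": hit_lat, "keypress_ms": hit_time}
    )
    false_alarms = pd.DataFrame({"keypress_ms": fa_time, "event_index": fa_ev})
    return AssignmentResult(hits=hits, false_alarms=false_alarms, n_targets=stream.n_targets)


def compute_a_prime(hit_rate, fa_rate):
    """Grier's nonparametric sensitivity A′ (0.5 = chance, 1 = perfect).

    For H ≥ F: A′ = 0.5 + (H−F)(1+H−F) / (4H(1−F)); the H < F case mirrors
    around 0.5.  Accepts scalars or arrays.
    """
    h = np.asarray(hit_rate, dtype=float)
    f = np.asarray(fa_rate, dtype=float)
    if np.any((h < 0) | (h > 1) | (f < 0) | (f > 1)):
        raise ScoringError("hit and false-alarm rates must lie in [0, 1]")
    out = np.full(np.broadcast(h, f).shape, 0.5)
    hb, fb = np.broadcast_arrays(h, f)
    above = hb > fb
    below = hb < fb
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (hb - fb) * (1 + hb - fb)
        out = np.where(above, 0.5 + num / (4 * hb * (1 - fb)), out)
        num2 = (fb - hb) * (1 + fb - hb)
        out = np.where(below, 0.5 - num2 / (4 * fb * (1 - hb)), out)
    if out.ndim == 0:
        return float(out)
    return out


def summarize_detection(
    stream: Stream,
    assignment: AssignmentResult,
    participant_id: str,
    task: str,
) -> dict:
    """One detection-summary row for a participant × task."""
    n_events = len(stream)
    t = assignment.n_targets
    n_nontarget = n_events - t
    hit_rate = assignment.n_hits / t if t else np.nan
    fa_rate = assignment.n_false_alarms / n_nontarget if n_nontarget else np.nan
    # rates can exceed 1 only if multiple FAs land on few non-targets; clamp for A'
    return {
        "participant_id": participant_id,
        "task": task,
        "n_targets": t,
        "n_events": n_events,
        "n_hits": assignment.n_hits,
        "n_false_alarms": assignment.n_false_alarms,
        "hit_rate": hit_rate,
        "fa_rate": min(fa_rate, 1.0) if np.isfinite(fa_rate) else fa_rate,
        "a_prime": compute_a_prime(hit_rate, min(fa_rate, 1.0)),
    }


def apply_exclusions(
    summaries: pd.DataFrame,
    min_hits: int = 6,
    a_prime_sd: float = 3.0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Flag participants to drop from the RT analysis of a task.

    Rule 1: fewer than ``min_hits`` valid keypresses (hits).  Rule 2: among
    the survivors of rule 1, A′ strictly below (group mean − ``a_prime_sd``
    × group SD), computed per diagnostic group per task.  Flags affect RT
    analyses only; 2-AFC accuracy is never excluded.  Idempotent.
    """
    out = summaries.copy()
    out["excluded_rt"] = False
    out["exclusion_reason"] = REASON_NONE

    too_few = out["n_hits"] < min_hits
    out.loc[too_few, "excluded_rt"] = True
    out.loc[too_few, "exclusion_reason"] = REASON_TOO_FEW

    for (task, group), idx in out[~too_few].groupby(["task", group_col], observed=True).groups.items():
        a = out.loc[idx, "a_prime"].to_numpy(dtype=float)
        if len(a) < 2:
            warnings.warn(
                f"A' outlier rule skipped for task={task!r} group={group!r}: "
                f"fewer than 2 unexcluded participants",
                stacklevel=2,
            )
            continue
        thresh = a.mean() - a_prime_sd * a.std(ddof=1)
        bad = idx[a < thresh]
        out.loc[bad, "excluded_rt"] = True
        out.loc[bad, "exclusion_reason"] = REASON_APRIME
    return out


@dataclass
class ScoredData:
    """Detection summaries plus the hit-level latency table for a dataset."""

    summaries: pd.DataFrame  # one row per participant x task, incl. exclusion flags
    hits: pd.DataFrame  # participant_id, task, target_occurrence_index, latency_ms


def score_bundle(bundle, min_hits: int = 6, a_prime_sd: float = 3.0) -> ScoredData:
    """Score every keypress log in a dataset bundle and apply exclusions."""
    time_col = bundle.keypresses["time_ms"].to_numpy(dtype=float)
    kp_by = bundle.keypresses.groupby(["participant_id", "task"], observed=True).indices
    rows = []
    h_pid, h_task, h_occ, h_lat = [], [], [], []
    for (pid, task), stream in bundle.streams.items():
        idx = kp_by.get((pid, task))
        kp = np.sort(time_col[idx]) if idx is not None else np.empty(0)
        kp, lo, hi = _check_keypresses(stream, kp, None)
        hit_occ, hit_lat, _, fa_time, _ = _assign_arrays(stream, kp, lo, hi)
        n_events, t = len(stream), stream.n_targets
        hit_rate = len(hit_occ) / t if t else np.nan
        fa_rate = min(len(fa_time) / (n_events - t), 1.0) if n_events > t else np.nan
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                "n_targets": t,
                "n_events": n_events,
                "n_hits": len(hit_occ),
                "n_false_alarms": len(fa_time),
                "hit_rate": hit_rate,
                "fa_rate": fa_rate,
                "a_prime": compute_a_prime(hit_rate, fa_rate),
            }
        )
        if len(hit_occ):
            h_pid.extend([pid] * len(hit_occ))
            h_task.extend([task] * len(hit_occ))
            h_occ.append(hit_occ)
            h_lat.append(hit_lat)
    summaries = pd.DataFrame(rows)
    groups = bundle.participants.set_index("participant_id")["group"]
    summaries["group"] = summaries["participant_id"].map(groups)
    summaries = apply_exclusions(summaries, min_hits=min_hits, a_prime_sd=a_prime_sd)
    hits = pd.DataFrame(
        {
            "participant_id": h_pid,
            "task": h_task,
            "target_occurrence_index": np.concatenate(h_occ) if h_occ else np.empty(0, np.int64),
            "latency_ms": np.concatenate(h_lat) if h_lat else np.empty(0),
        }
    )
    return ScoredData(summaries=summaries, hits=hits)
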