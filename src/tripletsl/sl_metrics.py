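"""Individual-level statistical-learning measures.

Online learning: hit latencies for a participant × task are z-scored
within that participant × task (controlling baseline RT differences), and
the RT slope is the OLS coefficient of z-normed RT on target occurrence
index (1..24 visual, 1..48 auditory).  Negative slopes mean accelerating
detection, i.e. learning.

Offline learning: proportion correct over the 2-AFC test trials (chance
0.5).

Composite SL score per task: mean of z(−RT slope) and z(2-AFC accuracy),
with both z-norms computed over the whole pooled sample.  Domain
composites average the four z-normed measures (2 reversed slopes + 2
accuracies) of a domain, using whichever components a child has
(participants excluded from the RT analysis still contribute accuracy;
children who skipped a task contribute the remaining components).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import NormingError
from .response_scoring import ScoredData

__all__ = [
    "znorm_rts",
    "fit_rt_slope",
    "afc_accuracy",
    "compute_measures",
    "composite_scores",
    "build_rt_table",
    "build_afc_table",
    "build_composite_table",
]


def znorm_rts(latencies) -> np.ndarray:
    """z-score hit latencies within one participant × task (sample SD)."""
    x = np.asarray(latencies, dtype=float)
    if len(x) < 2:
        raise NormingError("need at least 2 latencies to z-norm")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NormingError("zero-variance latencies cannot be z-normed")
    return (x - x.mean()) / sd


def fit_rt_slope(z_latencies, target_occurrence_indices) -> float:
    """OLS slope of z-normed RT on target occurrence index."""
    y = np.asarray(z_latencies, dtype=float)
    t = np.asarray(target_occurrence_indices, dtype=float)
    if len(y) != len(t):
        raise ValueError("z_latencies and indices differ in length")
    if len(np.unique(t)) < 2:
        raise NormingError("RT slope undefined: all occurrence indices equal")
    return float(np.polyfit(t, y, 1)[0])


def afc_accuracy(correct) -> float:
    """Proportion of correct 2-AFC responses."""
    c = np.asarray(correct, dtype=float)
    if len(c) == 0:
        raise NormingError("no 2-AFC responses")
    return float(c.mean())


def compute_measures(scored: ScoredData, bundle) -> pd.DataFrame:
    """Tidy per participant × task measures table.

    Columns: participant_id, task, rt_slope (NaN when RT-excluded or
    undefined), n_rt_observations, afc_accuracy, excluded_rt,
    exclusion_reason.
    """
    summ = scored.summaries
    excluded = dict(zip(zip(summ["participant_id"], summ["task"]), summ["excluded_rt"]))
    reasons = dict(zip(zip(summ["participant_id"], summ["task"]), summ["exclusion_reason"]))

    lat_col = scored.hits["latency_ms"].to_numpy(dtype=float)
    occ_col = scored.hits["target_occurrence_index"].to_numpy(dtype=float)
    slope_rows = {}
    for key, idx in scored.hits.groupby(["participant_id", "task"], observed=True).indices.items():
        if excluded[key]:
            continue
        try:
            slope_rows[key] = (fit_rt_slope(znorm_rts(lat_col[idx]), occ_col[idx]), len(idx))
        except NormingError:
            slope_rows[key] = (np.nan, len(idx))

    acc = bundle.afc_responses.groupby(["participant_id", "task"], observed=True)["correct"].mean()

    keys = sorted(bundle.streams)
    rows = []
    for key in keys:
        pid, task = key
        slope, n_rt = slope_rows.get(key, (np.nan, 0))
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                "rt_slope": slope,
                "n_rt_observations": n_rt,
                "afc_accuracy": acc.get(key, np.nan),
                "excluded_rt": bool(excluded[key]),
                "exclusion_reason": reasons[key],
            }
        )
    return pd.DataFrame(rows)


def _zcol(s: pd.Series) -> pd.Series:
    """z-norm a column over its non-missing entries (sample SD)."""
    x = s.astype(float)
    n = x.notna().sum()
    if n < 2:
        raise NormingError(f"cannot z-norm {s.name!r}: fewer than 2 observations")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise NormingError(f"cannot z-norm {s.name!r}: zero variance")
    return (x - x.mean()) / sd


def composite_scores(
    measures: pd.DataFrame,
    configs: dict,
    norm_groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill per-task composites and build the domain-composite table.

    Per task, z(−rt_slope) and z(afc_accuracy) are normed over the pooled
    sample (pass ``norm_groups`` — participant_id → group — to norm within
    diagnostic group instead, for sensitivity analyses).  The composite is
    the mean of the two available components; domain composites average a
    participant's four z-normed components within a domain.
    """
    m = measures.copy()
    m["z_neg_slope"] = np.nan
    m["z_accuracy"] = np.nan

    if norm_groups is not None:
        norm_key = m["participant_id"].map(norm_groups)
    else:
        norm_key = pd.Series("all", index=m.index)

    for (task, _), idx in m.groupby(["task", norm_key], observed=True).groups.items():
        sub = m.loc[idx]
        m.loc[idx, "z_neg_slope"] = _zcol(-sub["rt_slope"])
        m.loc[idx, "z_accuracy"] = _zcol(sub["afc_accuracy"])

    m["composite"] = m[["z_neg_slope", "z_accuracy"]].mean(axis=1, skipna=True)

    m["domain"] = m["task"].map({t: c.domain for t, c in configs.items()})
    m["modality"] = m["task"].map({t: c.modality for t, c in configs.items()})

    long = m.melt(
        id_vars=["participant_id", "domain"],
        value_vars=["z_neg_slope", "z_accuracy"],
        value_name="z_component",
    )
    dom = (
        long.groupby(["participant_id", "domain"], observed=True)["z_component"]
        .mean()
        .rename("score")
        .reset_index()
    )
    dom = dom[dom["score"].notna()].reset_index(drop=True)
    return m, dom


# ---------------------------------------------------------------------------
# tidy tables for the group-level models


def build_rt_table(scored: ScoredData, bundle) -> pd.DataFrame:
    """Hit-level z-RT table for the RT mixed model.

    One row per valid hit of every RT-included participant × task, with
    z-normed latency, target occurrence index ('order'), and participant /
    task factors.
    """
    summ = scored.summaries
    excluded = dict(zip(zip(summ["participant_id"], summ["task"]), summ["excluded_rt"]))
    parts = bundle.participants.set_index("participant_id")

    df = scored.hits
    keep = np.ones(len(df), dtype=bool)
    lat = df["latency_ms"].to_numpy(dtype=float)
    z = np.full(len(df), np.nan)
    for key, idx in df.groupby(["participant_id", "task"], observed=True).indices.items():
        x = lat[idx]
        if excluded[key] or len(x) < 2 or x.std(ddof=1) == 0:
            keep[idx] = False
            continue
        z[idx] = (x - x.mean()) / x.std(ddof=1)

    out = df.loc[keep, ["participant_id", "task"]].copy()
    out["group"] = out["participant_id"].map(parts["group"])
    out["sex"] = out["participant_id"].map(parts["sex"])
    out["domain"] = out["task"].map({t: c.domain for t, c in bundle.configs.items()})
    out["modality"] = out["task"].map({t: c.modality for t, c in bundle.configs.items()})
    out["order"] = df.loc[keep, "target_occurrence_index"].to_numpy(dtype=float)
    out["n_targets"] = out["task"].map({t: c.reps_per_triplet for t, c in bundle.configs.items()})
    out["z_rt"] = z[keep]
    return out.reset_index(drop=True)


def build_afc_table(bundle) -> pd.DataFrame:
    """Trial-level 2-AFC table for the mixed logistic model."""
    parts = bundle.participants.set_index("participant_id")
    df = bundle.afc_responses.copy()
    df["group"] = df["participant_id"].map(parts["group"])
    df["sex"] = df["participant_id"].map(parts["sex"])
    df["domain"] = df["task"].map({t: c.domain for t, c in bundle.configs.items()})
    df["modality"] = df["task"].map({t: c.modality for t, c in bundle.configs.items()})
    df["correct"] = df["correct"].astype(int)
    return df


def build_composite_table(measures_with_composite: pd.DataFrame, bundle) -> pd.DataFrame:
    """Task-level composite table for the composite mixed model."""
    parts = bundle.participants.set_index("participant_id")
    df = measures_with_composite.dropna(subset=["composite"]).copy()
    df["group"] = df["participant_id"].map(parts["group"])
    df["sex"] = df["participant_id"].map(parts["sex"])
    df["age_years"] = df["participant_id"].map(parts["age_years"])
    return df
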