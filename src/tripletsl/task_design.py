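"""Triplet-structured stream designs for statistical-learning (SL) tasks.

An SL task exposes participants to a continuous stream of stimuli built by
concatenating a small inventory of fixed ordered triplets.  Transitional
probability is 1 within a triplet and much lower across triplet boundaries,
so segmenting the stream amounts to learning the triplets.  Four task
configurations are bundled, crossing modality (visual / auditory) with
domain (linguistic / nonlinguistic):

==========  ========  =============  ====  =======
task        modality  domain         SOA   reps
==========  ========  =============  ====  =======
image       visual    nonlinguistic  1000  24
letter      visual    linguistic     1000  24
tone        auditory  nonlinguistic   480  48
syllable    auditory  linguistic      480  48
==========  ========  =============  ====  =======

Each task uses 12 unique stimuli partitioned into 4 triplets.  During
familiarization one triplet's third element is the detection target.  The
test phase is a 2-AFC over the full target × foil crossing, repeated twice
(32 trials), where foils preserve each element's within-triplet position
but never occurred in the stream.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, GenerationError
from .util import as_rng

__all__ = [
    "TaskConfig",
    "Triplet",
    "StreamEvent",
    "Stream",
    "TestTrial",
    "DEFAULT_TASKS",
    "build_triplet_inventory",
    "generate_familiarization_stream",
    "build_foils",
    "generate_test_phase",
    "test_phase_to_frame",
]


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one SL task.

    ``hit_window_ms`` (the keypress accept window around a target onset)
    defaults to one stimulus before and two after the target onset, i.e.
    (−SOA, +2·SOA): −1000..+2000 ms for the visual tasks and −480..+960 ms
    for the auditory ones.
    """

    task_name: str
    modality: str  # 'visual' | 'auditory'
    domain: str  # 'linguistic' | 'nonlinguistic'
    soa_ms: int
    reps_per_triplet: int
    stim_duration_ms: float
    n_stimuli: int = 12
    n_triplets: int = 4
    test_pause_ms: int = 1000
    test_reps: int = 2
    allow_immediate_repeat: bool = False

    def __post_init__(self):
        if self.modality not in ("visual", "auditory"):
            raise DesignError(f"unknown modality {self.modality!r}")
        if self.domain not in ("linguistic", "nonlinguistic"):
            raise DesignError(f"unknown domain {self.domain!r}")
        if self.n_stimuli != 3 * self.n_triplets:
            raise DesignError("n_stimuli must equal 3 * n_triplets")
        for name in ("soa_ms", "reps_per_triplet", "stim_duration_ms", "test_pause_ms", "test_reps"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")

    @property
    def hit_window_ms(self) -> tuple[float, float]:
        """Keypress accept window (lower, upper) relative to target onset."""
        return (-float(self.soa_ms), 2.0 * self.soa_ms)

    @property
    def n_events(self) -> int:
        return 3 * self.n_triplets * self.reps_per_triplet

    def to_dict(self) -> dict:
        return {
            "task_name": self.task_name,
            "modality": self.modality,
            "domain": self.domain,
            "soa_ms": self.soa_ms,
            "reps_per_triplet": self.reps_per_triplet,
            "stim_duration_ms": self.stim_duration_ms,
            "n_stimuli": self.n_stimuli,
            "n_triplets": self.n_triplets,
            "test_pause_ms": self.test_pause_ms,
            "test_reps": self.test_reps,
            "allow_immediate_repeat": self.allow_immediate_repeat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)


DEFAULT_TASKS: dict[str, TaskConfig] = {
    "image": TaskConfig("image", "visual", "nonlinguistic", soa_ms=1000, reps_per_triplet=24, stim_duration_ms=800),
    "letter": TaskConfig("letter", "visual", "linguistic", soa_ms=1000, reps_per_triplet=24, stim_duration_ms=800),
    "tone": TaskConfig("tone", "auditory", "nonlinguistic", soa_ms=480, reps_per_triplet=48, stim_duration_ms=328),
    "syllable": TaskConfig("syllable", "auditory", "linguistic", soa_ms=480, reps_per_triplet=48, stim_duration_ms=350),
}


@dataclass(frozen=True)
class Triplet:
    """An ordered set of three distinct stimuli; element order is meaningful."""

    triplet_id: str
    elements: tuple[str, str, str]

    def __post_init__(self):
        if len(self.elements) != 3 or len(set(self.elements)) != 3:
            raise DesignError(f"triplet {self.triplet_id!r} needs exactly 3 distinct elements")


class StreamEvent(NamedTuple):
    index: int  # 1-based position in the stream
    stimulus_id: str
    onset_ms: float
    triplet_id: str
    within_triplet_position: int  # 1..3
    is_target: bool
    target_occurrence_index: int  # 1..T for targets, 0 otherwise


@dataclass
class Stream:
    """An onset-timed familiarization sequence with triplet annotations.

    Columns are stored as parallel numpy arrays; ``events()`` iterates
    :class:`StreamEvent` rows and ``to_frame()`` returns the tidy table.
    """

    config: TaskConfig
    target_triplet_id: str
    stimulus_id: np.ndarray
    onset_ms: np.ndarray
    triplet_id: np.ndarray
    within_triplet_position: np.ndarray
    is_target: np.ndarray
    target_occurrence_index: np.ndarray

    def __len__(self) -> int:
        return len(self.stimulus_id)

    @property
    def index(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    @property
    def target_onsets(self) -> np.ndarray:
        return self.onset_ms[self.is_target]

    @property
    def duration_ms(self) -> float:
        return float(self.onset_ms[-1] + self.config.soa_ms)

    def events(self) -> Iterator[StreamEvent]:
        for i in range(len(self)):
            yield StreamEvent(
                i + 1,
                str(self.stimulus_id[i]),
                float(self.onset_ms[i]),
                str(self.triplet_id[i]),
                int(self.within_triplet_position[i]),
                bool(self.is_target[i]),
                int(self.target_occurrence_index[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        occ = pd.array(self.target_occurrence_index, dtype="Int64")
        occ[~self.is_target] = pd.NA
        return pd.DataFrame(
            {
                "index": self.index,
                "stimulus_id": self.stimulus_id,
                "onset_ms": self.onset_ms,
                "triplet_id": self.triplet_id,
                "within_triplet_position": self.within_triplet_position,
                "is_target": self.is_target,
                "target_occurrence_index": occ,
            }
        )


@dataclass(frozen=True)
class TestTrial:
    """One 2-AFC test trial: a familiar target triplet against a novel foil."""

    __test__ = False  # not a pytest class, despite the name

    trial_id: int
    target_triplet_id: str
    foil_id: str
    presentation_order: str  # 'target_first' | 'foil_first'
    rep: int  # 1..test_reps


def build_triplet_inventory(stimulus_ids: Sequence[str], seed=None) -> list[Triplet]:
    """Randomly partition distinct stimuli into ordered triplets.

    The stimulus count must be divisible by 3; 12 stimuli yield the four
    target triplets of the standard designs.
    """
    ids = list(stimulus_ids)
    if len(set(ids)) != len(ids):
        raise DesignError("stimulus_ids must be distinct")
    if len(ids) == 0 or len(ids) % 3 != 0:
        raise DesignError(f"stimulus count {len(ids)} is not a positive multiple of 3")
    rng = as_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return [
        Triplet(f"triplet_{k + 1}", tuple(shuffled[3 * k : 3 * k + 3]))
        for k in range(len(ids) // 3)
    ]


def _sample_triplet_order(n_triplets: int, reps: int, allow_repeat: bool, rng, max_restarts: int = 500) -> np.ndarray:
    """Sequence of triplet labels (0..n-1), each appearing ``reps`` times.

    Under the default no-immediate-repeat rule labels are drawn sequentially
    with probability proportional to remaining counts among the allowed
    labels, restarting on dead ends (rare for balanced counts).
    """
    total = n_triplets * reps
    labels = np.repeat(np.arange(n_triplets), reps)
    if allow_repeat:
        return rng.permutation(labels)
    if n_triplets == 1 and reps > 1:
        raise GenerationError("cannot avoid immediate repeats with a single triplet")
    for _ in range(max_restarts):
        counts = [reps] * n_triplets
        seq = [0] * total
        prev = -1
        u = rng.random(total)
        ok = True
        for i in range(total):
            remaining = total - i
            avail = remaining - (counts[prev] if prev >= 0 else 0)
            if avail <= 0:
                ok = False
                break
            r = u[i] * avail
            for j in range(n_triplets):
                if j == prev:
                    continue
                c = counts[j]
                if c == 0:
                    continue
                if r < c:
                    seq[i] = j
                    counts[j] = c - 1
                    prev = j
                    break
                r -= c
        if ok:
            return np.asarray(seq)
    raise GenerationError(
        f"could not build a no-repeat triplet order for {n_triplets} triplets x {reps} reps"
    )


def generate_familiarization_stream(
    inventory: Sequence[Triplet],
    config: TaskConfig,
    seed=None,
    target_triplet_id: str | None = None,
) -> Stream:
    """Concatenate randomized triplet presentations into an onset-timed stream.

    Each triplet occurs exactly ``config.reps_per_triplet`` times; onsets are
    (index − 1) × SOA.  The detection target is the third element of one
    triplet, drawn uniformly at random per call unless ``target_triplet_id``
    is given (in the experiment it is re-drawn per task per participant).
    """
    inventory = list(inventory)
    if len(inventory) != config.n_triplets:
        raise DesignError(
            f"inventory has {len(inventory)} triplets, config expects {config.n_triplets}"
        )
    rng = as_rng(seed)
    order = _sample_triplet_order(
        config.n_triplets, config.reps_per_triplet, config.allow_immediate_repeat, rng
    )
    if target_triplet_id is None:
        target_triplet_id = inventory[rng.integers(config.n_triplets)].triplet_id
    elif target_triplet_id not in {t.triplet_id for t in inventory}:
        raise DesignError(f"unknown target triplet {target_triplet_id!r}")

    elem = np.array([t.elements for t in inventory], dtype=object)  # (n_triplets, 3)
    tids = np.array([t.triplet_id for t in inventory], dtype=object)
    n = len(order) * 3
    stimulus = elem[order].reshape(n)
    triplet_col = np.repeat(tids[order], 3)
    position = np.tile(np.array([1, 2, 3]), len(order))
    onset = np.arange(n, dtype=float) * config.soa_ms
    is_target = (triplet_col == target_triplet_id) & (position == 3)
    occ = np.zeros(n, dtype=np.int64)
    occ[is_target] = np.arange(1, is_target.sum() + 1)
    return Stream(
        config=config,
        target_triplet_id=target_triplet_id,
        stimulus_id=stimulus,
        onset_ms=onset,
        triplet_id=triplet_col,
        within_triplet_position=position,
        is_target=is_target,
        target_occurrence_index=occ,
    )


def build_foils(inventory: Sequence[Triplet], seed=None) -> list[Triplet]:
    """Recombine target triplets into position-preserving novel foils.

    Foil i takes its position-k element from target σ_k(i), with the three
    source permutations chosen as distinct cyclic shifts of one random
    relabeling.  Hence every foil draws its elements from three different
    targets (so it never equals a target, and shares at most one element's
    source with any single target) while each element keeps its
    within-triplet position.
    """
    inventory = list(inventory)
    n = len(inventory)
    if n < 3:
        raise DesignError("foil construction needs at least 3 target triplets")
    rng = as_rng(seed)
    rho = rng.permutation(n)
    shifts = rng.permutation(n)[:3]  # distinct shifts -> distinct sources per foil
    foils = []
    for i in range(n):
        elements = tuple(
            inventory[rho[(i + shifts[k]) % n]].elements[k] for k in range(3)
        )
        foils.append(Triplet(f"foil_{i + 1}", elements))
    return foils


def generate_test_phase(
    inventory: Sequence[Triplet],
    foils: Sequence[Triplet],
    config: TaskConfig,
    seed=None,
) -> list[TestTrial]:
    """Full target × foil × repetition crossing, randomly ordered.

    Which sequence plays first within a trial is balanced 50/50 across the
    phase (the paradigm leaves this open) and randomized.
    """
    inventory = list(inventory)
    foils = list(foils)
    if not foils:
        raise DesignError("empty foil set")
    if not inventory:
        raise DesignError("empty target inventory")
    rng = as_rng(seed)
    combos = [
        (t.triplet_id, f.triplet_id, rep)
        for rep in range(1, config.test_reps + 1)
        for t in inventory
        for f in foils
    ]
    n = len(combos)
    orders = np.array(["target_first"] * (n // 2) + ["foil_first"] * (n - n // 2), dtype=object)
    orders = orders[rng.permutation(n)]
    trial_perm = rng.permutation(n)
    trials = []
    for trial_id, j in enumerate(trial_perm, start=1):
        t, f, rep = combos[j]
        trials.append(TestTrial(trial_id, t, f, str(orders[trial_id - 1]), rep))
    return trials


def test_phase_to_frame(trials: Sequence[TestTrial]) -> pd.DataFrame:
    """Tidy table of a 2-AFC test phase."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "target_triplet_id": [t.target_triplet_id for t in trials],
            "foil_id": [t.foil_id for t in trials],
            "presentation_order": [t.presentation_order for t in trials],
            "rep": [t.rep for t in trials],
        }
    )


test_phase_to_frame.__test__ = False  # keep pytest from collecting the name
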