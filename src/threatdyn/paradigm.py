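"""Maryland Threat Countdown (MTC) trial timelines.

The MTC paradigm crosses Valence (threat, safety) with Temporal Certainty
(certain, uncertain) in a randomized event-related design. Certain trials
present a descending integer countdown for exactly 18.75 s; uncertain trials
present a randomized integer stream for a variable duration (8.75-30.00 s)
whose mean is constrained to 18.75 s so that both certainty conditions
contribute the same number of measurements. Every anticipation epoch
culminates in reinforcer delivery (noxious shock + unpleasant photograph +
audio clip on threat trials; benign counterparts on safety trials) followed
by a 3.2-s white-noise visual mask.

Timing conventions: all times are seconds from scan start, volumes are
indexed from 0, and intervals are half-open ``[onset, onset + duration)``.
All anticipation onsets/durations fall on the TR grid (TR = 1.25 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InfeasibleConstraintError, ScheduleOverflowError

__all__ = [
    "TrialSpec",
    "ScanTimeline",
    "DesignTimeline",
    "generate_timeline",
    "sample_uncertain_durations",
    "integer_stream",
    "VALENCES",
    "CERTAINTIES",
    "CONDITIONS",
]

VALENCES = ("threat", "safety")
CERTAINTIES = ("certain", "uncertain")
#: the four anticipation conditions, named certainty-first
CONDITIONS = (
    "certain_threat",
    "certain_safety",
    "uncertain_threat",
    "uncertain_safety",
)

TR_DEFAULT_S = 1.25
N_VOLUMES_DEFAULT = 478
CERTAIN_DUR_S = 18.75
UNCERTAIN_MIN_S = 8.75
UNCERTAIN_MAX_S = 30.00
UNCERTAIN_MEAN_S = 18.75
#: the first three uncertain trials demonstrate short/medium/long epochs
DEMO_DURATIONS_S = (8.75, 15.00, 28.75)
#: integer display interval: 18.75 s / 30 integers
DIGIT_INTERVAL_S = 0.625

SHOCK_DUR_S = 0.1
IMAGE_DUR_S = 1.8
AUDIO_DUR_S = 0.8
BENIGN_DUR_S = 1.8
#: reinforcers co-onset; the compound epoch spans the longest of them
REINFORCER_SPAN_S = 1.8
MASK_DUR_S = 3.2


@dataclass
class TrialSpec:
    """One MTC trial: anticipation epoch, reinforcer events, and mask."""

    valence: str
    certainty: str
    onset_s: float
    antic_dur_s: float
    reinforcer_events: list = field(default_factory=list)
    mask_onset_s: float = 0.0
    mask_dur_s: float = MASK_DUR_S

    @property
    def condition(self) -> str:
        return f"{self.certainty}_{self.valence}"

    @property
    def offset_s(self) -> float:
        """End of the anticipation epoch (reinforcer onset)."""
        return self.onset_s + self.antic_dur_s

    def validate(self) -> None:
        if self.valence not in VALENCES or self.certainty not in CERTAINTIES:
            raise ValueError(f"unknown condition {self.certainty}_{self.valence}")
        if self.certainty == "certain":
            if abs(self.antic_dur_s - CERTAIN_DUR_S) > 1e-9:
                raise ValueError("certain trials must last exactly 18.75 s")
        else:
            if not (UNCERTAIN_MIN_S - 1e-9 <= self.antic_dur_s <= UNCERTAIN_MAX_S + 1e-9):
                raise ValueError("uncertain duration outside [8.75, 30.00] s")
        for kind, onset, dur in self.reinforcer_events:
            if onset < self.offset_s - 1e-9:
                raise ValueError("reinforcer precedes anticipation offset")
            if dur <= 0:
                raise ValueError("non-positive reinforcer duration")
        if self.mask_onset_s < self.offset_s - 1e-9:
            raise ValueError("mask precedes anticipation offset")


@dataclass
class ScanTimeline:
    """One EPI scan: acquisition grid plus its ordered trials."""

    tr_s: float
    n_volumes: int
    trials: list

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_volumes


@dataclass
class DesignTimeline:
    """A full MTC session (several scans) with the seed that produced it."""

    scans: list
    seed: int

    @property
    def tr_s(self) -> float:
        return self.scans[0].tr_s

    @property
    def n_volumes(self) -> int:
        return self.scans[0].n_volumes

    @property
    def trials(self):
        """All trials across scans, tagged with their scan index."""
        return [(i, t) for i, scan in enumerate(self.scans) for t in scan.trials]

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.scans)

    def uncertain_durations(self):
        return [
            t.antic_dur_s
            for _, t in self.trials
            if t.certainty == "uncertain"
        ]

    def condition_counts(self, scan_index=None):
        counts = {c: 0 for c in CONDITIONS}
        scans = self.scans if scan_index is None else [self.scans[scan_index]]
        for scan in scans:
            for t in scan.trials:
                counts[t.condition] += 1
        return counts


def _grid_steps(duration_s: float, tr_s: float) -> int:
    """Duration expressed in TR-grid steps above the uncertain minimum."""
    return int(round((duration_s - UNCERTAIN_MIN_S) / tr_s))


def sample_uncertain_durations(
    n: int,
    seed: int,
    include_demos: bool = True,
    tr_s: float = TR_DEFAULT_S,
    mean_s: float = UNCERTAIN_MEAN_S,
) -> list:
    """Draw ``n`` uncertain anticipation durations on the TR grid.

    Durations lie on multiples of ``tr_s`` within [8.75, 30.00] s and the
    sample mean is forced to ``mean_s`` by constrained resampling: free
    trials are drawn near-uniformly over the grid and then nudged one grid
    step at a time (at randomly chosen positions) until the target sum is
    met. With ``include_demos`` the first three values are the fixed
    short/medium/long demonstration epochs (8.75, 15.00, 28.75 s).

    Raises
    ------
    InfeasibleConstraintError
        If ``n`` is too small to reach the target mean given the fixed
        demonstration values, or the target is off the grid.
    """
    if n < 1:
        raise InfeasibleConstraintError("need at least one duration")
    rng = np.random.default_rng(seed)
    k_max = _grid_steps(UNCERTAIN_MAX_S, tr_s)
    target_total = mean_s * n
    target_k = (target_total - UNCERTAIN_MIN_S * n) / tr_s
    if abs(target_k - round(target_k)) > 1e-6:
        raise InfeasibleConstraintError(
            f"mean {mean_s} s unreachable on the {tr_s}-s grid for n={n}"
        )
    target_k = int(round(target_k))

    fixed = [_grid_steps(d, tr_s) for d in DEMO_DURATIONS_S] if include_demos else []
    if include_demos and n < 4:
        raise InfeasibleConstraintError(
            "need n >= 4 to include the three demonstration durations"
        )
    n_free = n - len(fixed)
    free_target = target_k - sum(fixed)
    if free_target < 0 or free_target > n_free * k_max:
        raise InfeasibleConstraintError(
            f"target mean {mean_s} s infeasible for n={n} with fixed demos"
        )

    ks = rng.integers(0, k_max + 1, size=n_free)
    # nudge random entries one grid step at a time toward the target sum
    delta = free_target - int(ks.sum())
    while delta != 0:
        step = 1 if delta > 0 else -1
        movable = np.flatnonzero((ks < k_max) if step > 0 else (ks > 0))
        idx = movable[rng.integers(len(movable))]
        ks[idx] += step
        delta -= step
    values = fixed + list(ks)
    return [UNCERTAIN_MIN_S + k * tr_s for k in values]


def integer_stream(trial: TrialSpec, seed: int) -> list:
    """Integers displayed during the anticipation epoch.

    Certain trials count down 30, 29, ..., 1 at 0.625-s intervals; uncertain
    trials draw from a near-uniform distribution over 1-45, one integer per
    0.625-s display slot.
    """
    if trial.antic_dur_s <= 0:
        raise ValueError("trial has non-positive anticipation duration")
    if trial.certainty == "certain":
        return list(range(30, 0, -1))
    count = int(round(trial.antic_dur_s / DIGIT_INTERVAL_S))
    rng = np.random.default_rng(seed)
    return [int(v) for v in rng.integers(1, 46, size=count)]


def _reinforcer_events(valence: str, offset_s: float) -> list:
    if valence == "threat":
        return [
            ("shock", offset_s, SHOCK_DUR_S),
            ("image", offset_s, IMAGE_DUR_S),
            ("audio", offset_s, AUDIO_DUR_S),
        ]
    return [("benign", offset_s, BENIGN_DUR_S)]


def generate_timeline(
    seed: int,
    n_scans: int = 3,
    trials_per_cond: int = 6,
    tr_s: float = TR_DEFAULT_S,
    n_volumes: int = N_VOLUMES_DEFAULT,
    start_pad_s: float = 2.5,
    max_jitter_tr: int = 4,
) -> DesignTimeline:
    """Generate a randomized MTC session.

    Each scan presents ``trials_per_cond`` trials of each of the four
    conditions in random order. Certain anticipation epochs last 18.75 s;
    uncertain epochs are drawn on the TR grid within [8.75, 30.00] s with
    the per-scan (hence session) mean constrained to 18.75 s. Reinforcers
    co-onset at epoch offset, the 3.2-s mask follows the reinforcer span,
    and any residual scan time is spent as a jittered inter-trial gap on the
    TR grid.

    The same seed always yields the same timeline.
    """
    if n_scans < 1 or trials_per_cond < 1:
        raise ValueError("n_scans and trials_per_cond must be positive")
    if tr_s <= 0 or n_volumes < 1:
        raise ValueError("tr_s and n_volumes must be positive")

    rng = np.random.default_rng(seed)
    trial_overhead_s = REINFORCER_SPAN_S + MASK_DUR_S  # 5.0 s, 4 TRs
    n_trials_scan = 4 * trials_per_cond
    n_unc_scan = 2 * trials_per_cond

    scans = []
    for scan_idx in range(n_scans):
        order = [c for c in CONDITIONS for _ in range(trials_per_cond)]
        rng.shuffle(order)

        # demonstration epochs occupy the first uncertain trials of the session
        unc_durs = sample_uncertain_durations(
            n_unc_scan,
            seed=int(rng.integers(2**31)),
            include_demos=(scan_idx == 0),
            tr_s=tr_s,
        )

        required = start_pad_s + sum(
            (CERTAIN_DUR_S if c.startswith("certain") else 0.0) + trial_overhead_s
            for c in order
        ) + sum(unc_durs)
        scan_dur = n_volumes * tr_s
        if required > scan_dur + 1e-9:
            raise ScheduleOverflowError(
                f"scan {scan_idx}: schedule needs {required:.2f} s "
                f"but only {scan_dur:.2f} s are available"
            )

        # spend the slack as per-trial jitter on the TR grid
        budget = int(np.floor((scan_dur - required) / tr_s))
        jitters = np.zeros(n_trials_scan, dtype=int)
        for _ in range(budget):
            open_slots = np.flatnonzero(jitters < max_jitter_tr)
            if len(open_slots) == 0:
                break
            jitters[open_slots[rng.integers(len(open_slots))]] += 1

        trials = []
        unc_iter = iter(unc_durs)
        t = start_pad_s
        for pos, cond in enumerate(order):
            certainty, valence = cond.split("_")
            dur = CERTAIN_DUR_S if certainty == "certain" else next(unc_iter)
            offset = t + dur
            trial = TrialSpec(
                valence=valence,
                certainty=certainty,
                onset_s=t,
                antic_dur_s=dur,
                reinforcer_events=_reinforcer_events(valence, offset),
                mask_onset_s=offset + REINFORCER_SPAN_S,
                mask_dur_s=MASK_DUR_S,
            )
            trial.validate()
            trials.append(trial)
            t = offset + trial_overhead_s + jitters[pos] * tr_s
        scans.append(ScanTimeline(tr_s=tr_s, n_volumes=n_volumes, trials=trials))

    return DesignTimeline(scans=scans, seed=seed)
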