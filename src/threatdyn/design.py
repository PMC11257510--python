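"""First-level design matrices: boxcar, Onset-Sustained-Phasic, Convolved Blocks.

Each builder turns an MTC timeline into a volumes x regressors matrix by
rasterizing event indicators on a microtime grid (TR/20), convolving them
with the canonical HRF, and sampling the result at volume midpoints
(matching slice-time correction to the TR center). Task regressors span
scans; Legendre polynomial drift (orders 0-4) is added per scan.

Model-specific structure:

* ``boxcar`` — one variable-duration rectangle per anticipation epoch;
  certain-safety anticipation is the (omitted) reference condition.
* ``osp`` — per condition, an Onset impulse at epoch start, a Sustained
  rectangle over the full epoch, and a Phasic rectangle covering the final
  6.15 s before epoch offset; the certain-safety Sustained regressor is the
  reference (its Onset and Phasic columns are retained).
* ``blocks`` — each epoch tiled by consecutive 6.25-s rectangles (final
  block truncated at epoch offset), giving 2-5 blocks for 8.75-30.00-s
  epochs; the second certain-safety block is the reference.

All three models also carry one compound reinforcer regressor per condition
(shock/photograph/audio co-onset at epoch offset; benign counterparts on
safety trials), a white-noise mask regressor, and an optional rating-prompt
regressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .exceptions import RankDeficiencyError
from .hrf import HRFKernel, canonical_hrf
from .paradigm import CONDITIONS, REINFORCER_SPAN_S, DesignTimeline

__all__ = [
    "ColumnInfo",
    "DesignMatrix",
    "VIFReport",
    "build_boxcar_design",
    "build_osp_design",
    "build_blocks_design",
    "compute_vif",
    "legendre_drift",
    "PHASIC_DUR_S",
    "BLOCK_LEN_S",
    "DRIFT_ORDER",
]

#: phasic-regressor duration, chosen to minimize regressor collinearity
PHASIC_DUR_S = 6.15
#: convolved-block length
BLOCK_LEN_S = 6.25
#: highest Legendre polynomial order in the per-scan drift basis
DRIFT_ORDER = 4


@dataclass(frozen=True)
class ColumnInfo:
    """Identity of one design-matrix column."""

    condition: str
    component: str
    scan: int | None = None  # None for task columns (they span scans)

    @property
    def name(self) -> str:
        if self.scan is None:
            return f"{self.condition}:{self.component}"
        return f"{self.condition}:{self.component}:scan{self.scan}"

    @property
    def is_drift(self) -> bool:
        return self.condition == "drift"


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with labeled columns."""

    X: np.ndarray
    labels: list
    reference_record: list
    tr_s: float
    scan_lengths: list
    model: str = ""

    def __post_init__(self):
        if self.X.shape[1] != len(self.labels):
            raise ValueError("column count does not match labels")

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    @property
    def task_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if not l.is_drift], dtype=int)

    @property
    def drift_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l.is_drift], dtype=int)

    @property
    def column_names(self) -> list:
        return [l.name for l in self.labels]

    def column_index(self, condition: str, component: str) -> int:
        for i, l in enumerate(self.labels):
            if l.condition == condition and l.component == component:
                return i
        raise KeyError(f"no column {condition}:{component}")

    def has_column(self, condition: str, component: str) -> bool:
        return any(
            l.condition == condition and l.component == component for l in self.labels
        )

    def contrast_vector(self, weights: dict) -> np.ndarray:
        """Expand ``{(condition, component) or "cond:comp": weight}`` to a
        full-length weight vector.

        Weights on the omitted reference columns are legal and contribute
        zero (the reference is the implicit baseline), so contrasting the
        reference condition against itself is exactly 0.
        """
        w = np.zeros(self.X.shape[1])
        for key, val in weights.items():
            cond, comp = key.split(":") if isinstance(key, str) else key
            if (cond, comp) in self.reference_record:
                continue
            w[self.column_index(cond, comp)] = val
        return w

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.column_names)

    def plot(self, ax=None):
        """Heatmap of the (column-normalized) design matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        Z = self.X / np.maximum(np.abs(self.X).max(axis=0), 1e-12)
        ax.imshow(Z, aspect="auto", interpolation="nearest", cmap="gray_r")
        ax.set_xticks(range(len(self.labels)))
        ax.set_xticklabels(self.column_names, rotation=90, fontsize=6)
        ax.set_ylabel("volume")
        return ax


@dataclass
class VIFReport:
    """Variance-inflation diagnostics for the task regressors."""

    per_column: dict
    mean_conditionwise: float
    condition_means: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# microtime rasterization and convolution (shared with the BOLD simulator)

def microtime_length(n_volumes: int, tr_s: float, dt_s: float) -> int:
    return int(round(n_volumes * tr_s / dt_s))


def rasterize_events(events, n_micro: int, dt_s: float) -> np.ndarray:
    """Indicator series on the microtime grid.

    ``events`` is a list of ``(onset_s, dur_s, amplitude)``; a zero duration
    denotes an impulse of unit area (one microtime sample of height
    ``amplitude / dt_s``). Intervals are half-open.
    """
    x = np.zeros(n_micro)
    for onset, dur, amp in events:
        i0 = int(round(onset / dt_s))
        if dur == 0:
            if 0 <= i0 < n_micro:
                x[i0] += amp / dt_s
        else:
            i1 = int(round((onset + dur) / dt_s))
            x[max(i0, 0):min(i1, n_micro)] += amp
    return x


def convolve_and_sample(
    neural: np.ndarray, hrf: HRFKernel, n_volumes: int, tr_s: float
) -> np.ndarray:
    """Convolve a microtime series with the HRF and sample volume midpoints."""
    n_micro = len(neural)
    conv = fftconvolve(neural, hrf.values)[:n_micro] * hrf.dt_s
    mid = np.floor((np.arange(n_volumes) + 0.5) * tr_s / hrf.dt_s).astype(int)
    return conv[np.minimum(mid, n_micro - 1)]


def legendre_drift(n_volumes: int, order: int = DRIFT_ORDER) -> np.ndarray:
    """Legendre polynomials of orders 0..order on [-1, 1] over the scan."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    cols = [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# event collection

def _common_events(timeline: DesignTimeline, include_rating: bool):
    """Reinforcer (per condition), mask, and optional rating regressors."""
    events = {}
    for cond in CONDITIONS:
        events[(cond, "reinforcer")] = []
    events[("mask", "mask")] = []
    if include_rating:
        events[("rating", "rating")] = []
    for scan_idx, trial in timeline.trials:
        events[(trial.condition, "reinforcer")].append(
            (scan_idx, trial.offset_s, REINFORCER_SPAN_S)
        )
        events[("mask", "mask")].append(
            (scan_idx, trial.mask_onset_s, trial.mask_dur_s)
        )
        if include_rating:
            rating = getattr(trial, "rating_event", None)
            if rating is not None:
                events[("rating", "rating")].append((scan_idx, rating[0], rating[1]))
    return events


def _assemble(
    timeline: DesignTimeline,
    hrf: HRFKernel,
    task_events: dict,
    reference_record: list,
    model: str,
    drift_order: int = DRIFT_ORDER,
) -> DesignMatrix:
    """Convolve per-scan task events into a concatenated design matrix."""
    scan_lengths = [s.n_volumes for s in timeline.scans]
    tr = timeline.tr_s
    dt = hrf.dt_s

    keys = [k for k, ev in task_events.items() if ev]
    n_total = sum(scan_lengths)
    cols = np.zeros((n_total, len(keys)))
    for j, key in enumerate(keys):
        per_scan = {i: [] for i in range(len(timeline.scans))}
        for scan_idx, onset, dur in task_events[key]:
            per_scan[scan_idx].append((onset, dur, 1.0))
        row0 = 0
        for i, scan in enumerate(timeline.scans):
            n_micro = microtime_length(scan.n_volumes, tr, dt)
            ind = rasterize_events(per_scan[i], n_micro, dt)
            cols[row0:row0 + scan.n_volumes, j] = convolve_and_sample(
                ind, hrf, scan.n_volumes, tr
            )
            row0 += scan.n_volumes

    labels = [ColumnInfo(cond, comp) for cond, comp in keys]

    drift_cols = []
    drift_labels = []
    row0 = 0
    for i, n_vol in enumerate(scan_lengths):
        basis = legendre_drift(n_vol, drift_order)
        block = np.zeros((n_total, basis.shape[1]))
        block[row0:row0 + n_vol, :] = basis
        drift_cols.append(block)
        drift_labels.extend(
            ColumnInfo("drift", f"poly{k}", scan=i) for k in range(drift_order + 1)
        )
        row0 += n_vol

    X = np.hstack([cols] + drift_cols)
    all_labels = labels + drift_labels

    for j, l in enumerate(all_labels):
        if not l.is_drift and not np.any(X[:, j]):
            raise ValueError(f"all-zero task column {l.name}")

    return DesignMatrix(
        X=X,
        labels=all_labels,
        reference_record=list(reference_record),
        tr_s=tr,
        scan_lengths=scan_lengths,
        model=model,
    )


def build_boxcar_design(
    timeline: DesignTimeline,
    hrf: HRFKernel | None = None,
    include_rating: bool = False,
) -> DesignMatrix:
    """Conventional variable-duration boxcar model.

    One rectangle spans each anticipation epoch; certain-safety anticipation
    is omitted as the first-level reference condition.
    """
    hrf = hrf or canonical_hrf()
    reference = [("certain_safety", "boxcar")]
    events = {}
    for cond in CONDITIONS:
        if (cond, "boxcar") not in reference:
            events[(cond, "boxcar")] = []
    for scan_idx, trial in timeline.trials:
        key = (trial.condition, "boxcar")
        if key in events:
            events[key].append((scan_idx, trial.onset_s, trial.antic_dur_s))
    events.update(_common_events(timeline, include_rating))
    return _assemble(timeline, hrf, events, reference, model="boxcar")


def build_osp_design(
    timeline: DesignTimeline,
    hrf: HRFKernel | None = None,
    phasic_dur_s: float = PHASIC_DUR_S,
    include_rating: bool = False,
) -> DesignMatrix:
    """Onset-Sustained-Phasic model.

    Per condition: an impulse at epoch onset, a full-epoch rectangle, and a
    rectangle covering the final ``phasic_dur_s`` seconds before offset. The
    certain-safety Sustained regressor is the reference; its Onset and
    Phasic columns are retained.
    """
    hrf = hrf or canonical_hrf()
    min_dur = min(t.antic_dur_s for _, t in timeline.trials)
    if phasic_dur_s > min_dur:
        raise ValueError(
            f"phasic duration {phasic_dur_s} s exceeds the shortest "
            f"anticipation epoch ({min_dur} s)"
        )
    reference = [("certain_safety", "sustained")]
    events = {}
    for cond in CONDITIONS:
        for comp in ("onset", "sustained", "phasic"):
            if (cond, comp) not in reference:
                events[(cond, comp)] = []
    for scan_idx, trial in timeline.trials:
        cond = trial.condition
        if (cond, "onset") in events:
            events[(cond, "onset")].append((scan_idx, trial.onset_s, 0.0))
        if (cond, "sustained") in events:
            events[(cond, "sustained")].append(
                (scan_idx, trial.onset_s, trial.antic_dur_s)
            )
        if (cond, "phasic") in events:
            events[(cond, "phasic")].append(
                (scan_idx, trial.offset_s - phasic_dur_s, phasic_dur_s)
            )
    events.update(_common_events(timeline, include_rating))
    return _assemble(timeline, hrf, events, reference, model="osp")


def n_blocks_for(duration_s: float, block_len_s: float = BLOCK_LEN_S) -> int:
    """Number of blocks tiling an epoch (final block truncated)."""
    return int(math.ceil(round(duration_s / block_len_s, 9)))


def build_blocks_design(
    timeline: DesignTimeline,
    hrf: HRFKernel | None = None,
    block_len_s: float = BLOCK_LEN_S,
    include_rating: bool = False,
) -> DesignMatrix:
    """Convolved Blocks model.

    Each anticipation epoch is tiled by consecutive ``block_len_s``
    rectangles, the final one truncated at epoch offset. The second
    certain-safety block is the reference condition.
    """
    hrf = hrf or canonical_hrf()
    if block_len_s <= 0:
        raise ValueError("block_len_s must be positive")
    reference = [("certain_safety", "block2")]
    events = {}
    max_blocks = {
        cond: max(
            (n_blocks_for(t.antic_dur_s, block_len_s)
             for _, t in timeline.trials if t.condition == cond),
            default=0,
        )
        for cond in CONDITIONS
    }
    for cond in CONDITIONS:
        for k in range(1, max_blocks[cond] + 1):
            if (cond, f"block{k}") not in reference:
                events[(cond, f"block{k}")] = []
    for scan_idx, trial in timeline.trials:
        cond = trial.condition
        for k in range(1, n_blocks_for(trial.antic_dur_s, block_len_s) + 1):
            key = (cond, f"block{k}")
            if key not in events:
                continue
            start = trial.onset_s + (k - 1) * block_len_s
            dur = min(block_len_s, trial.offset_s - start)
            events[key].append((scan_idx, start, dur))
    events.update(_common_events(timeline, include_rating))
    return _assemble(timeline, hrf, events, reference, model="blocks")


# ---------------------------------------------------------------------------
# collinearity diagnostics

#: components treated as regressors of no interest by the VIF diagnostic
EVENT_COMPONENTS = ("reinforcer", "mask", "rating")


def compute_vif(design: DesignMatrix, include_events: bool = False) -> VIFReport:
    """Variance inflation factors of the anticipation-epoch regressors.

    Drift columns are projected out first; VIF_j = 1/(1 - R^2_j) where
    column j is regressed on the other columns in the diagnostic set. The
    condition-wise mean averages VIFs within each condition's components
    first, then across conditions.

    By default the diagnostic set is the anticipation regressors of the
    four conditions: the reinforcer, mask, and rating regressors are
    modeled to soak up stimulus-evoked variance but are regressors of no
    interest, so they are excluded from the collinearity summary (set
    ``include_events=True`` to keep them in both the conditioning set and
    the average).
    """
    task = np.array([
        i for i in design.task_indices
        if include_events or design.labels[i].component not in EVENT_COMPONENTS
    ], dtype=int)
    if len(task) < 2:
        raise ValueError("need at least two task columns")
    Xt = design.X[:, task].copy()
    drift = design.drift_indices
    if len(drift):
        D = design.X[:, drift]
        coef, *_ = np.linalg.lstsq(D, Xt, rcond=None)
        Xt -= D @ coef

    per_column = {}
    for jj, col_idx in enumerate(task):
        y = Xt[:, jj]
        others = np.delete(Xt, jj, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(y @ y)
        r2 = 1.0 - float(resid @ resid) / ss_tot
        if r2 > 1.0 - 1e-10:
            raise RankDeficiencyError(
                f"task column {design.labels[col_idx].name} is perfectly "
                "predicted by the others",
                columns=[design.labels[col_idx].name],
            )
        per_column[design.labels[col_idx].name] = 1.0 / (1.0 - r2)

    by_cond = {}
    for col_idx in task:
        lab = design.labels[col_idx]
        by_cond.setdefault(lab.condition, []).append(per_column[lab.name])
    condition_means = {c: float(np.mean(v)) for c, v in by_cond.items()}
    mean_cw = float(np.mean(list(condition_means.values())))
    return VIFReport(
        per_column=per_column,
        mean_conditionwise=mean_cw,
        condition_means=condition_means,
    )
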