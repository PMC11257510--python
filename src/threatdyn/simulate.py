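"""Synthetic BOLD generation with known ground truth.

The forward model mirrors the analysis model: a neural scenario assigns
onset/sustained/phasic amplitudes (or an arbitrary within-epoch envelope) to
each condition; the resulting microtime neural series is convolved with the
canonical HRF, sampled at volume midpoints, and corrupted with per-scan
Legendre drift and stationary AR(1) noise. Because the identical
rasterize/convolve/sample helpers build both the simulator and the design
matrices, fitting the generating design to noiseless data recovers the true
amplitudes to numerical precision.

``simulate_signature`` builds a synthetic multivoxel weight map and
per-subject block-wise beta maps around a latent distress course, scaled so
the dot-product decoder reproduces the latent course exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import (
    PHASIC_DUR_S,
    convolve_and_sample,
    legendre_drift,
    microtime_length,
    rasterize_events,
)
from .hrf import HRFKernel, canonical_hrf
from .paradigm import (
    CONDITIONS,
    REINFORCER_SPAN_S,
    DesignTimeline,
    generate_timeline,
)

__all__ = [
    "NeuralScenario",
    "SimConfig",
    "BOLDSeries",
    "SyntheticDataset",
    "simulate_neural",
    "simulate_bold",
    "simulate_group",
    "simulate_signature",
]


@dataclass
class NeuralScenario:
    """Per-condition neural amplitudes (arbitrary units).

    ``amplitudes`` maps condition -> dict with keys among
    {"onset", "sustained", "phasic"}; missing entries are 0. An optional
    ``envelope`` per condition (sequence of values over equal subdivisions
    of normalized epoch time) overrides the component amplitudes for that
    condition. ``reinforcer_amp`` and ``mask_amp`` apply to all reinforcer
    and mask events.
    """

    amplitudes: dict = field(default_factory=dict)
    envelope: dict = field(default_factory=dict)
    phasic_dur_s: float = PHASIC_DUR_S
    reinforcer_amp: float = 0.0
    mask_amp: float = 0.0

    def component_amp(self, condition: str, component: str) -> float:
        return float(self.amplitudes.get(condition, {}).get(component, 0.0))

    def true_betas(self) -> dict:
        """Ground-truth amplitude for each (condition, component) label."""
        truth = {}
        for cond in CONDITIONS:
            for comp in ("onset", "sustained", "phasic"):
                truth[(cond, comp)] = self.component_amp(cond, comp)
            truth[(cond, "reinforcer")] = self.reinforcer_amp
        truth[("mask", "mask")] = self.mask_amp
        return truth

    def perturbed(self, rng: np.random.Generator, sd: float) -> "NeuralScenario":
        """Subject-level scenario: amplitudes jittered around the mean."""
        amps = {
            cond: {comp: amp + rng.normal(0.0, sd) for comp, amp in comps.items()}
            for cond, comps in self.amplitudes.items()
        }
        return NeuralScenario(
            amplitudes=amps,
            envelope=dict(self.envelope),
            phasic_dur_s=self.phasic_dur_s,
            reinforcer_amp=self.reinforcer_amp,
            mask_amp=self.mask_amp,
        )


@dataclass
class SimConfig:
    """Noise/drift configuration for the BOLD forward model."""

    noise_sd: float = 1.0
    ar1_phi: float = 0.4
    drift_coefs: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class BOLDSeries:
    """One BOLD time series (ROI mean or voxel) over concatenated scans."""

    data: np.ndarray
    tr_s: float
    scan_lengths: list
    censor: np.ndarray | None = None  # True = keep
    ground_truth: dict | None = None

    @property
    def n_volumes(self) -> int:
        return len(self.data)


@dataclass
class SyntheticDataset:
    """Group dataset: subjects x time, with per-subject ground truth."""

    data: np.ndarray
    ground_truth: pd.DataFrame
    timeline: DesignTimeline
    tr_s: float
    scan_lengths: list

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def simulate_neural(
    timeline: DesignTimeline,
    scenario: NeuralScenario,
    dt_s: float | None = None,
) -> list:
    """Microtime neural series per scan.

    Each condition contributes ``onset`` impulses at epoch start,
    ``sustained`` rectangles over the epoch, and ``phasic`` rectangles over
    the final ``scenario.phasic_dur_s`` seconds — or, if an envelope is
    given for the condition, a piecewise profile over equal fractions of
    the epoch. Reinforcer/mask events contribute their own amplitudes. The
    series is zero outside events.
    """
    dt = dt_s if dt_s is not None else canonical_hrf().dt_s
    series = []
    for scan in timeline.scans:
        events = []
        for trial in scan.trials:
            cond = trial.condition
            env = scenario.envelope.get(cond)
            if env is not None:
                seg = trial.antic_dur_s / len(env)
                for i, amp in enumerate(env):
                    if amp != 0.0:
                        events.append((trial.onset_s + i * seg, seg, float(amp)))
            else:
                a_on = scenario.component_amp(cond, "onset")
                a_sus = scenario.component_amp(cond, "sustained")
                a_ph = scenario.component_amp(cond, "phasic")
                if a_on:
                    events.append((trial.onset_s, 0.0, a_on))
                if a_sus:
                    events.append((trial.onset_s, trial.antic_dur_s, a_sus))
                if a_ph:
                    events.append(
                        (trial.offset_s - scenario.phasic_dur_s,
                         scenario.phasic_dur_s, a_ph)
                    )
            if scenario.reinforcer_amp:
                events.append((trial.offset_s, REINFORCER_SPAN_S,
                               scenario.reinforcer_amp))
            if scenario.mask_amp:
                events.append((trial.mask_onset_s, trial.mask_dur_s,
                               scenario.mask_amp))
        n_micro = microtime_length(scan.n_volumes, scan.tr_s, dt)
        series.append(rasterize_events(events, n_micro, dt))
    return series


def _ar1_noise(rng, n, phi, sd):
    """Stationary AR(1) series with innovation sd ``sd``."""
    e = rng.normal(0.0, sd, size=n)
    x = lfilter([1.0], [1.0, -phi], e)
    if phi != 0.0 and n > 0:
        # stationary initial condition
        x0 = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
        x += x0 * phi ** np.arange(1, n + 1)
    return x


def simulate_bold(
    neural: list,
    hrf: HRFKernel,
    config: SimConfig,
    tr_s: float,
    n_volumes: int,
    ground_truth: dict | None = None,
) -> BOLDSeries:
    """Forward model: convolve, downsample, add drift and AR(1) noise.

    ``neural`` is the per-scan microtime output of :func:`simulate_neural`.
    ``config.drift_coefs`` are Legendre coefficients (order 0 upward)
    applied identically to every scan; noise is independent across scans.
    """
    rng = np.random.default_rng(config.seed)
    chunks = []
    for x in neural:
        clean = convolve_and_sample(x, hrf, n_volumes, tr_s)
        if config.drift_coefs:
            basis = legendre_drift(n_volumes, len(config.drift_coefs) - 1)
            clean = clean + basis @ np.asarray(config.drift_coefs, dtype=float)
        if config.noise_sd > 0:
            clean = clean + _ar1_noise(rng, n_volumes, config.ar1_phi,
                                       config.noise_sd)
        chunks.append(clean)
    return BOLDSeries(
        data=np.concatenate(chunks),
        tr_s=tr_s,
        scan_lengths=[len(c) for c in chunks],
        ground_truth=ground_truth,
    )


def simulate_group(
    n_subj: int,
    scenario_mean: NeuralScenario,
    between_sd: float,
    config: SimConfig,
    timeline: DesignTimeline | None = None,
    hrf: HRFKernel | None = None,
) -> SyntheticDataset:
    """Simulate a group of subjects sharing one timeline.

    Subject amplitudes are drawn around ``scenario_mean`` with standard
    deviation ``between_sd`` (applied to every amplitude the scenario
    defines); each subject gets independent AR(1) noise. Ground truth is
    recorded per subject and (condition, component).
    """
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(config.seed)
    if timeline is None:
        timeline = generate_timeline(seed=int(rng.integers(2**31)))
    hrf = hrf or canonical_hrf()
    tr = timeline.tr_s
    n_vol = timeline.n_volumes

    data = []
    truth_rows = []
    for s in range(n_subj):
        scen = scenario_mean.perturbed(rng, between_sd) if between_sd > 0 \
            else scenario_mean
        neural = simulate_neural(timeline, scen, dt_s=hrf.dt_s)
        sub_cfg = SimConfig(
            noise_sd=config.noise_sd,
            ar1_phi=config.ar1_phi,
            drift_coefs=config.drift_coefs,
            seed=int(rng.integers(2**31)),
        )
        bold = simulate_bold(neural, hrf, sub_cfg, tr, n_vol,
                             ground_truth=scen.true_betas())
        data.append(bold.data)
        for (cond, comp), amp in scen.true_betas().items():
            truth_rows.append(
                dict(subject=s, condition=cond, component=comp, amplitude=amp)
            )
    return SyntheticDataset(
        data=np.vstack(data),
        ground_truth=pd.DataFrame(truth_rows),
        timeline=timeline,
        tr_s=tr,
        scan_lengths=[n_vol] * len(timeline.scans),
    )


def simulate_signature(
    n_voxels: int,
    latent_course: dict,
    n_subj: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic signature weights and block-wise beta maps.

    ``latent_course`` maps ``(certainty, block)`` -> latent distress value.
    A raw voxel pattern ``u`` ~ N(0, 1) carries the signal; the decoder
    weights are ``w = u / ||u||^2`` so that ``w . u = 1`` and the decoded
    response at zero noise equals the latent course exactly. Per-voxel
    Gaussian noise (sd ``noise_sd``) is added to each subject's beta maps;
    since ``||w|| ~ 1/sqrt(n_voxels)``, decoding accuracy improves as the
    pattern grows.

    Returns ``(weights, beta_maps, cells)`` where ``beta_maps`` has shape
    (n_subj, n_cells, n_voxels) and ``cells`` is the list of
    ``(certainty, block)`` keys in row order.
    """
    if n_voxels < 10:
        raise ValueError("need at least 10 voxels")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n_voxels)
    w = u / float(u @ u)
    cells = list(latent_course.keys())
    course = np.array([latent_course[c] for c in cells], dtype=float)
    beta = course[None, :, None] * u[None, None, :]
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, size=(n_subj, len(cells), n_voxels))
    else:
        beta = np.broadcast_to(beta, (n_subj, len(cells), n_voxels)).copy()
    return w, beta, cells
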