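"""Multivoxel signature decoding.

A fixed pattern of voxelwise weights (an independently trained "signature"
of negative affect) is applied to condition x block beta maps by a bare dot
product, yielding one scalar response per subject, threat-certainty, and
block. The resulting 2 (certainty) x 3 (block) table is analyzed with the
same repeated-measures GLM and polynomial-trend contrasts used for ROI
activation estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import IncompleteDesignError
from .groupstats import RepeatedMeasuresGLM, polynomial_trends

__all__ = [
    "WeightMap",
    "signature_response",
    "signature_table",
    "signature_analysis",
    "SignatureAnalysis",
]


@dataclass
class WeightMap:
    """Voxelwise signature weights over a mask."""

    weights: np.ndarray
    provenance: str = "synthetic"  # or "external"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def signature_response(beta_map, weights) -> float:
    """Dot product of a beta map with the signature weights."""
    w = weights.weights if isinstance(weights, WeightMap) else np.asarray(weights, float)
    b = np.asarray(beta_map, dtype=float)
    if b.shape != w.shape:
        raise ValueError(f"shape mismatch: beta {b.shape} vs weights {w.shape}")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite values in beta map or weights")
    return float(b @ w)


def signature_table(beta_maps, weights, cells) -> pd.DataFrame:
    """Decode per-subject, per-cell beta maps into a long response table.

    ``beta_maps`` has shape (n_subj, n_cells, n_voxels); ``cells`` lists the
    ``(certainty, block)`` identity of each cell row.
    """
    rows = []
    for s in range(beta_maps.shape[0]):
        for c, (certainty, block) in enumerate(cells):
            rows.append(
                dict(subject=s, certainty=certainty, block=int(block),
                     response=signature_response(beta_maps[s, c], weights))
            )
    return pd.DataFrame(rows)


@dataclass
class SignatureAnalysis:
    """Signature decoding results: rm-GLM effects plus per-certainty trends."""

    anova: object
    trends: dict  # certainty -> {"linear": TrendResult, "quadratic": ...}

    def summary(self) -> pd.DataFrame:
        return self.anova.summary()


def signature_analysis(table: pd.DataFrame) -> SignatureAnalysis:
    """2 (certainty) x 3 (block) repeated-measures GLM on signature
    responses, with linear/quadratic trend contrasts per certainty.

    The table needs columns subject, certainty, block, response and a
    complete crossing.
    """
    required = {"subject", "certainty", "block", "response"}
    if not required.issubset(table.columns):
        raise IncompleteDesignError(f"table must have columns {sorted(required)}")
    res = RepeatedMeasuresGLM(
        table, dv="response", within=["certainty", "block"], subject="subject"
    ).fit()
    trends = {}
    for certainty, sub in table.groupby("certainty"):
        wide = sub.pivot_table(index="subject", columns="block",
                               values="response", aggfunc="mean")
        wide = wide[sorted(wide.columns)]
        if wide.shape[1] != 3 or wide.isna().any().any():
            raise IncompleteDesignError(
                f"certainty level {certainty!r} lacks a complete 3-block table"
            )
        trends[certainty] = polynomial_trends(wide.to_numpy())
    return SignatureAnalysis(anova=res, trends=trends)
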