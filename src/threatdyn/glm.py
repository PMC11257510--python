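"""First-level estimation: AR(1)-prewhitened GLS with censoring.

The estimator follows the common fMRI convention: ordinary least squares on
the full design (task + per-scan Legendre drift), a lag-1 autocorrelation
estimate from the OLS residuals, one Cochrane-Orcutt-style prewhitening
pass, and OLS on the whitened system. Censored volumes are deleted;
whitening never couples rows across scan boundaries or censoring gaps (the
first usable row of each contiguous run is scaled by sqrt(1 - phi^2)).

The surface mirrors statsmodels: ``FirstLevelGLM(bold, design).fit()``
returns a :class:`FirstLevelResults` carrying estimates, standard errors,
the AR coefficient, residual diagnostics, and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .exceptions import (
    ExcessCensoringError,
    RankDeficiencyError,
    ZeroVarianceError,
)
from .simulate import BOLDSeries

__all__ = [
    "FirstLevelGLM",
    "FirstLevelResults",
    "ContrastResult",
    "fit_gls_ar1",
    "estimate_contrast",
    "standardize_betas",
]


@dataclass
class ContrastResult:
    """A linear contrast of first-level coefficients."""

    weights: np.ndarray
    estimate: float
    se: float
    t: float
    p: float
    dof: int


def _lag1_pairs(idx_kept: np.ndarray, scan_bounds: list) -> np.ndarray:
    """Positions j (into the kept rows) whose predecessor j-1 is the
    immediately preceding volume of the same scan."""
    starts = set()
    b = 0
    for n in scan_bounds:
        starts.add(b)
        b += n
    ok = np.zeros(len(idx_kept), dtype=bool)
    for j in range(1, len(idx_kept)):
        if idx_kept[j] == idx_kept[j - 1] + 1 and idx_kept[j] not in starts:
            ok[j] = True
    return np.flatnonzero(ok)


class FirstLevelGLM:
    """Single-series GLM with AR(1) prewhitening.

    Parameters
    ----------
    bold : BOLDSeries or 1-D array
        The measured time series over concatenated scans.
    design : DesignMatrix
        Volumes x regressors matrix (task + drift), matching ``bold``.
    censor : boolean array, optional
        True = keep. Censored rows are deleted before fitting.
    """

    def __init__(self, bold, design: DesignMatrix, censor=None):
        y = bold.data if isinstance(bold, BOLDSeries) else np.asarray(bold, float)
        if len(y) != design.X.shape[0]:
            raise ValueError(
                f"series length {len(y)} != design rows {design.X.shape[0]}"
            )
        if censor is None and isinstance(bold, BOLDSeries) and bold.censor is not None:
            censor = bold.censor
        if censor is None:
            censor = np.ones(len(y), dtype=bool)
        censor = np.asarray(censor, dtype=bool)
        if censor.sum() < 0.5 * len(y):
            raise ExcessCensoringError(
                f"{len(y) - censor.sum()} of {len(y)} volumes censored"
            )
        self.y = y
        self.design = design
        self.censor = censor

    def fit(self, ar1: float | str = "estimate") -> "FirstLevelResults":
        """Fit the model.

        ``ar1`` is the AR(1) coefficient: "estimate" (default) derives it
        from the lag-1 autocorrelation of the OLS residuals; a float forces
        a value (0.0 reduces the fit to OLS).
        """
        X = self.design.X
        kept = np.flatnonzero(self.censor)
        Xk, yk = X[kept], self.y[kept]

        beta_ols, _, rank, _ = np.linalg.lstsq(Xk, yk, rcond=None)
        if rank < Xk.shape[1]:
            # identify offending columns for the error message
            bad = []
            for j in range(Xk.shape[1]):
                others = np.delete(Xk, j, axis=1)
                r = Xk[:, j] - others @ np.linalg.lstsq(others, Xk[:, j], rcond=None)[0]
                if r @ r < 1e-10 * (Xk[:, j] @ Xk[:, j] + 1e-300):
                    bad.append(self.design.labels[j].name)
            raise RankDeficiencyError(
                "design matrix is rank deficient after censoring", columns=bad
            )
        resid = yk - Xk @ beta_ols

        if ar1 == "estimate":
            pairs = _lag1_pairs(kept, self.design.scan_lengths)
            denom = float(resid @ resid)
            phi = float(resid[pairs] @ resid[pairs - 1]) / denom if denom > 0 else 0.0
            phi = float(np.clip(phi, -0.99, 0.99))
        else:
            phi = float(ar1)

        if phi != 0.0:
            pairs = _lag1_pairs(kept, self.design.scan_lengths)
            has_prev = np.zeros(len(kept), dtype=bool)
            has_prev[pairs] = True
            scale0 = np.sqrt(1.0 - phi**2)
            Xw = np.where(has_prev[:, None], 0.0, scale0) * Xk
            yw = np.where(has_prev, 0.0, scale0) * yk
            Xw[pairs] = Xk[pairs] - phi * Xk[pairs - 1]
            yw[pairs] = yk[pairs] - phi * yk[pairs - 1]
        else:
            Xw, yw = Xk, yk

        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rw = yw - Xw @ beta
        dof = len(kept) - Xk.shape[1]
        sigma2 = float(rw @ rw) / dof
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))

        return FirstLevelResults(
            model=self,
            params=beta,
            bse=se,
            phi_hat=phi,
            sigma2_hat=sigma2,
            df_resid=dof,
            resid=yk - Xk @ beta,
            wresid=rw,
            cov_params=sigma2 * xtx_inv,
            kept=kept,
        )


@dataclass
class FirstLevelResults:
    """First-level fit: coefficients, uncertainties, diagnostics."""

    model: FirstLevelGLM
    params: np.ndarray
    bse: np.ndarray
    phi_hat: float
    sigma2_hat: float
    df_resid: int
    resid: np.ndarray
    wresid: np.ndarray
    cov_params: np.ndarray
    kept: np.ndarray

    @property
    def design(self) -> DesignMatrix:
        return self.model.design

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.bse > 0, self.params / self.bse, 0.0)

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(beta=self.params, se=self.bse, t=self.tvalues, p=self.pvalues),
            index=self.design.column_names,
        )

    def beta(self, condition: str, component: str) -> float:
        return float(self.params[self.design.column_index(condition, component)])

    def contrast(self, weights) -> ContrastResult:
        """Contrast of coefficients.

        ``weights`` is a full-length vector or a ``{(cond, comp): w}`` /
        ``{"cond:comp": w}`` mapping (entries on the omitted reference
        columns contribute 0).
        """
        if isinstance(weights, dict):
            w = self.design.contrast_vector(weights)
        else:
            w = np.asarray(weights, dtype=float)
            if len(w) != len(self.params):
                raise ValueError("weights length does not match columns")
        est = float(w @ self.params)
        var = float(w @ self.cov_params @ w)
        se = np.sqrt(max(var, 0.0))
        if np.any(w) and se == 0:
            raise ZeroVarianceError("contrast is not estimable (zero variance)")
        t = est / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), self.df_resid) if se > 0 else 1.0
        return ContrastResult(weights=w, estimate=est, se=se, t=t, p=p,
                              dof=self.df_resid)

    def standardized_params(self, bold_sd: float | None = None) -> np.ndarray:
        """Standardized regression coefficients.

        beta_j * sd(column j) / sd(series): the expected response change,
        in units of the data's standard deviation, per one-sd change of the
        regressor.
        """
        y = self.model.y[self.kept]
        sd_y = float(np.std(y, ddof=1)) if bold_sd is None else float(bold_sd)
        if sd_y <= 0:
            raise ZeroVarianceError("series has zero variance")
        Xk = self.design.X[self.kept]
        sd_x = np.std(Xk, axis=0, ddof=1)
        if np.any(sd_x[self.design.task_indices] == 0):
            raise ZeroVarianceError("zero-variance task column")
        return self.params * sd_x / sd_y

    def summary(self) -> str:
        lines = [
            "First-level GLM (AR(1)-prewhitened GLS)",
            f"  volumes used: {len(self.kept)}   df_resid: {self.df_resid}",
            f"  phi_hat: {self.phi_hat:+.4f}   sigma2_hat: {self.sigma2_hat:.4f}",
            "",
            self.params_frame().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def fit_gls_ar1(bold, design: DesignMatrix, censor=None) -> FirstLevelResults:
    """Functional wrapper: prewhitened GLS fit of one series."""
    return FirstLevelGLM(bold, design, censor=censor).fit()


def estimate_contrast(fit: FirstLevelResults, weights) -> ContrastResult:
    """Functional wrapper for :meth:`FirstLevelResults.contrast`."""
    return fit.contrast(weights)


def standardize_betas(fit: FirstLevelResults, bold_sd: float | None = None):
    """Functional wrapper for :meth:`FirstLevelResults.standardized_params`."""
    return fit.standardized_params(bold_sd)
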