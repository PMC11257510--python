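"""Group-level inference.

Covers the study-style second level: one-sample t-tests on per-subject
activation estimates, Benjamini-Hochberg FDR over voxelwise maps with
minimum-conjunction (logical AND) overlays, fully-within-subject
repeated-measures GLMs with Huynh-Feldt sphericity correction and partial
eta squared, linear/quadratic polynomial trend contrasts over ordered
blocks, Cohen's dz with interpretive bands, JZS (Cauchy-prior) Bayes
factors for paired/one-sample designs, and the minimum detectable effect of
a two-tailed one-sample t-test.

The repeated-measures GLM is exposed statsmodels-style:
``RepeatedMeasuresGLM(table, dv=..., within=[...], subject=...).fit()``
returns an :class:`RMResults` with one row per within-subject effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    IncompleteDesignError,
    IntegrationError,
    ZeroVarianceError,
)

__all__ = [
    "one_sample_t",
    "fdr_bh",
    "min_conjunction",
    "RepeatedMeasuresGLM",
    "RMResults",
    "RMEffect",
    "rm_anova",
    "polynomial_trends",
    "TrendResult",
    "cohens_dz",
    "bf10_paired",
    "BayesResult",
    "min_detectable_effect",
    "DEFAULT_RSCALE",
]

#: conventional default Cauchy prior scale for the JZS Bayes factor
DEFAULT_RSCALE = float(np.sqrt(2.0) / 2.0)


# ---------------------------------------------------------------------------
# simple tests and map-level operations

def one_sample_t(values):
    """One-sample two-tailed t-test against zero.

    Returns ``(t, p, dz)`` where dz = mean / sd is the standardized effect.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("values have zero variance")
    t, p = stats.ttest_1samp(v, 0.0)
    return float(t), float(p), float(v.mean() / sd)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    The family is the supplied (in-mask) tests; shape is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def min_conjunction(*masks):
    """Minimum-conjunction (voxelwise logical AND) of rejection masks."""
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError("mask shapes differ")
        out = out & m
    return out


# ---------------------------------------------------------------------------
# repeated-measures GLM

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) orthonormal basis orthogonal to the unit vector."""
    # Helmert-style contrasts, then orthonormalized (the F statistic is
    # invariant to the particular basis chosen).
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        C[:j, j - 1] = 1.0
        C[j, j - 1] = -j
    C /= np.linalg.norm(C, axis=0, keepdims=True)
    return C


@dataclass
class RMEffect:
    """One within-subject effect of a repeated-measures GLM."""

    name: str
    F: float
    df_num: float
    df_den: float
    hf_epsilon: float
    p_unc: float
    p_hf: float
    partial_eta2: float
    ss_effect: float
    ss_error: float


class RMResults:
    """Results of a fully-within-subject repeated-measures GLM."""

    def __init__(self, effects: dict, n_subjects: int, factors: dict):
        self.effects = effects
        self.n_subjects = n_subjects
        self.factors = factors

    def __getitem__(self, name: str) -> RMEffect:
        return self.effects[name]

    def summary(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                dict(effect=e.name, F=e.F, df_num=e.df_num, df_den=e.df_den,
                     hf_epsilon=e.hf_epsilon, p_unc=e.p_unc, p_hf=e.p_hf,
                     partial_eta2=e.partial_eta2)
            )
        return pd.DataFrame(rows).set_index("effect")

    def __repr__(self):
        return f"<RMResults: {list(self.effects)} n={self.n_subjects}>"


class RepeatedMeasuresGLM:
    """Fully-within-subject repeated-measures GLM.

    Parameters
    ----------
    table : DataFrame
        Long format, one row per subject x cell.
    dv : str
        Column holding the dependent variable.
    within : list of str
        Within-subject factor columns (any number of factors).
    subject : str
        Subject identifier column.

    Every subject must contribute exactly one observation per cell of the
    full factorial crossing. Each effect is tested against its own
    effect-by-subject error term; the Huynh-Feldt epsilon (capped at 1,
    exactly 1 for single-df effects) corrects the degrees of freedom of
    effects with more than one numerator df.
    """

    def __init__(self, table: pd.DataFrame, dv: str, within, subject: str):
        self.dv = dv
        self.within = list(within)
        self.subject = subject

        levels = {f: sorted(table[f].unique()) for f in self.within}
        subjects = sorted(table[subject].unique())
        n_cells = int(np.prod([len(v) for v in levels.values()]))
        pivot = table.pivot_table(
            index=subject, columns=self.within, values=dv, aggfunc="mean"
        )
        expected = n_cells
        if pivot.shape != (len(subjects), expected) or pivot.isna().any().any():
            raise IncompleteDesignError(
                "repeated-measures table must be a complete crossing with "
                "one observation per subject and cell"
            )
        counts = table.groupby([subject] + self.within).size()
        if (counts != 1).any():
            raise IncompleteDesignError("more than one row per subject and cell")
        if len(subjects) < max(len(v) for v in levels.values()):
            raise IncompleteDesignError("need at least as many subjects as levels")

        # order columns as the cartesian product of factor levels
        order = list(itertools.product(*[levels[f] for f in self.within]))
        if len(self.within) == 1:
            pivot = pivot[[o[0] for o in order]]
        else:
            pivot = pivot[order]
        self.levels = levels
        self.data = pivot.to_numpy(dtype=float)

    def fit(self) -> RMResults:
        n = self.data.shape[0]
        k_per = [len(self.levels[f]) for f in self.within]

        effects = {}
        for r in range(1, len(self.within) + 1):
            for combo in itertools.combinations(range(len(self.within)), r):
                mats = []
                for i, f in enumerate(self.within):
                    k = k_per[i]
                    if i in combo:
                        mats.append(_orthonormal_contrasts(k))
                    else:
                        mats.append(np.full((k, 1), 1.0 / np.sqrt(k)))
                M = mats[0]
                for m in mats[1:]:
                    M = np.kron(M, m)
                Y = self.data @ M                      # n x q contrast scores
                q = Y.shape[1]
                ybar = Y.mean(axis=0)
                ss_eff = float(n * (ybar @ ybar))
                R = Y - ybar
                ss_err = float((R * R).sum())
                df_num = q
                df_den = q * (n - 1)
                F = (ss_eff / df_num) / (ss_err / df_den) if ss_err > 0 else np.inf

                if q == 1:
                    eps = 1.0
                else:
                    S = (R.T @ R) / (n - 1)
                    tr = np.trace(S)
                    denom = q * float((S * S).sum())
                    # degenerate (zero-variance) contrast scores: sphericity
                    # holds trivially
                    gg = (tr * tr) / denom if denom > 0 else 1.0
                    gg = min(max(gg, 1.0 / q), 1.0)
                    hf = (n * q * gg - 2.0) / (q * (n - 1.0 - q * gg))
                    eps = float(min(hf, 1.0))

                p_unc = float(stats.f.sf(F, df_num, df_den))
                p_hf = float(stats.f.sf(F, df_num * eps, df_den * eps))
                name = " x ".join(self.within[i] for i in combo)
                effects[name] = RMEffect(
                    name=name, F=float(F), df_num=df_num, df_den=df_den,
                    hf_epsilon=eps, p_unc=p_unc, p_hf=p_hf,
                    partial_eta2=ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                    ss_effect=ss_eff, ss_error=ss_err,
                )
        return RMResults(effects, n_subjects=n, factors=self.levels)


def rm_anova(table: pd.DataFrame, factors, dv: str = "value",
             subject: str = "subject") -> RMResults:
    """Functional wrapper around :class:`RepeatedMeasuresGLM`."""
    return RepeatedMeasuresGLM(table, dv=dv, within=factors, subject=subject).fit()


# ---------------------------------------------------------------------------
# polynomial trends

LINEAR_WEIGHTS = (-1.0, 0.0, 1.0)
QUADRATIC_WEIGHTS = (1.0, -2.0, 1.0)


@dataclass
class TrendResult:
    """A polynomial trend contrast over ordered blocks."""

    name: str
    estimate: float
    t: float
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta2: float


def polynomial_trends(block_values) -> dict:
    """Linear and quadratic trend contrasts over blocks 1..3.

    ``block_values`` is an (n_subjects x 3) array (or DataFrame) of
    per-subject block means. Each contrast is evaluated as a one-sample
    t-test of the per-subject contrast scores; F = t^2 with (1, n-1) df.
    """
    Y = np.asarray(block_values, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError("expected an n x 3 array of block means")
    n = Y.shape[0]
    out = {}
    for name, w in [("linear", LINEAR_WEIGHTS), ("quadratic", QUADRATIC_WEIGHTS)]:
        scores = Y @ np.asarray(w)
        est = float(scores.mean())
        sd = scores.std(ddof=1)
        if sd == 0:
            t = 0.0 if est == 0 else np.inf
        else:
            t = est / (sd / np.sqrt(n))
        F = t * t
        p = float(stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        out[name] = TrendResult(
            name=name, estimate=est, t=float(t), F=float(F),
            df_num=1, df_den=n - 1, p=p,
            partial_eta2=float(F / (F + n - 1)) if np.isfinite(F) else 1.0,
        )
    return out


# ---------------------------------------------------------------------------
# effect sizes

#: Cohen benchmarks: nil <= 0.10, small ~0.20, medium ~0.50, large ~0.80;
#: band edges at the midpoints between adjacent benchmarks
_DZ_BANDS = [(0.10, "nil"), (0.35, "small"), (0.65, "medium"), (np.inf, "large")]


def dz_band(dz: float) -> str:
    """Interpretive band for a standardized paired effect size."""
    a = abs(dz)
    for edge, label in _DZ_BANDS:
        if a <= edge:
            return label
    return "large"


def cohens_dz(diffs):
    """Cohen's dz for paired differences: mean / sd, with its band."""
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("differences have zero variance")
    dz = float(d.mean() / sd)
    return dz, dz_band(dz)


# ---------------------------------------------------------------------------
# JZS Bayes factor

@dataclass
class BayesResult:
    """JZS Bayes factor with its interpretive band.

    Bands follow the printed benchmarks: BF10 <= 0.10 strong evidence for
    the null, 0.10-0.33 moderate, 0.33-1 weak; > 1 favors the alternative.
    """

    bf10: float
    band: str


def bf10_band(bf10: float) -> str:
    if bf10 <= 0.10:
        return "strong_null"
    if bf10 <= 1.0 / 3.0:
        return "moderate_null"
    if bf10 <= 1.0:
        return "weak_null"
    return "favors_alternative"


def bf10_paired(t: float, n: int, rscale: float = DEFAULT_RSCALE) -> BayesResult:
    """JZS Bayes factor for a one-sample / paired t statistic.

    The alternative places a Cauchy(0, rscale) prior on the standardized
    effect delta; marginalizing gives

        BF10 = integral over g of
               (1 + n g)^(-1/2) (1 + t^2/((1+n g) nu))^(-(nu+1)/2) pi(g) dg
               / (1 + t^2/nu)^(-(nu+1)/2)

    with nu = n - 1 and pi(g) the inverse-gamma(1/2, rscale^2/2) density
    induced by the Cauchy prior. The integral is evaluated numerically.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    nu = n - 1
    t = float(t)
    r2 = rscale * rscale

    def integrand(g):
        return (
            (1.0 + n * g) ** -0.5
            * (1.0 + t * t / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * np.sqrt(r2 / (2.0 * np.pi)) * g ** -1.5 * np.exp(-r2 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or (num > 0 and err / num > 1e-6) or num <= 0:
        raise IntegrationError(
            f"marginal likelihood integration failed (value {num}, err {err})"
        )
    denom = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    bf10 = float(num / denom)
    return BayesResult(bf10=bf10, band=bf10_band(bf10))


# ---------------------------------------------------------------------------
# power

def power_one_sample_t(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of a two-tailed one-sample t-test at effect size dz."""
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ncp = dz * np.sqrt(n)
    val = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if not np.isfinite(val):
        # the noncentral-t implementation loses accuracy at extreme
        # noncentrality; there the normal approximation is exact in practice
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        val = float(stats.norm.sf(zcrit - ncp) + stats.norm.cdf(-zcrit - ncp))
    return val


def min_detectable_effect(n: int, alpha: float = 0.05,
                          power: float = 0.80) -> float:
    """Smallest dz a two-tailed one-sample t-test detects with the target
    power, via the noncentral t distribution."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    f = lambda d: power_one_sample_t(n, d, alpha) - power
    return float(optimize.brentq(f, 1e-6, 10.0, xtol=1e-10))
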