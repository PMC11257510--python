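"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package:
the repeated-measures oracle works from cell-mean sums of squares via
inclusion-exclusion centering of marginal-mean tensors; the Bayes-factor
oracle marginalizes the Cauchy prior over the effect size directly with the
noncentral-t density; the FDR oracle enumerates the step-up rule.
"""

import itertools

import numpy as np
from scipy import integrate, stats


def rm_anova_oracle(data: np.ndarray, k_per):
    """Brute-force within-subject ANOVA from cell means.

    ``data`` is subjects x cells with cells ordered as the cartesian
    product of factor levels with sizes ``k_per``. Returns a dict keyed by
    factor-index tuples with (F, df_num, df_den, gg_eps, hf_eps, p_unc,
    p_hf, partial_eta2).
    """
    n = data.shape[0]
    shape = (n,) + tuple(k_per)
    Y = data.reshape(shape)
    nfac = len(k_per)

    def center(T, axis):
        return T - T.mean(axis=axis, keepdims=True)

    out = {}
    for r in range(1, nfac + 1):
        for combo in itertools.combinations(range(nfac), r):
            excluded = [f for f in range(nfac) if f not in combo]
            # marginal means over excluded factors (subject axis kept)
            T = Y.mean(axis=tuple(a + 1 for a in excluded), keepdims=False)
            # T has shape (n, k_f for f in combo)
            scale = float(np.prod([k_per[f] for f in excluded]))
            # effect tensor: inclusion-exclusion centering over each factor
            E = T.mean(axis=0)              # cell means over subjects
            for ax in range(E.ndim):
                E = center(E, ax)
            ss_eff = n * scale * float((E * E).sum())
            # effect-by-subject residual: center over factors and subjects
            Z = T.copy()
            for ax in range(1, Z.ndim):
                Z = center(Z, ax)
            Z = center(Z, 0)
            ss_err = scale * float((Z * Z).sum())
            q = int(np.prod([k_per[f] - 1 for f in combo]))
            df_num, df_den = q, q * (n - 1)
            F = (ss_eff / df_num) / (ss_err / df_den)

            # epsilon from the covariance of orthonormal contrast scores,
            # basis built by QR decomposition (different construction from
            # the implementation's Helmert contrasts)
            mats = []
            for f in range(nfac):
                k = k_per[f]
                if f in combo:
                    A = np.eye(k) - np.full((k, k), 1.0 / k)
                    Q, _ = np.linalg.qr(A)
                    # keep the k-1 columns spanning the centered space
                    B = Q[:, :k]
                    keep = [j for j in range(k)
                            if abs(np.ones(k) @ B[:, j]) < 1e-9]
                    mats.append(B[:, keep[: k - 1]])
                else:
                    mats.append(np.full((k, 1), 1.0 / np.sqrt(k)))
            M = mats[0]
            for m in mats[1:]:
                M = np.kron(M, m)
            scores = data @ M
            S = np.cov(scores, rowvar=False)
            S = np.atleast_2d(S)
            if q == 1:
                gg = hf = 1.0
            else:
                gg = np.trace(S) ** 2 / (q * (S * S).sum())
                hf = min(1.0, (n * q * gg - 2.0) / (q * (n - 1.0 - q * gg)))
            p_unc = stats.f.sf(F, df_num, df_den)
            p_hf = stats.f.sf(F, df_num * hf, df_den * hf)
            out[combo] = dict(F=F, df_num=df_num, df_den=df_den,
                              gg_eps=gg, hf_eps=hf, p_unc=p_unc, p_hf=p_hf,
                              partial_eta2=ss_eff / (ss_eff + ss_err))
    return out


def fdr_bh_oracle(pvals, q):
    """Direct enumeration of the Benjamini-Hochberg step-up rule."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def bf10_oracle(t, n, rscale):
    """JZS Bayes factor by marginalizing the Cauchy prior over the effect
    size against the noncentral-t density."""
    nu = n - 1
    root = np.sqrt(n)

    def num_integrand(d):
        v = stats.cauchy.pdf(d, 0.0, rscale) * stats.nct.pdf(t, nu, d * root)
        return v if np.isfinite(v) else 0.0

    # split at the likelihood peak so quad resolves the mass
    peak = t / root
    num = 0.0
    for a, b in [(-np.inf, min(0.0, peak)), (min(0.0, peak), max(0.0, peak)),
                 (max(0.0, peak), np.inf)]:
        if a == b:
            continue
        val, _ = integrate.quad(num_integrand, a, b, limit=400)
        num += val
    return num / stats.t.pdf(t, nu)


def power_normal_approx(n, alpha, power):
    """Large-n closed form for the minimum detectable effect."""
    return (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) / np.sqrt(n)
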