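"""Kernel score test of a SNP set's joint association with one disease.

The statistic is Q = (y - mu)' Z W^2 Z' (y - mu) over the set's dosage
matrix Z (subjects x SNPs), with mu from a covariate-adjusted logistic
null model.  Under the null, Q follows a weighted sum of chi-square(1)
variables; the p-value comes from characteristic-function inversion
(Imhof/Davies-style numerical integration), falling back to the Liu
four-moment match when the inversion fails.

The set defines only the SNP collection — all null-model subjects enter
the test; subject membership is consumed by the architecture stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats

from .io import GenotypeMatrix, PhenotypeTable
from .nsnmf import SNPSet

logger = logging.getLogger(__name__)


@dataclass
class NullModel:
    design: np.ndarray        # (n, q) covariate design incl. intercept
    mu: np.ndarray            # fitted probabilities
    residuals: np.ndarray     # y - mu
    weights: np.ndarray       # mu (1 - mu)
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if np.any((self.mu <= 0) | (self.mu >= 1)):
            raise ValueError("fitted probabilities must lie strictly in (0,1)")


def covariate_design(pheno: PhenotypeTable) -> np.ndarray:
    """Intercept, age, age^2, sex, BMI and any pcN columns present."""
    df = pheno.data
    cols = [np.ones(len(df)), df["age"].to_numpy(float),
            df["age"].to_numpy(float) ** 2, df["sex"].to_numpy(float),
            df["bmi"].to_numpy(float)]
    for c in pheno.pc_columns:
        cols.append(df[c].to_numpy(float))
    return np.column_stack(cols)


def fit_null(y, covariates, subject_ids=None) -> NullModel:
    """Logistic null fit by IRLS, iterated to gradient norm < 1e-8."""
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if classes == {0.0} or classes == {1.0}:
        raise ValueError("y is constant; both classes must be present")
    if classes != {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(y)), X])
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200,
                                                          tol=1e-12)
    mu = np.asarray(res.fittedvalues)
    grad = X.T @ (y - mu)
    if not res.converged or not np.all(np.isfinite(res.bse)):
        raise RuntimeError("null model failed to converge (separation?)")
    if np.linalg.norm(grad) > 1e-6:
        raise RuntimeError(f"null-model gradient norm {np.linalg.norm(grad):.2e}"
                           " too large")
    if np.any(mu <= 1e-10) or np.any(mu >= 1 - 1e-10):
        raise RuntimeError("fitted probabilities at the boundary (separation?)")
    if subject_ids is None:
        subject_ids = [str(i) for i in range(len(y))]
    return NullModel(design=X, mu=mu, residuals=y - mu,
                     weights=mu * (1 - mu), subject_ids=list(subject_ids))


@dataclass
class SetTestResult:
    label: str
    disease: str
    q_stat: float
    p_value: float
    eigenvalues: np.ndarray
    method: str               # "davies" or "liu"


# ---------------------------------------------------------------------------
# p-value of a positively weighted sum of chi-square(1) variables
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def _gl_integrate(f, a, b):
    half = 0.5 * (b - a)
    u = a + half * (_GL_NODES + 1.0)
    return half * float(np.sum(_GL_WEIGHTS * f(u)))


def _euler_accelerated_sum(terms):
    """Sum an (eventually) alternating series by iterated averaging."""
    partial = np.cumsum(terms)
    tail = partial[-min(len(partial), 24):]
    while len(tail) > 1:
        tail = 0.5 * (tail[:-1] + tail[1:])
    return float(tail[0])


def davies_pvalue(q: float, lambdas: np.ndarray, acc: float = 1e-9,
                  n_intervals: int = 48):
    """Upper-tail P(sum_j lambda_j chi2_1 > q) by CF inversion.

    Imhof's representation p = 1/2 + (1/pi) int_0^inf sin(theta(u)) /
    (u rho(u)) du is evaluated by Gauss-Legendre panels split at
    consecutive zeros of sin(theta(u)), with Euler acceleration of the
    alternating tail.  Returns (p, ok); ok is False when the value falls
    outside (0, 1] and the Liu fallback should be used.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0 or q <= 0:
        return 1.0, True

    def theta(u):
        return 0.5 * np.sum(np.arctan(np.outer(lam, u)), axis=0) - 0.5 * q * u

    def integrand(u):
        u = np.asarray(u, dtype=float)
        rho = np.exp(0.25 * np.sum(np.log1p(np.outer(lam, u) ** 2), axis=0))
        out = np.empty_like(u)
        tiny = u < 1e-300
        out[~tiny] = np.sin(theta(u[~tiny])) / (u[~tiny] * rho[~tiny])
        out[tiny] = 0.5 * (lam.sum() - q)       # limit at u -> 0+
        return out

    # theta is concave with theta'(0) = (sum lam - q)/2 and theta' -> -q/2;
    # past its peak it decreases strictly, so zeros of sin(theta) are the
    # descending levels k*pi.
    slam = lam.sum()
    if slam > q:
        from scipy.optimize import brentq
        u_hi = 1.0
        while 0.5 * np.sum(lam / (1 + (lam * u_hi) ** 2)) - 0.5 * q >= 0:
            u_hi *= 2
        u_peak = brentq(lambda u: 0.5 * np.sum(lam / (1 + (lam * u) ** 2))
                        - 0.5 * q, 1e-12, u_hi)
    else:
        u_peak = 0.0

    from scipy.optimize import brentq
    th_peak = float(theta(np.array([max(u_peak, 1e-12)]))[0])
    k_start = int(np.floor(th_peak / np.pi))
    breaks = [0.0]
    u_prev = max(u_peak, 1e-12)
    for k in range(k_start, k_start - n_intervals, -1):
        target = k * np.pi
        if target >= th_peak:
            continue
        # bracket the crossing theta(u) = target beyond u_prev
        step = 2.0 * np.pi / q if q > 0 else 1.0
        lo, hi = u_prev, u_prev + step
        while float(theta(np.array([hi]))[0]) > target:
            lo, hi = hi, hi + step
        u_zero = brentq(lambda u: float(theta(np.array([u]))[0]) - target,
                        lo, hi, xtol=1e-13, rtol=1e-14)
        breaks.append(u_zero)
        u_prev = u_zero
    scalar_f = lambda u: float(integrand(np.array([u]))[0])
    if len(breaks) < 8:  # degenerate phase; fall back to adaptive quad
        with np.errstate(over="ignore"):
            val, _ = integrate.quad(scalar_f, 0.0, np.inf, limit=800)
    else:
        # head panel is non-oscillatory (|theta| < pi) but can span a wide
        # u range; integrate it adaptively, then fixed GL per half-period
        head, _ = integrate.quad(scalar_f, breaks[0], breaks[1],
                                 limit=200, epsabs=acc * 1e-3, epsrel=1e-12)
        tail = np.array([_gl_integrate(integrand, a, b)
                         for a, b in zip(breaks[1:-1], breaks[2:])])
        val = head + (_euler_accelerated_sum(tail) if tail.size else 0.0)
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or p <= 0.0 or p > 1.0 + 1e-9:
        return p, False
    return min(float(p), 1.0), True


def liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Liu-Tang-Zhang four-moment chi-square approximation (upper tail)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam ** r) for r in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    if s1 ** 2 > s2:
        a = 1 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        dof = a ** 2 - 2 * delta
    else:
        delta = 0.0
        a = 1 / s1 if s1 > 0 else 1.0
        dof = 1 / s1 ** 2 if s1 > 0 else c1 ** 2 / c2
    t_star = (q - mu_q) / sigma_q
    mu_x = dof + delta
    sigma_x = np.sqrt(2) * np.sqrt(dof + 2 * delta)
    x = t_star * sigma_x + mu_x
    return float(stats.ncx2.sf(x, dof, delta)) if delta > 0 else \
        float(stats.chi2.sf(x, dof))


def mixture_pvalue(q: float, lambdas: np.ndarray):
    """Davies-style inversion with Liu fallback; returns (p, method)."""
    p, ok = davies_pvalue(q, lambdas)
    if ok:
        return p, "davies"
    return liu_pvalue(q, lambdas), "liu"


# ---------------------------------------------------------------------------
# the set test
# ---------------------------------------------------------------------------

def _beta_maf_weights(mafs: np.ndarray) -> np.ndarray:
    return stats.beta.pdf(np.clip(mafs, 1e-8, 1 - 1e-8), 1.0, 25.0)


def skat_test(s: SNPSet, g: GenotypeMatrix, null: NullModel,
              weights: str = "flat") -> SetTestResult:
    """Score test of the set's SNPs against the null model's phenotype.

    Missing dosages are mean-imputed per SNP over the tested subjects.
    """
    if weights not in ("flat", "beta"):
        raise ValueError(f"unknown weight scheme {weights!r}")
    if not s.snp_ids:
        raise ValueError("empty SNP list")
    sub = g.subset(snp_idx=g.snp_index(s.snp_ids),
                   subject_idx=g.subject_index(null.subject_ids))
    Z = sub.dosages.astype(float).T          # subjects x SNPs
    miss = sub.missing.T
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.nansum(np.where(miss, np.nan, Z), axis=0)
            / np.maximum((~miss).sum(axis=0), 1), 0.0)
        Z[miss] = np.broadcast_to(col_mean, Z.shape)[miss]
    if weights == "flat":
        w = np.ones(Z.shape[1])
    else:
        w = _beta_maf_weights(sub.minor_allele_frequencies())

    r = null.residuals
    Zw = Z * w[None, :]
    q_stat = float(np.sum((r @ Zw) ** 2))
    if not np.any(Zw):
        return SetTestResult(s.label, "", 0.0, 1.0, np.array([]), "davies")

    # eigenvalues of P0^1/2 K P0^1/2 via B = (I - Htilde) V^1/2 Z W
    v_half = np.sqrt(null.weights)
    Xv = null.design * v_half[:, None]
    # projection onto the column space of V^1/2 X
    Qx, _ = np.linalg.qr(Xv)
    M = v_half[:, None] * Zw
    B = M - Qx @ (Qx.T @ M)
    lam = np.linalg.eigvalsh(B.T @ B)
    lam = lam[lam > max(lam.max(), 0) * 1e-10] if lam.size else lam
    if lam.size == 0:
        return SetTestResult(s.label, "", q_stat, 1.0, lam, "davies")
    p, method = mixture_pvalue(q_stat, lam)
    return SetTestResult(s.label, "", q_stat, p, lam, method)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def test_all_sets(sets: list[SNPSet], g: GenotypeMatrix,
                  pheno: PhenotypeTable, weights: str = "flat",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Test every set against CHD and against T2D.

    A set is significant (and retained downstream) when its smaller of the
    two p-values beats alpha / n_generated_sets.
    """
    if not sets:
        return pd.DataFrame(columns=["label", "p_chd", "p_t2d", "q_chd",
                                     "q_t2d", "method_chd", "method_t2d",
                                     "significant"])
    pheno = pheno.aligned_to(g.subject_ids)
    X = covariate_design(pheno)
    nulls = {
        "CHD": fit_null(pheno.data["chd"].to_numpy(), X, g.subject_ids),
        "T2D": fit_null(pheno.data["t2d"].to_numpy(), X, g.subject_ids),
    }
    thresh = bonferroni_threshold(alpha, len(sets))
    rows = []
    for s in sets:
        res = {}
        for disease, null in nulls.items():
            r = skat_test(s, g, null, weights=weights)
            r.disease = disease
            res[disease] = r
        rows.append({
            "label": s.label,
            "p_chd": res["CHD"].p_value,
            "p_t2d": res["T2D"].p_value,
            "q_chd": res["CHD"].q_stat,
            "q_t2d": res["T2D"].q_stat,
            "method_chd": res["CHD"].method,
            "method_t2d": res["T2D"].method,
            "significant": min(res["CHD"].p_value,
                               res["T2D"].p_value) < thresh,
        })
    return pd.DataFrame(rows)
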