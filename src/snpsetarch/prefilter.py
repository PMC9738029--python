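"""Quality control, per-SNP logistic prescreen, panel pooling, ancestry PCs.

QC filters are applied in a fixed order (SNP missingness, MAF, HWE exact
test, subject call rate) and every step's removals are recorded in a
report so the accounting stays auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GwasResult:
    snp_id: str
    beta: float
    se: float
    wald_p: float
    disease: str
    flagged: bool = False

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test P (two-sided, no mid-p).

    Sums the probabilities of all heterozygote counts, conditional on the
    allele counts, that are no more likely than the observed one
    (Wigginton-style SNP-HWE).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # log-probability of each compatible het count, conditional on allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_rare_hom = (n_rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (hets * math.log(2.0)
            - _lgamma_arr(hets + 1)
            - _lgamma_arr(n_rare_hom + 1)
            - _lgamma_arr(n_common_hom + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = dict(zip(hets.tolist(), p.tolist()))[n_het]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x):
    from scipy.special import gammaln
    return gammaln(np.asarray(x, dtype=float))


def qc_filter(g: GenotypeMatrix, snp_missing_max: float = 0.05,
              maf_min: float = 0.01, hwe_p_min: float = 1e-6,
              subject_missing_max: float = 0.05):
    """Apply QC filters in order; thresholds are closed (>= / <= remove).

    Returns ``(filtered_matrix, report)`` where the report is a DataFrame
    with one row per step (step, snps_removed, subjects_removed).
    """
    if g.n_snps == 0 or g.n_subjects == 0:
        raise ValueError("empty genotype matrix")
    report = []

    keep = g.snp_missing_rates() < snp_missing_max
    report.append(("snp_missingness", int((~keep).sum()), 0))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    maf = g.minor_allele_frequencies()
    keep = maf > maf_min
    report.append(("maf", int((~keep).sum()), 0))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    hwe_keep = np.ones(g.n_snps, dtype=bool)
    for i in range(g.n_snps):
        row = g.dosages[i][~g.missing[i]]
        counts = [int((row == d).sum()) for d in (0, 1, 2)]
        if hwe_exact_p(*counts) < hwe_p_min:
            hwe_keep[i] = False
    report.append(("hwe", int((~hwe_keep).sum()), 0))
    g = g.subset(snp_idx=np.flatnonzero(hwe_keep))

    if g.n_snps == 0:
        raise ValueError("all SNPs removed by QC")

    subj_keep = g.subject_missing_rates() < subject_missing_max
    report.append(("subject_call_rate", 0, int((~subj_keep).sum())))
    g = g.subset(subject_idx=np.flatnonzero(subj_keep))

    report_df = pd.DataFrame(report, columns=["step", "snps_removed",
                                              "subjects_removed"])
    return g, report_df


def _logistic_fit(y, X):
    """IRLS logistic fit; returns (params, bse) or raises on failure."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError("IRLS did not converge")
    if not np.all(np.isfinite(res.bse)):
        raise RuntimeError("non-finite standard errors (separation?)")
    return res.params, res.bse


def logistic_gwas(g: GenotypeMatrix, y, covariates=None,
                  disease: str = "CHD") -> list[GwasResult]:
    """Additive-coded per-SNP logistic regression with Wald p-values.

    Subjects missing a dosage at a SNP are dropped for that SNP only.
    Non-estimable or non-convergent SNPs are flagged with p = 1.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must be binary with both classes present")
    n = g.n_subjects
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), C])) < C.shape[1] + 1:
            raise ValueError("covariate matrix (with intercept) not full rank")
    # standardize covariates for IRLS stability; betas for the SNP dosage
    # itself are unaffected (affine-invariance of the remaining fit)
    if C.shape[1]:
        C = (C - C.mean(0)) / np.where(C.std(0) > 0, C.std(0), 1.0)

    results = []
    for i in range(g.n_snps):
        obs = ~g.missing[i]
        dose = g.dosages[i, obs].astype(float)
        snp_id = g.snp_meta.at[i, "snp_id"]
        if dose.size == 0 or np.all(dose == dose[0]):
            results.append(GwasResult(snp_id, 0.0, np.nan, 1.0, disease,
                                      flagged=True))
            continue
        X = np.column_stack([np.ones(obs.sum()), dose, C[obs]])
        try:
            params, bse = _logistic_fit(y[obs], X)
            beta, se = float(params[1]), float(bse[1])
            if se > 1e3:  # quasi-separation: SE blows up
                raise RuntimeError("unstable fit")
            wald_p = float(2 * stats.norm.sf(abs(beta / se)))
            results.append(GwasResult(snp_id, beta, se, max(wald_p, 5e-324),
                                      disease))
        except Exception as exc:
            logger.warning("SNP %s: %s; flagged", snp_id, exc)
            results.append(GwasResult(snp_id, 0.0, np.nan, 1.0, disease,
                                      flagged=True))
    return results


def pool_panels(g: GenotypeMatrix, chd_results: list[GwasResult],
                t2d_results: list[GwasResult],
                p_thresh: float = 5e-5) -> GenotypeMatrix:
    """Merge the two prescreen panels into one pooled matrix.

    A SNP passing the loose threshold for both diseases is assigned to the
    disease with the smaller p and flagged as dual (``dual_hit`` column).
    """
    chd_by_id = {r.snp_id: r for r in chd_results}
    t2d_by_id = {r.snp_id: r for r in t2d_results}
    rows = []
    for snp_id in g.snp_ids:
        rc = chd_by_id.get(snp_id)
        rt = t2d_by_id.get(snp_id)
        hit_c = rc is not None and rc.wald_p < p_thresh
        hit_t = rt is not None and rt.wald_p < p_thresh
        if not (hit_c or hit_t):
            continue
        if hit_c and hit_t:
            chosen = rc if rc.wald_p <= rt.wald_p else rt
            dual = True
        else:
            chosen = rc if hit_c else rt
            dual = False
        rows.append((snp_id, chosen.disease, chosen.wald_p,
                     chosen.or_value, dual))
    if not rows:
        raise ValueError(f"no SNP passed the prescreen threshold {p_thresh}")
    pooled_ids = [r[0] for r in rows]
    out = g.restrict_to_snps(pooled_ids)
    out.snp_meta["panel_label"] = [r[1] for r in rows]
    out.snp_meta["gwas_p"] = [r[2] for r in rows]
    out.snp_meta["gwas_or"] = [r[3] for r in rows]
    out.snp_meta["risk_direction"] = ["risk" if r[3] > 1 else "protective"
                                      for r in rows]
    out.snp_meta["dual_hit"] = [r[4] for r in rows]
    n_dual = sum(r[4] for r in rows)
    if n_dual:
        logger.info("%d SNPs hit both panels; assigned to smaller p", n_dual)
    return out


def compute_pcs(g: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """Ancestry PCs of the mean-imputed, standardized dosage matrix.

    Returns an (n_subjects, n_pcs) array.  Sign convention: within each
    component, the largest-magnitude SNP loading is made positive, so the
    result is deterministic across LAPACK builds.
    """
    if n_pcs == 0:
        return np.empty((g.n_subjects, 0))
    if g.n_snps < n_pcs or g.n_subjects < n_pcs:
        raise ValueError(f"need at least {n_pcs} SNPs and subjects")
    X = g.dosages.astype(float)
    X[g.missing] = np.nan
    mu = np.nanmean(X, axis=1)
    if np.all(np.nanstd(X, axis=1) == 0):
        raise ValueError("degenerate (constant) genotype matrix")
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[0]]
    X -= X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    sd[sd == 0] = 1.0
    X /= sd[:, None]
    # SNPs x subjects: left vectors load SNPs, right vectors place subjects
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    pcs = (Vt[:k].T * s[:k])
    loadings = U[:, :k]
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            pcs[:, j] *= -1
            loadings[:, j] *= -1
    if k < n_pcs:
        pcs = np.column_stack([pcs, np.zeros((g.n_subjects, n_pcs - k))])
    return pcs


def gwas_results_frame(results: list[GwasResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp_id": r.snp_id, "disease": r.disease, "beta": r.beta,
        "se": r.se, "or": r.or_value, "p": r.wald_p, "flagged": r.flagged,
    } for r in results])
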