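"""Synthetic case-control cohorts with planted SNP x subject biclusters.

Cohorts carry two correlated binary diseases (CHD, T2D) whose joint
statuses define four disease-pattern subgroups with exact, configurable
sizes, plus covariates and optional missingness.  Ground truth for every
planted bicluster is returned so recovery can be scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PhenotypeTable, PATTERNS, default_snp_meta

logger = logging.getLogger(__name__)


@dataclass
class PlantedSet:
    """A ground-truth bicluster: concordant dosage planted on a cell block.

    ``penetrance_shift`` is a log-odds increment added to member subjects'
    liability for ``target_disease`` ("CHD", "T2D" or "both").
    """

    snp_indices: list[int]
    subject_indices: list[int]
    concordant_genotype: int = 2
    penetrance_shift: float = 0.0
    target_disease: str = "both"

    def __post_init__(self) -> None:
        if not self.snp_indices or not self.subject_indices:
            raise ValueError("planted set index lists must be non-empty")
        if self.concordant_genotype not in (0, 1, 2):
            raise ValueError("concordant_genotype must be in {0,1,2}")
        if self.target_disease not in ("CHD", "T2D", "both"):
            raise ValueError("target_disease must be CHD, T2D or both")


@dataclass
class CohortConfig:
    n_subjects: int = 441
    n_snps_chd: int = 110
    n_snps_t2d: int = 83
    #: (comorbid, chd_only, t2d_only, none)
    pattern_counts: tuple[int, int, int, int] = (61, 91, 97, 192)
    planted_sets: list[PlantedSet] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.45)
    missing_rate: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return self.n_snps_chd + self.n_snps_t2d

    def validate(self) -> None:
        if sum(self.pattern_counts) != self.n_subjects:
            raise ValueError(
                f"pattern_counts {self.pattern_counts} sum to "
                f"{sum(self.pattern_counts)}, not n_subjects={self.n_subjects}")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0.01, 0.5)")
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must lie in [0, 0.05]")
        for ps in self.planted_sets:
            if max(ps.snp_indices) >= self.n_snps:
                raise ValueError("planted SNP index out of bounds")
            if max(ps.subject_indices) >= self.n_subjects:
                raise ValueError("planted subject index out of bounds")
        known = {"age", "sex", "bmi"}
        unknown = set(self.covariate_effects) - known
        if unknown:
            raise ValueError(f"unknown covariate effects: {sorted(unknown)}")


class InfeasiblePatternError(RuntimeError):
    """Raised when the requested pattern counts cannot be realized."""


def _truncated_normal(rng, loc, scale, lo, hi, size):
    out = rng.normal(loc, scale, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _weighted_sample_without_replacement(rng, weights, k):
    """Efraimidis-Spirakis exponential-key sampling; returns k indices."""
    w = np.asarray(weights, dtype=float)
    if k == 0:
        return np.array([], dtype=np.intp)
    # weights this small mean the pattern is unreachable for the subject
    # within any bounded number of liability redraws
    positive = w > 1e-12
    if positive.sum() < k:
        raise InfeasiblePatternError(
            f"need {k} subjects but only {int(positive.sum())} have positive "
            "probability for this disease pattern")
    keys = np.full(w.shape, np.inf)
    keys[positive] = rng.exponential(1.0, int(positive.sum())) / w[positive]
    return np.argsort(keys, kind="stable")[:k]


def simulate_cohort(config: CohortConfig):
    """Generate (GenotypeMatrix, PhenotypeTable, ground_truth).

    Background dosages are binomial(2, MAF) per SNP; planted cells are then
    overwritten with each set's concordant genotype.  Disease statuses come
    from per-disease logistic liabilities (planted penetrance shifts plus
    covariate effects); the four pattern counts are matched exactly by
    weighted sampling without replacement over subjects, stratified by
    pattern, where a subject's weight is its joint liability for that
    pattern.  Missing entries are masked MCAR at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    m, n = config.n_snps, config.n_subjects

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    dosages = rng.binomial(2, mafs[:, None], size=(m, n)).astype(np.int8)
    for ps in config.planted_sets:
        dosages[np.ix_(ps.snp_indices, ps.subject_indices)] = ps.concordant_genotype

    # covariates
    age = _truncated_normal(rng, 60.0, 8.0, 40.0, 85.0, n)
    sex = rng.integers(0, 2, n)
    bmi = rng.normal(25.0, 3.0, n)

    # liabilities: baseline prevalence from the requested pattern counts
    c_com, c_chd, c_t2d, c_none = config.pattern_counts
    prev_chd = (c_com + c_chd) / n
    prev_t2d = (c_com + c_t2d) / n
    eta_chd = np.full(n, _logit(prev_chd))
    eta_t2d = np.full(n, _logit(prev_t2d))
    cov_std = {
        "age": (age - age.mean()) / age.std() if age.std() > 0 else age * 0,
        "sex": sex - sex.mean(),
        "bmi": (bmi - bmi.mean()) / bmi.std() if bmi.std() > 0 else bmi * 0,
    }
    for name, beta in config.covariate_effects.items():
        eta_chd = eta_chd + beta * cov_std[name]
        eta_t2d = eta_t2d + beta * cov_std[name]
    for ps in config.planted_sets:
        if ps.target_disease in ("CHD", "both"):
            eta_chd[ps.subject_indices] += ps.penetrance_shift
        if ps.target_disease in ("T2D", "both"):
            eta_t2d[ps.subject_indices] += ps.penetrance_shift

    p_chd = _expit(eta_chd)
    p_t2d = _expit(eta_t2d)
    pattern_weights = {
        "comorbid": p_chd * p_t2d,
        "chd_only": p_chd * (1 - p_t2d),
        "t2d_only": (1 - p_chd) * p_t2d,
        "none": (1 - p_chd) * (1 - p_t2d),
    }
    counts = dict(zip(PATTERNS, config.pattern_counts))
    pattern = np.empty(n, dtype=object)
    remaining = np.ones(n, dtype=bool)
    for pat in PATTERNS:
        pool = np.flatnonzero(remaining)
        w = pattern_weights[pat][pool]
        chosen = pool[_weighted_sample_without_replacement(rng, w, counts[pat])]
        pattern[chosen] = pat
        remaining[chosen] = False
    assert not remaining.any()
    chd = np.isin(pattern, ("comorbid", "chd_only")).astype(int)
    t2d = np.isin(pattern, ("comorbid", "t2d_only")).astype(int)

    missing = rng.random((m, n)) < config.missing_rate

    snp_ids = [f"snp{i:04d}" for i in range(m)]
    meta = default_snp_meta(snp_ids)
    meta["panel_label"] = (["CHD"] * config.n_snps_chd
                           + ["T2D"] * config.n_snps_t2d)
    direction = np.where(rng.random(m) < 0.5, "risk", "protective").astype(object)
    for ps in config.planted_sets:
        direction[ps.snp_indices] = ("risk" if ps.penetrance_shift >= 0
                                     else "protective")
    meta["risk_direction"] = direction
    meta["chrom"] = "1"
    meta["pos"] = np.arange(1, m + 1) * 1000

    subject_ids = [f"S{j:05d}" for j in range(n)]
    g = GenotypeMatrix(dosages, missing, meta, subject_ids)
    pheno = PhenotypeTable(pd.DataFrame({
        "subject_id": subject_ids,
        "chd": chd,
        "t2d": t2d,
        "age": age,
        "sex": sex,
        "bmi": bmi,
    }))
    return g, pheno, list(config.planted_sets)


def _logit(p):
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def jaccard_indices(a, b) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def score_recovery(found, truth, g: GenotypeMatrix | None = None):
    """Best Jaccard per planted set, separately on SNPs and on subjects.

    ``found`` holds SNPSet-like objects with ``snp_ids``/``subject_ids``;
    planted sets carry integer indices, translated through ``g`` when
    given, else via the default synthetic id scheme.
    """
    if not truth:
        raise ValueError("truth must be non-empty")

    def snp_name(i):
        return g.snp_ids[i] if g is not None else f"snp{i:04d}"

    def subj_name(j):
        return g.subject_ids[j] if g is not None else f"S{j:05d}"

    scores = []
    for ps in truth:
        t_snps = {snp_name(i) for i in ps.snp_indices}
        t_subj = {subj_name(j) for j in ps.subject_indices}
        best_snp = 0.0
        best_subj = 0.0
        for fs in found:
            best_snp = max(best_snp, jaccard_indices(fs.snp_ids, t_snps))
            best_subj = max(best_subj, jaccard_indices(fs.subject_ids, t_subj))
        scores.append({"snp_jaccard": best_snp, "subject_jaccard": best_subj})
    return scores


def write_manifest(config: CohortConfig, path) -> None:
    payload = asdict(config)
    payload["pattern_counts"] = list(config.pattern_counts)
    payload["maf_range"] = list(config.maf_range)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
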