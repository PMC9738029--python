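"""Nonsmooth NMF biclustering of the pooled SNP x subject matrix.

The model is X ~ W S H with smoothing matrix S = (1-theta) I + (theta/k)
11', fitted by multiplicative KL-divergence updates: the H-step uses the
effective basis W S and the W-step uses the effective coefficients S H.
Fuzzy SNP sets are read off the factors with a fraction-of-maximum rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FactorizationResult:
    W: np.ndarray          # SNP loadings, (m, k), columns sum to 1
    H: np.ndarray          # subject loadings, (k, n)
    theta: float
    k: int
    objective_trace: list[float]
    seed: int
    converged: bool

    @property
    def S(self) -> np.ndarray:
        return smoothing_matrix(self.k, self.theta)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.S @ self.H


@dataclass
class SNPSet:
    """A fuzzy bicluster labeled G_<k>_<i> (i is 1-based factor order)."""

    label: str
    k: int
    factor_index: int
    snp_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        expect = f"G_{self.k}_{self.factor_index}"
        if self.label != expect:
            raise ValueError(f"label {self.label!r} does not encode "
                             f"(k={self.k}, i={self.factor_index})")
        if not (1 <= self.factor_index <= self.k):
            raise ValueError("factor index must satisfy 1 <= i <= k")
        if not self.snp_ids or not self.subject_ids:
            raise ValueError("member lists must be non-empty")

    @classmethod
    def from_members(cls, k: int, i: int, snp_ids, subject_ids) -> "SNPSet":
        return cls(f"G_{k}_{i}", k, i, list(snp_ids), list(subject_ids))


def parse_label(label: str) -> tuple[int, int]:
    m = re.fullmatch(r"G_(\d+)_(\d+)", label)
    if not m:
        raise ValueError(f"malformed SNP-set label {label!r}")
    return int(m.group(1)), int(m.group(2))


def smoothing_matrix(k: int, theta: float) -> np.ndarray:
    return (1.0 - theta) * np.eye(k) + (theta / k) * np.ones((k, k))


def kl_divergence(X: np.ndarray, Y: np.ndarray) -> float:
    """Generalized KL divergence D(X || Y); 0 log 0 treated as 0."""
    Y = np.maximum(Y, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(X > 0, X * np.log(np.maximum(X, _EPS) / Y), 0.0)
    return float(np.sum(t - X + Y))


def nsnmf_factorize(X: np.ndarray, k: int, theta: float = 0.5,
                    max_iter: int = 2000, tol: float = 1e-6,
                    seed: int = 0, objective: str = "kl") -> FactorizationResult:
    """Factorize a nonnegative matrix as W S H at rank k.

    W columns are renormalized to unit sum each iteration (scale absorbed
    into H).  Iterations stop when the relative objective change drops
    below ``tol``, at ``max_iter``, or when a (numerically rare)
    normalization-induced uptick is detected — the pre-uptick factors are
    kept so the recorded trace is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    if np.any(~np.isfinite(X)):
        raise ValueError("X contains non-finite entries; impute upstream")
    if k < 2:
        raise ValueError("rank k must be >= 2")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")

    m, n = X.shape
    zero_rows = int((X.sum(axis=1) == 0).sum())
    zero_cols = int((X.sum(axis=0) == 0).sum())
    if zero_rows or zero_cols:
        logger.info("input has %d zero rows and %d zero columns; their "
                    "loadings will be zero", zero_rows, zero_cols)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, (m, k)) * scale
    H = rng.uniform(0.1, 1.0, (k, n)) * scale
    S = smoothing_matrix(k, theta)

    div = kl_divergence if objective == "kl" else _frobenius
    trace: list[float] = []
    converged = False
    prev = div(X, W @ S @ H)
    trace.append(prev)
    for it in range(max_iter):
        W_old, H_old = W, H
        if objective == "kl":
            W, H = _kl_step(X, W, H, S)
        else:
            W, H = _frob_step(X, W, H, S)
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
            raise FloatingPointError(
                f"non-finite factor values at iteration {it + 1}")
        obj = div(X, W @ S @ H)
        if obj > prev * (1 + 1e-12) + 1e-12:
            # normalization perturbed the objective upward; keep the
            # previous (better) factors and stop
            W, H = W_old, H_old
            converged = True
            break
        trace.append(obj)
        if prev > 0 and abs(prev - obj) / max(prev, _EPS) < tol:
            converged = True
            prev = obj
            break
        prev = obj
    return FactorizationResult(W=W, H=H, theta=theta, k=k,
                               objective_trace=trace, seed=seed,
                               converged=converged)


def _kl_step(X, W, H, S):
    A = W @ S                       # effective basis for the H update
    Y = np.maximum(A @ H, _EPS)
    H = H * (A.T @ (X / Y)) / np.maximum(A.sum(axis=0)[:, None], _EPS)
    B = S @ H                       # effective coefficients for the W update
    Y = np.maximum(W @ B, _EPS)
    W = W * ((X / Y) @ B.T) / np.maximum(B.sum(axis=1)[None, :], _EPS)
    return _normalize(W, H)


def _frob_step(X, W, H, S):
    A = W @ S
    H = H * np.maximum(A.T @ X, _EPS) / np.maximum(A.T @ A @ H, _EPS)
    B = S @ H
    W = W * np.maximum(X @ B.T, _EPS) / np.maximum(W @ B @ B.T, _EPS)
    return _normalize(W, H)


def _normalize(W, H):
    colsum = W.sum(axis=0)
    pos = colsum > _EPS
    W = W.copy()
    H = H.copy()
    W[:, pos] /= colsum[pos]
    H[pos, :] *= colsum[pos][:, None]
    return W, H


def _frobenius(X, Y):
    return float(np.sum((X - Y) ** 2))


def encode_matrix(g: GenotypeMatrix, coding: str = "offset_dosage") -> np.ndarray:
    """Encode dosages as a strictly positive matrix for factorization.

    ``offset_dosage`` maps {0,1,2} -> {1,2,3} so homozygous-reference
    genotypes stay informative under multiplicative updates.
    ``risk_dosage`` first reorients each SNP to risk-allele count (using
    snp_meta risk_direction), then offsets.  Missing entries are imputed
    with the per-SNP mode before offsetting.
    """
    if coding not in ("offset_dosage", "risk_dosage"):
        raise ValueError(f"unknown coding {coding!r}")
    D = g.dosages.astype(float).copy()
    # per-SNP mode imputation (smallest dosage wins ties, deterministic)
    for i in range(g.n_snps):
        miss = g.missing[i]
        if miss.any():
            obs = g.dosages[i][~miss]
            if obs.size == 0:
                mode = 0
            else:
                vals, counts = np.unique(obs, return_counts=True)
                mode = int(vals[np.argmax(counts)])
            D[i, miss] = mode
    if coding == "risk_dosage":
        protective = (g.snp_meta["risk_direction"].astype(str) == "protective").to_numpy()
        D[protective] = 2.0 - D[protective]
    return D + 1.0


def extract_snp_sets(f: FactorizationResult, g: GenotypeMatrix,
                     tau: float = 0.6, mode: str = "factor_wise") -> list[SNPSet]:
    """Read fuzzy SNP sets off the factors by the fraction-of-maximum rule.

    factor_wise (default): SNP j joins set i iff W[j,i] >= tau * max over
    SNPs of column i, and likewise subjects on rows of H.  entity_wise:
    the reference maximum is the entity's own maximum across factors.
    Empty extractions (possible only entity_wise) are dropped with a
    warning.  Both modes permit multi-membership.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    if mode not in ("factor_wise", "entity_wise"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    W, H, k = f.W, f.H, f.k
    snp_ids = np.asarray(g.snp_ids)
    subject_ids = np.asarray(g.subject_ids)
    sets: list[SNPSet] = []
    if mode == "factor_wise":
        w_ref = W.max(axis=0, keepdims=True)          # per-factor max
        h_ref = H.max(axis=1, keepdims=True)
        w_in = W >= tau * np.maximum(w_ref, _EPS)
        h_in = H >= tau * np.maximum(h_ref, _EPS)
    else:
        w_ref = W.max(axis=1, keepdims=True)          # per-entity max
        h_ref = H.max(axis=0, keepdims=True)
        w_in = W >= tau * np.maximum(w_ref, _EPS)
        h_in = H >= tau * np.maximum(h_ref, _EPS)
    for i in range(k):
        snps = snp_ids[w_in[:, i]].tolist()
        subjects = subject_ids[h_in[i, :]].tolist()
        if not snps or not subjects:
            logger.warning("factor %d of k=%d extracted an empty set; dropped",
                           i + 1, k)
            continue
        sets.append(SNPSet.from_members(k, i + 1, snps, subjects))
    return sets


def child_seed(master_seed: int, k: int) -> int:
    """Deterministic per-rank seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0])


def run_sweep(X: np.ndarray, g: GenotypeMatrix, k_min: int = 2,
              k_max: int | None = None, theta: float = 0.5,
              tau: float = 0.6, mode: str = "factor_wise",
              max_iter: int = 2000, tol: float = 1e-6,
              seed: int = 0, objective: str = "kl"):
    """One factorization per rank in [k_min, k_max]; sets labeled G_k_i.

    ``k_max`` defaults to floor(sqrt(n_snps)).  Returns
    ``(sets, factorizations)``.
    """
    if k_max is None:
        k_max = int(np.floor(np.sqrt(X.shape[0])))
    if k_min < 2 or k_max < k_min:
        raise ValueError(f"need 2 <= k_min <= k_max, got ({k_min}, {k_max})")
    all_sets: list[SNPSet] = []
    results: list[FactorizationResult] = []
    for k in range(k_min, k_max + 1):
        f = nsnmf_factorize(X, k=k, theta=theta, max_iter=max_iter, tol=tol,
                            seed=child_seed(seed, k), objective=objective)
        results.append(f)
        all_sets.extend(extract_snp_sets(f, g, tau=tau, mode=mode))
    logger.info("sweep k=%d..%d produced %d sets", k_min, k_max, len(all_sets))
    return all_sets, results


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def sets_to_json(sets: list[SNPSet]) -> list[dict]:
    return [{"label": s.label, "k": s.k, "factor_index": s.factor_index,
             "snp_ids": s.snp_ids, "subject_ids": s.subject_ids}
            for s in sets]


def sets_from_json(payload: list[dict]) -> list[SNPSet]:
    return [SNPSet(label=d["label"], k=d["k"], factor_index=d["factor_index"],
                   snp_ids=list(d["snp_ids"]), subject_ids=list(d["subject_ids"]))
            for d in payload]


def sets_to_membership_frame(sets: list[SNPSet]) -> pd.DataFrame:
    """Flat TSV-ready frame: one row per (set, member) pair."""
    rows = []
    for s in sets:
        rows += [{"label": s.label, "member_type": "snp", "member_id": i}
                 for i in s.snp_ids]
        rows += [{"label": s.label, "member_type": "subject", "member_id": i}
                 for i in s.subject_ids]
    return pd.DataFrame(rows, columns=["label", "member_type", "member_id"])
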