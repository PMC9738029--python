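"""Replication: regenerate SNP sets in a held-out sample on the same
variant panel and match them to discovery sets by hypergeometric overlap
of SNP membership (the two samples share SNPs, not subjects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .architecture import hypergeom_overlap, jaccard
from .io import GenotypeMatrix
from .nsnmf import SNPSet, encode_matrix, run_sweep

logger = logging.getLogger(__name__)


@dataclass
class MatchRecord:
    discovery_label: str
    best_replication_label: str
    shared_snps: int
    hypergeometric_p: float
    snp_jaccard: float
    replicated: bool


def replicate_sweep(g_replication: GenotypeMatrix, panel_snp_ids: list[str],
                    k_min: int = 2, k_max: int | None = None,
                    theta: float = 0.5, tau: float = 0.6,
                    mode: str = "factor_wise", max_iter: int = 2000,
                    tol: float = 1e-6, seed: int = 0,
                    coding: str = "offset_dosage") -> list[SNPSet]:
    """Run the discovery sweep procedure on the replication cohort.

    The replication matrix is restricted to the discovery panel's SNPs;
    the sweep uses the same k range, theta and tau, with its own seed.
    """
    shared = [s for s in panel_snp_ids if s in set(g_replication.snp_ids)]
    if not shared:
        raise ValueError("replication cohort shares no SNPs with the panel")
    if len(shared) < len(panel_snp_ids):
        logger.warning("replication cohort carries %d of %d panel SNPs",
                       len(shared), len(panel_snp_ids))
    g = g_replication.restrict_to_snps(shared)
    X = encode_matrix(g, coding=coding)
    sets, _ = run_sweep(X, g, k_min=k_min, k_max=k_max, theta=theta,
                        tau=tau, mode=mode, max_iter=max_iter, tol=tol,
                        seed=seed)
    return sets


def match_snp_sets(discovery_sets: list[SNPSet],
                   replication_sets: list[SNPSet], panel_size: int,
                   p_match: float = 1e-3) -> list[MatchRecord]:
    """Best hypergeometric SNP-overlap match per discovery set.

    Ties in p are broken by larger Jaccard, then by replication label, so
    matching is deterministic.  ``replicated`` flags best p < p_match;
    p = 0 can only arise from underflow of a (near-)total overlap.
    """
    if not discovery_sets or not replication_sets:
        raise ValueError("both set lists must be non-empty")
    records = []
    for d in discovery_sets:
        best = None
        for r in replication_sets:
            shared, p = hypergeom_overlap(d.snp_ids, r.snp_ids, panel_size)
            jc = jaccard(d.snp_ids, r.snp_ids)
            key = (p, -jc, r.label)
            if best is None or key < best[0]:
                best = (key, r, shared, p, jc)
        _, r, shared, p, jc = best
        records.append(MatchRecord(
            discovery_label=d.label, best_replication_label=r.label,
            shared_snps=shared, hypergeometric_p=p, snp_jaccard=jc,
            replicated=p < p_match))
    return records


def replicated_fraction(records: list[MatchRecord]) -> float:
    return sum(r.replicated for r in records) / len(records)


def match_frame(records: list[MatchRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "discovery_set": r.discovery_label,
        "best_match": r.best_replication_label,
        "shared_snps": r.shared_snps,
        "p": r.hypergeometric_p,
        "jaccard": r.snp_jaccard,
        "replicated": r.replicated,
    } for r in records])
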