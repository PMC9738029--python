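"""Genotype-phenotype architecture: hypergeometric co-clustering of SNP
sets with disease-pattern subject sets, and Jaccard redundancy filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import PhenotypeTable, PATTERNS
from .nsnmf import SNPSet

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeSet:
    pattern: str
    subject_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.subject_ids)


@dataclass
class RelationEdge:
    set_label: str
    partner: str              # disease-pattern label (or partner set label)
    overlap_count: int
    universe_size: int
    hypergeometric_p: float
    jaccard: float
    significant: bool = False


def define_phenotype_sets(pheno: PhenotypeTable) -> dict[str, PhenotypeSet]:
    """Partition subjects into the four disease-pattern sets."""
    out = {p: PhenotypeSet(p, []) for p in PATTERNS}
    for row in pheno.data.itertuples():
        out[row.pattern].subject_ids.append(row.subject_id)
    return out


def _log_hypergeom_pmf(k, n_draw, n_marked, universe_n):
    """log P(X = k) for X ~ Hypergeometric(universe_n, n_marked, n_draw)."""
    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    return (logc(n_marked, k) + logc(universe_n - n_marked, n_draw - k)
            - logc(universe_n, n_draw))


def hypergeom_overlap(a_ids, b_ids, universe_n: int):
    """Observed overlap and upper-tail P(X >= overlap) on a finite universe.

    Exact summation of the hypergeometric pmf in log space.
    """
    sa, sb = set(a_ids), set(b_ids)
    if len(sa) > universe_n or len(sb) > universe_n:
        raise ValueError("set larger than the stated universe")
    k_obs = len(sa & sb)
    if k_obs == 0:
        return 0, 1.0
    k_max = min(len(sa), len(sb))
    ks = np.arange(k_obs, k_max + 1)
    logs = _log_hypergeom_pmf(ks, len(sb), len(sa), universe_n)
    logs = logs[np.isfinite(logs)]  # -inf marks out-of-support terms
    if logs.size == 0:
        return k_obs, 0.0
    return k_obs, float(min(1.0, np.exp(logsumexp(logs))))


def jaccard(a_ids, b_ids) -> float:
    sa, sb = set(a_ids), set(b_ids)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def best_relation_pvalues(sets: list[SNPSet],
                         pheno_sets: dict[str, PhenotypeSet],
                         universe_n: int) -> dict[str, float]:
    """Each set's minimum hypergeometric p across the four patterns."""
    out = {}
    for s in sets:
        out[s.label] = min(
            hypergeom_overlap(s.subject_ids, ps.subject_ids, universe_n)[1]
            for ps in pheno_sets.values())
    return out


def redundancy_filter(sets: list[SNPSet], relation_p: dict[str, float],
                      jc_thresh: float = 0.8) -> list[SNPSet]:
    """Greedy selection of non-redundant sets, strongest relation first.

    Sets are sorted by (best relation p, k, factor index) — a canonical
    order making the result independent of input order — and accepted iff
    both SNP- and subject-Jaccard against every accepted set are <=
    ``jc_thresh`` ("over 0.8" redundant, boundary kept).
    """
    missing = [s.label for s in sets if s.label not in relation_p]
    if missing:
        raise KeyError(f"no relation p-value for sets {missing[:5]}")
    ordered = sorted(sets, key=lambda s: (relation_p[s.label], s.k,
                                          s.factor_index))
    accepted: list[SNPSet] = []
    for s in ordered:
        redundant = any(
            jaccard(s.snp_ids, a.snp_ids) > jc_thresh
            or jaccard(s.subject_ids, a.subject_ids) > jc_thresh
            for a in accepted)
        if not redundant:
            accepted.append(s)
    logger.info("redundancy filter kept %d of %d sets", len(accepted),
                len(sets))
    return accepted


def build_architecture(sets: list[SNPSet],
                       pheno_sets: dict[str, PhenotypeSet],
                       alpha: float = 0.05,
                       panel: pd.DataFrame | None = None) -> list[RelationEdge]:
    """All set x pattern hypergeometric relations that pass Bonferroni.

    The universe is the whole cohort (union of the four pattern sets) and
    the Bonferroni denominator is the number of retained sets.  When a
    panel frame is given, each edge is annotated with the set's
    effect-direction profile.
    """
    if not sets:
        return []
    universe = set()
    for ps in pheno_sets.values():
        universe |= set(ps.subject_ids)
    universe_n = len(universe)
    thresh = alpha / len(sets)
    direction_of: dict[str, str] = {}
    if panel is not None:
        pm = panel.set_index("snp_id")["risk_direction"].astype(str)
        for s in sets:
            dirs = {pm[x] for x in s.snp_ids if x in pm.index}
            direction_of[s.label] = dirs.pop() if len(dirs) == 1 else "mixed"
    edges = []
    for s in sets:
        for pattern, ps in pheno_sets.items():
            k, p = hypergeom_overlap(s.subject_ids, ps.subject_ids, universe_n)
            if p < thresh:
                edges.append(RelationEdge(
                    set_label=s.label, partner=pattern, overlap_count=k,
                    universe_size=universe_n, hypergeometric_p=p,
                    jaccard=jaccard(s.subject_ids, ps.subject_ids),
                    significant=True))
    for e in edges:
        e.direction = direction_of.get(e.set_label)  # type: ignore[attr-defined]
    return edges


def relations_frame(edges: list[RelationEdge]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set": e.set_label, "pattern": e.partner, "overlap": e.overlap_count,
        "universe": e.universe_size, "p": e.hypergeometric_p,
        "jaccard": e.jaccard, "significant": e.significant,
        "direction": getattr(e, "direction", None),
    } for e in edges], columns=["set", "pattern", "overlap", "universe",
                                "p", "jaccard", "significant", "direction"])


def relation_matrix(sets: list[SNPSet],
                    pheno_sets: dict[str, PhenotypeSet]) -> pd.DataFrame:
    """Set x pattern matrix of hypergeometric p (heatmap export)."""
    universe = set()
    for ps in pheno_sets.values():
        universe |= set(ps.subject_ids)
    data = {
        pattern: [hypergeom_overlap(s.subject_ids, ps.subject_ids,
                                    len(universe))[1] for s in sets]
        for pattern, ps in pheno_sets.items()
    }
    return pd.DataFrame(data, index=[s.label for s in sets])
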