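"""Posterior descriptors for SNP sets and cohort-level purity summaries.

Three per-set indicators are computed: disease risk (fraction of member
subjects who are cases for each disease), SNP composition (fraction of
member SNPs from each disease panel), and effect direction (fraction of
member SNPs with OR > 1 within each panel).  Raw fractions are kept
internally; rounding happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import PhenotypeTable
from .nsnmf import SNPSet


@dataclass
class SetDescriptor:
    label: str
    n_snps: int
    n_subjects: int
    chd_risk: float           # fraction of member subjects with CHD
    t2d_risk: float
    composition_chd: float    # fraction of member SNPs from the CHD panel
    composition_t2d: float
    risk_or_gt1_chd: float    # fraction of CHD-panel members with OR > 1
    risk_or_gt1_t2d: float

    def as_percent_row(self) -> dict:
        return {
            "label": self.label,
            "n_subjects": self.n_subjects,
            "n_snps": self.n_snps,
            "chd_risk_pct": round(100 * self.chd_risk),
            "t2d_risk_pct": round(100 * self.t2d_risk),
            "composition_chd_pct": round(100 * self.composition_chd),
            "composition_t2d_pct": round(100 * self.composition_t2d),
            "risk_or_gt1_chd_pct": round(100 * self.risk_or_gt1_chd),
            "risk_or_gt1_t2d_pct": round(100 * self.risk_or_gt1_t2d),
        }


def describe_set(s: SNPSet, pheno: PhenotypeTable,
                 panel: pd.DataFrame) -> SetDescriptor:
    """Compute the three posterior indicators for one SNP set.

    ``panel`` is a snp_meta frame carrying panel_label and risk_direction
    for every member SNP; effect direction is taken from each SNP's own
    panel disease prescreen.
    """
    ph = pheno.data.set_index("subject_id")
    missing_subj = [x for x in s.subject_ids if x not in ph.index]
    if missing_subj:
        raise KeyError(f"unresolvable subject id {missing_subj[0]!r} "
                       f"in set {s.label}")
    pm = panel.set_index("snp_id")
    missing_snp = [x for x in s.snp_ids if x not in pm.index]
    if missing_snp:
        raise KeyError(f"unresolvable SNP id {missing_snp[0]!r} "
                       f"in set {s.label}")
    members = ph.loc[s.subject_ids]
    snps = pm.loc[s.snp_ids]
    n_subj = len(members)
    n_snps = len(snps)
    labels = snps["panel_label"].astype(str)
    chd_snps = snps[labels == "CHD"]
    t2d_snps = snps[labels == "T2D"]

    def _risk_frac(sub):
        if len(sub) == 0:
            return 0.0
        return float((sub["risk_direction"].astype(str) == "risk").mean())

    return SetDescriptor(
        label=s.label,
        n_snps=n_snps,
        n_subjects=n_subj,
        chd_risk=float(members["chd"].mean()),
        t2d_risk=float(members["t2d"].mean()),
        composition_chd=len(chd_snps) / n_snps,
        composition_t2d=len(t2d_snps) / n_snps,
        risk_or_gt1_chd=_risk_frac(chd_snps),
        risk_or_gt1_t2d=_risk_frac(t2d_snps),
    )


def purity_summary(sets: list[SNPSet], panel: pd.DataFrame) -> tuple[float, float]:
    """(fraction of sets mixing panel labels, fraction mixing directions).

    A set "mixes" a property when both values of it occur among member SNPs.
    """
    if not sets:
        raise ValueError("set list must be non-empty")
    pm = panel.set_index("snp_id")
    mixed_panel = 0
    mixed_direction = 0
    for s in sets:
        snps = pm.loc[s.snp_ids]
        if snps["panel_label"].astype(str).nunique() > 1:
            mixed_panel += 1
        if snps["risk_direction"].astype(str).nunique() > 1:
            mixed_direction += 1
    return mixed_panel / len(sets), mixed_direction / len(sets)


def descriptor_table(descriptors: list[SetDescriptor]) -> pd.DataFrame:
    """Report table with integer percentages, one row per set."""
    return pd.DataFrame([d.as_percent_row() for d in descriptors])
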