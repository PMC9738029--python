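"""Genotype, phenotype and panel-metadata I/O on a single in-memory model.

The internal genotype representation is a SNP x subject matrix of
alternate-allele dosages in {0, 1, 2} with an explicit missingness mask
(never a sentinel dosage).  All readers normalize to this model; all
writers consume it, so ``write(read(x))`` round-trips losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mutually exclusive disease-pattern labels, in canonical order.
PATTERNS = ("comorbid", "chd_only", "t2d_only", "none")

SNP_META_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt",
    "panel_label", "risk_direction", "gwas_p", "gwas_or",
]


def disease_pattern(chd: int, t2d: int) -> str:
    """Map a (CHD status, T2D status) pair to its disease-pattern label."""
    if chd not in (0, 1) or t2d not in (0, 1):
        raise ValueError(f"statuses must be 0/1, got chd={chd!r}, t2d={t2d!r}")
    if chd and t2d:
        return "comorbid"
    if chd:
        return "chd_only"
    if t2d:
        return "t2d_only"
    return "none"


def default_snp_meta(snp_ids: list[str]) -> pd.DataFrame:
    """Minimal per-SNP metadata for sources that carry none (e.g. bare TSV)."""
    n = len(snp_ids)
    return pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": ["1"] * n,
        "pos": np.arange(1, n + 1, dtype=np.int64),
        "ref": ["A"] * n,
        "alt": ["B"] * n,
        "panel_label": pd.array([None] * n, dtype="string"),
        "risk_direction": pd.array([None] * n, dtype="string"),
        "gwas_p": np.full(n, np.nan),
        "gwas_or": np.full(n, np.nan),
    })


@dataclass
class GenotypeMatrix:
    """SNP x subject additive-dosage matrix with metadata and missing mask.

    Attributes
    ----------
    dosages : ndarray of shape (n_snps, n_subjects), int8
        Alternate-allele counts in {0, 1, 2}.  Entries under ``missing``
        are undefined and must not be interpreted.
    missing : bool ndarray, same shape
        True where the genotype is missing.
    snp_meta : DataFrame
        One row per SNP, columns ``SNP_META_COLUMNS``.
    subject_ids : list of str
    """

    dosages: np.ndarray
    missing: np.ndarray
    snp_meta: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.subject_ids = list(self.subject_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (SNPs x subjects)")
        if self.missing.shape != self.dosages.shape:
            raise ValueError("missing mask shape must match dosages")
        if len(self.snp_meta) != self.dosages.shape[0]:
            raise ValueError("snp_meta length must equal SNP row count")
        if len(self.subject_ids) != self.dosages.shape[1]:
            raise ValueError("subject_ids length must equal column count")
        snp_ids = self.snp_meta["snp_id"]
        if snp_ids.duplicated().any():
            dups = snp_ids[snp_ids.duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dups[:5]}")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        observed = self.dosages[~self.missing]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            bad = sorted(set(observed[~np.isin(observed, (0, 1, 2))].tolist()))
            raise ValueError(f"dosages outside {{0,1,2}}: {bad}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["snp_id"].tolist()

    def snp_index(self, snp_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_meta["snp_id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def subject_index(self, subject_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            return np.array([lookup[s] for s in subject_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown subject id {exc.args[0]!r}") from None

    def subset(self, snp_idx=None, subject_idx=None) -> "GenotypeMatrix":
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        subject_idx = (np.arange(self.n_subjects) if subject_idx is None
                       else np.asarray(subject_idx))
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(snp_idx, subject_idx)],
            missing=self.missing[np.ix_(snp_idx, subject_idx)],
            snp_meta=self.snp_meta.iloc[snp_idx].reset_index(drop=True),
            subject_ids=[self.subject_ids[i] for i in subject_idx],
        )

    def restrict_to_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        return self.subset(snp_idx=self.snp_index(snp_ids))

    # -- derived statistics ----------------------------------------------

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls."""
        d = np.ma.masked_array(self.dosages.astype(float), mask=self.missing)
        return np.asarray(d.mean(axis=1).filled(np.nan)) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        af = self.allele_frequencies()
        return np.minimum(af, 1.0 - af)

    def snp_missing_rates(self) -> np.ndarray:
        return self.missing.mean(axis=1)

    def subject_missing_rates(self) -> np.ndarray:
        return self.missing.mean(axis=0)


@dataclass
class PhenotypeTable:
    """Per-subject disease statuses, derived pattern, and covariates.

    ``data`` has one row per subject with columns ``subject_id``, ``chd``,
    ``t2d``, ``pattern``, ``age``, ``sex``, ``bmi`` and zero or more
    ``pc1..pcN`` ancestry coordinates; optional trait columns pass through.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "chd", "t2d", "age", "sex", "bmi")

    def __post_init__(self) -> None:
        df = self.data.copy().reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in phenotype table")
        derived = [disease_pattern(int(c), int(t))
                   for c, t in zip(df["chd"], df["t2d"])]
        if "pattern" in df.columns:
            given = df["pattern"].astype(str).tolist()
            if given != derived:
                bad = next(i for i, (g, d) in enumerate(zip(given, derived)) if g != d)
                raise ValueError(
                    f"pattern column disagrees with statuses at row {bad}: "
                    f"{given[bad]!r} vs derived {derived[bad]!r}")
        df["pattern"] = derived
        self.data = df

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c.startswith("pc") and c[2:].isdigit()]

    def pattern_counts(self) -> dict[str, int]:
        counts = self.data["pattern"].value_counts()
        return {p: int(counts.get(p, 0)) for p in PATTERNS}

    def aligned_to(self, subject_ids: list[str]) -> "PhenotypeTable":
        """Reorder rows to a given subject-id order via an explicit join."""
        df = self.data.set_index("subject_id")
        missing = [s for s in subject_ids if s not in df.index]
        if missing:
            raise KeyError(f"subjects absent from phenotype table: {missing[:5]}")
        return PhenotypeTable(df.loc[subject_ids].reset_index())


# ---------------------------------------------------------------------------
# genotype TSV dialect: SNPs as rows, subjects as columns, NA for missing
# ---------------------------------------------------------------------------

def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    vals = np.where(g.missing, "NA", g.dosages.astype(object))
    df = pd.DataFrame(vals, index=pd.Index(g.snp_ids, name="snp_id"),
                      columns=g.subject_ids)
    df.to_csv(path, sep="\t")


def read_genotype_tsv(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    subject_ids = [str(c) for c in df.columns]
    arr = df.to_numpy()
    missing = pd.isna(arr)
    dosages = np.zeros(arr.shape, dtype=np.int8)
    obs = ~missing
    try:
        dosages[obs] = np.asarray([int(v) for v in arr[obs]], dtype=np.int8)
    except ValueError as exc:
        raise ValueError(f"malformed dosage in {path}: {exc}") from None
    snp_ids = [str(s) for s in df.index]
    meta = default_snp_meta(snp_ids) if snp_meta is None else _align_meta(snp_meta, snp_ids)
    return GenotypeMatrix(dosages, missing, meta, subject_ids)


def _align_meta(meta: pd.DataFrame, snp_ids: list[str]) -> pd.DataFrame:
    meta = meta.set_index("snp_id")
    missing = [s for s in snp_ids if s not in meta.index]
    if missing:
        raise KeyError(f"SNPs absent from metadata: {missing[:5]}")
    out = meta.loc[snp_ids].reset_index()
    base = default_snp_meta(snp_ids)
    for col in SNP_META_COLUMNS:
        if col not in out.columns:
            out[col] = base[col]
    return out[SNP_META_COLUMNS + [c for c in out.columns if c not in SNP_META_COLUMNS]]


# ---------------------------------------------------------------------------
# PLINK text .ped / .map
# ---------------------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, prefix, phenotypes: PhenotypeTable | None = None) -> None:
    """Write PLINK text files ``<prefix>.ped`` and ``<prefix>.map``.

    Allele letters come from snp_meta ref/alt; missing genotypes are "0 0".
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in g.snp_meta.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    pheno_by_id = {}
    if phenotypes is not None:
        pheno_by_id = {r.subject_id: r for r in phenotypes.data.itertuples()}
    ref = g.snp_meta["ref"].to_numpy()
    alt = g.snp_meta["alt"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for j, sid in enumerate(g.subject_ids):
            rec = pheno_by_id.get(sid)
            sex = str(int(rec.sex) + 1) if rec is not None else "0"
            phe = str(int(rec.chd) + 1) if rec is not None else "-9"
            fields = [sid, sid, "0", "0", sex, phe]
            for i in range(g.n_snps):
                if g.missing[i, j]:
                    fields += ["0", "0"]
                else:
                    d = g.dosages[i, j]
                    a = [ref[i], ref[i]] if d == 0 else (
                        [ref[i], alt[i]] if d == 1 else [alt[i], alt[i]])
                    fields += a
            fh.write("\t".join(fields) + "\n")


def read_ped_map(prefix, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into the internal dosage model.

    Without ``snp_meta`` supplying ref/alt, the alternate allele at each
    SNP is inferred as the minor allele observed in the file (ties broken
    lexicographically), matching PLINK's A1 convention.
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{prefix}.map line {lineno}: expected 4 fields")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)
    subject_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            subject_ids.append(parts[1])
            allele_rows.append([(parts[6 + 2 * i], parts[7 + 2 * i])
                                for i in range(m)])
    n = len(subject_ids)
    snp_ids = [r[1] for r in map_rows]
    if snp_meta is not None:
        meta = _align_meta(snp_meta, snp_ids)
    else:
        meta = default_snp_meta(snp_ids)
        meta["chrom"] = [r[0] for r in map_rows]
        meta["pos"] = [r[2] for r in map_rows]
    dosages = np.zeros((m, n), dtype=np.int8)
    missing = np.zeros((m, n), dtype=bool)
    alts, refs = [], []
    for i in range(m):
        calls = [allele_rows[j][i] for j in range(n)]
        seen: dict[str, int] = {}
        for a, b in calls:
            for al in (a, b):
                if al != "0":
                    seen[al] = seen.get(al, 0) + 1
        if snp_meta is not None:
            alt = meta.at[i, "alt"]
            ref_al = meta.at[i, "ref"]
        else:
            if len(seen) > 2:
                raise ValueError(f"SNP {snp_ids[i]}: more than two alleles")
            # minor allele as alternate; lexicographic tie-break
            ordered = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
            alt = ordered[0][0] if ordered else "B"
            ref_al = ordered[-1][0] if len(ordered) > 1 else "A"
            meta.at[i, "alt"] = alt
            meta.at[i, "ref"] = ref_al
        for j, (a, b) in enumerate(calls):
            if a == "0" or b == "0":
                missing[i, j] = True
            else:
                dosages[i, j] = (a == alt) + (b == alt)
        refs.append(ref_al)
        alts.append(alt)
    return GenotypeMatrix(dosages, missing, meta, subject_ids)


# ---------------------------------------------------------------------------
# VCF (biallelic SNVs only)
# ---------------------------------------------------------------------------

def write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = list(dict.fromkeys(g.snp_meta["chrom"].astype(str)))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.subject_ids) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, row in g.snp_meta.iterrows():
            gts = ["./." if g.missing[i, j] else gt_codes[int(g.dosages[i, j])]
                   for j in range(g.n_subjects)]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF of biallelic SNVs; multi-allelic records are skipped.

    GT is converted to alternate-allele dosage; a half-missing call
    (e.g. ``./1``) is treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    rows, metas = [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        dos = np.zeros(len(subject_ids), dtype=np.int8)
        miss = np.zeros(len(subject_ids), dtype=bool)
        for j, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                miss[j] = True
            else:
                dos[j] = (a > 0) + (b > 0)
        rows.append((dos, miss))
        metas.append((variant.ID or f"{variant.CHROM}:{variant.POS}",
                      str(variant.CHROM), variant.POS, variant.REF,
                      variant.ALT[0]))
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    snp_ids = [m[0] for m in metas]
    meta = default_snp_meta(snp_ids)
    meta["chrom"] = [m[1] for m in metas]
    meta["pos"] = [m[2] for m in metas]
    meta["ref"] = [m[3] for m in metas]
    meta["alt"] = [m[4] for m in metas]
    dosages = np.vstack([r[0] for r in rows]) if rows else np.zeros((0, len(subject_ids)), np.int8)
    missing = np.vstack([r[1] for r in rows]) if rows else np.zeros((0, len(subject_ids)), bool)
    return GenotypeMatrix(dosages, missing, meta, subject_ids)


def read_genotypes(path, format: str = "tsv", snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Dispatch to the format-specific reader; output is always SNPs x subjects."""
    if format == "tsv":
        return read_genotype_tsv(path, snp_meta=snp_meta)
    if format == "ped_map":
        return read_ped_map(path, snp_meta=snp_meta)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotype and panel TSV
# ---------------------------------------------------------------------------

def write_phenotype_tsv(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    n0 = len(df)
    df = df.dropna(subset=["chd", "t2d"])
    if len(df) < n0:
        logger.info("dropped %d subjects missing a disease status", n0 - len(df))
    df = df.astype({"chd": int, "t2d": int})
    df["subject_id"] = df["subject_id"].astype(str)
    return PhenotypeTable(df)


def write_panel_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns:
        raise ValueError("panel metadata must carry a snp_id column")
    return df
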