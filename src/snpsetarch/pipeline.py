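"""Pipeline orchestration: structured config, staged execution, manifests.

Stages communicate only through files in the output directory; each stage
writes a manifest (config hash, seed, input-file hashes, package version)
so a rerun with identical inputs is byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import architecture as arch
from . import characterize as char
from . import io as gio
from . import network as net
from . import nsnmf
from . import prefilter
from . import replication as repl
from . import simulate
from . import skat

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "gwas", "sweep", "characterize", "skat",
          "architecture", "network", "replicate"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    genotypes: str | None = None          # input path; None -> use simulate stage
    phenotypes: str | None = None
    panel: str | None = None
    # simulate
    n_subjects: int = 441
    n_snps_chd: int = 110
    n_snps_t2d: int = 83
    pattern_counts: tuple[int, int, int, int] = (61, 91, 97, 192)
    maf_range: tuple[float, float] = (0.05, 0.45)
    missing_rate: float = 0.0
    # qc
    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    subject_missing_max: float = 0.05
    # prescreen
    p_thresh: float = 5e-5
    n_pcs: int = 10
    # nsnmf
    theta: float = 0.5
    k_min: int = 2
    k_max: int | None = None
    tau: float = 0.6
    mode: str = "factor_wise"
    max_iter: int = 2000
    tol: float = 1e-6
    # skat
    skat_weights: str = "flat"
    skat_alpha: float = 0.05
    # architecture / network / replication
    jc_thresh: float = 0.8
    arch_alpha: float = 0.05
    network_alpha: float = 0.05
    p_match: float = 1e-3
    seed: int = 0


_RANGES = {
    "snp_missing_max": (0.0, 1.0), "maf_min": (0.0, 0.5),
    "hwe_p_min": (0.0, 1.0), "subject_missing_max": (0.0, 1.0),
    "p_thresh": (0.0, 1.0), "theta": (0.0, 1.0), "tau": (0.0, 1.0),
    "skat_alpha": (0.0, 1.0), "jc_thresh": (0.0, 1.0),
    "arch_alpha": (0.0, 1.0), "network_alpha": (0.0, 1.0),
    "p_match": (0.0, 1.0), "missing_rate": (0.0, 0.05),
}


class ConfigError(ValueError):
    pass


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults, check ranges, reject unknown keys.

    Errors are aggregated into one human-readable message.
    """
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown config key {k!r}" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.pattern_counts, list):
        cfg.pattern_counts = tuple(cfg.pattern_counts)
    if isinstance(cfg.maf_range, list):
        cfg.maf_range = tuple(cfg.maf_range)
    for name, (lo, hi) in _RANGES.items():
        v = getattr(cfg, name)
        if not (lo <= v <= hi):
            errors.append(f"{name}={v} outside [{lo}, {hi}]")
    if cfg.k_min < 2:
        errors.append(f"k_min={cfg.k_min} must be >= 2")
    if cfg.k_max is not None and cfg.k_max < cfg.k_min:
        errors.append(f"k_max={cfg.k_max} must be >= k_min={cfg.k_min}")
    if cfg.mode not in ("factor_wise", "entity_wise"):
        errors.append(f"mode={cfg.mode!r} not factor_wise/entity_wise")
    if cfg.skat_weights not in ("flat", "beta"):
        errors.append(f"skat_weights={cfg.skat_weights!r} not flat/beta")
    if len(cfg.pattern_counts) != 4:
        errors.append("pattern_counts must have 4 entries")
    elif sum(cfg.pattern_counts) != cfg.n_subjects:
        errors.append("pattern_counts must sum to n_subjects")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text() if path else ""
    return validate_config(yaml.safe_load(text) if text.strip() else {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    payload = dataclasses.asdict(cfg)
    for key in ("out_dir", "genotypes", "phenotypes", "panel"):
        payload.pop(key, None)  # paths don't affect scientific identity
    return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                     default=str).encode()).hexdigest()


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    h = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
    return int(np.random.SeedSequence([cfg.seed, h]).generate_state(1)[0])


class Pipeline:
    """Runs stages against an output directory; artifacts are plain text."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- artifact helpers -------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.out / name

    def _require(self, name: str, producer: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {name!r}; run stage {producer!r} first")
        return p

    def _write_manifest(self, stage: str, inputs: list[str],
                        outputs: list[str]) -> None:
        manifest = {
            "stage": stage,
            "config_hash": _config_hash(self.cfg),
            "seed": _stage_seed(self.cfg, stage),
            "version": __version__,
            "inputs": {n: _sha256(self._path(n)) for n in inputs},
            "outputs": {n: _sha256(self._path(n)) for n in outputs},
        }
        with open(self._path(f"manifest_{stage}.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    # -- stages -----------------------------------------------------------

    def run_stage(self, name: str) -> None:
        if name == "run-all":
            for stage in STAGES:
                if stage == "simulate" and self.cfg.genotypes is not None:
                    continue
                self.run_stage(stage)
            return
        method = getattr(self, "stage_" + name.replace("-", "_"), None)
        if method is None:
            raise ValueError(f"unknown stage {name!r}")
        logger.info("running stage %s", name)
        method()

    def stage_simulate(self) -> None:
        c = self.cfg
        config = simulate.CohortConfig(
            n_subjects=c.n_subjects, n_snps_chd=c.n_snps_chd,
            n_snps_t2d=c.n_snps_t2d, pattern_counts=tuple(c.pattern_counts),
            maf_range=tuple(c.maf_range), missing_rate=c.missing_rate,
            seed=_stage_seed(c, "simulate"))
        g, pheno, _ = simulate.simulate_cohort(config)
        gio.write_genotype_tsv(g, self._path("genotypes.tsv"))
        gio.write_phenotype_tsv(pheno, self._path("phenotypes.tsv"))
        gio.write_panel_tsv(g.snp_meta, self._path("panel.tsv"))
        simulate.write_manifest(config, self._path("cohort_config.json"))
        self._write_manifest("simulate", [],
                             ["genotypes.tsv", "phenotypes.tsv", "panel.tsv"])

    def _load_inputs(self):
        c = self.cfg
        gpath = Path(c.genotypes) if c.genotypes else self._require(
            "genotypes.tsv", "simulate")
        ppath = Path(c.phenotypes) if c.phenotypes else self._require(
            "phenotypes.tsv", "simulate")
        panel_path = Path(c.panel) if c.panel else self._require(
            "panel.tsv", "simulate")
        meta = gio.read_panel_tsv(panel_path)
        g = gio.read_genotypes(gpath, format="tsv", snp_meta=meta)
        pheno = gio.read_phenotypes(ppath)
        return g, pheno

    def stage_qc(self) -> None:
        g, pheno = self._load_inputs()
        filtered, report = prefilter.qc_filter(
            g, self.cfg.snp_missing_max, self.cfg.maf_min,
            self.cfg.hwe_p_min, self.cfg.subject_missing_max)
        logger.info("QC: %d -> %d SNPs, %d -> %d subjects",
                    g.n_snps, filtered.n_snps, g.n_subjects,
                    filtered.n_subjects)
        gio.write_genotype_tsv(filtered, self._path("qc_genotypes.tsv"))
        gio.write_panel_tsv(filtered.snp_meta, self._path("qc_panel.tsv"))
        report.to_csv(self._path("qc_report.tsv"), sep="\t", index=False)
        self._write_manifest("qc", ["genotypes.tsv"],
                             ["qc_genotypes.tsv", "qc_report.tsv"])

    def _load_qc(self):
        meta = gio.read_panel_tsv(self._require("qc_panel.tsv", "qc"))
        g = gio.read_genotypes(self._require("qc_genotypes.tsv", "qc"),
                               snp_meta=meta)
        _, pheno = self._load_inputs()
        pheno = pheno.aligned_to(g.subject_ids)
        return g, pheno

    def stage_gwas(self) -> None:
        c = self.cfg
        g, pheno = self._load_qc()
        pcs = (prefilter.compute_pcs(g, c.n_pcs)
               if c.n_pcs else np.empty((g.n_subjects, 0)))
        covs = np.column_stack([
            pheno.data["age"].to_numpy(float),
            pheno.data["sex"].to_numpy(float),
            pheno.data["bmi"].to_numpy(float), pcs])
        results = []
        for disease, col in (("CHD", "chd"), ("T2D", "t2d")):
            res = prefilter.logistic_gwas(
                g, pheno.data[col].to_numpy(), covariates=covs,
                disease=disease)
            results.append(prefilter.gwas_results_frame(res))
        out = pd.concat(results, ignore_index=True)
        out.to_csv(self._path("gwas_results.tsv"), sep="\t", index=False)
        # persist PCs so downstream covariate adjustment reuses them
        pc_df = pd.DataFrame(pcs, columns=[f"pc{i+1}" for i in range(pcs.shape[1])])
        pc_df.insert(0, "subject_id", g.subject_ids)
        pc_df.to_csv(self._path("pcs.tsv"), sep="\t", index=False)
        self._write_manifest("gwas", ["qc_genotypes.tsv"],
                             ["gwas_results.tsv", "pcs.tsv"])

    def _pooled(self):
        g, pheno = self._load_qc()
        res = pd.read_csv(self._require("gwas_results.tsv", "gwas"), sep="\t")
        to_results = lambda df, disease: [
            prefilter.GwasResult(str(r.snp_id), r.beta, r.se, r.p, disease,
                                 bool(r.flagged))
            for r in df[df["disease"] == disease].itertuples()]
        pooled = prefilter.pool_panels(
            g, to_results(res, "CHD"), to_results(res, "T2D"),
            p_thresh=self.cfg.p_thresh)
        pcs_path = self._path("pcs.tsv")
        if pcs_path.exists():
            pcs = pd.read_csv(pcs_path, sep="\t")
            pheno = gio.PhenotypeTable(
                pheno.data.merge(pcs, on="subject_id", how="left"))
        return pooled, pheno

    def stage_sweep(self) -> None:
        c = self.cfg
        pooled, _ = self._pooled()
        gio.write_panel_tsv(pooled.snp_meta, self._path("pooled_panel.tsv"))
        gio.write_genotype_tsv(pooled, self._path("pooled_genotypes.tsv"))
        X = nsnmf.encode_matrix(pooled)
        sets, _ = nsnmf.run_sweep(
            X, pooled, k_min=c.k_min, k_max=c.k_max, theta=c.theta,
            tau=c.tau, mode=c.mode, max_iter=c.max_iter, tol=c.tol,
            seed=_stage_seed(c, "sweep"))
        with open(self._path("snp_sets.json"), "w") as fh:
            json.dump(nsnmf.sets_to_json(sets), fh, indent=1)
        nsnmf.sets_to_membership_frame(sets).to_csv(
            self._path("snp_set_members.tsv"), sep="\t", index=False)
        logger.info("sweep produced %d sets", len(sets))
        self._write_manifest("sweep", ["gwas_results.tsv"],
                             ["snp_sets.json", "pooled_panel.tsv"])

    def _load_sets(self):
        with open(self._require("snp_sets.json", "sweep")) as fh:
            return nsnmf.sets_from_json(json.load(fh))

    def stage_characterize(self) -> None:
        pooled, pheno = self._pooled()
        sets = self._load_sets()
        descriptors = [char.describe_set(s, pheno, pooled.snp_meta)
                       for s in sets]
        char.descriptor_table(descriptors).to_csv(
            self._path("set_descriptors.tsv"), sep="\t", index=False)
        mix_panel, mix_dir = char.purity_summary(sets, pooled.snp_meta)
        with open(self._path("purity.json"), "w") as fh:
            json.dump({"mixed_panel_fraction": mix_panel,
                       "mixed_direction_fraction": mix_dir}, fh, indent=2)
        self._write_manifest("characterize", ["snp_sets.json"],
                             ["set_descriptors.tsv", "purity.json"])

    def stage_skat(self) -> None:
        pooled, pheno = self._pooled()
        sets = self._load_sets()
        table = skat.test_all_sets(sets, pooled, pheno,
                                   weights=self.cfg.skat_weights,
                                   alpha=self.cfg.skat_alpha)
        table.to_csv(self._path("skat_results.tsv"), sep="\t", index=False)
        logger.info("SKAT: %d of %d sets significant",
                    int(table["significant"].sum()), len(table))
        self._write_manifest("skat", ["snp_sets.json"], ["skat_results.tsv"])

    def _retained(self):
        sets = self._load_sets()
        table = pd.read_csv(self._require("skat_results.tsv", "skat"),
                            sep="\t")
        keep = set(table.loc[table["significant"], "label"])
        return [s for s in sets if s.label in keep]

    def stage_architecture(self) -> None:
        c = self.cfg
        pooled, pheno = self._pooled()
        retained = self._retained()
        pheno_sets = arch.define_phenotype_sets(pheno)
        if not retained:
            arch.relations_frame([]).to_csv(
                self._path("relations.tsv"), sep="\t", index=False)
            with open(self._path("retained_sets.json"), "w") as fh:
                json.dump([], fh)
            self._write_manifest("architecture", ["skat_results.tsv"],
                                 ["relations.tsv", "retained_sets.json"])
            return
        rel_p = arch.best_relation_pvalues(retained, pheno_sets,
                                           pheno.n_subjects)
        nonredundant = arch.redundancy_filter(retained, rel_p,
                                              jc_thresh=c.jc_thresh)
        edges = arch.build_architecture(nonredundant, pheno_sets,
                                        alpha=c.arch_alpha,
                                        panel=pooled.snp_meta)
        arch.relations_frame(edges).to_csv(
            self._path("relations.tsv"), sep="\t", index=False)
        arch.relation_matrix(nonredundant, pheno_sets).to_csv(
            self._path("relation_matrix.tsv"), sep="\t")
        with open(self._path("retained_sets.json"), "w") as fh:
            json.dump(nsnmf.sets_to_json(nonredundant), fh, indent=1)
        logger.info("architecture: %d sets retained, %d significant edges",
                    len(nonredundant), len(edges))
        self._write_manifest("architecture", ["skat_results.tsv"],
                             ["relations.tsv", "retained_sets.json"])

    def stage_network(self) -> None:
        with open(self._require("retained_sets.json", "architecture")) as fh:
            retained = nsnmf.sets_from_json(json.load(fh))
        panel = gio.read_panel_tsv(self._require("pooled_panel.tsv", "sweep"))
        if not retained:
            logger.info("no retained sets; skipping network")
            return
        netw = net.build_genotypic_network(retained, panel_size=len(panel),
                                           alpha=self.cfg.network_alpha)
        net.export_graph(netw, self._path("network.graphml"),
                         format="graphml")
        net.export_graph(netw, self._path("network_edges.tsv"),
                         format="edge_tsv")
        self._write_manifest("network", ["retained_sets.json"],
                             ["network.graphml", "network_edges.tsv"])

    def stage_replicate(self) -> None:
        c = self.cfg
        panel = gio.read_panel_tsv(self._require("pooled_panel.tsv", "sweep"))
        discovery = self._load_sets()
        # held-out cohort simulated from the same panel dimensions
        rep_counts = (87, 133, 93, 158)
        config = simulate.CohortConfig(
            n_subjects=sum(rep_counts), n_snps_chd=c.n_snps_chd,
            n_snps_t2d=c.n_snps_t2d, pattern_counts=rep_counts,
            maf_range=tuple(c.maf_range), missing_rate=c.missing_rate,
            seed=_stage_seed(c, "replicate"))
        g_rep, _, _ = simulate.simulate_cohort(config)
        shared = [s for s in panel["snp_id"].astype(str)
                  if s in set(g_rep.snp_ids)]
        rep_sets = repl.replicate_sweep(
            g_rep, shared, k_min=c.k_min, k_max=c.k_max, theta=c.theta,
            tau=c.tau, mode=c.mode, max_iter=c.max_iter, tol=c.tol,
            seed=_stage_seed(c, "replicate-sweep"))
        records = repl.match_snp_sets(discovery, rep_sets,
                                      panel_size=len(shared),
                                      p_match=c.p_match)
        repl.match_frame(records).to_csv(
            self._path("replication_matches.tsv"), sep="\t", index=False)
        self._write_manifest("replicate", ["snp_sets.json"],
                             ["replication_matches.tsv"])
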