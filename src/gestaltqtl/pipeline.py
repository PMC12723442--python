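"""End-to-end orchestration: simulate -> filter -> phenotypes -> kinship -> GWAS -> report.

A single :class:`RunConfig` carries every threshold of the analysis
(defaults are the study's values) plus the global seed; every output
directory gets a ``run_metadata.json`` embedding the config hash and seed
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, kinship, phenotypes, postgwas, simdata, variants

log = logging.getLogger("gestaltqtl")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All pipeline knobs; defaults follow the study's reported thresholds."""

    out_dir: str = "gestaltqtl_run"
    seed: int = 0
    # inputs (None -> produced by the simulate stage)
    vcf: str | None = None
    colonies: str | None = None
    traits: str | None = None
    genetic_map: str | None = None
    gff: str | None = None
    kinship_tsv: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for simdata.SimParams
    # filtering cascade
    sample_missingness_1: float = 0.5
    sample_missingness_2: float = 0.6
    min_call_rate: float = 0.8
    min_depth: int = 6
    max_depth: int = 250
    min_maf: float = 0.15
    blacklist_radius_bp: int = 600
    excess_coverage: float | None = None  # None -> mean + 2 SD
    min_colony_calls: int = 3
    # phenotypes
    iqr_k: float = 1.5
    trait_pc_min_explained: float = 0.04
    # association
    levels: tuple = ("individual", "colony")
    n_structure_pcs_individual: int = 45
    n_structure_pcs_colony: int = 8
    kinship_method: str = "grm"  # "grm" | "ibd" | "pedigree" (simulated runs)
    use_mlmm: bool = False
    n_perm: int = 0  # 100 in the study; 0 skips the permutation stage
    # reporting
    q_thresholds: tuple = (0.05, 0.1, 0.2, 0.3)
    cluster_gap_cM: float = 12.0
    upstream_bp: int = 2000

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("levels", "q_thresholds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return result
        return inner
    return wrap


@_stage("simulate")
def _run_simulate(cfg: RunConfig):
    params = simdata.SimParams(seed=cfg.seed, **cfg.sim)
    rng = np.random.default_rng(cfg.seed)
    pedigree, haps = simdata.simulate_colonies(params, rng=rng)
    traits, truth = simdata.simulate_traits(haps, pedigree, params, rng=rng)
    sim_dir = os.path.join(cfg.out_dir, "sim")
    paths = simdata.write_fixture(pedigree, haps, traits, sim_dir,
                                  qtl_truth=truth, seed=cfg.seed)
    return paths, pedigree, haps


@_stage("filter")
def _run_filter(cfg: RunConfig, report: variants.FilterReport):
    for path, name in ((cfg.vcf, "vcf"), (cfg.colonies, "colonies"),
                       (cfg.traits, "traits")):
        if path is None or not os.path.exists(path):
            raise PipelineError(f"missing input: {name} ({path})")
    gm = variants.read_vcf(cfg.vcf, cfg.colonies)
    report.add("input", gm.n_loci, gm.n_samples)
    gm = variants.drop_non_biallelic(gm, report)
    gm = variants.filter_samples_missingness(gm, cfg.sample_missingness_1, report)
    haploid = gm.subset(sample_mask=gm.samples["ploidy"].to_numpy() == 1)
    if haploid.n_samples:
        bl = variants.haploid_blacklist(haploid, cfg.blacklist_radius_bp)
        gm = variants.apply_blacklist(gm, bl, report)
    gm = variants.filter_loci(gm, cfg.min_call_rate, cfg.min_depth,
                              cfg.max_depth, cfg.min_maf, report)
    gm = variants.excess_coverage_filter(gm, cfg.excess_coverage, report)
    gm = variants.filter_samples_missingness(gm, cfg.sample_missingness_2, report)
    # haploid controls served the blacklist; drop them from association
    gm = gm.subset(sample_mask=gm.samples["ploidy"].to_numpy() == 2)
    if cfg.genetic_map:
        gm = gm.attach_map(pd.read_csv(cfg.genetic_map, sep="\t"))
    mask = variants.require_colony_calls(gm, cfg.min_colony_calls)
    cgm = variants.colony_genotypes(gm.subset(locus_mask=mask), cfg.min_colony_calls)
    report.add("colony_min_calls", int(mask.sum()), len(cgm.colonies),
               loci_removed=int((~mask).sum()))
    return gm, cgm


def _normalize_or_standardize(tm: pd.DataFrame, min_values: int = 10):
    """Best-fit normalization; small traits pass through standardized."""
    counts = tm.notna().sum()
    rich = tm.loc[:, counts >= min_values]
    poor = tm.loc[:, counts < min_values]
    choices = {}
    parts = []
    if rich.shape[1]:
        normed, choices = phenotypes.normalize_best_fit(rich)
        parts.append(normed)
    if poor.shape[1]:
        parts.append((poor - poor.mean()) / poor.std(ddof=1))
    out = pd.concat(parts, axis=1)[tm.columns]
    return out, choices


@_stage("phenotypes")
def _run_phenotypes(cfg: RunConfig, sample_ids):
    tm = pd.read_csv(cfg.traits, sep="\t", index_col=0)
    tm = tm.loc[[s for s in sample_ids if s in tm.index]]
    colony_map = variants.read_colony_map(cfg.colonies)
    out = {}
    ind = phenotypes.remove_outliers_iqr(tm, cfg.iqr_k)
    ind_norm, ind_choice = _normalize_or_standardize(ind)
    out["individual"] = ind_norm
    col = phenotypes.colony_average(tm, colony_map)
    col = phenotypes.remove_outliers_iqr(col, cfg.iqr_k)
    col_norm, col_choice = _normalize_or_standardize(col)
    out["colony"] = col_norm
    out["choices"] = {
        "individual": {t: dataclasses.asdict(c) for t, c in ind_choice.items()},
        "colony": {t: dataclasses.asdict(c) for t, c in col_choice.items()},
    }
    return out


@_stage("kinship")
def _run_kinship(cfg: RunConfig, gm, cgm, pedigree=None):
    ids = gm.samples["sample_id"].tolist()
    if cfg.kinship_tsv:
        K_ind = kinship.KinshipMatrix.from_tsv(cfg.kinship_tsv)
    elif cfg.kinship_method == "pedigree" and pedigree is not None:
        K_ind = kinship.pedigree_kinship(pedigree)
        keep = [K_ind.ids.index(s) for s in ids]
        K_ind = kinship.KinshipMatrix(K_ind.values[np.ix_(keep, keep)], ids, "pedigree")
    else:
        K_ind = kinship.grm(gm.dosage, sample_ids=ids)
    K_col = kinship.grm(cgm.mean_dosage, sample_ids=cgm.colonies)
    return K_ind, K_col


@_stage("gwas")
def _run_gwas(cfg: RunConfig, level, y, X, K, G, loci, rng_seed):
    res = (
        assoc.mlmm(y, X, K, G, loci=loci).results
        if cfg.use_mlmm
        else assoc.snp_scan(y, X, K, G, loci=loci)
    )
    if cfg.n_perm > 0:
        null = assoc.permutation_null(y, X, K, G, n_perm=cfg.n_perm, seed=rng_seed)
        res["p_emp"] = assoc.empirical_pvalues(res["p"].to_numpy(), null.pool())
        res["q"] = assoc.bh_fdr(res["p_emp"].to_numpy())
    else:
        res["p_emp"] = np.nan
        res["q"] = assoc.bh_fdr(res["p"].to_numpy())
    res["level"] = level
    return res


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths and key frames."""
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    report = variants.FilterReport()
    pedigree = None
    if cfg.simulate:
        paths, pedigree, _ = _run_simulate(cfg)
        cfg = dataclasses.replace(
            cfg, vcf=paths["vcf"], colonies=paths["colonies"],
            traits=paths["traits"], genetic_map=paths["genetic_map"],
            gff=paths.get("gff"),
        )
    gm, cgm = _run_filter(cfg, report)
    pheno = _run_phenotypes(cfg, gm.samples["sample_id"].tolist())
    K_ind, K_col = _run_kinship(cfg, gm, cgm, pedigree)

    results = []
    ss = np.random.SeedSequence(cfg.seed)
    level_seeds = {lvl: int(s.generate_state(1)[0] % (2**31))
                   for lvl, s in zip(("individual", "colony"), ss.spawn(2))}
    loci_cols = [c for c in ("locus_id", "chrom", "bp", "cM") if c in gm.loci.columns]
    for level in cfg.levels:
        if level == "individual":
            G = gm.dosage
            ids = gm.samples["sample_id"].tolist()
            K = K_ind
            n_pcs = min(cfg.n_structure_pcs_individual, len(ids) - 2)
            tm = pheno["individual"]
            loci = gm.loci[loci_cols]
            pcs = kinship.structure_pcs(G, n_pcs, sample_ids=ids)
        else:
            G = cgm.mean_dosage
            ids = cgm.colonies
            K = K_col
            n_pcs = min(cfg.n_structure_pcs_colony, len(ids) - 2)
            tm = pheno["colony"]
            loci = cgm.loci[[c for c in loci_cols if c in cgm.loci.columns]]
            pcs = kinship.structure_pcs(G, n_pcs, sample_ids=ids)
        tm = tm.reindex(ids)
        X = np.column_stack([np.ones(len(ids)), pcs.loc[ids].to_numpy()])
        for trait in tm.columns:
            y = tm[trait].to_numpy(float)
            ok = ~np.isnan(y)
            res = _run_gwas(
                cfg, level, y[ok], X[ok],
                K.values[np.ix_(ok, ok)], np.asarray(G, float)[ok], loci,
                rng_seed=level_seeds[level],
            )
            res["trait"] = trait
            results.append(res)
    all_res = pd.concat(results, ignore_index=True)
    assoc_path = os.path.join(cfg.out_dir, "associations.tsv")
    all_res.to_csv(assoc_path, sep="\t", index=False)

    hits, counts = postgwas.threshold_hits(all_res, cfg.q_thresholds)
    counts.to_csv(os.path.join(cfg.out_dir, "hit_counts.tsv"), sep="\t")
    clusters = (
        postgwas.cluster_qtls(hits, cfg.cluster_gap_cM)
        if "cM" in hits.columns and hits["cM"].notna().any()
        else []
    )
    gene_table = None
    if cfg.gff and len(hits):
        gene_table = postgwas.gene_hits(hits, cfg.gff, cfg.upstream_bp)
        gene_table.to_csv(os.path.join(cfg.out_dir, "gene_hits.tsv"),
                          sep="\t", index=False)
    report.to_json(os.path.join(cfg.out_dir, "filter_report.json"))
    meta = {
        "config_hash": config.hash(),
        "seed": cfg.seed,
        "config": dataclasses.asdict(config),
        "n_hits": int(len(hits)),
        "n_clusters": len(clusters),
    }
    with open(os.path.join(cfg.out_dir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    with open(os.path.join(cfg.out_dir, "normalization.json"), "w") as fh:
        json.dump(pheno["choices"], fh, indent=2, default=str)
    return {
        "out_dir": cfg.out_dir,
        "associations": assoc_path,
        "results": all_res,
        "hits": hits,
        "counts": counts,
        "clusters": clusters,
        "gene_hits": gene_table,
        "report": report,
    }
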