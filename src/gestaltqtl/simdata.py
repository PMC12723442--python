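"""Synthetic colony, genotype and trait generator.

Emulates the statistical structure of a monogyne, polyandrous ant
population sampled for a colony-level ("Gestalt") GWAS: each colony is
founded by one diploid queen mated to several haploid males; diploid
workers inherit one recombinant queen gamete and one intact paternal
haplotype.  Traits are built from known QTLs with a controlled percent
explained variability (PEV), a colony-level environmental effect, and
optional Gestalt mixing of nestmate phenotypes.

Haplodiploid relatedness among nestmate workers under k equally
contributing patrilines is r = 0.25 + 0.5/k (0.75 for full sisters).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "Pedigree",
    "HaplotypeSet",
    "simulate_map",
    "simulate_colonies",
    "simulate_traits",
    "write_fixture",
]

#: assumed physical scale of the genetic map (uniform recombination rate)
BP_PER_CM = 20_000


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Parameters of the synthetic study design.

    Defaults follow the study design being emulated: 47 monogyne colonies,
    queens mated to 2-10 males, six sampled workers per colony, 27 linkage
    groups.  ``n_loci`` defaults to a desk-scale marker panel; the study's
    catalog (~1.7e5 SNPs) is reachable by raising it.

    ``pev`` is the fraction of trait variance explained by *each* QTL;
    ``colony_env_var`` the fraction contributed by a colony-level
    environmental effect; ``gestalt_m`` in [0, 1] mixes each worker's
    phenotype with the colony mean (1 = fully shared colony odor).
    ``pev_scale`` selects whether PEV is calibrated on the pre-mixing
    individual phenotype ("individual") or on the observed, post-mixing
    phenotype ("observed") -- the latter makes PEV the colony-level
    variance fraction when ``gestalt_m=1``.
    """

    n_colonies: int = 47
    workers_per_colony: int | tuple[int, int] = 6
    patrilines: tuple[int, int] = (2, 10)
    n_loci: int = 2_000
    n_chromosomes: int = 27
    chrom_length_cM: float | tuple[float, ...] = 75.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 34
    qtl_per_trait: int = 1
    pev: float = 0.23
    colony_env_var: float = 0.3
    gestalt_m: float = 0.5
    pev_scale: str = "individual"
    paternity_alpha: float | None = None
    compositional: bool = False
    n_haploid_controls: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_colonies < 1 or self.n_loci < 1 or self.n_chromosomes < 1:
            raise SimulationError("counts must be positive")
        lo, hi = self.patrilines
        if lo < 1 or hi < lo:
            raise SimulationError("patriline range invalid (min >= 1)")
        if not (0.0 <= self.gestalt_m <= 1.0):
            raise SimulationError("gestalt_m must be in [0, 1]")
        if not (0.0 < self.founder_maf_range[0] <= self.founder_maf_range[1] <= 0.5):
            raise SimulationError("founder_maf_range must lie in (0, 0.5]")
        total_pev = self.pev * self.qtl_per_trait
        if total_pev < 0 or self.colony_env_var < 0 or total_pev + self.colony_env_var > 1:
            raise SimulationError("qtl_per_trait*pev + colony_env_var must be in [0, 1]")
        if self.pev_scale not in ("individual", "observed"):
            raise SimulationError("pev_scale must be 'individual' or 'observed'")

    def chrom_lengths(self) -> np.ndarray:
        if np.isscalar(self.chrom_length_cM):
            return np.full(self.n_chromosomes, float(self.chrom_length_cM))
        lengths = np.asarray(self.chrom_length_cM, dtype=float)
        if lengths.size != self.n_chromosomes:
            raise SimulationError("chrom_length_cM length mismatch")
        return lengths


@dataclass
class Pedigree:
    """Per-worker parentage within each simulated colony."""

    workers: pd.DataFrame  # sample_id, colony_id, father
    n_patrilines: dict[str, int] = field(default_factory=dict)

    def relatedness_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Expected additive relatedness among workers (haplodiploid).

        Within a colony: 0.75 for full sisters (same father), 0.25 for
        maternal half sisters; zero between colonies (founders unrelated);
        1 on the diagonal.
        """
        ids = self.workers["sample_id"].tolist()
        colony = self.workers["colony_id"].to_numpy()
        father = self.workers["father"].to_numpy()
        same_col = colony[:, None] == colony[None, :]
        same_father = same_col & (father[:, None] == father[None, :])
        r = np.where(same_col, 0.25, 0.0) + np.where(same_father, 0.5, 0.0)
        np.fill_diagonal(r, 1.0)
        return r, ids


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes per sample, with founder-origin labels.

    ``alleles[sid]`` has shape (ploidy, n_loci) with values in {0, 1};
    ``origins`` labels each allele with the founder haplotype it descends
    from (queen haplotypes 0/1, father j -> 2+j), enabling exact
    identity-by-descent bookkeeping on error-free data.
    """

    alleles: dict[str, np.ndarray]
    origins: dict[str, np.ndarray]
    marker_map: pd.DataFrame
    phased: bool = True

    @property
    def sample_ids(self) -> list[str]:
        return list(self.alleles)

    def ploidy(self, sample_id: str) -> int:
        return self.alleles[sample_id].shape[0]

    def dosage_matrix(self, sample_ids=None) -> pd.DataFrame:
        ids = sample_ids if sample_ids is not None else self.sample_ids
        rows = [self.alleles[s].sum(axis=0) for s in ids]
        return pd.DataFrame(
            np.asarray(rows, dtype=float), index=ids, columns=self.marker_map["locus_id"]
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_map(n_chromosomes, n_loci, chrom_length_cM, seed=None) -> pd.DataFrame:
    """Draw a marker map with strictly increasing bp and cM positions.

    cM positions are proportional to bp under a uniform recombination rate
    of 1 cM per ``BP_PER_CM`` bp.  Loci are spread as evenly as possible
    over chromosomes.
    """
    if n_loci < 1 or n_chromosomes < 1:
        raise SimulationError("n_loci and n_chromosomes must be positive")
    if n_loci < n_chromosomes:
        raise SimulationError("need at least one locus per chromosome")
    lengths = (
        np.full(n_chromosomes, float(chrom_length_cM))
        if np.isscalar(chrom_length_cM)
        else np.asarray(chrom_length_cM, dtype=float)
    )
    if lengths.size != n_chromosomes or np.any(lengths <= 0):
        raise SimulationError("chromosome lengths must be positive")
    rng = _rng(seed)
    per = np.full(n_chromosomes, n_loci // n_chromosomes)
    per[: n_loci % n_chromosomes] += 1
    records = []
    for c in range(n_chromosomes):
        n_c = int(per[c])
        cm = np.sort(rng.uniform(0.0, lengths[c] * (1 - 1e-6), size=n_c))
        bp = np.round(cm * BP_PER_CM).astype(np.int64) + 1
        bp = bp + np.arange(n_c)  # break rounding ties, keep strictly increasing
        cm = (bp - 1) / BP_PER_CM
        for i in range(n_c):
            records.append((f"chr{c + 1}", int(bp[i]), float(cm[i])))
    df = pd.DataFrame(records, columns=["chrom", "bp", "cM"])
    df.insert(0, "locus_id", [f"L{i + 1}" for i in range(len(df))])
    return df


def _meiosis(parent_alleles, parent_origins, chrom_index, rec_frac, rng):
    """One gamete from a diploid parent under the Haldane crossover model.

    ``rec_frac[i]`` is the recombination fraction between locus i and
    locus i+1 (zero across chromosome boundaries is enforced by starting
    each chromosome on a fresh random haplotype).
    """
    n_loci = parent_alleles.shape[1]
    hap = np.empty(n_loci, dtype=np.int8)
    # per-interval switch indicator; chromosome starts re-randomized below
    switch = rng.random(n_loci) < np.concatenate(([0.0], rec_frac))
    new_chrom = np.concatenate(([True], chrom_index[1:] != chrom_index[:-1]))
    switch[new_chrom] = False
    current = np.cumsum(switch) % 2
    starts = rng.integers(0, 2, size=new_chrom.sum())
    start_per_locus = np.repeat(starts, np.diff(np.flatnonzero(np.concatenate((new_chrom, [True])))))
    hap = (current + start_per_locus) % 2
    idx = np.arange(n_loci)
    return parent_alleles[hap, idx], parent_origins[hap, idx]


def haldane_recombination_fraction(d_cM: np.ndarray) -> np.ndarray:
    """r = (1 - exp(-2 d / 100)) / 2 for map distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_colonies(params: SimParams, marker_map: pd.DataFrame | None = None,
                      rng: np.random.Generator | None = None):
    """Simulate founder haplotypes, matings and worker genomes.

    Returns ``(pedigree, haplotypes)``.  Founder ALT-allele frequencies are
    drawn per locus with MAF uniform in ``founder_maf_range`` (ALT is the
    minor or major allele with equal probability).  Each worker receives a
    recombinant queen gamete (Haldane model, no interference) and a copy of
    one father's haplotype, the father drawn per colony paternity shares
    (equal by default, Dirichlet-distributed if ``paternity_alpha`` is set).
    """
    rng = rng if rng is not None else _rng(params.seed)
    if marker_map is None:
        marker_map = simulate_map(
            params.n_chromosomes, params.n_loci, params.chrom_length_cM, seed=rng
        )
    n_loci = len(marker_map)
    chrom_codes = pd.factorize(marker_map["chrom"])[0]
    d = np.diff(marker_map["cM"].to_numpy())
    rec = haldane_recombination_fraction(np.maximum(d, 0.0))

    maf = rng.uniform(*params.founder_maf_range, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    freq = np.where(flip, 1.0 - maf, maf)

    lo, hi = params.patrilines
    alleles: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    rows = []
    n_pat: dict[str, int] = {}
    for c in range(params.n_colonies):
        colony_id = f"C{c + 1:02d}"
        queen = (rng.random((2, n_loci)) < freq).astype(np.int8)
        queen_orig = np.vstack([np.zeros(n_loci, np.int16), np.ones(n_loci, np.int16)])
        k = int(rng.integers(lo, hi + 1))
        n_pat[colony_id] = k
        males = (rng.random((k, n_loci)) < freq).astype(np.int8)
        if params.paternity_alpha is None:
            shares = np.full(k, 1.0 / k)
        else:
            shares = rng.dirichlet(np.full(k, params.paternity_alpha))
        if np.isscalar(params.workers_per_colony):
            nw = int(params.workers_per_colony)
        else:
            wlo, whi = params.workers_per_colony
            nw = int(rng.integers(wlo, whi + 1))
        for w in range(nw):
            sid = f"{colony_id}_W{w + 1}"
            gam_a, gam_o = _meiosis(queen, queen_orig, chrom_codes, rec, rng)
            father = int(rng.choice(k, p=shares))
            pat_a = males[father]
            pat_o = np.full(n_loci, 2 + father, np.int16)
            alleles[sid] = np.vstack([gam_a, pat_a.astype(np.int8)])
            origins[sid] = np.vstack([gam_o, pat_o])
            rows.append((sid, colony_id, father))
    # unrelated haploid control males (for the heterozygous-haploid blacklist)
    for h in range(params.n_haploid_controls):
        sid = f"HM{h + 1}"
        alleles[sid] = (rng.random((1, n_loci)) < freq).astype(np.int8)
        origins[sid] = np.full((1, n_loci), -1, np.int16)

    pedigree = Pedigree(
        workers=pd.DataFrame(rows, columns=["sample_id", "colony_id", "father"]),
        n_patrilines=n_pat,
    )
    haps = HaplotypeSet(alleles=alleles, origins=origins, marker_map=marker_map)
    return pedigree, haps


def realized_relatedness(haps: HaplotypeSet, sid_i: str, sid_j: str) -> float:
    """Genome-wide realized pedigree relatedness from founder origins.

    r = (P(maternal alleles IBD) + P(paternal alleles IBD)) / 2 for two
    diploid workers, averaging exact origin identity over loci.
    """
    oi, oj = haps.origins[sid_i], haps.origins[sid_j]
    mat = np.mean(oi[0] == oj[0])
    pat = np.mean(oi[1] == oj[1])
    return float((mat + pat) / 2.0)


def _mix(values: np.ndarray, colony_codes: np.ndarray, m: float) -> np.ndarray:
    """Gestalt mixing: (1-m) * own + m * colony mean (own included)."""
    if m == 0.0:
        return values
    n_col = colony_codes.max() + 1
    sums = np.bincount(colony_codes, weights=values, minlength=n_col)
    counts = np.bincount(colony_codes, minlength=n_col)
    means = sums / counts
    return (1.0 - m) * values + m * means[colony_codes]


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s < 1e-12:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def simulate_traits(haps: HaplotypeSet, pedigree: Pedigree, params: SimParams,
                    rng: np.random.Generator | None = None):
    """Simulate trait values with known QTLs.

    Per trait, ``qtl_per_trait`` QTLs are drawn among loci with realized
    worker MAF >= 0.1 and each is scaled (against the realized dosage
    variance) to explain exactly ``pev`` of the phenotypic variance on the
    scale selected by ``pev_scale``.  A colony environmental effect
    (variance fraction ``colony_env_var``) and individual noise make up
    the remainder; Gestalt mixing is applied last (before the optional
    compositional renormalization).

    Returns ``(trait_matrix, qtl_truth)``.
    """
    rng = rng if rng is not None else _rng(None if params.seed is None else params.seed + 1)
    worker_ids = pedigree.workers["sample_id"].tolist()
    X = haps.dosage_matrix(worker_ids).to_numpy()
    n, n_loci = X.shape
    colony_codes = pd.factorize(pedigree.workers["colony_id"])[0]

    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    eligible = np.flatnonzero(maf >= 0.1)
    need = params.n_traits * params.qtl_per_trait
    if params.qtl_per_trait > 0 and len(eligible) < need:
        raise SimulationError(
            f"only {len(eligible)} loci with MAF >= 0.1; "
            f"{need} QTLs requested -- PEV {params.pev} unattainable"
        )
    total_pev = params.pev * params.qtl_per_trait
    chosen = (
        rng.choice(eligible, size=need, replace=False) if need else np.empty(0, int)
    )
    values = np.empty((n, params.n_traits))
    truth_rows = []
    locus_ids = haps.marker_map["locus_id"].to_numpy()
    for t in range(params.n_traits):
        qtls = chosen[t * params.qtl_per_trait : (t + 1) * params.qtl_per_trait]
        signs = rng.choice([-1.0, 1.0], size=len(qtls))
        g = np.zeros(n)
        for q, s in zip(qtls, signs):
            xq = X[:, q]
            if xq.std() < 1e-9:
                raise SimulationError(f"locus {locus_ids[q]} is monomorphic; PEV unattainable")
            g += np.sqrt(params.pev) * s * _standardize(xq)
        e_col = rng.standard_normal(colony_codes.max() + 1)[colony_codes]
        eps = rng.standard_normal(n)
        resid_var = 1.0 - total_pev - params.colony_env_var
        other = np.sqrt(params.colony_env_var) * _standardize(e_col) + np.sqrt(
            resid_var
        ) * _standardize(eps)
        if params.pev_scale == "individual":
            y = _mix(g + other, colony_codes, params.gestalt_m)
        else:  # calibrate PEV on the observed (post-mixing) phenotype
            gm = _mix(g, colony_codes, params.gestalt_m)
            om = _mix(other, colony_codes, params.gestalt_m)
            y = np.sqrt(total_pev) * _standardize(gm) + np.sqrt(1.0 - total_pev) * _standardize(om)
        values[:, t] = y
        for q, s in zip(qtls, signs):
            xq = X[:, q]
            truth_rows.append(
                {
                    "trait": f"trait_{t + 1}",
                    "locus_id": locus_ids[q],
                    "chrom": haps.marker_map["chrom"].iloc[q],
                    "bp": int(haps.marker_map["bp"].iloc[q]),
                    "cM": float(haps.marker_map["cM"].iloc[q]),
                    "effect": float(np.sqrt(params.pev) * s / max(xq.std(), 1e-12)),
                    "pev": params.pev,
                }
            )
    if params.compositional:
        # interpret simulated values as log-abundances, renormalize rows
        amounts = np.exp(values)
        values = amounts / amounts.sum(axis=1, keepdims=True)
    traits = pd.DataFrame(
        values, index=pd.Index(worker_ids, name="sample_id"),
        columns=[f"trait_{t + 1}" for t in range(params.n_traits)],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["trait", "locus_id", "chrom", "bp", "cM", "effect", "pev"],
    )
    return traits, truth


# ---------------------------------------------------------------------------
# fixture writing

def _simulate_depth(shape, rng, mean=12.0, size=8.0):
    """Per-call read depth, negative binomial with the study's mean coverage."""
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=shape)


def write_fixture(pedigree: Pedigree, haps: HaplotypeSet, traits: pd.DataFrame,
                  out_dir, qtl_truth: pd.DataFrame | None = None,
                  depth_mean: float = 12.0, seed: int | None = 0) -> dict[str, str]:
    """Write the simulated study to disk as the pipeline's input formats.

    Emits a VCF 4.2 (diploid workers plus haploid control males, GT:DP), a
    colony map TSV, a trait TSV, a genetic-map TSV, a synthetic-gene GFF3
    and (optionally) the QTL truth TSV.  Round-trips losslessly through
    :func:`gestaltqtl.variants.read_vcf`.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    mm = haps.marker_map
    worker_ids = pedigree.workers["sample_id"].tolist()
    haploid_ids = [s for s in haps.sample_ids if haps.ploidy(s) == 1]
    sample_ids = worker_ids + haploid_ids
    n_loci = len(mm)
    depth = _simulate_depth((len(sample_ids), n_loci), rng, mean=depth_mean)

    paths = {}
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gestaltqtl.simdata\n")
        for chrom in mm["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j in range(n_loci):
            fields = [
                str(mm["chrom"].iloc[j]), str(int(mm["bp"].iloc[j])),
                str(mm["locus_id"].iloc[j]), "A", "T", ".", "PASS", ".", "GT:DP",
            ]
            for i, sid in enumerate(sample_ids):
                a = haps.alleles[sid][:, j]
                # haplotypes are simulated phased; write them that way
                gt = "|".join(str(int(x)) for x in a)
                fields.append(f"{gt}:{int(depth[i, j])}")
            fh.write("\t".join(fields) + "\n")
    paths["vcf"] = vcf_path

    colony_rows = [(sid, cid, 2) for sid, cid in
                   zip(pedigree.workers["sample_id"], pedigree.workers["colony_id"])]
    colony_rows += [(sid, "haploid_control", 1) for sid in haploid_ids]
    colonies = pd.DataFrame(colony_rows, columns=["sample_id", "colony_id", "ploidy"])
    paths["colonies"] = os.path.join(out_dir, "colonies.tsv")
    colonies.to_csv(paths["colonies"], sep="\t", index=False)

    paths["traits"] = os.path.join(out_dir, "traits.tsv")
    traits.to_csv(paths["traits"], sep="\t")

    paths["genetic_map"] = os.path.join(out_dir, "genetic_map.tsv")
    mm.to_csv(paths["genetic_map"], sep="\t", index=False)

    paths["gff"] = os.path.join(out_dir, "genes.gff3")
    _write_synthetic_genes(mm, paths["gff"])

    if qtl_truth is not None:
        paths["qtl_truth"] = os.path.join(out_dir, "qtl_truth.tsv")
        qtl_truth.to_csv(paths["qtl_truth"], sep="\t", index=False)
    return paths


def _write_synthetic_genes(marker_map: pd.DataFrame, path: str,
                           gene_length: int = 5_000, gap: int = 15_000) -> None:
    """Tile synthetic genes (with one exon each) along every chromosome."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g = 0
        for chrom, grp in marker_map.groupby("chrom", sort=False):
            end_bp = int(grp["bp"].max()) + gene_length + gap
            pos = 1
            strand_flip = False
            while pos + gene_length <= end_bp:
                g += 1
                strand = "-" if strand_flip else "+"
                strand_flip = not strand_flip
                gid = f"gene{g}"
                fh.write(
                    f"{chrom}\tsim\tgene\t{pos}\t{pos + gene_length - 1}\t.\t{strand}\t.\tID={gid};Name={gid}\n"
                )
                e_start = pos + gene_length // 4
                e_end = pos + gene_length // 2
                fh.write(
                    f"{chrom}\tsim\texon\t{e_start}\t{e_end}\t.\t{strand}\t.\tID={gid}.e1;Parent={gid}\n"
                )
                pos += gene_length + gap
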