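"""Genotype I/O and the SNP-catalog / sample filtering cascade.

Implements the full pre-association filtering pipeline for a ddRAD/WGS SNP
catalog of colony-sampled ants: biallelic-SNP restriction, sample
missingness passes, per-call depth masking with call-rate and MAF locus
filters, a blacklist around loci where haploid males appear heterozygous
(collapsed-repeat artifacts), an excess-coverage filter, the per-colony
call requirement, and colony-level genotypes (mean allele dosage = twice
the colony allele frequency).

Dosage codes the count of ALT alleles (0/1/2 diploid, 0/1 haploid);
missing calls are ``NaN``.  Coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenotypeMatrix",
    "ColonyGenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_colony_map",
    "drop_non_biallelic",
    "filter_samples_missingness",
    "filter_loci",
    "haploid_blacklist",
    "apply_blacklist",
    "excess_coverage_filter",
    "excess_coverage_threshold",
    "require_colony_calls",
    "colony_genotypes",
]


class VariantDataError(ValueError):
    pass


@dataclass
class FilterReport:
    """Per-stage accounting of removed loci and samples."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_loci: int, n_samples: int,
            loci_removed: int = 0, samples_removed: int = 0, **extra) -> None:
        rec = {
            "stage": stage,
            "loci_removed": int(loci_removed),
            "samples_removed": int(samples_removed),
            "n_loci": int(n_loci),
            "n_samples": int(n_samples),
        }
        rec.update(extra)
        self.stages.append(rec)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.stages, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class GenotypeMatrix:
    """Samples x loci allele-dosage calls with per-call read depth.

    ``dosage`` is float with NaN for missing; ``depth`` is float with NaN
    where the VCF carried no DP (treated as depth-pass).  ``loci`` carries
    locus_id/chrom/bp (+ ref/alt and, once a genetic map is attached, cM);
    ``samples`` carries sample_id/colony_id/ploidy.
    """

    dosage: np.ndarray
    depth: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame
    het: np.ndarray | None = None  # call carried two distinct alleles

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def subset(self, sample_mask=None, locus_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        lm = np.ones(self.n_loci, bool) if locus_mask is None else np.asarray(locus_mask)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(sm, lm)],
            depth=self.depth[np.ix_(sm, lm)],
            loci=self.loci.loc[lm].reset_index(drop=True),
            samples=self.samples.loc[sm].reset_index(drop=True),
            het=None if self.het is None else self.het[np.ix_(sm, lm)],
        )

    def missing_fraction_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def call_rate_per_locus(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """ALT allele frequency per locus from called dosages and ploidy."""
        ploidy = self.samples["ploidy"].to_numpy(float)[:, None]
        called = ~np.isnan(self.dosage)
        with np.errstate(invalid="ignore"):
            num = np.nansum(self.dosage, axis=0)
            den = (called * ploidy).sum(axis=0)
        return np.divide(num, den, out=np.full(self.n_loci, np.nan), where=den > 0)

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def attach_map(self, genetic_map: pd.DataFrame) -> "GenotypeMatrix":
        """Left-join cM positions onto ``loci`` by locus_id."""
        loci = self.loci.merge(
            genetic_map[["locus_id", "cM"]], on="locus_id", how="left"
        )
        return GenotypeMatrix(self.dosage, self.depth, loci, self.samples)


@dataclass
class ColonyGenotypeMatrix:
    """Colonies x loci mean dosage in [0, 2] -- twice the colony allele frequency."""

    mean_dosage: np.ndarray
    n_called: np.ndarray
    loci: pd.DataFrame
    colonies: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_dosage, index=self.colonies,
                            columns=self.loci["locus_id"])


def read_colony_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "colony_id": str})
    if "ploidy" not in df.columns:
        df["ploidy"] = 2
    return df


def read_vcf(path, colony_map) -> GenotypeMatrix:
    """Read GT (+ optional DP) calls from a VCF into a GenotypeMatrix.

    ``colony_map`` maps sample_id -> colony_id (DataFrame or TSV path; a
    ``ploidy`` column marks haploid control males).  Every VCF sample must
    appear in the map.  Dosage counts ALT alleles; any record that is not
    a biallelic SNP gets NaN dosages and is flagged in ``loci`` for
    :func:`drop_non_biallelic`.
    """
    if not isinstance(colony_map, pd.DataFrame):
        colony_map = read_colony_map(colony_map)
    cmap = colony_map.set_index("sample_id")
    vcf = pysam.VariantFile(str(path))
    vcf_samples = list(vcf.header.samples)
    unknown = [s for s in vcf_samples if s not in cmap.index]
    if unknown:
        raise VariantDataError(
            f"samples in VCF absent from colony map: {', '.join(unknown)}"
        )
    dosages, depths, hets, loci = [], [], [], []
    for rec in vcf:
        alts = rec.alts or ()
        is_snp = (
            len(alts) == 1
            and rec.ref is not None
            and len(rec.ref) == 1
            and len(alts[0]) == 1
            and alts[0] in "ACGT"
        )
        row_d = np.full(len(vcf_samples), np.nan)
        row_dp = np.full(len(vcf_samples), np.nan)
        row_het = np.zeros(len(vcf_samples), bool)
        for i, s in enumerate(vcf_samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if is_snp and gt is not None and all(a is not None for a in gt):
                row_d[i] = float(sum(gt))
                row_het[i] = len(set(gt)) > 1
            dp = call.get("DP")
            if dp is not None:
                row_dp[i] = float(dp)
        dosages.append(row_d)
        depths.append(row_dp)
        hets.append(row_het)
        loci.append(
            {
                "locus_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "bp": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(alts) if alts else ".",
                "biallelic_snp": is_snp,
            }
        )
    loci_df = pd.DataFrame(loci)
    if loci_df.duplicated(["chrom", "bp"]).any():
        raise VariantDataError("duplicate loci by (chrom, bp)")
    samples = pd.DataFrame(
        {
            "sample_id": vcf_samples,
            "colony_id": [cmap.loc[s, "colony_id"] for s in vcf_samples],
            "ploidy": [int(cmap.loc[s, "ploidy"]) for s in vcf_samples],
        }
    )
    return GenotypeMatrix(
        dosage=np.asarray(dosages).T.copy(),
        depth=np.asarray(depths).T.copy(),
        loci=loci_df,
        samples=samples,
        het=np.asarray(hets).T.copy(),
    )


def write_vcf(gm: GenotypeMatrix, path) -> str:
    """Write the (filtered) genotype matrix back out as an uncompressed VCF.

    Dosages are re-encoded as unphased GT (0/0, 0/1, 1/1 diploid; 0 or 1
    haploid; ./. missing) with DP where depth is known.
    """
    ploidy = gm.samples["ploidy"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=gestaltqtl.variants\n")
        for chrom in gm.loci["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples["sample_id"]) + "\n")
        for j in range(gm.n_loci):
            locus = gm.loci.iloc[j]
            fields = [str(locus["chrom"]), str(int(locus["bp"])),
                      str(locus["locus_id"]), str(locus.get("ref", "A")),
                      str(locus.get("alt", "T")), ".", "PASS", ".", "GT:DP"]
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                if np.isnan(d):
                    gt = "." if ploidy[i] == 1 else "./."
                elif ploidy[i] == 1:
                    gt = str(int(d))
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                dp = gm.depth[i, j]
                fields.append(f"{gt}:{int(dp)}" if not np.isnan(dp) else f"{gt}:.")
            fh.write("\t".join(fields) + "\n")
    return str(path)


def drop_non_biallelic(gm: GenotypeMatrix, report: FilterReport | None = None) -> GenotypeMatrix:
    """Keep only biallelic SNP records (drops indels and multi-allelic sites)."""
    if "biallelic_snp" in gm.loci.columns:
        keep = gm.loci["biallelic_snp"].to_numpy(bool)
    else:
        keep = np.ones(gm.n_loci, bool)
    out = gm.subset(locus_mask=keep)
    if report is not None:
        report.add("biallelic_snps", out.n_loci, out.n_samples,
                   loci_removed=int((~keep).sum()))
    return out


def filter_samples_missingness(gm: GenotypeMatrix, max_missing_fraction: float,
                               report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove samples whose missing-call fraction strictly exceeds the threshold.

    Run twice in the study cascade: at 0.5 on the raw biallelic catalog and
    at 0.6 after locus filtering.
    """
    if not (0.0 < max_missing_fraction < 1.0):
        raise VariantDataError("max_missing_fraction must be in (0, 1)")
    miss = gm.missing_fraction_per_sample()
    keep = miss <= max_missing_fraction
    if not keep.any():
        raise VariantDataError("all samples removed by missingness filter")
    out = gm.subset(sample_mask=keep)
    if report is not None:
        report.add(f"sample_missingness<={max_missing_fraction}", out.n_loci,
                   out.n_samples, samples_removed=int((~keep).sum()))
    return out


def filter_loci(gm: GenotypeMatrix, min_call_rate: float = 0.8, min_depth: int = 6,
                max_depth: int = 250, min_maf: float = 0.15,
                report: FilterReport | None = None) -> GenotypeMatrix:
    """Depth-mask calls, then drop loci by call rate and MAF.

    Calls with depth outside [min_depth, max_depth] are set missing first
    (calls without depth information pass); call rate and MAF are then
    computed from the surviving calls.  MAF = min(f, 1-f) with f the mean
    dosage over called alleles.
    """
    dosage = gm.dosage.copy()
    with np.errstate(invalid="ignore"):
        bad_depth = (gm.depth < min_depth) | (gm.depth > max_depth)
    dosage[bad_depth & ~np.isnan(gm.depth)] = np.nan
    masked = GenotypeMatrix(dosage, gm.depth, gm.loci, gm.samples)
    call_rate = masked.call_rate_per_locus()
    maf = masked.maf()
    keep = (call_rate >= min_call_rate) & (maf >= min_maf)
    out = masked.subset(locus_mask=keep)
    if report is not None:
        report.add(
            f"locus_callrate>={min_call_rate},maf>={min_maf},depth[{min_depth},{max_depth}]",
            out.n_loci, out.n_samples, loci_removed=int((~keep).sum()),
        )
    return out


def haploid_blacklist(haploid_gm: GenotypeMatrix, radius_bp: int = 600) -> pd.DataFrame:
    """Intervals around loci where a haploid male is called heterozygous.

    A heterozygous call in a haploid sample marks a collapsed repeat in the
    assembly; every locus within ``radius_bp`` (inclusive on both sides) of
    such a call is blacklisted.  Returns merged intervals
    (chrom, start, end), 1-based inclusive.
    """
    hap_mask = haploid_gm.samples["ploidy"].to_numpy() == 1
    if not hap_mask.any():
        warnings.warn("no haploid samples supplied; empty blacklist")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if haploid_gm.het is not None:
        het = haploid_gm.het[hap_mask].any(axis=0)
    else:
        # no call-level allele info: a dosage of 1 on a declared-haploid,
        # diploid-coded sample is the heterozygous artifact
        het = np.nansum(haploid_gm.dosage[hap_mask] == 1.0, axis=0) > 0
    hits = haploid_gm.loci.loc[het, ["chrom", "bp"]]
    intervals = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        start = end = None
        for bp in sorted(grp["bp"]):
            lo, hi = bp - radius_bp, bp + radius_bp
            if start is None:
                start, end = lo, hi
            elif lo <= end + 1:
                end = max(end, hi)
            else:
                intervals.append((chrom, max(start, 1), end))
                start, end = lo, hi
        if start is not None:
            intervals.append((chrom, max(start, 1), end))
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


def apply_blacklist(gm: GenotypeMatrix, blacklist: pd.DataFrame,
                    report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove loci falling inside blacklist intervals (inclusive bounds)."""
    keep = np.ones(gm.n_loci, bool)
    for _, iv in blacklist.iterrows():
        inside = (
            (gm.loci["chrom"] == iv["chrom"])
            & (gm.loci["bp"] >= iv["start"])
            & (gm.loci["bp"] <= iv["end"])
        )
        keep &= ~inside.to_numpy()
    out = gm.subset(locus_mask=keep)
    if report is not None:
        report.add("haploid_blacklist", out.n_loci, out.n_samples,
                   loci_removed=int((~keep).sum()))
    return out


def excess_coverage_threshold(gm: GenotypeMatrix) -> float:
    """Default excess-coverage cutoff: mean + 2 SD of per-locus mean depth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_locus = np.nanmean(gm.depth, axis=0)
    per_locus = per_locus[~np.isnan(per_locus)]
    if per_locus.size == 0:
        raise VariantDataError("no depth information available")
    return float(per_locus.mean() + 2.0 * per_locus.std())


def excess_coverage_filter(gm: GenotypeMatrix, max_mean_depth: float | None = None,
                           report: FilterReport | None = None) -> GenotypeMatrix:
    """Drop loci whose mean depth over called samples exceeds the cutoff.

    With ``max_mean_depth=None`` the cutoff is mean + 2 SD of the
    per-locus mean depth distribution.
    """
    called = ~np.isnan(gm.dosage)
    depth = np.where(called & ~np.isnan(gm.depth), gm.depth, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_depth = np.nanmean(depth, axis=0)
    if max_mean_depth is None:
        # default cutoff from the same distribution the rule tests
        valid = mean_depth[~np.isnan(mean_depth)]
        if valid.size == 0:
            raise VariantDataError("no depth information available")
        max_mean_depth = float(valid.mean() + 2.0 * valid.std())
    keep = ~(mean_depth > max_mean_depth)  # loci with no depth info pass
    out = gm.subset(locus_mask=keep)
    if report is not None:
        report.add("excess_coverage", out.n_loci, out.n_samples,
                   loci_removed=int((~keep).sum()), threshold=float(max_mean_depth))
    return out


def require_colony_calls(gm: GenotypeMatrix, min_per_colony: int = 3) -> np.ndarray:
    """Mask of loci with >= min_per_colony called genotypes in *every* colony."""
    diploid = gm.subset(sample_mask=gm.samples["ploidy"].to_numpy() == 2)
    colonies = diploid.samples["colony_id"]
    sizes = colonies.value_counts()
    too_small = sizes[sizes < min_per_colony]
    if len(too_small):
        raise VariantDataError(
            f"colonies with fewer than {min_per_colony} members: "
            + ", ".join(too_small.index.astype(str))
        )
    called = ~np.isnan(diploid.dosage)
    mask = np.ones(gm.n_loci, bool)
    for _, idx in colonies.groupby(colonies).groups.items():
        mask &= called[np.asarray(idx)].sum(axis=0) >= min_per_colony
    return mask


def colony_genotypes(gm: GenotypeMatrix, min_per_colony: int = 3) -> ColonyGenotypeMatrix:
    """Mean called dosage per colony per locus (= 2 x colony allele frequency).

    Cells with fewer than ``min_per_colony`` called members are missing.
    Haploid control samples are excluded.
    """
    diploid = gm.subset(sample_mask=gm.samples["ploidy"].to_numpy() == 2)
    colony_ids = sorted(diploid.samples["colony_id"].unique())
    mean = np.full((len(colony_ids), gm.n_loci), np.nan)
    n_called = np.zeros((len(colony_ids), gm.n_loci), int)
    for ci, cid in enumerate(colony_ids):
        rows = diploid.samples["colony_id"].to_numpy() == cid
        d = diploid.dosage[rows]
        cnt = (~np.isnan(d)).sum(axis=0)
        n_called[ci] = cnt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(d, axis=0)
        m[cnt < min_per_colony] = np.nan
        mean[ci] = m
    return ColonyGenotypeMatrix(mean_dosage=mean, n_called=n_called,
                                loci=gm.loci.copy(), colonies=colony_ids)
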