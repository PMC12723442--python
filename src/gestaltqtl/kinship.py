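"""Relatedness matrices and structure covariates.

The primary kinship definition is the total map length (cM) of
identity-by-descent haplotype segments shared between every pair of
samples, detected here by an exact-match segment scan on phased,
error-free haplotypes (suitable for simulated or externally phased data;
an error-tolerant HMM detector is deliberately out of scope).  A
VanRaden-style genomic relationship matrix (GRM) is the fallback when
phased haplotypes are unavailable, and SNP-space principal components
provide fixed population-structure covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "KinshipMatrix",
    "haplotypes_from_vcf",
    "ibd_segments",
    "ibd_kinship",
    "grm",
    "structure_pcs",
    "pedigree_kinship",
]


class KinshipError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    """Symmetric non-negative relatedness with its provenance tag."""

    values: np.ndarray
    ids: list
    method: str  # "ibd_length" | "ibd_length_scaled" | "grm" | "pedigree"
    normalization: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, method="external") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(float), ids=list(df.index), method=method)


def haplotypes_from_vcf(path, genetic_map: "pd.DataFrame"):
    """Build a phased HaplotypeSet from a VCF with phased genotypes.

    Requires every diploid call to be phased (``|`` separator) and every
    record to appear in the genetic map (locus_id -> chrom/bp/cM);
    unphased or missing calls raise, directing the caller to
    :func:`grm` instead.
    """
    import pysam

    from .simdata import HaplotypeSet

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    by_locus = genetic_map.set_index("locus_id")
    alleles = {s: [] for s in samples}
    kept = []
    for rec in vcf:
        lid = rec.id or f"{rec.chrom}:{rec.pos}"
        if lid not in by_locus.index:
            continue
        kept.append(lid)
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                raise KinshipError(f"missing call for {s} at {lid}: use grm() instead")
            if len(gt) > 1 and not call.phased:
                raise KinshipError(f"unphased call for {s} at {lid}: use grm() instead")
            alleles[s].append(tuple(int(a) for a in gt))
    if not kept:
        raise KinshipError("no VCF records matched the genetic map")
    mm = by_locus.loc[kept].reset_index()
    mm = mm.sort_values(["chrom", "bp"], kind="mergesort").reset_index(drop=True)
    order = [kept.index(l) for l in mm["locus_id"]]
    out_alleles = {}
    for s in samples:
        arr = np.asarray(alleles[s], dtype=np.int8)[order]
        out_alleles[s] = arr.T.copy()  # (ploidy, n_loci)
    origins = {s: np.full_like(a, -1, dtype=np.int16) for s, a in out_alleles.items()}
    return HaplotypeSet(alleles=out_alleles, origins=origins, marker_map=mm)


def _runs_of_identity(eq: np.ndarray):
    """(start, end) index pairs of maximal True runs (end inclusive)."""
    if not eq.any():
        return []
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts, ends))


def ibd_segments(haps, min_length_cM: float = 1.0, include_self: bool = False) -> pd.DataFrame:
    """Exact-match shared-haplotype segments between all sample pairs.

    For every pair of haplotypes from distinct samples, maximal runs of
    identical alleles whose cM span is at least ``min_length_cM`` are
    reported once.  Requires phased input.
    """
    if not getattr(haps, "phased", True):
        raise KinshipError("unphased haplotypes: use grm() instead")
    mm = haps.marker_map
    chrom_codes, chroms = pd.factorize(mm["chrom"])
    cM = mm["cM"].to_numpy(float)
    ids = haps.sample_ids
    records = []
    for i in range(len(ids)):
        for j in range(i, len(ids)):
            if i == j and not include_self:
                continue
            hi, hj = haps.alleles[ids[i]], haps.alleles[ids[j]]
            for a in range(hi.shape[0]):
                for b in range(hj.shape[0]):
                    eq = hi[a] == hj[b]
                    for c in range(len(chroms)):
                        sel = chrom_codes == c
                        idx = np.flatnonzero(sel)
                        for s, e in _runs_of_identity(eq[sel]):
                            start_cM = cM[idx[s]]
                            end_cM = cM[idx[e]]
                            length = end_cM - start_cM
                            if length >= min_length_cM:
                                records.append(
                                    (ids[i], ids[j], a, b, chroms[c],
                                     float(start_cM), float(end_cM), float(length))
                                )
    return pd.DataFrame(
        records,
        columns=["sample_i", "sample_j", "hap_i", "hap_j", "chrom",
                 "start_cM", "end_cM", "length_cM"],
    )


def ibd_kinship(segments: pd.DataFrame, sample_ids, total_map_cM: float,
                scaled: bool = False) -> KinshipMatrix:
    """Kinship as total shared IBD segment length per sample pair.

    Entry (i, j) sums segment lengths over all haplotype pairings of the
    two samples; the diagonal is fixed at 2 x total map length (a sample
    shares both its haplotypes with itself).  With ``scaled=True`` the
    matrix is divided by the total map length so clones and self score 2
    and full sisters about 1.5.
    """
    ids = list(sample_ids)
    pos = {s: k for k, s in enumerate(ids)}
    K = np.zeros((len(ids), len(ids)))
    for _, seg in segments.iterrows():
        i, j = pos.get(seg["sample_i"]), pos.get(seg["sample_j"])
        if i is None or j is None or i == j:
            continue
        K[i, j] += seg["length_cM"]
        K[j, i] += seg["length_cM"]
    np.fill_diagonal(K, 2.0 * total_map_cM)
    method = "ibd_length"
    if scaled:
        K = K / total_map_cM
        method = "ibd_length_scaled"
    return KinshipMatrix(values=K, ids=ids, method=method)


def grm(dosage, sample_ids=None) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from an allele-dosage matrix.

    Accepts a samples x loci array/DataFrame with values in [0, 2]
    (individual dosages or colony mean dosages); missing cells are
    mean-imputed per locus.  K = Z Z' / sum 2 f (1 - f) with Z the
    frequency-centered dosages.
    """
    if isinstance(dosage, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(dosage.index)
        dosage = dosage.to_numpy(float)
    X = np.array(dosage, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise KinshipError("need at least 2 samples and 2 loci")
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    poly = X.std(axis=0) > 1e-12
    if not poly.any():
        raise KinshipError("all loci are monomorphic")
    f = X.mean(axis=0) / 2.0
    X = X[:, poly]
    f = np.clip(f[poly], 1e-12, 1 - 1e-12)
    Z = X - 2.0 * f
    denom = float(np.sum(2.0 * f * (1.0 - f)))
    K = Z @ Z.T / denom
    ids = list(sample_ids) if sample_ids is not None else list(range(X.shape[0]))
    return KinshipMatrix(values=K, ids=ids, method="grm")


def structure_pcs(dosage, n_components: int, sample_ids=None) -> pd.DataFrame:
    """Top principal components of the (mean-imputed, centered) dosage matrix.

    Used as fixed covariates for population structure in the mixed model.
    """
    if isinstance(dosage, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(dosage.index)
        dosage = dosage.to_numpy(float)
    X = np.array(dosage, dtype=float)
    if n_components >= X.shape[0]:
        raise KinshipError("n_components must be < number of samples")
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    pca = PCA(n_components=n_components, svd_solver="full")  # deterministic
    scores = pca.fit_transform(X)
    idx = sample_ids if sample_ids is not None else range(X.shape[0])
    return pd.DataFrame(
        scores, index=idx, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


def pedigree_kinship(pedigree) -> KinshipMatrix:
    """Expected haplodiploid relatedness from the known pedigree.

    Full sisters 0.75, maternal half sisters 0.25, unrelated between
    colonies, 1 on the diagonal.  The mixed model uses kinship only up to
    a positive scalar, so this is directly usable as K.
    """
    r, ids = pedigree.relatedness_matrix()
    return KinshipMatrix(values=r, ids=ids, method="pedigree")
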