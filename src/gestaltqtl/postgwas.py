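"""Post-GWAS reporting: hit tables, QTL clusters, uniformity, gene hits.

Turns per-locus association results into the study's reported structures:
cumulative significant-hit counts at several q-value thresholds, QTL
clusters chained within a cM gap on each linkage group, a one-sample
Kolmogorov-Smirnov test of QTL positions against genome-wide uniformity,
strand-aware SNP-to-gene assignment (gene body or 2000 bp upstream of the
start), and Manhattan / Q-Q plot tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "threshold_hits",
    "cluster_qtls",
    "QtlCluster",
    "ks_uniform",
    "gene_hits",
    "plot_tables",
    "save_figures",
]


class PostGwasError(ValueError):
    pass


def threshold_hits(results: pd.DataFrame,
                   q_thresholds=(0.05, 0.1, 0.2, 0.3)):
    """Significant hits and cumulative per-trait counts at each q threshold.

    ``results`` needs columns q and trait (plus any locus metadata, which
    is carried through).  A hit at q < 0.05 also counts at every looser
    threshold, matching the cumulative columns of the study's hit tables.
    Returns ``(hits, counts)`` where hits is the q < max(thresholds)
    subset and counts is a trait x threshold table.
    """
    q_thresholds = tuple(sorted(q_thresholds))
    q = results["q"].to_numpy(float)
    hits = results.loc[q < max(q_thresholds)].copy()
    traits = sorted(results["trait"].unique()) if "trait" in results else ["all"]
    counts = pd.DataFrame(0, index=traits, columns=list(q_thresholds))
    for thr in q_thresholds:
        sub = results.loc[q < thr]
        if "trait" in results:
            c = sub.groupby("trait").size()
            counts.loc[c.index, thr] = c.to_numpy()
        else:
            counts.loc["all", thr] = len(sub)
    return hits, counts


@dataclass
class QtlCluster:
    chrom: str
    members: pd.DataFrame = field(repr=False)
    span_cM: float = 0.0
    levels: tuple = ()

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_qtls(hits: pd.DataFrame, gap_cM: float = 12.0) -> list[QtlCluster]:
    """Single-linkage chaining of hits within ``gap_cM`` on each linkage group.

    Hits are sorted by cM per chromosome and split where adjacent
    positions differ by more than the gap; only clusters of two or more
    hits are reported.  Hits without a cM position are excluded with a
    warning.  The result is invariant to input order.
    """
    if gap_cM <= 0:
        raise PostGwasError("gap_cM must be positive")
    mapped = hits.dropna(subset=["cM"])
    if len(mapped) < len(hits):
        warnings.warn(f"{len(hits) - len(mapped)} unmapped hits excluded from clustering")
    clusters = []
    for chrom, grp in mapped.groupby("chrom", sort=True):
        grp = grp.sort_values(["cM", "locus_id"] if "locus_id" in grp else "cM")
        cm = grp["cM"].to_numpy(float)
        breaks = np.flatnonzero(np.diff(cm) > gap_cM) + 1
        for part in np.split(np.arange(len(grp)), breaks):
            if part.size >= 2:
                members = grp.iloc[part]
                levels = (
                    tuple(sorted(members["level"].unique()))
                    if "level" in members
                    else ()
                )
                clusters.append(
                    QtlCluster(
                        chrom=chrom,
                        members=members.reset_index(drop=True),
                        span_cM=float(cm[part[-1]] - cm[part[0]]),
                        levels=levels,
                    )
                )
    return clusters


def ks_uniform(hits: pd.DataFrame, genetic_map: pd.DataFrame):
    """One-sample KS test of hit positions against genome-wide uniformity.

    Positions are mapped to cumulative genome-wide cM (prefix sums of
    per-linkage-group map lengths) and rescaled to [0, 1]; the statistic
    is the standard one-sample KS D in [0, 1] against U(0, 1).
    """
    mapped = hits.dropna(subset=["cM"])
    if len(mapped) < 3:
        raise PostGwasError("need at least 3 mapped hits")
    lengths = genetic_map.groupby("chrom", sort=True)["cM"].max()
    offsets = lengths.cumsum().shift(fill_value=0.0)
    total = float(lengths.sum())
    pos = mapped["cM"].to_numpy(float) + mapped["chrom"].map(offsets).to_numpy(float)
    u = pos / total
    res = stats.kstest(u, "uniform")
    return float(res.statistic), float(res.pvalue)


def _parse_gff_genes(gff_path):
    """Gene and exon intervals from a GFF3 file via gffutils.

    Malformed records (wrong field count, non-numeric coordinates) are
    dropped with a warning before the database is built.
    """
    import gffutils

    good_lines = []
    with open(gff_path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or not (parts[3].isdigit() and parts[4].isdigit()):
                warnings.warn(f"skipping malformed GFF record at line {line_no}")
                continue
            good_lines.append(line)
    db = gffutils.create_db(
        "".join(good_lines), dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes, exons = [], []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", feat.attributes.get("Name", [feat.id]))[0]
        genes.append((feat.seqid, feat.start, feat.end, feat.strand, gid))
    for feat in db.features_of_type("exon"):
        parent = feat.attributes.get("Parent", [""])[0]
        exons.append((feat.seqid, feat.start, feat.end, parent))
    genes = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"])
    exons = pd.DataFrame(exons, columns=["chrom", "start", "end", "gene_id"])
    return genes, exons


def gene_hits(hits: pd.DataFrame, gff_path, upstream_bp: int = 2000) -> pd.DataFrame:
    """Assign each hit to candidate genes.

    A gene is a candidate if the hit lies inside the gene body or within
    ``upstream_bp`` bp 5' of the gene start (strand-aware: the window is
    [start - upstream_bp, start - 1] on the plus strand and
    [end + 1, end + upstream_bp] on the minus strand, inclusive).  Hits
    inside an exon of the gene are flagged ``in_exon``.  Returns one row
    per (hit, gene) pair; hits with no gene get gene_id NaN.
    """
    genes, exons = _parse_gff_genes(gff_path)
    rows = []
    for _, hit in hits.iterrows():
        chrom, bp = hit["chrom"], int(hit["bp"])
        g = genes[genes["chrom"] == chrom]
        in_body = (g["start"] <= bp) & (bp <= g["end"])
        plus_up = (g["strand"] == "+") & (g["start"] - upstream_bp <= bp) & (bp <= g["start"] - 1)
        minus_up = (g["strand"] == "-") & (g["end"] + 1 <= bp) & (bp <= g["end"] + upstream_bp)
        matched = g[in_body | plus_up | minus_up]
        if matched.empty:
            row = dict(hit)
            row.update({"gene_id": np.nan, "relation": np.nan, "in_exon": False})
            rows.append(row)
            continue
        for _, gene in matched.iterrows():
            body = gene["start"] <= bp <= gene["end"]
            ex = exons[
                (exons["gene_id"] == gene["gene_id"])
                & (exons["start"] <= bp)
                & (bp <= exons["end"])
            ]
            row = dict(hit)
            row.update(
                {
                    "gene_id": gene["gene_id"],
                    "relation": "body" if body else "upstream",
                    "in_exon": bool(len(ex)),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def plot_tables(results: pd.DataFrame, fdr_lines=(0.1, 0.3)):
    """Manhattan and Q-Q plot data from a per-locus result table.

    Manhattan: cumulative genome coordinate (prefix sums of per-chromosome
    spans, cM if available else bp) and -log10 p, plus the p-value
    threshold line per requested FDR level (largest p with q below the
    level; NaN when nothing passes).  Q-Q: expected quantiles
    -log10((i - 0.5)/n) against sorted observed -log10 p.
    """
    res = results.dropna(subset=["p"]).copy()
    coord_col = "cM" if "cM" in res.columns and res["cM"].notna().all() else "bp"
    spans = res.groupby("chrom", sort=True)[coord_col].max()
    offsets = spans.cumsum().shift(fill_value=0.0)
    manhattan = pd.DataFrame(
        {
            "chrom": res["chrom"],
            "coord": res[coord_col] + res["chrom"].map(offsets),
            "neglog10p": -np.log10(res["p"]),
        }
    ).reset_index(drop=True)
    lines = {}
    if "q" in res.columns:
        for level in fdr_lines:
            passing = res.loc[res["q"] < level, "p"]
            lines[level] = float(-np.log10(passing.max())) if len(passing) else np.nan
    p_sorted = np.sort(res["p"].to_numpy(float))
    n = p_sorted.size
    # rank-paired: smallest p against smallest expected quantile
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
            "observed": -np.log10(p_sorted),
        }
    )
    return manhattan, lines, qq


def save_figures(results: pd.DataFrame, manhattan_path, qq_path,
                 fdr_lines=(0.1, 0.3)):
    """Render Manhattan and Q-Q figures from a result table (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manhattan, lines, qq = plot_tables(results, fdr_lines=fdr_lines)
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, (_, grp) in enumerate(manhattan.groupby("chrom", sort=True)):
        ax.scatter(grp["coord"], grp["neglog10p"], s=4,
                   color="C0" if i % 2 == 0 else "C1")
    styles = {0.1: ("purple", ":"), 0.3: ("red", ":")}
    for level, yline in lines.items():
        if np.isfinite(yline):
            color, ls = styles.get(level, ("grey", "--"))
            ax.axhline(yline, color=color, linestyle=ls, linewidth=1,
                       label=f"FDR {int(level * 100)}%")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    if lines:
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(manhattan_path, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(qq["expected"], qq["observed"], ".", markersize=3)
    lim = max(qq["expected"].max(), qq["observed"].max())
    ax.plot([0, lim], [0, lim], "k--", linewidth=1)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(qq_path, dpi=150)
    plt.close(fig)
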