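"""Context-resolved DNA-methylation summaries from bisulfite calls.

Levels are unweighted means over covered cytosine sites (each retained
site counts once); a ``weighted=True`` variant pools raw read counts
instead.  The default ``min_coverage`` of 1 suits the desk-scale
simulated fixtures; real WGBS practice typically requires >= 3-5 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import squareform

from .core import CONTEXTS, GenomeAnnotation, MethylationCallSet

_H = set("ATC")


def classify_cytosine_context(trinucleotide: str) -> str:
    """CG* -> CpG; C[ACT]G -> CHG; C[ACT][ACT] -> CHH (H = A, T or C)."""
    tri = trinucleotide.upper()
    if len(tri) != 3 or set(tri) - set("ACGT"):
        raise ValueError(f"trinucleotide must be 3 letters over ACGT, got {trinucleotide!r}")
    if tri[0] != "C":
        raise ValueError(f"trinucleotide must start with C, got {trinucleotide!r}")
    if tri[1] == "G":
        return "CpG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


@dataclass
class SiteLevelTable:
    """Per-site methylation levels for one sample.

    ``table`` columns: chrom, pos, context, coverage, level.
    """

    table: pd.DataFrame
    n_dropped: int
    sample_id: str = "sample"
    genotype: str = "WT"

    def __post_init__(self) -> None:
        lv = self.table["level"]
        if ((lv < 0) | (lv > 1)).any():
            raise ValueError("levels must lie in [0, 1]")

    def restrict(self, chroms: set[str] | Sequence[str]) -> "SiteLevelTable":
        chroms = set(chroms)
        sub = self.table[self.table["chrom"].isin(chroms)].reset_index(drop=True)
        return SiteLevelTable(sub, 0, self.sample_id, self.genotype)


def site_levels(calls: MethylationCallSet, min_coverage: int = 1) -> SiteLevelTable:
    """Per-site level = methylated / coverage; low-coverage sites dropped."""
    rec = calls.records
    cov = rec["methylated"] + rec["unmethylated"]
    keep = cov >= min_coverage
    out = pd.DataFrame(
        {
            "chrom": rec.loc[keep, "chrom"].to_numpy(),
            "pos": rec.loc[keep, "pos"].to_numpy(),
            "context": rec.loc[keep, "context"].to_numpy(),
            "coverage": cov[keep].to_numpy(),
            "level": (rec.loc[keep, "methylated"] / cov[keep]).to_numpy(),
        }
    )
    return SiteLevelTable(out, int((~keep).sum()), calls.sample_id, calls.genotype)


def global_levels_by_context(sites: SiteLevelTable) -> pd.DataFrame:
    """Mean and quartile summary per context; absent contexts are omitted."""
    if sites.table.empty:
        raise ValueError("empty site table")
    rows = {}
    for ctx, grp in sites.table.groupby("context"):
        lv = grp["level"]
        rows[ctx] = {
            "n": len(lv),
            "mean": lv.mean(),
            "q25": lv.quantile(0.25),
            "median": lv.median(),
            "q75": lv.quantile(0.75),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "context"
    return df.reindex([c for c in CONTEXTS if c in df.index])


def _merged_starts_ends(intervals) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return np.array([]), np.array([])
    arr = np.array(merged)
    return arr[:, 0], arr[:, 1]


def _in_intervals(table: pd.DataFrame, intervals) -> np.ndarray:
    """Boolean mask: site position inside any interval (per chromosome)."""
    mask = np.zeros(len(table), dtype=bool)
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    pos = table["pos"].to_numpy()
    chroms = table["chrom"].to_numpy()
    for chrom, ivs in by_chrom.items():
        starts, ends = _merged_starts_ends(ivs)
        sel = chroms == chrom
        if not sel.any() or len(starts) == 0:
            continue
        p = pos[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel)[inside]] = True
    return mask


def aggregate_by_element(
    sites: SiteLevelTable,
    annotation: GenomeAnnotation,
    promoter_flank: int = 2000,
    weighted: bool = False,
) -> pd.DataFrame:
    """Mean CpG level per genome-element class.

    Element classes: promoter, gene_body, CGI, repeat, ICR, intergenic.
    A site may contribute to several classes; intergenic collects sites
    falling in no other class.  Classes the annotation does not provide
    (e.g. UTR/exon subdivision on the toy annotation) are simply absent.
    """
    cpg = sites.table[sites.table["context"] == "CpG"]
    element_intervals = {
        "promoter": [
            g.promoter(promoter_flank, annotation.chrom_sizes[g.chrom])
            for g in annotation.genes
        ],
        "gene_body": [g.body for g in annotation.genes],
        "CGI": annotation.cgis,
        "repeat": annotation.repeats,
        "ICR": annotation.icrs,
    }
    rows = {}
    in_any = np.zeros(len(cpg), dtype=bool)
    for element, ivs in element_intervals.items():
        if not ivs:
            continue
        mask = _in_intervals(cpg, ivs)
        in_any |= mask
        rows[element] = _level_summary(cpg[mask], weighted)
    rows["intergenic"] = _level_summary(cpg[~in_any], weighted)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "element"
    return df


def _level_summary(sub: pd.DataFrame, weighted: bool) -> dict:
    if sub.empty:
        return {"n_sites": 0, "mean_level": np.nan}
    if weighted:
        w = sub["coverage"].to_numpy(dtype=float)
        mean = float(np.average(sub["level"], weights=w))
    else:
        mean = float(sub["level"].mean())
    return {"n_sites": len(sub), "mean_level": mean}


def icr_levels(
    sites: SiteLevelTable, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ICR mean CpG level plus maternal/paternal group summaries.

    ICRs with no covered CpG are reported with NaN mean (missing), not 0.
    """
    if not annotation.icrs:
        raise ValueError("annotation has no ICRs")
    cpg = sites.table[sites.table["context"] == "CpG"]
    rows = []
    for iv in annotation.icrs:
        sel = cpg[
            (cpg["chrom"] == iv.chrom) & (cpg["pos"] >= iv.start) & (cpg["pos"] < iv.end)
        ]
        rows.append(
            {
                "icr_id": iv.name,
                "parent": annotation.icr_parent.get(iv.name or "", "unknown"),
                "n_sites": len(sel),
                "mean_level": sel["level"].mean() if len(sel) else np.nan,
            }
        )
    per_icr = pd.DataFrame(rows).set_index("icr_id")
    groups = (
        per_icr.dropna(subset=["mean_level"])
        .groupby("parent")["mean_level"]
        .agg(["count", "mean", "median", "min", "max"])
    )
    return per_icr, groups


def conversion_efficiency(sites: SiteLevelTable, lambda_chrom: str = "chrL") -> float:
    """Bisulfite conversion rate from the unmethylated spike chromosome.

    1 − pooled methylated-call fraction over all contexts on the spike.
    """
    sub = sites.table[sites.table["chrom"] == lambda_chrom]
    if sub.empty:
        raise ValueError(f"no covered cytosines on spike chromosome {lambda_chrom!r}")
    total = float(sub["coverage"].sum())
    methylated = float((sub["level"] * sub["coverage"]).sum())
    return 1.0 - methylated / total


@dataclass
class ClusteringResult:
    samples: list[str]
    linkage: np.ndarray
    distance: pd.DataFrame
    labels: dict[str, int] = field(default_factory=dict)  # k=2 flat cut
    newick: str = ""
    n_shared_sites: int = 0


def cluster_samples_by_cpg(
    site_tables: Mapping[str, SiteLevelTable],
    min_coverage: int = 1,
    min_shared_sites: int = 100,
) -> ClusteringResult:
    """Average-linkage hierarchical clustering on 1 − Pearson over shared CpGs."""
    if len(site_tables) < 2:
        raise ValueError("need >= 2 samples to cluster")
    samples = list(site_tables)
    levels = {}
    for name, st in site_tables.items():
        t = st.table
        sub = t[(t["context"] == "CpG") & (t["coverage"] >= min_coverage)]
        s = pd.Series(
            sub["level"].to_numpy(),
            index=pd.MultiIndex.from_arrays([sub["chrom"], sub["pos"]]),
        )
        levels[name] = s[~s.index.duplicated()]
    shared = None
    for s in levels.values():
        shared = s.index if shared is None else shared.intersection(s.index)
    if shared is None or len(shared) < min_shared_sites:
        raise ValueError(
            f"too few shared CpG sites ({0 if shared is None else len(shared)} "
            f"< {min_shared_sites})"
        )
    mat = np.vstack([levels[s].loc[shared].to_numpy() for s in samples])
    sds = mat.std(axis=1)
    flat = [samples[i] for i in np.flatnonzero(sds == 0)]
    if flat:
        raise ValueError(f"undefined correlation: zero-variance sample(s) {flat}")
    corr = np.corrcoef(mat)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = average(squareform(dist, checks=False))
    labels = {s: int(c) for s, c in zip(samples, fcluster(z, t=2, criterion="maxclust"))}
    return ClusteringResult(
        samples=samples,
        linkage=z,
        distance=pd.DataFrame(dist, index=samples, columns=samples),
        labels=labels,
        newick=_linkage_to_newick(z, samples),
        n_shared_sites=len(shared),
    )


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        bl_l = node.dist - node.left.dist
        bl_r = node.dist - node.right.dist
        return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

    return walk(tree) + ";"
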