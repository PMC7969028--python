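"""Histone-mark signal quantification over bins, peaks and promoters.

RPKM here is reads per kilobase of feature per million mapped reads,
where the feature length is the bin, peak or promoter size.  A read is
assigned to every feature containing its *midpoint*, which makes counts
additive over non-overlapping tilings of the genome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomeAnnotation, GenomicInterval, ReadSet, SignalMatrix


@dataclass
class FilterReport:
    n_in: int
    n_retained: int
    n_excluded: int
    min_rpkm: float


@dataclass
class ProfileMatrix:
    """Anchor-relative signal profiles (minus-strand anchors flipped).

    ``offsets`` are the left edges of the offset bins; ``values`` is an
    anchors × offsets grid, ``aggregate`` the per-offset mean over anchors.
    """

    anchors: list[tuple[str, int, str]]
    offsets: np.ndarray
    values: np.ndarray
    aggregate: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_signal": self.aggregate}
        )


def make_bins(annotation: GenomeAnnotation, bin_size: int) -> list[GenomicInterval]:
    """Tile every chromosome from 0 in ``bin_size`` steps (last bin truncated)."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    bins = []
    for chrom, length in annotation.chrom_sizes.items():
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            bins.append(GenomicInterval(chrom, start, end, ".", f"{chrom}:{start}-{end}"))
    return bins


def promoters_from_genes(
    genes: Sequence, flank: int = 2000, chrom_sizes: Mapping[str, int] | None = None
) -> list[GenomicInterval]:
    """±flank windows around annotated TSSs, labelled by gene id."""
    out = []
    for g in genes:
        length = chrom_sizes.get(g.chrom) if chrom_sizes else None
        out.append(g.promoter(flank, length))
    return out


def _overlapping(starts: np.ndarray, ends: np.ndarray) -> bool:
    return bool(np.any(ends[:-1] > starts[1:]))


def count_midpoints(readset: ReadSet, features: Sequence[GenomicInterval]) -> np.ndarray:
    """Number of read midpoints falling in each feature.

    Uses a sorted searchsorted pass per chromosome for non-overlapping
    feature sets and an interval tree otherwise (each read counted in
    every containing feature).
    """
    counts = np.zeros(len(features), dtype=np.int64)
    feats_by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, f in enumerate(features):
        feats_by_chrom[f.chrom].append(i)
    reads = readset.reads
    for chrom, idxs in feats_by_chrom.items():
        sub = reads[reads["chrom"] == chrom]
        if sub.empty:
            continue
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        order = sorted(idxs, key=lambda i: features[i].start)
        starts = np.array([features[i].start for i in order])
        ends = np.array([features[i].end for i in order])
        if not _overlapping(starts, ends):
            pos = np.searchsorted(starts, mids, side="right") - 1
            ok = (pos >= 0) & (mids < ends[np.clip(pos, 0, None)])
            hit, n = np.unique(pos[ok], return_counts=True)
            for h, c in zip(hit, n):
                counts[order[h]] += c
        else:
            tree = IntervalTree()
            for i in idxs:
                tree.addi(features[i].start, features[i].end, i)
            for m in mids:
                for h in tree.at(int(m)):
                    counts[h.data] += 1
    return counts


def rpkm(readset: ReadSet, features: Sequence[GenomicInterval]) -> pd.Series:
    """RPKM per feature: count / (feature kb × mapped-read millions)."""
    if readset.total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    lengths = np.array([f.length for f in features], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("feature lengths must be > 0")
    counts = count_midpoints(readset, features)
    values = counts / (lengths / 1e3) / (readset.total_mapped / 1e6)
    index = [f.name or f"{f.chrom}:{f.start}-{f.end}" for f in features]
    return pd.Series(values, index=index, name=readset.sample_id)


def signal_matrix(
    readsets: Sequence[ReadSet], features: Sequence[GenomicInterval]
) -> SignalMatrix:
    """RPKM matrix over one feature set for several samples."""
    cols = {rs.sample_id: rpkm(rs, features) for rs in readsets}
    values = pd.DataFrame(cols)
    ids = list(values.index)
    feat = [(fid, f) for fid, f in zip(ids, features)]
    return SignalMatrix(feat, values, "rpkm")


def filter_low_quality_peaks(
    peaks: Sequence[GenomicInterval],
    rpkm_values: Sequence[float] | pd.Series,
    min_rpkm: float = 2.0,
) -> tuple[list[GenomicInterval], FilterReport]:
    """Drop peaks with RPKM below ``min_rpkm`` (RPKM == min_rpkm is retained)."""
    vals = np.asarray(rpkm_values, dtype=float)
    if len(vals) != len(peaks):
        raise ValueError("need exactly one RPKM value per peak")
    keep = vals >= min_rpkm
    retained = [p for p, k in zip(peaks, keep) if k]
    report = FilterReport(len(peaks), int(keep.sum()), int((~keep).sum()), min_rpkm)
    return retained, report


def zscore_standardize(matrix: SignalMatrix, axis: str = "feature") -> SignalMatrix:
    """Standardize rows (axis='feature') or columns (axis='sample').

    Population SD is used; zero-SD rows/columns map to all zeros.
    """
    if matrix.value_kind != "rpkm":
        raise ValueError("zscore_standardize expects an rpkm matrix")
    if axis not in ("feature", "sample"):
        raise ValueError("axis must be 'feature' or 'sample'")
    arr = matrix.values.to_numpy(dtype=float)
    ax = 1 if axis == "feature" else 0
    mean = arr.mean(axis=ax, keepdims=True)
    sd = arr.std(axis=ax, keepdims=True)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    values = pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    return SignalMatrix(matrix.features, values, "zscore", zscore_axis=axis)


def peak_genomic_distribution(
    peaks: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    tss_flank: int = 2000,
    tes_flank: int = 2000,
) -> pd.Series:
    """Fractions of peaks at TSSs, TESs, gene bodies and intergenic space.

    Each peak is assigned once, by midpoint, with precedence
    TSS > TES > gene body > intergenic; fractions sum to 1.
    """
    counts = {"TSS": 0, "TES": 0, "gene_body": 0, "intergenic": 0}
    tss_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    tes_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    body_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in annotation.genes:
        length = annotation.chrom_sizes[g.chrom]
        tss_tree[g.chrom].addi(max(0, g.tss - tss_flank), min(length, g.tss + tss_flank), g.gene_id)
        tes_tree[g.chrom].addi(max(0, g.tes - tes_flank), min(length, g.tes + tes_flank), g.gene_id)
        body_tree[g.chrom].addi(g.body.start, g.body.end, g.gene_id)
    for p in peaks:
        mid = p.midpoint
        if tss_tree[p.chrom].at(mid):
            counts["TSS"] += 1
        elif tes_tree[p.chrom].at(mid):
            counts["TES"] += 1
        elif body_tree[p.chrom].at(mid):
            counts["gene_body"] += 1
        else:
            counts["intergenic"] += 1
    total = max(1, len(peaks))
    return pd.Series({k: v / total for k, v in counts.items()}, name="fraction")


def average_profile(
    readset: ReadSet,
    anchors: Sequence[tuple[str, int, str]],
    window: int = 2000,
    step: int = 100,
) -> ProfileMatrix:
    """Anchor-centred RPKM-scaled coverage profile from read midpoints.

    ``anchors`` are (id, position, strand) triples; minus-strand anchors
    are orientation-flipped so positive offsets are always downstream.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    if (2 * window) % step != 0:
        raise ValueError("step must divide 2*window")
    n_bins = 2 * window // step
    offsets = np.arange(-window, window, step)
    values = np.zeros((len(anchors), n_bins))
    reads_by_chrom = {
        chrom: ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        for chrom, sub in readset.reads.groupby("chrom")
    }
    anchor_chrom = _anchor_chroms(anchors, readset)
    scale = (step / 1e3) * (readset.total_mapped / 1e6)
    for ai, (aid, pos, strand) in enumerate(anchors):
        chrom = anchor_chrom[ai]
        mids = reads_by_chrom.get(chrom)
        if mids is None:
            continue
        rel = (mids - pos) if strand != "-" else (pos - mids)
        idx = (rel + window) // step
        ok = (idx >= 0) & (idx < n_bins)
        if ok.any():
            binc = np.bincount(idx[ok].astype(int), minlength=n_bins)
            values[ai] = binc / scale
    return ProfileMatrix(list(anchors), offsets, values, values.mean(axis=0))


def _anchor_chroms(anchors: Sequence[tuple[str, int, str]], readset: ReadSet) -> list[str]:
    """Anchor ids are 'chrom:pos' strings or gene ids carried with a chrom prefix.

    The pipeline passes anchors whose id embeds the chromosome as
    'chrom|label'; a bare id falls back to treating the id's prefix
    before ':' or '|' as the chromosome.
    """
    chroms = []
    for aid, _, _ in anchors:
        if "|" in aid:
            chroms.append(aid.split("|", 1)[0])
        elif ":" in aid:
            chroms.append(aid.split(":", 1)[0])
        else:
            raise ValueError(
                f"anchor id {aid!r} must encode its chromosome as 'chrom|label'"
            )
    return chroms


def gene_anchors(genes: Sequence, which: str = "tss") -> list[tuple[str, int, str]]:
    """Build (chrom|gene_id, position, strand) anchor triples from gene models."""
    out = []
    for g in genes:
        pos = g.tss if which == "tss" else g.tes
        out.append((f"{g.chrom}|{g.gene_id}", pos, g.strand))
    return out
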