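"""Domain types and file I/O for the analysis pipeline.

All coordinates are 0-based, half-open (BED convention) throughout the
package; ``length == end - start`` always holds.  Chromosome names are
opaque strings — no "chr" prefix normalisation is attempted.

The types here are the coordinate currency shared by every stage:
intervals, gene models, read sets, signal matrices, methylation call
sets and expression tables.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MARKS = ("H3K4me3", "H3K27me3", "H2AK119ub1", "H3K36me3")
GENOTYPES = ("WT", "KO")
#: short tokens used for promoter-state sets
MARK_TOKENS = {"H3K4me3": "K4", "H3K27me3": "K27", "H2AK119ub1": "ub"}
STRANDS = ("+", "-", ".")
CONTEXTS = ("CpG", "CHG", "CHH")


class FormatError(ValueError):
    """Raised for malformed input files (carries line numbers where known)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic region; ``strand`` is '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start for {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene body; TSS/TES are derived from strand, never stored."""

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unstranded genes are rejected "
                "(TSS undefined without orientation)"
            )

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tes(self) -> int:
        return self.body.end - 1 if self.strand == "+" else self.body.start

    def promoter(self, flank: int = 2000, chrom_length: int | None = None) -> GenomicInterval:
        """±flank window around the TSS, clipped to chromosome bounds."""
        start = max(0, self.tss - flank)
        end = self.tss + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end, self.strand, self.gene_id)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models and labelled region sets."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)
    icrs: list[GenomicInterval] = field(default_factory=list)
    icr_parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            self._check_fits(g.body, f"gene {g.gene_id}")
        icr_names: set[str] = set()
        for group, regions in (("CGI", self.cgis), ("repeat", self.repeats), ("ICR", self.icrs)):
            for iv in regions:
                self._check_fits(iv, f"{group} {iv.name or ''}")
        for iv in self.icrs:
            if iv.name in icr_names:
                raise ValueError(f"duplicate ICR id {iv.name}")
            icr_names.add(iv.name)
        for icr_id, parent in self.icr_parent.items():
            if parent not in ("maternal", "paternal"):
                raise ValueError(f"ICR {icr_id}: parent must be maternal/paternal")

    def _check_fits(self, iv: GenomicInterval, what: str) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"{what}: chromosome {iv.chrom} not in chrom_sizes")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"{what}: {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {self.chrom_sizes[iv.chrom]}"
            )

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class ReadSet:
    """Aligned-read surrogates for one ChIP sample.

    ``reads`` is a DataFrame with columns chrom/start/end sorted by
    (chrom, start).  ``total_mapped`` may exceed the number of retained
    reads: when only a genomic window is represented, it records the
    genome-wide mapped-read count that RPKM normalises against.
    """

    sample_id: str
    mark: str
    genotype: str
    reads: pd.DataFrame
    total_mapped: int

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.total_mapped < len(self.reads):
            raise ValueError("total_mapped < number of retained reads")
        self.reads = (
            self.reads[["chrom", "start", "end"]]
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[GenomicInterval],
        sample_id: str,
        mark: str,
        genotype: str,
        total_mapped: int,
    ) -> "ReadSet":
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end) for iv in intervals],
            columns=["chrom", "start", "end"],
        )
        return cls(sample_id, mark, genotype, df, total_mapped)

    @classmethod
    def from_bed(
        cls, path: str | Path, sample_id: str, mark: str, genotype: str, total_mapped: int
    ) -> "ReadSet":
        # fast vectorised path for plain BED; falls back to the tolerant
        # line-by-line reader on anything unusual
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, usecols=[0, 1, 2],
                names=["chrom", "start", "end"], dtype={0: str, 1: np.int64, 2: np.int64},
            )
            if (df["end"] <= df["start"]).any() or (df["start"] < 0).any():
                raise FormatError(f"{path}: end <= start or negative start")
        except (ValueError, pd.errors.ParserError):
            return cls.from_intervals(read_bed(path), sample_id, mark, genotype, total_mapped)
        return cls(sample_id, mark, genotype, df, total_mapped)


@dataclass
class SignalMatrix:
    """features × samples grid of RPKM (or z-score) values.

    ``values`` is indexed by feature id with one column per sample.
    """

    features: list[tuple[str, GenomicInterval]]
    values: pd.DataFrame
    value_kind: str = "rpkm"
    zscore_axis: str | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in ("rpkm", "zscore"):
            raise ValueError(f"value_kind must be rpkm or zscore, got {self.value_kind}")
        ids = [fid for fid, _ in self.features]
        if list(self.values.index) != ids:
            raise ValueError("values index does not match feature list")
        if self.value_kind == "rpkm":
            if (self.values.to_numpy() < 0).any():
                raise ValueError("RPKM values must be non-negative")
            if self.zscore_axis is not None:
                raise ValueError("rpkm matrix cannot record a zscore axis")
        elif self.zscore_axis not in ("feature", "sample"):
            raise ValueError("zscore matrix must record which axis was standardized")

    @property
    def feature_lengths(self) -> pd.Series:
        return pd.Series(
            {fid: iv.length for fid, iv in self.features}, name="length"
        ).reindex(self.values.index)


@dataclass
class MethylationCallSet:
    """Per-cytosine counts with context labels for one WGBS sample."""

    records: pd.DataFrame  # chrom, pos, context, methylated, unmethylated
    sample_id: str
    genotype: str
    dropped_zero_coverage: int = 0

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "context", "methylated", "unmethylated"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        rec = self.records
        if (rec["pos"] < 0).any():
            raise ValueError("negative position")
        if (rec[["methylated", "unmethylated"]].to_numpy() < 0).any():
            raise ValueError("negative counts")
        bad = set(rec["context"].unique()) - set(CONTEXTS)
        if bad:
            raise FormatError(f"unknown context {sorted(bad)}")
        if ((rec["methylated"] + rec["unmethylated"]) < 1).any():
            raise ValueError("retained records must have coverage >= 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (file order, 0-based half-open).

    track/browser/comment lines are tolerated; column 4 is kept as the
    interval name and column 6 as the strand when present.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}: line {lineno}: end <= start")
            if start < 0:
                raise FormatError(f"{path}: line {lineno}: negative start")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 else "."
            if strand not in STRANDS:
                raise FormatError(f"{path}: line {lineno}: invalid strand {strand!r}")
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (BED3 columns padded with name/score/strand)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_methylation_coverage(
    path: str | Path,
    sample_id: str = "sample",
    genotype: str = "WT",
    one_based: bool = False,
) -> MethylationCallSet:
    """Read a Bismark-coverage-style table.

    Columns (with header): chrom, pos, context, methylated, unmethylated.
    Positions in this dialect are 0-based; pass ``one_based=True`` for
    files in Bismark's native 1-based form (converted on load).  Records
    with zero total coverage are dropped and counted in
    ``dropped_zero_coverage``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = ["chrom", "pos", "context", "methylated", "unmethylated"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = set(df["context"].unique()) - set(CONTEXTS)
    if bad:
        raise FormatError(f"{path}: unknown context {sorted(bad)}")
    if one_based:
        df["pos"] = df["pos"] - 1
    cov = df["methylated"] + df["unmethylated"]
    dropped = int((cov == 0).sum())
    df = df[cov > 0].reset_index(drop=True)
    return MethylationCallSet(df[req], sample_id, genotype, dropped)


def write_methylation_coverage(calls: MethylationCallSet, path: str | Path) -> None:
    calls.records.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a tab-separated gene table with header gene_id/chrom/start/end/strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(str(row.gene_id), GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand))
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.body.start, g.body.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_fpkm_table(path: str | Path) -> pd.DataFrame:
    """Gene × sample FPKM matrix (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: FPKM values must be >= 0")
    return df


def write_fpkm_table(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_bedgraph(values: pd.Series, features: Sequence[GenomicInterval], path: str | Path) -> None:
    """Export per-feature signal as bedGraph (feature order preserved)."""
    with open(path, "w") as fh:
        for iv, v in zip(features, values.to_numpy()):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# interval assignment
# ---------------------------------------------------------------------------


def _subject_trees(subjects: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, iv in enumerate(subjects):
        trees[iv.chrom].addi(iv.start, iv.end, idx)
    return trees


def overlap_assign(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
    mode: str = "any",
) -> list[str | None]:
    """Assign each query to the label (``name``) of one subject, or None.

    Modes: ``any`` (any overlap), ``midpoint`` (subject containing the
    query midpoint, half-open), ``max_overlap`` (largest overlap length).
    Ties (and multiple hits in any/midpoint mode) break deterministically
    by earliest subject start, then lexicographic label.
    """
    if mode not in ("any", "midpoint", "max_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    trees = _subject_trees(subjects)

    def key(idx: int) -> tuple[int, str]:
        s = subjects[idx]
        return (s.start, s.name or "")

    out: list[str | None] = []
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is None:
            out.append(None)
            continue
        if mode == "midpoint":
            hits = [h.data for h in tree.at(q.midpoint)]
        else:
            hits = [h.data for h in tree.overlap(q.start, q.end)]
        if not hits:
            out.append(None)
            continue
        if mode == "max_overlap":
            best = max(
                hits,
                key=lambda i: (q.overlap_length(subjects[i]), -key(i)[0]),
            )
            # resolve exact ties on overlap length explicitly
            best_len = q.overlap_length(subjects[best])
            tied = [i for i in hits if q.overlap_length(subjects[i]) == best_len]
            best = min(tied, key=key)
            out.append(subjects[best].name)
        else:
            out.append(subjects[min(hits, key=key)].name)
    return out
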