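"""Synthetic two-genotype multi-omic data with planted ground truth.

The generator emulates the statistical structure of a WT-vs-knockout
oocyte epigenome study: four histone marks (H3K4me3, H3K27me3,
H2AK119ub1, H3K36me3) as ChIP read sets, CpG methylomes with
hyper/hypomethylated domains anticorrelated with Polycomb-mark gain,
and expression coupled to promoter H3K4me3/H3K27me3.  Every planted
assignment is recorded in a :class:`GroundTruth` so downstream
classification stages have a known-answer oracle.

The toy genome is a window of a few megabases cut from a notional
genome of ``effective_genome_size`` (default 1 Gb): reads are emitted
only inside the window, while ``total_mapped`` records the genome-wide
count the window depth implies.  This pins the absolute RPKM scale —
background well below 1, enriched features in the single digits —
in the regime where fixed RPKM thresholds are meaningful, independent
of the window size chosen for a run.

Couplings are explicit configuration, not hard-coded, so tests can
switch them off and verify the pipeline does not invent correlations:

* ``couple_methylation`` — Polycomb-gain bin classes (I–III) sit in
  WT-hypermethylated domains and lose methylation in the KO; loss
  classes (IV–VI) sit in hypomethylated domains and gain slightly.
* ``couple_expression`` — expression follows promoter state (K27
  dominant-repressive) and genes inside K27-gain bins are repressed in
  the KO.
* ``couple_k36`` — H3K36me3 is enriched over the bodies of expressed
  genes, per genotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    GENOTYPES,
    MARK_TOKENS,
    MARKS,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    MethylationCallSet,
    ReadSet,
    sha256_of,
    write_bed,
    write_chrom_sizes,
    write_fpkm_table,
    write_gene_table,
    write_methylation_coverage,
)
from .integrate import state_string

_TOKEN_TO_MARK = {v: k for k, v in MARK_TOKENS.items()}


def _default_state_frequencies() -> dict[str, float]:
    return {
        "none": 0.25,
        "K4": 0.30,
        "K27": 0.10,
        "ub": 0.06,
        "K4+K27": 0.12,
        "K4+ub": 0.08,
        "K27+ub": 0.04,
        "K4+K27+ub": 0.05,
    }


def _default_bin_class_frequencies() -> dict[str, float]:
    return {
        "unchanged": 0.52,
        "I": 0.08,
        "II": 0.08,
        "III": 0.08,
        "IV": 0.08,
        "V": 0.08,
        "VI": 0.08,
    }


def _default_fpkm_by_state() -> dict[str, float]:
    # K27-containing states are repressed; K4-only is the most active.
    return {
        "K4": 25.0,
        "K4+ub": 12.0,
        "ub": 4.0,
        "none": 0.3,
        "K4+K27": 0.8,
        "K27": 0.5,
        "K27+ub": 0.4,
        "K4+K27+ub": 0.7,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 500
    gene_length: int = 8_000
    bin_size: int = 10_000
    promoter_flank: int = 2_000
    reads_per_sample: int = 200_000
    read_length: int = 150
    #: the toy chromosomes are a window of a notional genome this large;
    #: total_mapped = reads_per_sample * effective_genome_size / window size,
    #: which pins the absolute RPKM scale regardless of toy-genome size
    effective_genome_size: float = 1.0e9
    enrichment_fold: float = 8.0
    state_frequencies: dict[str, float] = field(default_factory=_default_state_frequencies)
    bin_class_frequencies: dict[str, float] = field(default_factory=_default_bin_class_frequencies)
    # methylation landscape
    domain_size: int = 200_000
    methylation_high: float = 0.8
    methylation_low: float = 0.1
    methylation_ko_delta: float = 0.5
    methylation_ko_gain: float = 0.1
    cgi_fraction: float = 0.5
    cgi_halfwidth: int = 500
    cgi_level: float = 0.05
    n_repeats: int = 30
    repeat_length: int = 1_000
    n_icrs: int = 8
    icr_length: int = 2_000
    icr_maternal_level: float = 0.85
    icr_paternal_level: float = 0.05
    icr_ko_delta: float = 0.3
    # WGBS sampling
    site_spacing: int = 100
    frac_cpg: float = 0.8
    frac_chg: float = 0.1
    frac_chh: float = 0.1
    coverage: float = 30.0
    non_cpg_level: float = 0.01
    lambda_chrom: str = "chrL"
    lambda_length: int = 48_500
    lambda_n_sites: int = 2_000
    conversion_efficiency_true: float = 0.995
    # expression
    fpkm_by_state: dict[str, float] = field(default_factory=_default_fpkm_by_state)
    de_fraction: float = 0.25
    de_effect_fold: float = 4.0
    dispersion: float = 0.1
    k36_fpkm_min: float = 5.0
    bin_repression_factor: float = 0.5
    bin_activation_factor: float = 1.5
    n_meth_replicates: int = 2
    # coupling switches
    couple_methylation: bool = True
    couple_expression: bool = True
    couple_k36: bool = True

    def __post_init__(self) -> None:
        for name, freqs in (
            ("state_frequencies", self.state_frequencies),
            ("bin_class_frequencies", self.bin_class_frequencies),
        ):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in freqs.values()):
                raise ValueError(f"{name} must be non-negative")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if not (0 <= self.methylation_low < self.methylation_high <= 1):
            raise ValueError("need 0 <= methylation_low < methylation_high <= 1")
        if abs(self.frac_cpg + self.frac_chg + self.frac_chh - 1.0) > 1e-9:
            raise ValueError("context fractions must sum to 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted per-feature assignments used as the acceptance oracle."""

    promoter_state: pd.Series  # gene_id -> state string
    bin_class: pd.Series  # bin_id -> class (I..VI / unchanged)
    domains: pd.DataFrame  # chrom, start, end, kind, wt_mean
    bin_methylation: pd.DataFrame  # bin_id -> wt_mean, ko_mean
    expression_effect: pd.DataFrame  # gene_id -> wt_mean, ko_mean, de_planted


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def methylation_domains(config: SimulationConfig, chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Alternating hyper/hypomethylated blocks tiled over the real chromosomes."""
    rows = []
    for chrom, length in chrom_sizes.items():
        if chrom == config.lambda_chrom:
            continue
        kind = "hyper"
        for start in range(0, length, config.domain_size):
            end = min(start + config.domain_size, length)
            mean = config.methylation_high if kind == "hyper" else config.methylation_low
            rows.append({"chrom": chrom, "start": start, "end": end, "kind": kind, "wt_mean": mean})
            kind = "hypo" if kind == "hyper" else "hyper"
    return pd.DataFrame(rows)


def build_toy_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Toy annotation: tiled genes on alternating strands, CGIs, repeats, ICRs.

    One extra chromosome (``lambda_chrom``) carries only the unmethylated
    conversion spike and no genes.
    """
    if config.chrom_length < 50 * config.bin_size:
        raise ValueError("chrom_length must be >= 50 * bin_size")
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    per_chrom = _split_counts(config.n_genes, config.n_chroms)
    min_cell = config.gene_length + 2 * config.promoter_flank + 2_000
    rng = _rng(config, 0)
    genes: list[GeneModel] = []
    gid = 0
    width = max(4, len(str(config.n_genes)))
    for ci, (chrom, n_here) in enumerate(zip(chrom_sizes, per_chrom)):
        if n_here == 0:
            continue
        cell = config.chrom_length // n_here
        if cell < min_cell:
            raise ValueError(
                f"{config.n_genes} genes do not fit: need chromosome length >= "
                f"{min_cell * n_here} (cell {cell} < minimum {min_cell})"
            )
        for i in range(n_here):
            gid += 1
            strand = "+" if (gid % 2) else "-"
            body_start = i * cell + (cell - config.gene_length) // 2
            body = GenomicInterval(
                chrom, body_start, body_start + config.gene_length, strand
            )
            genes.append(GeneModel(f"g{gid:0{width}d}", body))
    # CGIs at a configurable fraction of promoters
    n_cgi = int(round(config.cgi_fraction * len(genes)))
    cgi_gene_idx = rng.choice(len(genes), size=n_cgi, replace=False) if n_cgi else []
    cgis = []
    for i in sorted(cgi_gene_idx):
        g = genes[i]
        start = max(0, g.tss - config.cgi_halfwidth)
        end = min(chrom_sizes[g.chrom], g.tss + config.cgi_halfwidth)
        cgis.append(GenomicInterval(g.chrom, start, end, ".", f"cgi_{g.gene_id}"))
    # repeats scattered uniformly
    repeats = []
    real_chroms = list(chrom_sizes)
    for ri in range(config.n_repeats):
        chrom = real_chroms[int(rng.integers(len(real_chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - config.repeat_length))
        repeats.append(
            GenomicInterval(chrom, start, start + config.repeat_length, ".", f"rep{ri + 1:03d}")
        )
    # ICRs centred in successive hypermethylated domains
    domains = methylation_domains(config, chrom_sizes)
    hyper = domains[domains["kind"] == "hyper"].reset_index(drop=True)
    if len(hyper) < config.n_icrs:
        raise ValueError("not enough hypermethylated domains for the requested ICRs")
    icrs, icr_parent = [], {}
    picks = np.linspace(0, len(hyper) - 1, config.n_icrs).round().astype(int)
    for j, di in enumerate(picks):
        d = hyper.iloc[di]
        mid = (int(d.start) + int(d.end)) // 2
        iv = GenomicInterval(
            d.chrom, mid - config.icr_length // 2, mid + config.icr_length // 2, ".", f"icr{j + 1:02d}"
        )
        icrs.append(iv)
        icr_parent[iv.name] = "maternal" if j % 2 == 0 else "paternal"
    chrom_sizes[config.lambda_chrom] = config.lambda_length
    return GenomeAnnotation(chrom_sizes, genes, cgis, repeats, icrs, icr_parent)


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total % parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def plant_truth(config: SimulationConfig, annotation: GenomeAnnotation) -> GroundTruth:
    """Draw promoter states, bin classes and expression effects.

    Bin classes are planted only in bins that do not intersect any
    promoter (so promoter-state and bin-class signal stay separable) and,
    when methylation coupling is on, gain classes I–III only inside
    WT-hypermethylated domains and loss classes IV–VI only inside
    hypomethylated domains.
    """
    from .chip import make_bins, promoters_from_genes  # local import avoids cycle

    rng = _rng(config, 1)
    genes = annotation.genes
    # --- promoter states, K4-states preferentially at CGI promoters
    state_names = list(config.state_frequencies)
    probs = np.array([config.state_frequencies[s] for s in state_names])
    drawn = rng.choice(len(state_names), size=len(genes), p=probs)
    drawn_states = [state_names[i] for i in drawn]
    cgi_genes = {iv.name.removeprefix("cgi_") for iv in annotation.cgis if iv.name}
    k4_states = [s for s in drawn_states if "K4" in s.split("+")]
    other_states = [s for s in drawn_states if "K4" not in s.split("+")]
    order = [g.gene_id for g in genes]
    cgi_first = sorted(order, key=lambda g: (g not in cgi_genes, g))
    rng.shuffle(k4_states)
    rng.shuffle(other_states)
    assigned = {}
    for g in cgi_first:
        assigned[g] = k4_states.pop() if k4_states else other_states.pop()
    promoter_state = pd.Series({g: assigned[g] for g in order}, name="state")

    # --- bin classes
    bins = make_bins(annotation, config.bin_size)
    bins = [b for b in bins if b.chrom != config.lambda_chrom]
    promoters = promoters_from_genes(genes, config.promoter_flank, annotation.chrom_sizes)
    prom_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in promoters:
        prom_by_chrom.setdefault(p.chrom, []).append(p)
    domains = methylation_domains(config, annotation.chrom_sizes)
    dom_by_chrom = {c: g.sort_values("start") for c, g in domains.groupby("chrom")}

    def overlaps_promoter(b: GenomicInterval) -> bool:
        return any(b.overlap_length(p) > 0 for p in prom_by_chrom.get(b.chrom, []))

    def domain_kind(b: GenomicInterval) -> str:
        d = dom_by_chrom[b.chrom]
        idx = d["start"].searchsorted(b.midpoint, side="right") - 1
        return d.iloc[int(idx)]["kind"]

    class_names = list(config.bin_class_frequencies)
    bin_class = {}
    gain = {"I", "II", "III"}
    loss = {"IV", "V", "VI"}
    feasible_cache: dict[str, tuple[list[str], np.ndarray]] = {}
    any_hyper = (domains["kind"] == "hyper").any()
    for b in bins:
        if overlaps_promoter(b):
            bin_class[b.name] = "unchanged"
            continue
        if config.couple_methylation:
            kind = domain_kind(b)
            allowed = {"unchanged"} | (gain if kind == "hyper" else loss)
        else:
            kind = "any"
            allowed = set(class_names)
        if kind not in feasible_cache:
            names = [c for c in class_names if c in allowed]
            p = np.array([config.bin_class_frequencies[c] for c in names])
            if p.sum() == 0:
                names, p = ["unchanged"], np.array([1.0])
            feasible_cache[kind] = (names, p / p.sum())
        names, p = feasible_cache[kind]
        bin_class[b.name] = names[int(rng.choice(len(names), p=p))]
    bin_class = pd.Series(bin_class, name="bin_class")
    if config.couple_methylation and not any_hyper and (set(bin_class) & gain):
        raise ValueError("infeasible coupling: no hypermethylated domain available")

    # --- per-bin planted methylation means
    bm_rows = {}
    for b in bins:
        d = dom_by_chrom[b.chrom]
        idx = int(d["start"].searchsorted(b.midpoint, side="right")) - 1
        wt = float(d.iloc[idx]["wt_mean"])
        ko = wt
        if config.couple_methylation:
            cls = bin_class[b.name]
            if cls in gain:
                ko = max(0.0, wt - config.methylation_ko_delta)
            elif cls in loss:
                ko = min(1.0, wt + config.methylation_ko_gain)
        bm_rows[b.name] = {"wt_mean": wt, "ko_mean": ko}
    bin_methylation = pd.DataFrame.from_dict(bm_rows, orient="index")
    bin_methylation.index.name = "bin_id"

    # --- expression effects
    expr_rows = {}
    k4_only_genes = [g for g in order if promoter_state[g] == "K4"]
    n_de = int(round(config.de_fraction * len(k4_only_genes)))
    de_set = set(
        rng.choice(k4_only_genes, size=n_de, replace=False)
    ) if (n_de and config.couple_expression) else set()
    gene_bin = {}
    bins_by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in bins:
        bins_by_chrom.setdefault(b.chrom, []).append(b)
    for g in genes:
        bs = bins_by_chrom.get(g.chrom, [])
        starts = np.array([b.start for b in bs])
        i = int(np.searchsorted(starts, g.body.midpoint, side="right")) - 1
        gene_bin[g.gene_id] = bs[i].name if (0 <= i < len(bs) and g.body.midpoint < bs[i].end) else None
    for g in order:
        if config.couple_expression:
            wt = config.fpkm_by_state[promoter_state[g]]
        else:
            wt = float(np.mean(list(config.fpkm_by_state.values())))
        ko = wt
        if g in de_set:
            ko = wt / config.de_effect_fold
        if config.couple_expression and gene_bin[g] is not None:
            cls = bin_class.get(gene_bin[g], "unchanged")
            if cls in ("I", "II"):
                ko *= config.bin_repression_factor
            elif cls in ("IV", "V"):
                ko *= config.bin_activation_factor
        expr_rows[g] = {"wt_mean": wt, "ko_mean": ko, "de_planted": g in de_set}
    expression_effect = pd.DataFrame.from_dict(expr_rows, orient="index")
    expression_effect.index.name = "gene_id"

    return GroundTruth(promoter_state, bin_class, domains, bin_methylation, expression_effect)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _enriched_regions(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    mark: str,
    genotype: str,
    config: SimulationConfig,
) -> list[GenomicInterval]:
    """Regions where the truth places ``mark`` for ``genotype``."""
    from .chip import promoters_from_genes

    token = MARK_TOKENS.get(mark)
    regions: list[GenomicInterval] = []
    genes_by_id = annotation.genes_by_id
    if token is not None:  # promoter component for K4/K27/ub
        for gene_id, state in truth.promoter_state.items():
            if token in state.split("+"):
                g = genes_by_id[gene_id]
                regions.append(g.promoter(config.promoter_flank, annotation.chrom_sizes[g.chrom]))
    # bin component for the Polycomb marks
    bin_classes_for = {
        "H3K27me3": {"WT": {"IV", "V"}, "KO": {"I", "II"}},
        "H2AK119ub1": {"WT": {"V", "VI"}, "KO": {"II", "III"}},
    }
    if mark in bin_classes_for:
        wanted = bin_classes_for[mark][genotype]
        for bin_id, cls in truth.bin_class.items():
            if cls in wanted:
                chrom, span = bin_id.split(":")
                start, end = map(int, span.split("-"))
                regions.append(GenomicInterval(chrom, start, end, ".", bin_id))
    if mark == "H3K36me3" and config.couple_k36:
        col = "wt_mean" if genotype == "WT" else "ko_mean"
        expressed = truth.expression_effect.index[
            truth.expression_effect[col] >= config.k36_fpkm_min
        ]
        regions.extend(genes_by_id[g].body for g in expressed)
    return regions


def simulate_chip_reads(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    mark: str,
    genotype: str,
    config: SimulationConfig,
) -> ReadSet:
    """Fixed-length reads from uniform background + fold-weighted enrichment.

    Sampling weight is proportional to 1 everywhere on the real
    chromosomes plus (fold − 1) extra on enriched regions; with
    ``enrichment_fold == 1`` the density is exactly uniform.  The read
    count is Poisson-jittered around ``reads_per_sample``.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    rng = _rng(config, 2, MARKS.index(mark), GENOTYPES.index(genotype))
    real_chroms = [c for c in annotation.chrom_sizes if c != config.lambda_chrom]
    segments = [
        (c, 0, annotation.chrom_sizes[c], 1.0) for c in real_chroms
    ]
    for iv in _enriched_regions(truth, annotation, mark, genotype, config):
        extra = config.enrichment_fold - 1.0
        if extra > 0:
            segments.append((iv.chrom, iv.start, iv.end, extra))
    weights = np.array([(e - s) * w for _, s, e, w in segments], dtype=float)
    probs = weights / weights.sum()
    n = int(rng.poisson(config.reads_per_sample))
    seg_idx = rng.choice(len(segments), size=n, p=probs)
    offsets = rng.random(n)
    rows = {"chrom": [], "start": [], "end": []}
    seg_chrom = np.array([s[0] for s in segments])
    seg_start = np.array([s[1] for s in segments])
    seg_len = np.array([s[2] - s[1] for s in segments])
    starts = (seg_start[seg_idx] + offsets * seg_len[seg_idx]).astype(np.int64)
    chroms = seg_chrom[seg_idx]
    chrom_len = np.array([annotation.chrom_sizes[c] for c in chroms])
    ends = np.minimum(starts + config.read_length, chrom_len)
    starts = np.minimum(starts, ends - 1)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    window = sum(annotation.chrom_sizes[c] for c in real_chroms)
    scale = max(1.0, config.effective_genome_size / window)
    return ReadSet(
        sample_id=f"{mark}_{genotype}",
        mark=mark,
        genotype=genotype,
        reads=df,
        total_mapped=int(round(config.reads_per_sample * scale)),
    )


# ---------------------------------------------------------------------------
# WGBS simulation
# ---------------------------------------------------------------------------


def _site_layout(config: SimulationConfig, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Fixed site grid with contexts; shared by all samples of one config."""
    rng = _rng(config, 3)
    rows = []
    for chrom, length in annotation.chrom_sizes.items():
        if chrom == config.lambda_chrom:
            pos = np.linspace(0, length - 1, config.lambda_n_sites).astype(np.int64)
        else:
            pos = np.arange(0, length, config.site_spacing, dtype=np.int64)
        ctx = rng.choice(
            np.array(["CpG", "CHG", "CHH"]),
            size=len(pos),
            p=[config.frac_cpg, config.frac_chg, config.frac_chh],
        )
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "context": ctx}))
    return pd.concat(rows, ignore_index=True)


def _site_means(
    layout: pd.DataFrame,
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    genotype: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Planted methylation probability per site for one genotype."""
    p = np.full(len(layout), config.non_cpg_level)
    chroms = layout["chrom"].to_numpy()
    pos = layout["pos"].to_numpy()
    ctx = layout["context"].to_numpy()
    is_lambda = chroms == config.lambda_chrom
    p[is_lambda] = 1.0 - config.conversion_efficiency_true
    col = "wt_mean" if genotype == "WT" else "ko_mean"
    cpg = (ctx == "CpG") & ~is_lambda
    # per-bin means (domain mean, possibly class-shifted) cover every real-chrom bin
    bm = truth.bin_methylation[col]
    for chrom in np.unique(chroms[cpg]):
        sel = cpg & (chroms == chrom)
        bin_start = (pos[sel] // config.bin_size) * config.bin_size
        bin_end = np.minimum(bin_start + config.bin_size, annotation.chrom_sizes[chrom])
        ids = [f"{chrom}:{s}-{e}" for s, e in zip(bin_start, bin_end)]
        p[sel] = bm.reindex(ids).to_numpy()
    # CGI promoters stay hypomethylated in both genotypes
    for iv in annotation.cgis:
        sel = cpg & (chroms == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        p[sel] = config.cgi_level
    # ICRs: parent-of-origin levels; maternal ICRs lose methylation in the KO
    for iv in annotation.icrs:
        parent = annotation.icr_parent.get(iv.name or "", "maternal")
        level = (
            config.icr_maternal_level if parent == "maternal" else config.icr_paternal_level
        )
        if genotype == "KO" and parent == "maternal" and config.couple_methylation:
            level = max(0.0, level - config.icr_ko_delta)
        sel = cpg & (chroms == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        p[sel] = level
    return np.clip(p, 0.0, 1.0)


def simulate_wgbs(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    genotype: str,
    config: SimulationConfig,
    replicate: int = 0,
) -> MethylationCallSet:
    """Binomial methylation calls on a fixed site grid.

    Coverage is Poisson around ``config.coverage``; zero-coverage sites
    are kept in the emitted records (the reader drops and counts them).
    """
    layout = _site_layout(config, annotation)
    p = _site_means(layout, truth, annotation, genotype, config)
    rng = _rng(config, 4, GENOTYPES.index(genotype), replicate)
    cov = rng.poisson(config.coverage, size=len(layout))
    meth = rng.binomial(cov, p)
    records = pd.DataFrame(
        {
            "chrom": layout["chrom"],
            "pos": layout["pos"],
            "context": layout["context"],
            "methylated": meth,
            "unmethylated": cov - meth,
        }
    )
    nonzero = cov > 0
    callset = MethylationCallSet(
        records[nonzero].reset_index(drop=True),
        sample_id=f"{genotype}_rep{replicate + 1}",
        genotype=genotype,
        dropped_zero_coverage=int((~nonzero).sum()),
    )
    # keep zero-coverage rows for the on-disk file so the reader exercise is real
    callset.records_with_zeros = records  # type: ignore[attr-defined]
    return callset


def simulate_expression(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """FPKM table (genes × WT/KO), log-normal around the planted means.

    Mean-preserving parameterisation: FPKM = mean · exp(N(−σ²/2, σ)),
    so dispersion 0 returns the planted means exactly.
    """
    rng = _rng(config, 5)
    eff = truth.expression_effect
    sigma = config.dispersion
    out = {}
    for col, name in (("wt_mean", "WT"), ("ko_mean", "KO")):
        means = eff[col].to_numpy(dtype=float)
        if sigma == 0:
            vals = means
        else:
            vals = means * np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(means)))
        out[name] = vals
    return pd.DataFrame(out, index=eff.index)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig):
    """Run the full generator: annotation, truth, reads, methylomes, expression."""
    annotation = build_toy_genome(config)
    truth = plant_truth(config, annotation)
    readsets = [
        simulate_chip_reads(truth, annotation, mark, genotype, config)
        for mark in MARKS
        for genotype in GENOTYPES
    ]
    callsets = [
        simulate_wgbs(truth, annotation, genotype, config, replicate=r)
        for genotype in GENOTYPES
        for r in range(config.n_meth_replicates)
    ]
    expression = simulate_expression(truth, config)
    return annotation, truth, readsets, callsets, expression


def write_fixture_bundle(
    outdir: str | Path,
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    readsets: list[ReadSet],
    callsets: list[MethylationCallSet],
    expression: pd.DataFrame,
) -> Path:
    """Write every simulated object in the formats the pipeline reads.

    Returns the manifest path; the manifest lists every file with a
    sha256 checksum, so identical seeds give identical checksums.
    """
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"parent of output directory missing: {outdir.parent}")
    for sub in ("annotation", "reads", "peaks", "methylation", "expression", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    files: list[Path] = []

    def emit(path: Path) -> Path:
        files.append(path)
        return path

    ann = outdir / "annotation"
    write_chrom_sizes(annotation.chrom_sizes, emit(ann / "chrom_sizes.tsv"))
    write_gene_table(annotation.genes, emit(ann / "genes.tsv"))
    write_bed(annotation.cgis, emit(ann / "cgis.bed"))
    write_bed(annotation.repeats, emit(ann / "repeats.bed"))
    write_bed(annotation.icrs, emit(ann / "icrs.bed"))
    pd.Series(annotation.icr_parent, name="parent").rename_axis("icr_id").to_csv(
        emit(ann / "icr_parents.tsv"), sep="\t"
    )

    sample_rows = []
    for rs in readsets:
        path = outdir / "reads" / f"{rs.sample_id}.bed"
        ivs = (
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in rs.reads.itertuples(index=False)
        )
        write_bed(ivs, emit(path))
        sample_rows.append(
            {
                "sample_id": rs.sample_id,
                "mark": rs.mark,
                "genotype": rs.genotype,
                "total_mapped": rs.total_mapped,
                "path": str(path.relative_to(outdir)),
            }
        )
        peaks = _enriched_regions(truth, annotation, rs.mark, rs.genotype, config)
        peak_path = outdir / "peaks" / f"{rs.sample_id}.bed"
        write_bed(
            (
                GenomicInterval(p.chrom, p.start, p.end, ".", p.name or f"peak{i + 1}")
                for i, p in enumerate(peaks)
            ),
            emit(peak_path),
        )
    pd.DataFrame(sample_rows).to_csv(emit(outdir / "samples.tsv"), sep="\t", index=False)

    meth_rows = []
    for cs in callsets:
        path = outdir / "methylation" / f"{cs.sample_id}.cov.tsv"
        records = getattr(cs, "records_with_zeros", cs.records)
        records.to_csv(emit(path), sep="\t", index=False)
        meth_rows.append(
            {
                "sample_id": cs.sample_id,
                "genotype": cs.genotype,
                "path": str(path.relative_to(outdir)),
            }
        )
    pd.DataFrame(meth_rows).to_csv(emit(outdir / "meth_samples.tsv"), sep="\t", index=False)

    write_fpkm_table(expression, emit(outdir / "expression" / "fpkm.tsv"))

    tdir = outdir / "truth"
    truth.promoter_state.rename_axis("gene_id").to_csv(emit(tdir / "promoter_states.tsv"), sep="\t")
    truth.bin_class.rename_axis("bin_id").to_csv(emit(tdir / "bin_classes.tsv"), sep="\t")
    truth.domains.to_csv(emit(tdir / "domains.tsv"), sep="\t", index=False)
    truth.bin_methylation.to_csv(emit(tdir / "bin_methylation.tsv"), sep="\t")
    truth.expression_effect.to_csv(
        emit(tdir / "expression_effects.tsv"), sep="\t", float_format="%.6g"
    )

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    files.append(outdir / "config.yaml")

    manifest = pd.DataFrame(
        {
            "path": [str(f.relative_to(outdir)) for f in files],
            "sha256": [sha256_of(f) for f in files],
        }
    ).sort_values("path")
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
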