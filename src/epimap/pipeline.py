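"""Configuration, orchestration and reporting.

One entry point simulates a fixture bundle (``run_simulate``), one runs
the full analysis from a bundle directory to a report directory
(``run_analysis``), and one compares results against planted ground
truth (``run_recover``).  All figure-equivalent outputs are
tab-separated tables; identical config + inputs give byte-identical
tables (the structured log carries the only timestamps).
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import chip, integrate, methylome
from .core import (
    GenomeAnnotation,
    ReadSet,
    read_bed,
    read_chrom_sizes,
    read_fpkm_table,
    read_gene_table,
    read_methylation_coverage,
    sha256_of,
    write_bedgraph,
)
from .simulate import SimulationConfig, simulate_all, write_fixture_bundle

_FLOAT_FMT = "%.6g"


@dataclass
class AnalyzeConfig:
    """Paths and numeric parameters of the analysis stages."""

    bundle: str = ""
    bin_size: int = 10_000
    promoter_flank: int = 2_000
    min_peak_rpkm: float = 2.0
    state_threshold: float = 1.0
    up_fold: float = 2.0
    down_fold: float = 2.0
    change_min_rpkm: float = 2.0
    change_pseudocount: float = 0.5
    de_fold: float = 1.5
    de_min_fpkm: float = 0.5
    de_pseudocount: float = 0.1
    min_coverage: int = 1
    min_shared_sites: int = 100
    weighted: bool = False
    one_based: bool = False
    profile_window: int = 2_000
    profile_step: int = 100
    plot: bool = False

    _RANGES = {
        "bin_size": (1, None),
        "promoter_flank": (1, None),
        "min_peak_rpkm": (0, None),
        "state_threshold": (0, None),
        "up_fold": (1, None),
        "down_fold": (1, None),
        "change_min_rpkm": (0, None),
        "change_pseudocount": (0, None),
        "de_fold": (1, None),
        "de_min_fpkm": (0, None),
        "de_pseudocount": (0, None),
        "min_coverage": (1, None),
        "min_shared_sites": (2, None),
        "profile_window": (1, None),
        "profile_step": (1, None),
    }


@dataclass
class PipelineConfig:
    seed: int = 1
    simulate: SimulationConfig | None = None
    analyze: AnalyzeConfig | None = None


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists all problems at once."""


def _check_unknown(given: dict, allowed: list[str], where: str, problems: list[str]) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f' (did you mean "{hint[0]}"?)' if hint else ""
            problems.append(f"{where}: unknown key \"{key}\"{suffix}")


def validate_config(path: str | Path, check_paths: bool = True) -> PipelineConfig:
    """Load and validate a YAML pipeline config, reporting all problems at once.

    ``check_paths=False`` skips input-path existence checks (used when the
    same config first simulates the bundle it will later analyze).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    _check_unknown(raw, ["seed", "simulate", "analyze"], "top level", problems)
    seed = raw.get("seed", 1)
    if not isinstance(seed, int):
        problems.append("seed: must be an integer")
    sim = None
    if "simulate" in raw:
        block = raw["simulate"] or {}
        allowed = [f.name for f in dataclasses.fields(SimulationConfig) if f.name != "seed"]
        _check_unknown(block, allowed, "simulate", problems)
        try:
            sim = SimulationConfig(seed=seed, **{k: v for k, v in block.items() if k in allowed})
        except (TypeError, ValueError) as exc:
            problems.append(f"simulate: {exc}")
    ana = None
    if "analyze" in raw:
        block = raw["analyze"] or {}
        allowed = [f.name for f in dataclasses.fields(AnalyzeConfig)]
        _check_unknown(block, allowed, "analyze", problems)
        clean = {k: v for k, v in block.items() if k in allowed}
        try:
            ana = AnalyzeConfig(**clean)
        except TypeError as exc:
            problems.append(f"analyze: {exc}")
        if ana is not None:
            for key, (lo, hi) in AnalyzeConfig._RANGES.items():
                v = getattr(ana, key)
                if lo is not None and v < lo:
                    problems.append(f"analyze.{key}: {v} below minimum {lo}")
                if hi is not None and v > hi:
                    problems.append(f"analyze.{key}: {v} above maximum {hi}")
            if check_paths and ana.bundle and not Path(ana.bundle).exists():
                problems.append(f"analyze.bundle: path does not exist: {ana.bundle}")
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return PipelineConfig(seed=seed, simulate=sim, analyze=ana)


class StageLog:
    """Line-delimited structured log; one record per stage."""

    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def record(self, stage: str, status: str, wall_time: float, **counts: Any) -> None:
        rec = {"stage": stage, "status": status, "wall_s": round(wall_time, 3), **counts}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


@dataclass
class RunReport:
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    log_path: str = ""
    skipped: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_simulate(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Generate a fixture bundle from the simulate block."""
    if config.simulate is None:
        raise ConfigError("config has no simulate block")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = StageLog(outdir / "simulate.log")
    t0 = time.perf_counter()
    annotation, truth, readsets, callsets, expression = simulate_all(config.simulate)
    manifest_path = write_fixture_bundle(
        outdir, config.simulate, annotation, truth, readsets, callsets, expression
    )
    log.record(
        "simulate",
        "ok",
        time.perf_counter() - t0,
        n_genes=len(annotation.genes),
        n_chip_samples=len(readsets),
        n_meth_samples=len(callsets),
    )
    manifest = pd.read_csv(manifest_path, sep="\t")
    report = RunReport(
        outputs=dict(zip(manifest["path"], manifest["sha256"])),
        parameters=config.simulate.to_dict(),
        counts={
            "n_genes": len(annotation.genes),
            "n_chip_samples": len(readsets),
            "n_meth_samples": len(callsets),
            "n_bins": len(truth.bin_class),
        },
        log_path=str(log.path),
    )
    report.write(outdir / "simulate_report.json")
    return report


@dataclass
class Bundle:
    """A loaded fixture/input bundle."""

    annotation: GenomeAnnotation
    readsets: dict[str, ReadSet]  # sample_id -> reads
    peaks: dict[str, list]  # sample_id -> peak intervals
    meth: dict[str, methylome.SiteLevelTable]
    expression: pd.DataFrame | None
    truth_dir: Path | None


def load_bundle(bundle_dir: str | Path, min_coverage: int = 1, one_based: bool = False) -> Bundle:
    d = Path(bundle_dir)
    ann_dir = d / "annotation"
    chrom_sizes = read_chrom_sizes(ann_dir / "chrom_sizes.tsv")
    genes = read_gene_table(ann_dir / "genes.tsv")
    cgis = read_bed(ann_dir / "cgis.bed") if (ann_dir / "cgis.bed").exists() else []
    repeats = read_bed(ann_dir / "repeats.bed") if (ann_dir / "repeats.bed").exists() else []
    icrs = read_bed(ann_dir / "icrs.bed") if (ann_dir / "icrs.bed").exists() else []
    icr_parent = {}
    if (ann_dir / "icr_parents.tsv").exists():
        s = pd.read_csv(ann_dir / "icr_parents.tsv", sep="\t", index_col=0)["parent"]
        icr_parent = s.to_dict()
    annotation = GenomeAnnotation(chrom_sizes, genes, cgis, repeats, icrs, icr_parent)
    readsets, peaks = {}, {}
    samples_path = d / "samples.tsv"
    if samples_path.exists():
        for row in pd.read_csv(samples_path, sep="\t").itertuples(index=False):
            rs = ReadSet.from_bed(
                d / row.path, row.sample_id, row.mark, row.genotype, int(row.total_mapped)
            )
            readsets[row.sample_id] = rs
            peak_path = d / "peaks" / f"{row.sample_id}.bed"
            if peak_path.exists():
                peaks[row.sample_id] = read_bed(peak_path)
    meth = {}
    meth_path = d / "meth_samples.tsv"
    if meth_path.exists():
        for row in pd.read_csv(meth_path, sep="\t").itertuples(index=False):
            calls = read_methylation_coverage(
                d / row.path, row.sample_id, row.genotype, one_based=one_based
            )
            meth[row.sample_id] = methylome.site_levels(calls, min_coverage=min_coverage)
    expression = None
    fpkm_path = d / "expression" / "fpkm.tsv"
    if fpkm_path.exists():
        expression = read_fpkm_table(fpkm_path)
    truth_dir = d / "truth" if (d / "truth").exists() else None
    return Bundle(annotation, readsets, peaks, meth, expression, truth_dir)


def _by_mark_genotype(readsets: dict[str, ReadSet]) -> dict[tuple[str, str], ReadSet]:
    return {(rs.mark, rs.genotype): rs for rs in readsets.values()}


def _save(df: pd.DataFrame, path: Path, outputs: dict[str, str], index: bool = True, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index, index_label=index_label)
    outputs[path.name] = sha256_of(path)


def run_analysis(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Run every analysis stage on a bundle and write a report directory.

    Stage order: quantify → peak filter → promoter states → methylome
    summaries → bin classes → covariates/tests → DE → profiles →
    truth recovery (when ground truth is present).  Stages whose inputs
    are missing (e.g. no KO samples) are skipped with a logged reason.
    """
    if config.analyze is None:
        raise ConfigError("config has no analyze block")
    p = config.analyze
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = StageLog(outdir / "analysis.log")
    report = RunReport(parameters=dataclasses.asdict(p), log_path=str(log.path))
    out = report.outputs

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                counts = fn() or {}
            except _SkipStage as exc:
                report.skipped[name] = str(exc)
                log.record(name, "skipped", time.perf_counter() - t0, reason=str(exc))
                return None
            except Exception as exc:
                log.record(name, "failed", time.perf_counter() - t0, error=str(exc))
                report.write(outdir / "analysis_report.json")
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.record(name, "ok", time.perf_counter() - t0, **counts)
            report.counts.update({f"{name}.{k}": v for k, v in counts.items()})
            return None
        return deco

    bundle = load_bundle(p.bundle, min_coverage=p.min_coverage, one_based=p.one_based)
    ann = bundle.annotation
    by_mg = _by_mark_genotype(bundle.readsets)
    genotypes_present = sorted({g for _, g in by_mg}, reverse=True)
    lambda_chrom = _guess_lambda_chrom(ann)
    bins = [b for b in chip.make_bins(ann, p.bin_size) if b.chrom != lambda_chrom]
    promoters = chip.promoters_from_genes(ann.genes, p.promoter_flank, ann.chrom_sizes)

    state: dict[str, Any] = {}

    @stage("quantify")
    def _quantify():
        bin_rpkm, prom_rpkm = {}, {}
        for sid, rs in bundle.readsets.items():
            bin_rpkm[sid] = chip.rpkm(rs, bins)
            prom_rpkm[sid] = chip.rpkm(rs, promoters)
            write_bedgraph(bin_rpkm[sid], bins, outdir / f"bins_{sid}.bedgraph")
            out[f"bins_{sid}.bedgraph"] = sha256_of(outdir / f"bins_{sid}.bedgraph")
        state["bin_rpkm"] = pd.DataFrame(bin_rpkm)
        state["prom_rpkm"] = pd.DataFrame(prom_rpkm)
        _save(state["bin_rpkm"], outdir / "bin_rpkm.tsv", out, index_label="bin_id")
        _save(state["prom_rpkm"], outdir / "promoter_rpkm.tsv", out, index_label="gene_id")
        return {"n_bins": len(bins), "n_promoters": len(promoters), "n_samples": len(bundle.readsets)}

    @stage("peak_filter")
    def _peaks():
        if not bundle.peaks:
            raise _SkipStage("no peak files in bundle")
        rows = []
        dist_rows = {}
        for sid, pk in bundle.peaks.items():
            rs = bundle.readsets[sid]
            vals = chip.rpkm(rs, pk)
            retained, rep = chip.filter_low_quality_peaks(pk, vals.to_numpy(), p.min_peak_rpkm)
            rows.append(
                {
                    "sample_id": sid,
                    "n_in": rep.n_in,
                    "n_retained": rep.n_retained,
                    "n_excluded": rep.n_excluded,
                }
            )
            dist_rows[sid] = chip.peak_genomic_distribution(
                retained, ann, p.promoter_flank, p.promoter_flank
            )
        _save(pd.DataFrame(rows), outdir / "peak_filter_report.tsv", out, index=False)
        _save(pd.DataFrame(dist_rows).T.rename_axis("sample_id"), outdir / "peak_genomic_distribution.tsv", out)
        return {"n_peak_samples": len(rows)}

    @stage("promoter_states")
    def _states():
        need = [("H3K4me3", "WT"), ("H3K27me3", "WT"), ("H2AK119ub1", "WT")]
        if any(k not in by_mg for k in need):
            raise _SkipStage("missing WT promoter-mark samples")
        pr = state["prom_rpkm"]
        states = integrate.classify_promoter_states(
            pr[by_mg[("H3K4me3", "WT")].sample_id],
            pr[by_mg[("H3K27me3", "WT")].sample_id],
            pr[by_mg[("H2AK119ub1", "WT")].sample_id],
            threshold=p.state_threshold,
        )
        state["states"] = states
        _save(states, outdir / "promoter_states.tsv", out, index_label="gene_id")
        counts = states["state"].value_counts().to_dict()
        if bundle.expression is not None:
            for col in bundle.expression.columns:
                summary = integrate.expression_by_state(states, bundle.expression[col])
                _save(summary, outdir / f"expression_by_state_{col}.tsv", out)
        # z-scored promoter matrix export for external heatmaps, sorted for
        # reproducibility by WT H3K4me3 RPKM (descending)
        prom_matrix = chip.signal_matrix(list(bundle.readsets.values()), promoters)
        z = chip.zscore_standardize(prom_matrix, axis="feature")
        zdf = z.values.loc[
            pr[by_mg[("H3K4me3", "WT")].sample_id].sort_values(ascending=False).index
        ]
        _save(zdf, outdir / "promoter_zscore_matrix.tsv", out, index_label="gene_id")
        return {f"state_{k}": int(v) for k, v in counts.items()}

    @stage("methylome")
    def _meth():
        if not bundle.meth:
            raise _SkipStage("no methylation samples in bundle")
        counts = {}
        for sid, sites in bundle.meth.items():
            real = sites.restrict([c for c in ann.chrom_sizes if c != lambda_chrom])
            _save(
                methylome.global_levels_by_context(real),
                outdir / f"methylation_by_context_{sid}.tsv",
                out,
            )
            _save(
                methylome.aggregate_by_element(real, ann, p.promoter_flank, weighted=p.weighted),
                outdir / f"methylation_by_element_{sid}.tsv",
                out,
            )
            if ann.icrs:
                per_icr, groups = methylome.icr_levels(real, ann)
                _save(per_icr, outdir / f"icr_levels_{sid}.tsv", out)
                _save(groups, outdir / f"icr_group_levels_{sid}.tsv", out)
            if lambda_chrom is not None:
                counts[f"conversion_efficiency_{sid}"] = round(
                    methylome.conversion_efficiency(sites, lambda_chrom), 6
                )
            counts[f"sites_dropped_{sid}"] = sites.n_dropped
        if len(bundle.meth) >= 2:
            try:
                clust = methylome.cluster_samples_by_cpg(
                    bundle.meth, p.min_coverage, p.min_shared_sites
                )
                (outdir / "methylome_dendrogram.nwk").write_text(clust.newick + "\n")
                out["methylome_dendrogram.nwk"] = sha256_of(outdir / "methylome_dendrogram.nwk")
                _save(clust.distance, outdir / "methylome_distance.tsv", out)
                labels = pd.Series(clust.labels, name="cluster").rename_axis("sample_id")
                _save(labels.to_frame(), outdir / "methylome_clusters.tsv", out)
                counts["n_shared_cpg"] = clust.n_shared_sites
            except ValueError as exc:
                report.skipped["methylome.clustering"] = str(exc)
        return counts

    @stage("bin_classes")
    def _bins():
        need = [(m, g) for m in ("H3K27me3", "H2AK119ub1") for g in ("WT", "KO")]
        if any(k not in by_mg for k in need):
            raise _SkipStage("need WT and KO H3K27me3/H2AK119ub1 samples")
        br = state["bin_rpkm"]
        table = integrate.classify_bin_changes(
            br[by_mg[("H3K27me3", "WT")].sample_id],
            br[by_mg[("H3K27me3", "KO")].sample_id],
            br[by_mg[("H2AK119ub1", "WT")].sample_id],
            br[by_mg[("H2AK119ub1", "KO")].sample_id],
            p.up_fold,
            p.down_fold,
            p.change_min_rpkm,
            p.change_pseudocount,
        )
        state["bin_table"] = table
        _save(table, outdir / "bin_change_classes.tsv", out, index_label="bin_id")
        # genomic distribution of changed bins (TSS/TES/body/intergenic)
        changed = [b for b in bins if table.loc[b.name, "bin_class"] not in ("unchanged",)]
        if changed:
            dist = chip.peak_genomic_distribution(changed, ann, p.promoter_flank, p.promoter_flank)
            _save(dist.to_frame().rename_axis("category"), outdir / "changed_bin_distribution.tsv", out)
        return table["bin_class"].value_counts().add_prefix("class_").to_dict()

    @stage("covariates")
    def _cov():
        if "bin_table" not in state:
            raise _SkipStage("bin classes unavailable")
        meth_by_geno = {}
        for sites in bundle.meth.values():
            meth_by_geno.setdefault(sites.genotype, sites)
        extra = None
        if ("H3K36me3", "WT") in by_mg and ("H3K36me3", "KO") in by_mg:
            br = state["bin_rpkm"]
            extra = {
                "WT": br[by_mg[("H3K36me3", "WT")].sample_id],
                "KO": br[by_mg[("H3K36me3", "KO")].sample_id],
            }
        expr = bundle.expression
        if expr is not None and not {"WT", "KO"} <= set(expr.columns):
            expr = None
        res = integrate.bin_class_covariates(
            state["bin_table"]["bin_class"],
            bins,
            meth_sites=meth_by_geno if {"WT", "KO"} <= set(meth_by_geno) else None,
            extra_rpkm=extra,
            extra_name="H3K36me3",
            expression=expr,
            genes=ann.genes,
        )
        _save(res.summaries, outdir / "bin_class_covariates.tsv", out, index=False)
        _save(res.tests, outdir / "bin_class_tests.tsv", out, index=False)
        # single-mark change classes for H3K36me3 with its own covariates
        if extra is not None:
            k36 = integrate.bin_mark_change_classes(
                extra["WT"], extra["KO"], p.up_fold, p.down_fold, p.change_min_rpkm, p.change_pseudocount
            )
            _save(k36.to_frame(), outdir / "k36_change_classes.tsv", out, index_label="bin_id")
            res36 = integrate.bin_class_covariates(
                k36.replace({"up": "I", "down": "IV"}).rename("bin_class"),
                bins,
                meth_sites=meth_by_geno if {"WT", "KO"} <= set(meth_by_geno) else None,
                expression=expr,
                genes=ann.genes,
            )
            summaries = res36.summaries.replace({"bin_class": {"I": "up", "IV": "down"}})
            tests = res36.tests.replace({"bin_class": {"I": "up", "IV": "down"}})
            _save(summaries[summaries["bin_class"].isin(["up", "down", "unchanged"])],
                  outdir / "k36_class_covariates.tsv", out, index=False)
            _save(tests[tests["bin_class"].isin(["up", "down", "unchanged"])],
                  outdir / "k36_class_tests.tsv", out, index=False)
        return {}

    @stage("differential_expression")
    def _de():
        expr = bundle.expression
        if expr is None:
            raise _SkipStage("no expression table")
        if not {"WT", "KO"} <= set(expr.columns):
            raise _SkipStage("expression table lacks WT/KO columns")
        calls = integrate.call_de_genes(
            expr, "WT", "KO", p.de_fold, p.de_min_fpkm, p.de_pseudocount
        )
        state["de_calls"] = calls
        _save(calls.to_frame(), outdir / "de_calls.tsv", out, index_label="gene_id")
        return calls.value_counts().add_prefix("de_").to_dict()

    @stage("profiles")
    def _profiles():
        anchors = chip.gene_anchors(ann.genes, "tss")
        anchor_sets = {"all_genes": anchors}
        if "de_calls" in state:
            calls = state["de_calls"]
            for direction in ("down", "up"):
                ids = set(calls.index[calls == direction])
                sel = [a for a, g in zip(anchors, ann.genes) if g.gene_id in ids]
                if sel:
                    anchor_sets[f"{direction}_genes"] = sel
        for set_name, anc in anchor_sets.items():
            cols = {"offset": None}
            frames = {}
            for sid, rs in bundle.readsets.items():
                prof = chip.average_profile(rs, anc, p.profile_window, p.profile_step)
                frames[sid] = prof.aggregate
                cols["offset"] = prof.offsets
            df = pd.DataFrame({"offset": cols["offset"], **frames})
            _save(df, outdir / f"tss_profiles_{set_name}.tsv", out, index=False)
        if "states" in state and bundle.meth:
            wt_sites = next(
                (s for s in bundle.meth.values() if s.genotype == "WT"), None
            )
            if wt_sites is not None:
                mp = integrate.methylation_profile_by_tss_state(
                    wt_sites, state["states"], ann.genes, p.profile_window, p.profile_step
                )
                _save(mp, outdir / "methylation_profile_by_state.tsv", out, index=False)
        return {"n_anchor_sets": len(anchor_sets)}

    @stage("truth_recovery")
    def _recover():
        if bundle.truth_dir is None:
            raise _SkipStage("no ground truth in bundle")
        return run_recover(bundle.truth_dir, outdir, outputs=out)

    if p.plot:
        _render_plots(outdir, state, report)

    report.write(outdir / "analysis_report.json")
    return report


class _SkipStage(Exception):
    pass


def _guess_lambda_chrom(annotation: GenomeAnnotation) -> str | None:
    """The spike chromosome is the one carrying no genes (if any)."""
    with_genes = {g.chrom for g in annotation.genes}
    free = [c for c in annotation.chrom_sizes if c not in with_genes]
    return free[0] if len(free) == 1 else None


def run_recover(
    truth_dir: str | Path, results_dir: str | Path, outputs: dict[str, str] | None = None
) -> dict:
    """Compare planted truth with analysis outputs; write a recovery table."""
    truth_dir, results_dir = Path(truth_dir), Path(results_dir)
    rows = []
    counts: dict[str, Any] = {}
    ps_path = results_dir / "promoter_states.tsv"
    if ps_path.exists():
        truth_states = pd.read_csv(truth_dir / "promoter_states.tsv", sep="\t", index_col=0)["state"]
        called = pd.read_csv(ps_path, sep="\t", index_col=0)["state"]
        common = truth_states.index.intersection(called.index)
        frac = float((truth_states.loc[common] == called.loc[common]).mean())
        rows.append({"quantity": "promoter_state_recovery", "n": len(common), "value": frac})
        counts["promoter_state_recovery"] = round(frac, 4)
    bc_path = results_dir / "bin_change_classes.tsv"
    if bc_path.exists():
        truth_cls = pd.read_csv(truth_dir / "bin_classes.tsv", sep="\t", index_col=0)["bin_class"]
        called = pd.read_csv(bc_path, sep="\t", index_col=0)["bin_class"]
        common = truth_cls.index.intersection(called.index)
        planted = common[truth_cls.loc[common] != "unchanged"]
        frac_changed = float((truth_cls.loc[planted] == called.loc[planted]).mean()) if len(planted) else float("nan")
        frac_all = float((truth_cls.loc[common] == called.loc[common]).mean())
        rows.append({"quantity": "bin_class_recovery_planted", "n": len(planted), "value": frac_changed})
        rows.append({"quantity": "bin_class_recovery_all", "n": len(common), "value": frac_all})
        counts["bin_class_recovery_planted"] = round(frac_changed, 4)
        counts["bin_class_recovery_all"] = round(frac_all, 4)
    de_path = results_dir / "de_calls.tsv"
    if de_path.exists() and (truth_dir / "expression_effects.tsv").exists():
        eff = pd.read_csv(truth_dir / "expression_effects.tsv", sep="\t", index_col=0)
        calls = pd.read_csv(de_path, sep="\t", index_col=0)["de_call"]
        planted_down = eff.index[eff["de_planted"].astype(bool)]
        if len(planted_down):
            frac = float((calls.reindex(planted_down) == "down").mean())
            rows.append({"quantity": "planted_de_down_recovery", "n": len(planted_down), "value": frac})
            counts["planted_de_down_recovery"] = round(frac, 4)
    df = pd.DataFrame(rows)
    path = results_dir / "truth_recovery.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if outputs is not None:
        outputs[path.name] = sha256_of(path)
    return counts


def _render_plots(outdir: Path, state: dict, report: RunReport) -> None:
    """Optional quick-look figures; analysis tables never depend on these."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "bin_table" in state:
        counts = state["bin_table"]["bin_class"].value_counts()
        fig, ax = plt.subplots(figsize=(5, 3))
        counts.plot.bar(ax=ax)
        ax.set_ylabel("bins")
        fig.tight_layout()
        fig.savefig(outdir / "bin_class_counts.png", dpi=100)
        plt.close(fig)
        report.outputs["bin_class_counts.png"] = sha256_of(outdir / "bin_class_counts.png")
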