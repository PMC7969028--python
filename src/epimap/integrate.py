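"""Cross-mark classifications and statistics.

Implements the headline downstream analyses of a two-genotype
(WT vs knockout) oocyte epigenome study:

* promoter chromatin states from thresholded H3K4me3 / H3K27me3 /
  H2AK119ub1 RPKM (eight combinatorial states, plus the four-group
  K4/K27 label used for heatmap panels);
* expression summaries per state (box/whisker statistics by the
  1.5 × IQR rule);
* fold-change differential-expression calls with a pseudocount and an
  expression floor;
* the six-class taxonomy of 10-kb bins by directional H3K27me3 /
  H2AK119ub1 change between genotypes, with per-class covariates;
* two-tailed Student's t tests (pooled-variance unpaired, and paired).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomicInterval
from .methylome import SiteLevelTable

STATE_ORDER = ("K4", "K27", "ub")
ALL_STATES = (
    "K4", "K27", "ub", "K4+K27", "K4+ub", "K27+ub", "K4+K27+ub", "none",
)
BIN_CLASSES = ("I", "II", "III", "IV", "V", "VI", "mixed", "unchanged")

_CLASS_MAP = {
    ("up", "none"): "I",
    ("up", "up"): "II",
    ("none", "up"): "III",
    ("down", "none"): "IV",
    ("down", "down"): "V",
    ("none", "down"): "VI",
    ("up", "down"): "mixed",
    ("down", "up"): "mixed",
    ("none", "none"): "unchanged",
}


def state_string(marks: frozenset | set | Sequence[str]) -> str:
    """Canonical state label: marks joined in K4, K27, ub order ('none' if empty)."""
    present = [m for m in STATE_ORDER if m in set(marks)]
    return "+".join(present) if present else "none"


def classify_promoter_states(
    k4: pd.Series, k27: pd.Series, ub: pd.Series, threshold: float = 1.0
) -> pd.DataFrame:
    """Combinatorial promoter state from per-mark promoter RPKM.

    A mark is called present iff its RPKM is strictly greater than
    ``threshold``.  The four-group label uses only K4/K27:
    A = K4-only, B = bivalent, C = K27-only, D = neither.
    """
    if not (k4.index.equals(k27.index) and k4.index.equals(ub.index)):
        raise ValueError("promoter sets differ across marks")
    p4 = k4 > threshold
    p27 = k27 > threshold
    pub = ub > threshold
    states = [
        state_string({m for m, on in zip(STATE_ORDER, flags) if on})
        for flags in zip(p4, p27, pub)
    ]
    group = np.where(
        p4 & ~p27, "A", np.where(p4 & p27, "B", np.where(p27, "C", "D"))
    )
    return pd.DataFrame(
        {
            "k4_rpkm": k4,
            "k27_rpkm": k27,
            "ub_rpkm": ub,
            "state": states,
            "group": group,
        },
        index=k4.index,
    )


def _box_stats(values: np.ndarray) -> dict:
    """Median/quartiles plus Tukey whiskers (no further than 1.5 × IQR)."""
    if len(values) == 0:
        return {
            "n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
            "lo_whisker": np.nan, "hi_whisker": np.nan, "mean": np.nan,
        }
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr]
    hi = values[values <= q3 + 1.5 * iqr]
    return {
        "n": len(values),
        "median": med,
        "q1": q1,
        "q3": q3,
        "lo_whisker": lo.min() if len(lo) else np.nan,
        "hi_whisker": hi.max() if len(hi) else np.nan,
        "mean": values.mean(),
    }


def expression_by_state(
    states: pd.DataFrame, fpkm: pd.Series
) -> pd.DataFrame:
    """Per-state expression summary, ranked by median (descending).

    Every one of the eight states is reported, empty ones with n=0.
    """
    common = states.index.intersection(fpkm.index)
    if len(common) == 0:
        raise ValueError("no shared gene ids between states and expression")
    st = states.loc[common, "state"]
    x = fpkm.loc[common]
    rows = {}
    for state in ALL_STATES:
        rows[state] = _box_stats(x[st == state].to_numpy(dtype=float))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "state"
    return df.sort_values("median", ascending=False, na_position="last")


def call_de_genes(
    expression: pd.DataFrame,
    wt_column: str = "WT",
    ko_column: str = "KO",
    fold: float = 1.5,
    min_fpkm: float = 0.5,
    pseudocount: float = 0.1,
) -> pd.Series:
    """Fold-change DE calls: down / up / unchanged per gene.

    down iff (FPKM_WT + ε) / (FPKM_KO + ε) > fold and FPKM_WT >= min_fpkm;
    up symmetric.  The pseudocount keeps the ratio finite at FPKM → 0 and
    the floor suppresses calls among unexpressed genes.
    """
    wt = expression[wt_column].astype(float)
    ko = expression[ko_column].astype(float)
    ratio_down = (wt + pseudocount) / (ko + pseudocount)
    ratio_up = (ko + pseudocount) / (wt + pseudocount)
    call = np.where(
        (ratio_down > fold) & (wt >= min_fpkm),
        "down",
        np.where((ratio_up > fold) & (ko >= min_fpkm), "up", "unchanged"),
    )
    return pd.Series(call, index=expression.index, name="de_call")


def set_overlap(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Venn partition counts: (|A only|, |A ∩ B|, |B only|)."""
    a, b = set(set_a), set(set_b)
    both = a & b
    return (len(a - both), len(both), len(b - both))


def mark_change_call(
    wt: pd.Series,
    ko: pd.Series,
    up_fold: float = 2.0,
    down_fold: float = 2.0,
    min_rpkm: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-feature directional change call for one mark: up / down / none.

    up iff (KO + c)/(WT + c) >= up_fold and KO >= min_rpkm; down is the
    genotype-mirrored rule, so relabelling genotypes swaps up and down.
    """
    if not wt.index.equals(ko.index):
        raise ValueError("WT and KO tracks are on different feature sets")
    up = ((ko + pseudocount) / (wt + pseudocount) >= up_fold) & (ko >= min_rpkm)
    down = ((wt + pseudocount) / (ko + pseudocount) >= down_fold) & (wt >= min_rpkm)
    return pd.Series(
        np.where(up & ~down, "up", np.where(down & ~up, "down", "none")),
        index=wt.index,
        name="call",
    )


def classify_bin_changes(
    k27_wt: pd.Series,
    k27_ko: pd.Series,
    ub_wt: pd.Series,
    ub_ko: pd.Series,
    up_fold: float = 2.0,
    down_fold: float = 2.0,
    min_rpkm: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Six-class taxonomy of bins by joint H3K27me3/H2AK119ub1 change.

    (K27, ub) calls map to: (up, none) → I, (up, up) → II, (none, up) → III,
    (down, none) → IV, (down, down) → V, (none, down) → VI; opposite
    directions → mixed; (none, none) → unchanged.  The result partitions
    the bin set exhaustively and exclusively.
    """
    for s in (k27_ko, ub_wt, ub_ko):
        if not k27_wt.index.equals(s.index):
            raise ValueError("bin tiling mismatch across the four tracks")
    k27_call = mark_change_call(k27_wt, k27_ko, up_fold, down_fold, min_rpkm, pseudocount)
    ub_call = mark_change_call(ub_wt, ub_ko, up_fold, down_fold, min_rpkm, pseudocount)
    cls = [
        _CLASS_MAP[(c27, cub)] for c27, cub in zip(k27_call, ub_call)
    ]
    return pd.DataFrame(
        {
            "k27_wt": k27_wt,
            "k27_ko": k27_ko,
            "ub_wt": ub_wt,
            "ub_ko": ub_ko,
            "k27_call": k27_call,
            "ub_call": ub_call,
            "bin_class": cls,
        },
        index=k27_wt.index,
    )


def bin_mark_change_classes(
    wt: pd.Series,
    ko: pd.Series,
    up_fold: float = 2.0,
    down_fold: float = 2.0,
    min_rpkm: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Two-direction bin table for a single mark (e.g. H3K36me3)."""
    call = mark_change_call(wt, ko, up_fold, down_fold, min_rpkm, pseudocount)
    return call.replace({"none": "unchanged"}).rename("change_class")


@dataclass
class TestResult:
    """Two-tailed Student's t-test outcome."""

    statistic: float
    df: int
    pvalue: float
    flavor: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


_P_MIN = float(np.finfo(float).tiny)


def students_t_test(x, y, flavor: str = "unpaired") -> TestResult:
    """Classical two-tailed Student's t-test.

    unpaired: pooled-variance t with df = n_x + n_y − 2.
    paired: one-sample t on differences (equal lengths required).
    Zero variance with equal means gives t=0, p=1; zero variance with
    unequal means reports the underflow-safe minimum p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if flavor == "unpaired":
        nx, ny = len(x), len(y)
        if nx < 2 or ny < 2:
            raise ValueError("unpaired test needs >= 2 observations per group")
        df = nx + ny - 2
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
        diff = x.mean() - y.mean()
        if sp2 == 0:
            stat, p = _degenerate(diff)
        else:
            stat = diff / np.sqrt(sp2 * (1 / nx + 1 / ny))
            p = 2 * sps.t.sf(abs(stat), df)
    elif flavor == "paired":
        if len(x) != len(y):
            raise ValueError("paired test requires equal group sizes")
        if len(x) < 2:
            raise ValueError("paired test needs >= 2 pairs")
        d = x - y
        n = len(d)
        df = n - 1
        sd = d.std(ddof=1)
        if sd == 0:
            stat, p = _degenerate(d.mean())
        else:
            stat = d.mean() / (sd / np.sqrt(n))
            p = 2 * sps.t.sf(abs(stat), df)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    p = 1.0 if stat == 0 else float(min(max(p, _P_MIN), 1.0))
    return TestResult(
        float(stat), int(df), p, flavor, len(x), len(y), float(x.mean()), float(y.mean())
    )


def _degenerate(diff: float) -> tuple[float, float]:
    if diff == 0:
        return 0.0, 1.0
    return (np.inf if diff > 0 else -np.inf), _P_MIN


# ---------------------------------------------------------------------------
# covariates over bin classes
# ---------------------------------------------------------------------------


def bin_mean_methylation(
    sites: SiteLevelTable, bins: Sequence[GenomicInterval]
) -> pd.Series:
    """Mean CpG site level per bin (NaN for bins with no covered CpG)."""
    cpg = sites.table[sites.table["context"] == "CpG"]
    out = pd.Series(np.nan, index=[b.name for b in bins], dtype=float)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for b in bins:
        by_chrom[b.chrom].append(b)
    for chrom, bs in by_chrom.items():
        sub = cpg[cpg["chrom"] == chrom]
        if sub.empty:
            continue
        bs = sorted(bs, key=lambda b: b.start)
        starts = np.array([b.start for b in bs])
        ends = np.array([b.end for b in bs])
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        lv = sub["level"].to_numpy()[ok]
        grp = idx[ok]
        sums = np.bincount(grp, weights=lv, minlength=len(bs))
        counts = np.bincount(grp, minlength=len(bs))
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for b, m in zip(bs, means):
            out[b.name] = m
    return out


def genes_to_bins(genes: Sequence, bins: Sequence[GenomicInterval]) -> pd.Series:
    """Bin id per gene, by gene-body midpoint (NaN if outside the tiling)."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for b in bins:
        by_chrom[b.chrom].append(b)
    out = {}
    for g in genes:
        bs = sorted(by_chrom.get(g.chrom, []), key=lambda b: b.start)
        mid = g.body.midpoint
        assigned = None
        if bs:
            starts = np.array([b.start for b in bs])
            i = int(np.searchsorted(starts, mid, side="right")) - 1
            if i >= 0 and mid < bs[i].end:
                assigned = bs[i].name
        out[g.gene_id] = assigned
    return pd.Series(out, name="bin_id")


@dataclass
class CovariateResult:
    summaries: pd.DataFrame  # class × genotype × covariate distribution stats
    tests: pd.DataFrame  # one row per class × covariate with t / df / p


def bin_class_covariates(
    classes: pd.Series,
    bins: Sequence[GenomicInterval],
    meth_sites: Mapping[str, SiteLevelTable] | None = None,
    extra_rpkm: Mapping[str, pd.Series] | None = None,
    extra_name: str = "extra_mark",
    expression: pd.DataFrame | None = None,
    genes: Sequence | None = None,
    wt_column: str = "WT",
    ko_column: str = "KO",
) -> CovariateResult:
    """Per-class WT/KO covariate distributions and genotype-contrast tests.

    Region-level covariates (bin methylation, an extra mark's bin RPKM)
    are compared WT vs KO with unpaired t-tests; expression of the genes
    assigned to each class (gene-body midpoint in bin) is compared with
    a paired t-test, since the same genes are measured in both genotypes.
    Classes with no bins (or < 2 covariate values) are reported empty.
    """
    covariates: dict[str, tuple[pd.Series, pd.Series, str]] = {}
    if meth_sites is not None:
        covariates["methylation"] = (
            bin_mean_methylation(meth_sites["WT"], bins),
            bin_mean_methylation(meth_sites["KO"], bins),
            "unpaired",
        )
    if extra_rpkm is not None:
        covariates[extra_name] = (extra_rpkm["WT"], extra_rpkm["KO"], "unpaired")
    gene_bins = None
    if expression is not None:
        if genes is None:
            raise ValueError("expression covariate requires gene models")
        gene_bins = genes_to_bins(genes, bins)
    sum_rows, test_rows = [], []
    for cls in BIN_CLASSES:
        bin_ids = classes.index[classes == cls]
        for name, (wt_vals, ko_vals, flavor) in covariates.items():
            w = wt_vals.reindex(bin_ids).dropna().to_numpy(dtype=float)
            k = ko_vals.reindex(bin_ids).dropna().to_numpy(dtype=float)
            for geno, vals in (("WT", w), ("KO", k)):
                sum_rows.append(
                    {"bin_class": cls, "covariate": name, "genotype": geno, **_box_stats(vals)}
                )
            test_rows.append(_safe_test(cls, name, w, k, flavor))
        if expression is not None:
            in_cls = gene_bins[gene_bins.isin(bin_ids)].index
            in_cls = expression.index.intersection(in_cls)
            w = expression.loc[in_cls, wt_column].to_numpy(dtype=float)
            k = expression.loc[in_cls, ko_column].to_numpy(dtype=float)
            for geno, vals in (("WT", w), ("KO", k)):
                sum_rows.append(
                    {"bin_class": cls, "covariate": "expression", "genotype": geno, **_box_stats(vals)}
                )
            test_rows.append(_safe_test(cls, "expression", w, k, "paired"))
    return CovariateResult(pd.DataFrame(sum_rows), pd.DataFrame(test_rows))


def _safe_test(cls: str, name: str, w: np.ndarray, k: np.ndarray, flavor: str) -> dict:
    row = {"bin_class": cls, "covariate": name, "flavor": flavor, "n_wt": len(w), "n_ko": len(k)}
    try:
        res = students_t_test(w, k, flavor)
        row.update({"t": res.statistic, "df": res.df, "p": res.pvalue})
    except ValueError:
        row.update({"t": np.nan, "df": np.nan, "p": np.nan})
    return row


def methylation_profile_by_tss_state(
    sites: SiteLevelTable,
    states: pd.DataFrame,
    genes: Sequence,
    window: int = 2000,
    step: int = 100,
) -> pd.DataFrame:
    """Mean CpG level by TSS-relative offset bin, per promoter state.

    Minus-strand genes are orientation-flipped; states with no genes are
    omitted from the output columns.
    """
    if (2 * window) % step != 0:
        raise ValueError("step must divide 2*window")
    n_bins = 2 * window // step
    offsets = np.arange(-window, window, step)
    cpg = sites.table[sites.table["context"] == "CpG"]
    by_chrom = {c: g for c, g in cpg.groupby("chrom")}
    sums = defaultdict(lambda: np.zeros(n_bins))
    counts = defaultdict(lambda: np.zeros(n_bins))
    gene_state = states["state"]
    for g in genes:
        if g.gene_id not in gene_state.index:
            continue
        state = gene_state[g.gene_id]
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        rel = (pos - g.tss) if g.strand != "-" else (g.tss - pos)
        idx = (rel + window) // step
        ok = (idx >= 0) & (idx < n_bins)
        if not ok.any():
            continue
        lv = sub["level"].to_numpy()[ok]
        ii = idx[ok].astype(int)
        sums[state] += np.bincount(ii, weights=lv, minlength=n_bins)
        counts[state] += np.bincount(ii, minlength=n_bins)
    data = {"offset": offsets}
    for state in ALL_STATES:
        if state in sums and counts[state].sum() > 0:
            with np.errstate(invalid="ignore"):
                data[state] = np.where(
                    counts[state] > 0, sums[state] / np.maximum(counts[state], 1), np.nan
                )
    return pd.DataFrame(data)
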