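"""Promoter states, DE calls, bin-change taxonomy, t-tests, covariates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epimap import integrate
from epimap.integrate import (
    call_de_genes,
    classify_bin_changes,
    classify_promoter_states,
    expression_by_state,
    mark_change_call,
    set_overlap,
    students_t_test,
)


def series(values, prefix="f"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestPromoterStates:
    def _one(self, k4, k27, ub, threshold=1.0):
        out = classify_promoter_states(
            series([k4]), series([k27]), series([ub]), threshold
        )
        return out["state"].iloc[0], out["group"].iloc[0]

    @pytest.mark.parametrize(
        "k4,k27,ub,state,group",
        [
            (2.0, 0.5, 0.5, "K4", "A"),
            (1.5, 1.5, 1.5, "K4+K27+ub", "B"),
            (1.0, 1.0, 1.0, "none", "D"),  # strictly-greater boundary
            (0.5, 2.0, 0.5, "K27", "C"),
            (0.5, 0.5, 2.0, "ub", "D"),  # ub ignored for the 4-group label
            (2.0, 2.0, 0.5, "K4+K27", "B"),
        ],
    )
    def test_thresholding_and_groups(self, k4, k27, ub, state, group):
        assert self._one(k4, k27, ub) == (state, group)

    def test_mismatched_promoter_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            classify_promoter_states(series([1.0]), series([1.0], prefix="x"), series([1.0]))

    def test_states_partition_genes(self):
        rng = np.random.default_rng(0)
        k4, k27, ub = (series(rng.exponential(1, 500)) for _ in range(3))
        states = classify_promoter_states(k4, k27, ub)
        summary = expression_by_state(states, series(rng.exponential(5, 500)))
        assert summary["n"].sum() == 500


class TestExpressionByState:
    def test_single_gene_state_median_is_value(self):
        states = classify_promoter_states(series([5.0]), series([0.0]), series([0.0]))
        out = expression_by_state(states, series([7.5]))
        assert out.loc["K4", "median"] == 7.5
        assert out.loc["K4", "n"] == 1

    def test_whiskers_bounded_by_observed_range(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(10, 1, 50), [50.0]])  # one outlier
        states = classify_promoter_states(
            series(np.full(51, 5.0)), series(np.zeros(51)), series(np.zeros(51))
        )
        out = expression_by_state(states, series(vals))
        assert out.loc["K4", "hi_whisker"] <= vals.max()
        assert out.loc["K4", "hi_whisker"] < 50.0  # outlier beyond 1.5 IQR excluded
        assert out.loc["K4", "lo_whisker"] >= vals.min()

    def test_planted_k4_state_has_highest_median(self, small_sim):
        _, truth, _, _, expression = small_sim
        states = pd.DataFrame({"state": truth.promoter_state})
        out = expression_by_state(states, expression["WT"])
        assert out.index[0] == "K4"


class TestDeCalls:
    def _call(self, wt, ko, **kw):
        expr = pd.DataFrame({"WT": [wt], "KO": [ko]}, index=["g"])
        return call_de_genes(expr, **kw)["g"]

    def test_ratio_above_fold_is_down(self):
        # (3.0 + 0.1) / (1.9 + 0.1) = 1.55 > 1.5
        assert self._call(3.0, 1.9) == "down"

    def test_equal_expression_unchanged(self):
        assert self._call(4.0, 4.0) == "unchanged"

    def test_expression_floor_suppresses_call(self):
        assert self._call(0.2, 0.01) == "unchanged"

    def test_up_call_symmetric(self):
        assert self._call(1.9, 3.0) == "up"

    def test_planted_halving_detected_at_default_dispersion(self):
        """Genes with KO/WT mean ratio 0.5 are called down in >= 95% of cases."""
        from epimap.simulate import GroundTruth, SimulationConfig, simulate_expression

        n = 400
        eff = pd.DataFrame(
            {"wt_mean": np.full(n, 20.0), "ko_mean": np.full(n, 10.0), "de_planted": True},
            index=[f"g{i}" for i in range(n)],
        )
        truth = GroundTruth(
            promoter_state=pd.Series(dtype=object),
            bin_class=pd.Series(dtype=object),
            domains=pd.DataFrame(),
            bin_methylation=pd.DataFrame(),
            expression_effect=eff,
        )
        expr = simulate_expression(truth, SimulationConfig(seed=5))
        calls = call_de_genes(expr)
        assert (calls == "down").mean() >= 0.95


class TestSetOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, (1, 2, 1)),
            ({"a"}, {"b"}, (1, 0, 1)),
            ({"a", "b"}, {"a", "b", "c"}, (0, 2, 1)),
            (set(), set(), (0, 0, 0)),
        ],
    )
    def test_partition_counts(self, a, b, expected):
        assert set_overlap(a, b) == expected


class TestBinChanges:
    def _tab(self, k27_wt, k27_ko, ub_wt, ub_ko, **kw):
        return classify_bin_changes(
            series([k27_wt]), series([k27_ko]), series([ub_wt]), series([ub_ko]), **kw
        )["bin_class"].iloc[0]

    @pytest.mark.parametrize(
        "k27_wt,k27_ko,ub_wt,ub_ko,expected",
        [
            (0.5, 4.0, 1.0, 1.0, "I"),  # ectopic K27 gain
            (0.5, 4.0, 0.5, 4.0, "II"),  # both gained
            (1.0, 1.0, 0.5, 4.0, "III"),
            (4.0, 0.5, 1.0, 1.0, "IV"),
            (4.0, 0.5, 4.0, 0.5, "V"),
            (1.0, 1.0, 4.0, 0.5, "VI"),
            (4.0, 0.5, 0.5, 4.0, "mixed"),
            (2.0, 2.0, 2.0, 2.0, "unchanged"),
        ],
    )
    def test_class_mapping(self, k27_wt, k27_ko, ub_wt, ub_ko, expected):
        assert self._tab(k27_wt, k27_ko, ub_wt, ub_ko) == expected

    def test_min_rpkm_floor_blocks_call(self):
        # 8x fold but KO below the RPKM floor of 2
        assert self._tab(0.1, 1.5, 1.0, 1.0) == "unchanged"

    def test_tiling_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_bin_changes(
                series([1.0]), series([1.0]), series([1.0], prefix="x"), series([1.0])
            )

    def test_genotype_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        vals = [series(rng.exponential(2, 1000)) for _ in range(4)]
        fwd = classify_bin_changes(*vals)["bin_class"]
        rev = classify_bin_changes(vals[1], vals[0], vals[3], vals[2])["bin_class"]
        swap = {"I": "IV", "II": "V", "III": "VI", "IV": "I", "V": "II", "VI": "III",
                "mixed": "mixed", "unchanged": "unchanged"}
        assert (rev == fwd.map(swap)).all()

    def test_agrees_with_per_bin_reimplementation(self):
        rng = np.random.default_rng(3)
        vals = [series(rng.exponential(2, 1000)) for _ in range(4)]
        got = classify_bin_changes(*vals)["bin_class"]

        def one(k27w, k27k, ubw, ubk, up=2.0, down=2.0, floor=2.0, c=0.5):
            def call(w, k):
                u = (k + c) / (w + c) >= up and k >= floor
                d = (w + c) / (k + c) >= down and w >= floor
                return "up" if u and not d else "down" if d and not u else "none"

            m = {("up", "none"): "I", ("up", "up"): "II", ("none", "up"): "III",
                 ("down", "none"): "IV", ("down", "down"): "V", ("none", "down"): "VI",
                 ("up", "down"): "mixed", ("down", "up"): "mixed", ("none", "none"): "unchanged"}
            return m[(call(k27w, k27k), call(ubw, ubk))]

        expected = [
            one(*(v.iloc[i] for v in vals)) for i in range(1000)
        ]
        assert list(got) == expected

    def test_single_mark_classes_swap_under_relabelling(self):
        rng = np.random.default_rng(4)
        wt, ko = series(rng.exponential(2, 500)), series(rng.exponential(2, 500))
        fwd = integrate.bin_mark_change_classes(wt, ko)
        rev = integrate.bin_mark_change_classes(ko, wt)
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert (rev == fwd.map(swap)).all()


class TestStudentsT:
    def test_closed_form_unpaired(self):
        res = students_t_test([1, 2, 3], [4, 5, 6], "unpaired")
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.pvalue == pytest.approx(0.0213, abs=2e-3)

    def test_identical_paired_vectors(self):
        res = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_zero_variance_unequal_means(self):
        res = students_t_test([1.0, 1.0], [2.0, 2.0], "unpaired")
        assert res.pvalue > 0  # underflow-safe minimum, not literal zero
        assert res.pvalue < 1e-300

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal"):
            students_t_test([1, 2, 3], [1, 2], "paired")

    def test_pvalue_within_bounds_property(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            res = students_t_test(x, y, "unpaired")
            assert 0 < res.pvalue <= 1

    def test_agrees_with_permutation_oracle(self):
        """Unpaired p within 0.02 of a 20,000-rep permutation p, 50 cases."""
        rng = np.random.default_rng(6)
        n_rep = 20_000
        for _ in range(50):
            nx = int(rng.integers(8, 16))
            ny = int(rng.integers(8, 16))
            x = rng.normal(0, 1, nx)
            y = rng.normal(rng.uniform(-1.5, 1.5), 1, ny)
            res = students_t_test(x, y, "unpaired")
            pooled = np.concatenate([x, y])
            perms = np.argsort(rng.random((n_rep, nx + ny)), axis=1)
            shuffled = pooled[perms]
            xs, ys = shuffled[:, :nx], shuffled[:, nx:]
            sp2 = ((nx - 1) * xs.var(axis=1, ddof=1) + (ny - 1) * ys.var(axis=1, ddof=1)) / (
                nx + ny - 2
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = (xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(
                    sp2 * (1 / nx + 1 / ny)
                )
            p_perm = np.mean(np.abs(t_perm) >= abs(res.statistic) - 1e-12)
            assert abs(res.pvalue - p_perm) < 0.02


class TestCovariates:
    def test_planted_methylation_contrast_and_expression_repression(self, small_cfg, small_sim):
        from epimap import chip, methylome

        annotation, truth, readsets, callsets, expression = small_sim
        bins = [
            b for b in chip.make_bins(annotation, small_cfg.bin_size)
            if b.chrom != small_cfg.lambda_chrom
        ]
        meth = {
            c.genotype: methylome.site_levels(c)
            for c in callsets
            if c.sample_id.endswith("rep1")
        }
        res = integrate.bin_class_covariates(
            truth.bin_class,
            bins,
            meth_sites=meth,
            expression=expression,
            genes=annotation.genes,
        )
        s = res.summaries.set_index(["bin_class", "covariate", "genotype"])
        gain_wt = s.loc[("I", "methylation", "WT"), "median"]
        loss_wt = s.loc[("IV", "methylation", "WT"), "median"]
        assert gain_wt > loss_wt  # gain classes sit in hypermethylated domains
        t = res.tests.set_index(["bin_class", "covariate"])
        assert t.loc[("I", "methylation"), "p"] < 0.01  # KO methylation loss

    def test_empty_class_reported_without_test(self):
        bins = []
        classes = pd.Series(dtype=object)
        res = integrate.bin_class_covariates(classes, bins, meth_sites=None)
        assert res.summaries.empty or res.summaries["n"].eq(0).all()


class TestMethylationProfile:
    def test_uniform_methylation_gives_flat_profiles(self):
        from epimap.core import GeneModel, GenomicInterval
        from epimap.methylome import SiteLevelTable

        genes = [GeneModel("g1", GenomicInterval("chr1", 10_000, 20_000, "+"))]
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(5_000, 25_000, 50),
                "context": "CpG",
                "coverage": 10,
                "level": 0.7,
            }
        )
        states = pd.DataFrame({"state": ["K4"]}, index=["g1"])
        prof = integrate.methylation_profile_by_tss_state(
            SiteLevelTable(df, 0), states, genes
        )
        np.testing.assert_allclose(prof["K4"], 0.7, atol=1e-12)

    def test_cgi_promoter_dip_for_k4_genes(self, small_cfg, small_sim):
        from epimap import methylome

        annotation, truth, _, callsets, _ = small_sim
        wt = methylome.site_levels(next(c for c in callsets if c.genotype == "WT"))
        states = pd.DataFrame({"state": truth.promoter_state})
        prof = integrate.methylation_profile_by_tss_state(
            wt, states, annotation.genes, window=4000, step=400
        )
        centre = prof["K4"][(prof["offset"] >= -400) & (prof["offset"] < 400)].mean()
        edge = prof["K4"][(prof["offset"] < -3000) | (prof["offset"] >= 3000)].mean()
        assert centre < edge  # CGI hypomethylation dips at the TSS

    def test_empty_states_omitted(self):
        from epimap.core import GeneModel, GenomicInterval
        from epimap.methylome import SiteLevelTable

        genes = [GeneModel("g1", GenomicInterval("chr1", 10_000, 20_000, "+"))]
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [10_100], "context": ["CpG"], "coverage": [5], "level": [0.5]}
        )
        states = pd.DataFrame({"state": ["K27"]}, index=["g1"])
        prof = integrate.methylation_profile_by_tss_state(SiteLevelTable(df, 0), states, genes)
        assert "K4" not in prof.columns and "K27" in prof.columns
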