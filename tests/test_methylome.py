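"""Cytosine contexts, methylation levels, element/ICR aggregation, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epimap import methylome
from epimap.core import GenomeAnnotation, GenomicInterval, GeneModel, MethylationCallSet
from epimap.methylome import (
    SiteLevelTable,
    aggregate_by_element,
    classify_cytosine_context,
    cluster_samples_by_cpg,
    conversion_efficiency,
    global_levels_by_context,
    icr_levels,
    site_levels,
)
from epimap.simulate import build_toy_genome, plant_truth, simulate_wgbs

from conftest import small_config


def calls_from(rows, sample_id="s", genotype="WT"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "context", "methylated", "unmethylated"])
    return MethylationCallSet(df, sample_id, genotype)


def table_from(levels, chrom="chr1", context="CpG", coverage=10, start=0, spacing=10):
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(start, start + spacing * len(levels), spacing),
            "context": context,
            "coverage": coverage,
            "level": levels,
        }
    )
    return SiteLevelTable(df, 0)


class TestContextClassification:
    @pytest.mark.parametrize(
        "tri,expected",
        [
            ("CGA", "CpG"), ("CGG", "CpG"), ("CGT", "CpG"), ("CGC", "CpG"),
            ("CAG", "CHG"), ("CTG", "CHG"), ("CCG", "CHG"),
            ("CTT", "CHH"), ("CAC", "CHH"), ("CCA", "CHH"),
        ],
    )
    def test_definition(self, tri, expected):
        assert classify_cytosine_context(tri) == expected

    @pytest.mark.parametrize("tri", ["AGT", "CGN", "CG", "cgxx"])
    def test_invalid_input_rejected(self, tri):
        with pytest.raises(ValueError):
            classify_cytosine_context(tri)

    def test_lowercase_accepted(self):
        assert classify_cytosine_context("cag") == "CHG"


class TestSiteLevels:
    def test_level_is_methylated_fraction(self):
        st = site_levels(calls_from([("chr1", 5, "CpG", 5, 5)]))
        assert st.table["level"].iloc[0] == 0.5

    def test_fully_unmethylated(self):
        st = site_levels(calls_from([("chr1", 5, "CpG", 0, 10)]))
        assert st.table["level"].iloc[0] == 0.0

    def test_min_coverage_drops_and_counts(self):
        st = site_levels(
            calls_from([("chr1", 5, "CpG", 2, 1), ("chr1", 9, "CpG", 5, 5)]),
            min_coverage=5,
        )
        assert len(st.table) == 1
        assert st.n_dropped == 1


class TestGlobalLevels:
    def test_mean_over_sites(self):
        st = table_from([0.0, 1.0])
        out = global_levels_by_context(st)
        assert out.loc["CpG", "mean"] == 0.5

    def test_absent_context_is_missing_not_zero(self):
        out = global_levels_by_context(table_from([0.4, 0.6]))
        assert "CHG" not in out.index

    def test_simulated_domain_mean_within_3_se(self):
        rng = np.random.default_rng(5)
        cov = 30
        meth = rng.binomial(cov, 0.8, size=2000)
        st = table_from(meth / cov, coverage=cov)
        out = global_levels_by_context(st)
        se = np.sqrt(0.8 * 0.2 / (cov * 2000))
        assert abs(out.loc["CpG", "mean"] - 0.8) < 3 * se


def brute_force_element_means(table, elements):
    """Per-site loop oracle: unweighted mean per element, intergenic = rest."""
    sums = {e: 0.0 for e in elements}
    counts = {e: 0 for e in elements}
    inter_sum = inter_n = 0
    for row in table.itertuples(index=False):
        if row.context != "CpG":
            continue
        hit = False
        for e, ivs in elements.items():
            for iv in ivs:
                if iv.chrom == row.chrom and iv.start <= row.pos < iv.end:
                    sums[e] += row.level
                    counts[e] += 1
                    hit = True
                    break
        if not hit:
            inter_sum += row.level
            inter_n += 1
    out = {e: (sums[e] / counts[e] if counts[e] else np.nan) for e in elements}
    out["intergenic"] = inter_sum / inter_n if inter_n else np.nan
    return out


class TestAggregateByElement:
    def test_cgi_mean_of_two_sites(self):
        ann = GenomeAnnotation(
            {"chr1": 1000}, cgis=[GenomicInterval("chr1", 0, 100, name="cgi1")]
        )
        st = table_from([0.2, 0.4], spacing=10)
        out = aggregate_by_element(st, ann)
        assert out.loc["CGI", "mean_level"] == pytest.approx(0.3)

    def test_site_outside_elements_is_intergenic_only(self):
        ann = GenomeAnnotation(
            {"chr1": 1000}, cgis=[GenomicInterval("chr1", 0, 5, name="cgi1")]
        )
        st = table_from([0.9], start=500)
        out = aggregate_by_element(st, ann)
        assert out.loc["intergenic", "n_sites"] == 1
        assert out.loc["CGI", "n_sites"] == 0

    def test_agrees_with_per_site_loop_oracle(self):
        rng = np.random.default_rng(6)
        genes = [
            GeneModel(f"g{i}", GenomicInterval("chr1", 10_000 * i + 2_000, 10_000 * i + 8_000, "+"))
            for i in range(5)
        ]
        ann = GenomeAnnotation(
            {"chr1": 100_000},
            genes=genes,
            cgis=[GenomicInterval("chr1", 1_000, 3_000, name="c1")],
            repeats=[GenomicInterval("chr1", 50_000, 52_000, name="r1")],
        )
        n = 3_000
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": rng.integers(0, 100_000, size=n),
                "context": rng.choice(["CpG", "CHH"], size=n, p=[0.9, 0.1]),
                "coverage": 10,
                "level": rng.random(n),
            }
        )
        st = SiteLevelTable(df, 0)
        got = aggregate_by_element(st, ann)
        elements = {
            "promoter": [g.promoter(2000, 100_000) for g in genes],
            "gene_body": [g.body for g in genes],
            "CGI": ann.cgis,
            "repeat": ann.repeats,
        }
        expected = brute_force_element_means(df, elements)
        for element, mean in expected.items():
            np.testing.assert_allclose(got.loc[element, "mean_level"], mean, rtol=1e-12)

    def test_gene_body_hypermethylation_survives_pipeline(self, small_cfg, small_sim):
        annotation, truth, _, callsets, _ = small_sim
        wt = methylome.site_levels(
            next(c for c in callsets if c.genotype == "WT")
        ).restrict([c for c in annotation.chrom_sizes if c != small_cfg.lambda_chrom])
        out = aggregate_by_element(wt, annotation)
        # CGI promoters are planted hypomethylated; everything else follows domains
        assert out.loc["CGI", "mean_level"] < out.loc["gene_body", "mean_level"]


class TestIcrLevels:
    def _annotation(self):
        return GenomeAnnotation(
            {"chr1": 10_000},
            icrs=[
                GenomicInterval("chr1", 0, 100, name="icr1"),
                GenomicInterval("chr1", 5_000, 5_100, name="icr2"),
            ],
            icr_parent={"icr1": "maternal", "icr2": "paternal"},
        )

    def test_per_icr_mean(self):
        per_icr, _ = icr_levels(table_from([0.9, 0.7], spacing=10), self._annotation())
        assert per_icr.loc["icr1", "mean_level"] == pytest.approx(0.8)

    def test_uncovered_icr_is_missing_not_zero(self):
        per_icr, _ = icr_levels(table_from([0.9], start=0), self._annotation())
        assert np.isnan(per_icr.loc["icr2", "mean_level"])

    def test_planted_maternal_loss_recovered(self, small_cfg, small_sim):
        annotation, truth, _, callsets, _ = small_sim
        levels = {}
        for geno in ("WT", "KO"):
            st = methylome.site_levels(next(c for c in callsets if c.genotype == geno))
            per_icr, groups = icr_levels(st, annotation)
            levels[geno] = groups.loc["maternal", "mean"]
        n_sites = small_cfg.icr_length // small_cfg.site_spacing * small_cfg.frac_cpg
        se = np.sqrt(0.85 * 0.15 / (small_cfg.coverage * max(n_sites, 1)))
        assert abs(levels["WT"] - small_cfg.icr_maternal_level) < 4 * se
        expected_ko = small_cfg.icr_maternal_level - small_cfg.icr_ko_delta
        assert abs(levels["KO"] - expected_ko) < 4 * se


class TestConversionEfficiency:
    def test_definition(self):
        rows = [("chrL", i, "CpG", 0, 1) for i in range(995)]
        rows += [("chrL", 2000 + i, "CpG", 1, 0) for i in range(5)]
        st = site_levels(calls_from(rows))
        assert conversion_efficiency(st, "chrL") == pytest.approx(0.995)

    def test_all_unmethylated_gives_one(self):
        st = site_levels(calls_from([("chrL", 1, "CHH", 0, 10)]))
        assert conversion_efficiency(st, "chrL") == 1.0

    def test_no_lambda_sites_rejected(self):
        st = site_levels(calls_from([("chr1", 1, "CpG", 1, 1)]))
        with pytest.raises(ValueError):
            conversion_efficiency(st, "chrL")

    def test_unbiased_over_replicates(self):
        """Mean estimate over 200 simulated replicates sits within 3 SE of truth."""
        cfg = small_config(
            seed=11, chrom_length=500_000, n_genes=10, n_icrs=1, site_spacing=5_000
        )
        ann = build_toy_genome(cfg)
        truth = plant_truth(cfg, ann)
        estimates = []
        for r in range(200):
            cs = simulate_wgbs(truth, ann, "WT", cfg, replicate=r)
            estimates.append(conversion_efficiency(site_levels(cs), cfg.lambda_chrom))
        estimates = np.array(estimates)
        p = 1 - cfg.conversion_efficiency_true
        n_calls = cfg.lambda_n_sites * cfg.coverage
        se_mean = np.sqrt(p * (1 - p) / n_calls) / np.sqrt(200)
        assert abs(estimates.mean() - cfg.conversion_efficiency_true) < 3 * se_mean


class TestClustering:
    def test_identical_samples_have_zero_distance(self):
        a = table_from(np.linspace(0, 1, 200))
        res = cluster_samples_by_cpg({"a": a, "b": a}, min_shared_sites=100)
        assert res.distance.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_shared_sites_rejected(self):
        a = table_from([0.1, 0.5, 0.9])
        with pytest.raises(ValueError, match="shared"):
            cluster_samples_by_cpg({"a": a, "b": a}, min_shared_sites=100)

    def test_constant_sample_rejected(self):
        a = table_from(np.linspace(0, 1, 200))
        b = table_from(np.full(200, 0.5))
        with pytest.raises(ValueError, match="undefined correlation"):
            cluster_samples_by_cpg({"a": a, "b": b}, min_shared_sites=100)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cluster_samples_by_cpg({"a": table_from([0.5, 0.7])})

    def test_genotypes_separate_at_k2(self, small_sim):
        _, _, _, callsets, _ = small_sim
        tables = {c.sample_id: site_levels(c) for c in callsets}
        res = cluster_samples_by_cpg(tables)
        wt = {res.labels[s] for s in res.samples if s.startswith("WT")}
        ko = {res.labels[s] for s in res.samples if s.startswith("KO")}
        assert len(wt) == 1 and len(ko) == 1 and wt != ko

    def test_newick_contains_all_samples(self, small_sim):
        _, _, _, callsets, _ = small_sim
        tables = {c.sample_id: site_levels(c) for c in callsets}
        res = cluster_samples_by_cpg(tables)
        assert res.newick.endswith(";")
        for s in res.samples:
            assert s in res.newick
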