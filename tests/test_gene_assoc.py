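"""Gene-level association stage: filtering, windows, LD, scores, orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from tissuenet import (
    SimulationConfig,
    ar1_ld_source,
    bonferroni_threshold,
    filter_common,
    gene_score,
    ld_from_panel,
    map_variants_to_genes,
    run_gene_assoc,
    set_test,
    simulate_all,
    simulate_dosage_panel,
)
from tissuenet.gene_assoc import ar1_corr


def _variants(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "freq", "z"])


class TestFilterCommon:
    def test_maf_boundary_is_inclusive(self):
        v = _variants([(f"v{i}", "1", 100 + i, f, 0.0)
                       for i, f in enumerate([0.005, 0.01, 0.3])])
        kept = filter_common(v, maf_min=0.01)
        assert kept["variant_id"].tolist() == ["v1", "v2"]

    def test_empty_and_all_pass(self):
        v = _variants([("v0", "1", 1, 0.2, 0.0)])
        assert len(filter_common(v.iloc[:0])) == 0
        pd.testing.assert_frame_equal(filter_common(v), v)

    def test_missing_freq_column_named_in_error(self):
        with pytest.raises(ValueError, match="freq"):
            filter_common(pd.DataFrame({"variant_id": ["v0"], "z": [1.0]}))


class TestWindows:
    genes = pd.DataFrame(
        [{"gene_id": "GA", "chrom": "1", "start": 100_000, "end": 200_000}]
    )

    def test_flank_boundary_closed(self):
        v = _variants([("in", "1", 50_000, 0.3, 0.0), ("out", "1", 49_999, 0.3, 0.0)])
        windows = map_variants_to_genes(v, self.genes, flank=50_000)
        assert windows == {"GA": ["in"]}

    def test_variant_between_close_genes_joins_both_windows(self):
        genes = pd.DataFrame([
            {"gene_id": "GA", "chrom": "1", "start": 10_000, "end": 20_000},
            {"gene_id": "GB", "chrom": "1", "start": 50_000, "end": 60_000},
        ])  # 30 kb apart: a variant between them lies in both 50 kb windows
        v = _variants([("mid", "1", 35_000, 0.3, 0.0)])
        windows = map_variants_to_genes(v, genes, flank=50_000)
        assert windows == {"GA": ["mid"], "GB": ["mid"]}

    def test_chromosome_mismatch_reported(self):
        v = _variants([("v0", "chr1", 100, 0.3, 0.0)])
        with pytest.raises(ValueError, match="chromosome"):
            map_variants_to_genes(v, self.genes)

    def test_duplicate_variant_ids_keep_first_with_warning(self):
        v = _variants([("dup", "1", 150_000, 0.3, 0.0), ("dup", "1", 160_000, 0.3, 0.0)])
        with pytest.warns(UserWarning, match="duplicate"):
            windows = map_variants_to_genes(v, self.genes)
        assert windows == {"GA": ["dup"]}


class TestLDFromPanel:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        panel = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        R, ids = ld_from_panel(panel, ["a", "b", "c"])
        assert ids == ["a", "b", "c"]
        assert R[0, 1] == pytest.approx(1.0)

    def test_independent_columns_have_small_correlation(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["a", "b"])
        R, _ = ld_from_panel(panel, ["a", "b"])
        assert abs(R[0, 1]) < 0.05

    def test_monomorphic_column_dropped_with_warning(self):
        panel = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="monomorphic"):
            R, ids = ld_from_panel(panel, ["a", "b"])
        assert ids == ["a"] and R.shape == (1, 1)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            ld_from_panel(pd.DataFrame({"a": [1.0]}), ["a"])

    def test_copula_panel_recovers_ar1_ld(self):
        """The dosage-panel emitter produces LD close to the target AR(1)."""
        config = SimulationConfig(n_genes=4, n_variants_per_gene=(8, 8),
                                  planted_module_size=2, set_size=3,
                                  ld_rho=0.6, seed=5)
        study = simulate_all(config)
        panel = simulate_dosage_panel(study.variants, config, n_samples=4000)
        vids = study.variants.loc[study.variants["gene_id"] == "G0000",
                                  "variant_id"].tolist()
        R, _ = ld_from_panel(panel, vids)
        k = len(vids)
        # copula + binomial(2, f) marginals attenuate correlation, so check
        # the AR(1) shape rather than exact values: positive, decaying by lag
        lag1 = np.mean([R[i, i + 1] for i in range(k - 1)])
        lag3 = np.mean([R[i, i + 3] for i in range(k - 3)])
        assert 0.3 < lag1 < 0.7
        assert lag3 < lag1
        assert np.max(np.abs(R - ar1_corr(k, 0.6))) < 0.3


class TestSetTest:
    def test_trace_identity(self):
        R = ar1_corr(6, 0.4)
        _, lam, _, _ = set_test(np.ones(6), R)
        assert lam.sum() == pytest.approx(6.0, abs=1e-8)

    def test_dimension_mismatch_and_nonfinite(self):
        with pytest.raises(ValueError, match="mismatch"):
            set_test(np.ones(3), np.eye(2))
        with pytest.raises(ValueError, match="finite"):
            set_test(np.array([np.nan]), np.eye(1))

    def test_statistic_is_sum_of_squares(self):
        z = np.array([1.0, -2.0, 0.5])
        T, _, _, _ = set_test(z, np.eye(3))
        assert T == pytest.approx(5.25)


class TestGeneScore:
    def test_median_and_boundary(self):
        assert gene_score(0.5) == pytest.approx(0.0, abs=1e-12)
        assert gene_score(1.0) == 0.0  # floored for module scoring
        assert gene_score(1.0, nonnegative=False) < -35

    def test_matches_normal_quantile(self):
        assert gene_score(0.0228) == pytest.approx(norm.isf(0.0228), rel=1e-12)
        assert gene_score(0.0228) == pytest.approx(2.0, abs=5e-3)

    def test_tiny_p_capped(self):
        assert gene_score(1e-320) == pytest.approx(norm.isf(1e-300))
        assert gene_score(1e-320) < 37.1

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            gene_score(bad)


class TestBonferroni:
    def test_published_scale(self):
        """alpha=0.05 over 26,228 tests gives 1.91e-6 at 3 significant figures."""
        t = bonferroni_threshold(0.05, 26_228)
        assert f"{t:.3g}" == "1.91e-06"

    def test_identity_and_proportionality(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 2 * 26_228) == pytest.approx(
            bonferroni_threshold(0.05, 26_228) / 2
        )

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRunGeneAssoc:
    def test_null_gene_pvalues_uniform(self):
        config = SimulationConfig(n_genes=300, noncentrality=0.0, seed=21)
        study = simulate_all(config)
        assoc = run_gene_assoc(study.variants, study.genes,
                               ar1_ld_source(config.ld_rho))
        assert len(assoc) == 300
        assert kstest(assoc["p"], "uniform").pvalue > 0.01

    def test_planted_genes_flagged_and_best_variant_minimal(self, small_planted_study):
        study = small_planted_study
        assoc = run_gene_assoc(study.variants, study.genes,
                               ar1_ld_source(study.config.ld_rho))
        sig = set(assoc.loc[assoc["significant"], "gene_id"])
        assert study.truth.causal_genes <= sig
        # reported best variant is the window's minimum variant p
        top = assoc.iloc[0]
        window = study.variants[study.variants["gene_id"] == top["gene_id"]]
        assert top["best_variant_p"] == pytest.approx(window["p"].min())

    def test_gene_without_variants_absent(self):
        genes = pd.DataFrame([
            {"gene_id": "GA", "chrom": "1", "start": 1, "end": 10},
            {"gene_id": "FAR", "chrom": "1", "start": 10**7, "end": 10**7 + 10},
        ])
        v = _variants([("v0", "1", 5, 0.3, 1.0)])
        assoc = run_gene_assoc(v, genes, ar1_ld_source(0.0), flank=100)
        assert assoc["gene_id"].tolist() == ["GA"]

    def test_single_variant_gene_p_equals_variant_p(self):
        genes = pd.DataFrame([{"gene_id": "GA", "chrom": "1", "start": 1, "end": 10}])
        v = _variants([("v0", "1", 5, 0.3, 1.7)])
        assoc = run_gene_assoc(v, genes, ar1_ld_source(0.5), flank=100)
        assert assoc.loc[0, "p"] == pytest.approx(2 * norm.sf(1.7), abs=1e-12)
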