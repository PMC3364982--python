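"""Genome-scan machinery: LRS algebra, thresholds, intervals, two-locus fits."""

import io
import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from lickqtl.genome import parse_geno, uniform_map
from lickqtl.scan import (
    bootstrap_peak, composite_scan, fit_two_qtl, genomewide_p,
    lod_drop_interval, lrs_to_lod, pairwise_scan, permutation_thresholds,
    scan_single, variance_explained, ScanResult, interval_dosage,
)
from lickqtl.simulate import (
    GeneratorConfig, QTLSpec, simulate_ri_genotypes, simulate_strain_phenotypes,
)
from conftest import make_geno


def brute_force_lrs(y, x):
    """Independent two-group least-squares oracle: n*ln(RSS0/RSS1)."""
    mask = ~np.isnan(x)
    y, x = np.asarray(y, float)[mask], np.asarray(x, float)[mask]
    n = y.size
    rss0 = np.sum((y - y.mean()) ** 2)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss1 = np.sum((y - X @ beta) ** 2)
    return n * np.log(rss0 / rss1), beta[1]


class TestParseGeno:
    GENO = (
        "@type:riset\n"
        "Chr\tLocus\tcM\tMb\tS1\tS2\n"
        "1\tmA\t0\t3\tB\tD\n"
        "1\tmB\t10\t20\tH\tD\n"
    )

    def test_minimal_file(self):
        g = parse_geno(io.StringIO(self.GENO))
        assert g.strains == ["S1", "S2"]
        assert g.codes.shape == (2, 2)
        assert g.metadata["type"] == "riset"

    def test_h_is_missing_in_dosage(self):
        g = parse_geno(io.StringIO(self.GENO))
        d = g.dosage("mB")
        assert np.isnan(d[0]) and d[1] == 1.0

    def test_invalid_code_named_in_error(self):
        bad = self.GENO.replace("\tH\t", "\tX\t")
        with pytest.raises(ValueError, match="mB"):
            parse_geno(io.StringIO(bad))

    def test_duplicate_marker_rejected(self):
        bad = self.GENO.replace("mB", "mA")
        with pytest.raises(ValueError, match="duplicate"):
            parse_geno(io.StringIO(bad))


class TestScanSingle:
    def test_closed_form_two_group_example(self):
        # pheno [1,2,3,4] on [B,B,D,D]: RSS0 = 5, RSS1 = 1 -> LRS = 4 ln 5
        geno = make_geno(["B", "B", "D", "D"])
        pheno = pd.Series([1.0, 2, 3, 4], index=geno.strains)
        res = scan_single(pheno, geno, mode="marker", min_strains=4)
        row = res.table.iloc[0]
        assert row["LRS"] == pytest.approx(4 * np.log(5.0), abs=1e-9)
        assert row["additive_effect"] == pytest.approx(1.0)
        assert row["LOD"] == pytest.approx(row["LRS"] / (2 * np.log(10)), abs=1e-12)

    def test_constant_phenotype_zero_everywhere(self):
        geno = make_geno(["BD", "BB", "DB", "DD", "BD", "DB", "BB", "DD"])
        pheno = pd.Series(np.ones(8), index=geno.strains)
        res = scan_single(pheno, geno)
        assert np.allclose(res.table["LRS"].dropna(), 0.0)

    def test_equal_group_means_zero_lrs(self):
        geno = make_geno(["B", "B", "D", "D"])
        pheno = pd.Series([1.0, 2, 1, 2], index=geno.strains)
        res = scan_single(pheno, geno, min_strains=4)
        assert res.table["LRS"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_locus_skipped(self):
        geno = make_geno(["BB", "BD", "BB", "BD"])  # marker 0 monomorphic
        pheno = pd.Series([1.0, 2, 3, 4], index=geno.strains)
        res = scan_single(pheno, geno, min_strains=4)
        assert np.isnan(res.table["LRS"].iloc[0])
        assert res.table["flag"].iloc[0] == "degenerate"

    def test_missing_genotypes_dropped_per_locus(self):
        geno = make_geno(["B", "B", "B", "D", "D", "U"])
        y = np.array([1.0, 2, 3, 7, 8, 100.0])  # strain with U ignored
        pheno = pd.Series(y, index=geno.strains)
        res = scan_single(pheno, geno, mode="marker", min_strains=5)
        expected, _ = brute_force_lrs(y, geno.dosage("m0"))
        assert res.table["n"].iloc[0] == 5
        assert res.table["LRS"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_oracle_equivalence_random_panels(self):
        # scan LRS == independent two-group regression oracle, 100 panels
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(8, 16)
            codes = rng.choice(["B", "D"], size=(n, 3))
            # ensure polymorphic markers
            codes[0, :], codes[1, :] = "B", "D"
            geno = make_geno(["".join(r) for r in codes])
            pheno = pd.Series(rng.normal(size=n), index=geno.strains)
            res = scan_single(pheno, geno)
            for j in range(3):
                exp_lrs, exp_slope = brute_force_lrs(
                    pheno.to_numpy(), geno.dosage()[:, j])
                assert res.table["LRS"].iloc[j] == pytest.approx(exp_lrs, abs=1e-9)
                assert res.table["additive_effect"].iloc[j] == pytest.approx(
                    exp_slope, abs=1e-9)

    def test_perfect_fit_capped_not_infinite(self):
        geno = make_geno(["B", "B", "B", "B", "D", "D", "D", "D"])
        pheno = pd.Series([1.0, 1, 1, 1, 2, 2, 2, 2], index=geno.strains)
        res = scan_single(pheno, geno)
        row = res.table.iloc[0]
        assert np.isfinite(row["LRS"]) and row["flag"] == "perfect_fit"

    def test_too_few_strains_rejected(self):
        geno = make_geno(["B", "D", "B"])
        with pytest.raises(ValueError, match=">= 8"):
            scan_single(pd.Series([1.0, 2, 3], index=geno.strains), geno)


class TestIntervalMode:
    def test_marker_positions_use_observed_dosage(self):
        geno = make_geno(["BD", "DB", "BB", "DD"] * 2, cM=[0.0, 10.0])
        info, D = interval_dosage(geno, np.arange(8), grid_cM=1.0)
        marker_cols = info["is_marker"].to_numpy()
        obs = geno.dosage()
        assert np.allclose(D[:, marker_cols], obs)

    def test_pseudomarker_dosage_between_concordant_flanks(self):
        geno = make_geno(["BB", "DD"] * 4, cM=[0.0, 10.0])
        info, D = interval_dosage(geno, np.arange(8), grid_cM=5.0)
        mid = ~info["is_marker"].to_numpy()
        # concordant flanks pull E[x] toward the shared allele
        assert np.all(D[0, mid] < -0.9)  # B/B flanks
        assert np.all(D[1, mid] > 0.9)  # D/D flanks

    def test_discordant_flanks_give_intermediate_dosage(self):
        geno = make_geno(["BD"] * 8, cM=[0.0, 10.0])
        info, D = interval_dosage(geno, np.arange(8), grid_cM=5.0)
        mid = ~info["is_marker"].to_numpy()
        assert np.all(np.abs(D[:, mid]) < 0.5)

    def test_interval_scan_runs_and_contains_markers(self):
        gmap = uniform_map(n_chrom=2, markers_per_chrom=4, spacing_cM=10.0)
        geno = simulate_ri_genotypes(gmap, 20, seed=3)
        pheno = pd.Series(np.random.default_rng(0).normal(size=20),
                          index=geno.strains)
        res = scan_single(pheno, geno, mode="interval", grid_cM=2.0)
        assert res.table["is_marker"].sum() == len(gmap)
        assert len(res.table) > len(gmap)


class TestLodConversion:
    def test_printed_pair(self):
        # LRS 25.2 corresponds to LOD 5.5 at one decimal
        assert round(lrs_to_lod(25.2), 1) == 5.5
        assert lrs_to_lod(25.2) == pytest.approx(25.2 / (2 * np.log(10)))

    def test_zero_and_unit(self):
        assert lrs_to_lod(0.0) == 0.0
        assert lrs_to_lod(2 * np.log(10)) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lrs_to_lod(-1.0)


@pytest.fixture(scope="module")
def panel():
    gmap = uniform_map(n_chrom=3, markers_per_chrom=10, spacing_cM=5.0)
    geno = simulate_ri_genotypes(gmap, 25, seed=8)
    pheno = pd.Series(np.random.default_rng(8).normal(size=25),
                      index=geno.strains)
    return geno, pheno


class TestPermutations:

    def test_threshold_ordering(self, panel):
        geno, pheno = panel
        thr = permutation_thresholds(pheno, geno, n_perm=500, seed=1)
        assert thr.significant >= thr.suggestive

    def test_seed_reproducibility(self, panel):
        geno, pheno = panel
        a = permutation_thresholds(pheno, geno, n_perm=300, seed=5)
        b = permutation_thresholds(pheno, geno, n_perm=300, seed=5)
        assert a.significant == b.significant
        assert np.array_equal(a.null_max_lrs, b.null_max_lrs)

    def test_missing_genotype_fallback_matches_dense(self, panel):
        geno, pheno = panel
        dense = permutation_thresholds(pheno, geno, n_perm=500, seed=3)
        geno2 = replace_code(geno)  # one U code forces the per-locus path
        sparse = permutation_thresholds(pheno, geno2, n_perm=500, seed=3)
        # same null up to one locus losing one strain and a different
        # permutation stream: thresholds agree statistically
        assert abs(dense.significant - sparse.significant) < 3.0

    def test_min_permutations_enforced(self, panel):
        geno, pheno = panel
        with pytest.raises(ValueError):
            permutation_thresholds(pheno, geno, n_perm=50, seed=1)

    def test_genomewide_p_extremes(self):
        null = np.arange(100, dtype=float)
        assert genomewide_p(1000.0, null) == pytest.approx(1 / 101)
        assert genomewide_p(-1.0, null) == pytest.approx(1.0)
        assert genomewide_p(float(np.median(null)), null) == pytest.approx(
            0.5, abs=0.02)


def replace_code(geno):
    codes = geno.codes.copy()
    codes[0, 0] = "U"
    from lickqtl.genome import GenotypeMatrix
    return GenotypeMatrix(strains=geno.strains, gmap=geno.gmap, codes=codes)


class TestLodDropInterval:
    @staticmethod
    def _scan_from_lod(lods, chrom="1"):
        n = len(lods)
        table = pd.DataFrame({
            "locus": [f"m{i}" for i in range(n)], "chrom": chrom,
            "cM": np.arange(n, dtype=float), "Mb": 2.0 * np.arange(n),
            "n": 10, "LRS": np.array(lods) * 2 * np.log(10),
            "LOD": np.array(lods, dtype=float),
            "additive_effect": 0.0, "flag": "",
        })
        return ScanResult(table=table)

    def test_triangular_profile(self):
        # peak LOD 5, slope 0.5/locus: 1.5 drop spans 3 loci either side
        lods = [5 - 0.5 * abs(i - 6) for i in range(13)]
        iv = lod_drop_interval(self._scan_from_lod(lods), drop=1.5)
        assert iv.left_cM == 3.0 and iv.right_cM == 9.0

    def test_peak_at_chromosome_end(self):
        lods = [5.0, 4.0, 3.0, 2.0, 1.0]
        iv = lod_drop_interval(self._scan_from_lod(lods), drop=1.5)
        assert iv.left_cM == 0.0 and iv.right_cM == 1.0

    def test_flat_profile_spans_chromosome(self):
        iv = lod_drop_interval(self._scan_from_lod([2.0] * 6), drop=1.5)
        assert iv.left_cM == 0.0 and iv.right_cM == 5.0


class TestBootstrap:
    def test_frequencies_sum_to_one_and_reproduce(self):
        gmap = uniform_map(n_chrom=2, markers_per_chrom=5, spacing_cM=10.0)
        geno = simulate_ri_genotypes(gmap, 20, seed=4)
        pheno = pd.Series(np.random.default_rng(4).normal(size=20),
                          index=geno.strains)
        f1 = bootstrap_peak(pheno, geno, n_boot=200, seed=9)
        f2 = bootstrap_peak(pheno, geno, n_boot=200, seed=9)
        assert f1.sum() == pytest.approx(1.0)
        assert f1.equals(f2)

    def test_strong_qtl_dominates_peak_position(self):
        gmap = uniform_map(n_chrom=3, markers_per_chrom=5, spacing_cM=15.0)
        geno = simulate_ri_genotypes(gmap, 40, seed=5)
        planted = gmap.names[7]
        cfg = GeneratorConfig(n_strains=40, mice_per_strain=1,
                              sigma2_strain=1.0, sigma2_env=0.0,
                              qtls=(QTLSpec(planted, 8.0),), seed=5)
        tab = simulate_strain_phenotypes(geno, cfg)
        pheno = tab.data.groupby("strain")["mpi"].mean()
        freq = bootstrap_peak(pheno, geno, n_boot=300, seed=6)
        assert freq.idxmax() == planted
        assert freq.max() > 0.8


@pytest.fixture(scope="module")
def two_qtl_panel():
    gmap = uniform_map(n_chrom=3, markers_per_chrom=6, spacing_cM=12.0)
    geno = simulate_ri_genotypes(gmap, 60, seed=12)
    m1, m2 = gmap.names[2], gmap.names[8]  # chromosomes 1 and 2
    cfg = GeneratorConfig(n_strains=60, mice_per_strain=1,
                          sigma2_strain=1.0, sigma2_env=0.0,
                          qtls=(QTLSpec(m1, 3.0), QTLSpec(m2, 2.0)),
                          seed=12)
    tab = simulate_strain_phenotypes(geno, cfg)
    pheno = tab.data.groupby("strain")["mpi"].mean()
    return geno, pheno, m1, m2


class TestCompositeScan:

    def test_controlled_marker_nullified(self, two_qtl_panel):
        geno, pheno, m1, _ = two_qtl_panel
        top = scan_single(pheno, geno).peak()["locus"]
        res = composite_scan(pheno, geno, [top])
        row = res.table[res.table["locus"] == top].iloc[0]
        assert row["LRS"] < 1e-6
        assert row["flag"] == "collinear"

    def test_uncontrolled_locus_preserved(self):
        # two exactly orthogonal loci, controlled marker explaining little
        # variance: the other's composite LRS stays within 10% of its
        # single-scan value, and is never reduced below it
        codes = ["BB", "BD", "DB", "DD"] * 50
        geno = make_geno(codes, chrom=["1", "2"], cM=[0.0, 0.0])
        x1 = np.array([-1 if c[0] == "B" else 1 for c in codes], float)
        x2 = np.array([-1 if c[1] == "B" else 1 for c in codes], float)
        rng = np.random.default_rng(17)
        pheno = pd.Series(0.5 * x1 + 2.0 * x2 + rng.normal(0, 3.0, len(codes)),
                          index=geno.strains)
        single = scan_single(pheno, geno)
        comp = composite_scan(pheno, geno, ["m0"])
        lrs_single = single.table.set_index("locus").loc["m1", "LRS"]
        lrs_comp = comp.table.set_index("locus").loc["m1", "LRS"]
        assert lrs_comp == pytest.approx(lrs_single, rel=0.10)
        assert lrs_comp >= lrs_single - 1e-9

    def test_no_controls_identical_to_single_scan(self, two_qtl_panel):
        geno, pheno, *_ = two_qtl_panel
        a = scan_single(pheno, geno).table
        b = composite_scan(pheno, geno, []).table
        pd.testing.assert_frame_equal(a, b)


class TestTwoQTLFit:
    @staticmethod
    def _panel_from_design(y, codes):
        geno = make_geno(codes, chrom=["1", "2"], cM=[0.0, 0.0])
        pheno = pd.Series(y, index=geno.strains)
        return geno, pheno

    # all four diplotype classes twice -> full rank with interaction
    CODES = ["BB", "BD", "DB", "DD"] * 2

    def test_additive_data_zero_interaction(self):
        x1 = np.array([-1 if c[0] == "B" else 1 for c in self.CODES], float)
        x2 = np.array([-1 if c[1] == "B" else 1 for c in self.CODES], float)
        geno, pheno = self._panel_from_design(2.0 * x1 + 1.0 * x2, self.CODES)
        fit = fit_two_qtl(pheno, geno, "m0", "m1")
        assert fit.coefficients["i"] == pytest.approx(0.0, abs=1e-9)
        assert fit.interaction_LRS == pytest.approx(0.0, abs=1e-6)

    def test_pure_interaction_detected(self):
        y = np.array([(-1 if c[0] == "B" else 1) * (-1 if c[1] == "B" else 1)
                      for c in self.CODES], dtype=float)
        rng = np.random.default_rng(0)
        y = y + rng.normal(0, 1e-6, y.size)  # break exact degeneracy of RSS=0
        geno, pheno = self._panel_from_design(y, self.CODES)
        fit = fit_two_qtl(pheno, geno, "m0", "m1")
        assert fit.interaction_LRS == pytest.approx(fit.total_LRS, rel=1e-3)

    def test_exact_coefficient_recovery(self):
        # planted a1 = 2, a2 = 1, i = 0.5, no noise: exact linear solve
        x1 = np.array([-1 if c[0] == "B" else 1 for c in self.CODES], float)
        x2 = np.array([-1 if c[1] == "B" else 1 for c in self.CODES], float)
        y = 5.0 + 2.0 * x1 + 1.0 * x2 + 0.5 * x1 * x2
        geno, pheno = self._panel_from_design(y, self.CODES)
        fit = fit_two_qtl(pheno, geno, "m0", "m1")
        assert fit.coefficients["intercept"] == pytest.approx(5.0, abs=1e-9)
        assert fit.coefficients["a1"] == pytest.approx(2.0, abs=1e-9)
        assert fit.coefficients["a2"] == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients["i"] == pytest.approx(0.5, abs=1e-9)

    def test_confounded_interaction_dropped(self):
        codes = ["BB", "BD", "DB"] * 3  # no DD,DD class
        x1 = np.array([-1 if c[0] == "B" else 1 for c in codes], float)
        x2 = np.array([-1 if c[1] == "B" else 1 for c in codes], float)
        geno = make_geno(codes, chrom=["1", "2"], cM=[0.0, 0.0])
        pheno = pd.Series(x1 + x2 + np.linspace(0, 0.1, 9), index=geno.strains)
        fit = fit_two_qtl(pheno, geno, "m0", "m1")
        # x1*x2 with 3 classes: {+1,-1,-1} pattern is NOT collinear with
        # [1,x1,x2] here, so just assert the fit reports a coherent model
        assert fit.total_LRS >= fit.interaction_LRS >= 0

    def test_interaction_null_on_additive_panels(self):
        # median interaction LRS < 1.5 across replicates of additive truth
        gmap = uniform_map(n_chrom=2, markers_per_chrom=3, spacing_cM=20.0)
        m1, m2 = gmap.names[0], gmap.names[4]
        med = []
        for seed in range(60):
            geno = simulate_ri_genotypes(gmap, 30, seed=seed)
            cfg = GeneratorConfig(n_strains=30, mice_per_strain=1,
                                  sigma2_strain=1.0, sigma2_env=0.0,
                                  qtls=(QTLSpec(m1, 2.0), QTLSpec(m2, 1.0)),
                                  seed=seed)
            tab = simulate_strain_phenotypes(geno, cfg)
            pheno = tab.data.groupby("strain")["mpi"].mean()
            try:
                fit = fit_two_qtl(pheno, geno, m1, m2)
            except ValueError:
                continue
            med.append(fit.interaction_LRS)
        assert np.median(med) < 1.5


class TestPairwiseScan:
    def test_two_planted_qtls_top_pair(self):
        gmap = uniform_map(n_chrom=3, markers_per_chrom=4, spacing_cM=15.0)
        m1, m2 = gmap.names[1], gmap.names[6]
        hits = 0
        for seed in range(25):
            geno = simulate_ri_genotypes(gmap, 50, seed=seed)
            cfg = GeneratorConfig(n_strains=50, mice_per_strain=1,
                                  sigma2_strain=2.0, sigma2_env=0.0,
                                  qtls=(QTLSpec(m1, 3.0), QTLSpec(m2, 2.5)),
                                  seed=seed)
            tab = simulate_strain_phenotypes(geno, cfg)
            pheno = tab.data.groupby("strain")["mpi"].mean()
            pairs = pairwise_scan(pheno, geno, thin_cM=10.0, max_markers=50)
            top = {pairs.iloc[0]["marker1"], pairs.iloc[0]["marker2"]}
            hits += top == {m1, m2}
        assert hits / 25 >= 0.9

    def test_single_marker_phenotype_always_in_top_pairs(self):
        gmap = uniform_map(n_chrom=2, markers_per_chrom=3, spacing_cM=25.0)
        planted = gmap.names[1]
        geno = simulate_ri_genotypes(gmap, 40, seed=2)
        cfg = GeneratorConfig(n_strains=40, mice_per_strain=1,
                              sigma2_strain=0.2, sigma2_env=0.0,
                              qtls=(QTLSpec(planted, 5.0),), seed=2)
        tab = simulate_strain_phenotypes(geno, cfg)
        pheno = tab.data.groupby("strain")["mpi"].mean()
        pairs = pairwise_scan(pheno, geno, thin_cM=10.0)
        for _, row in pairs.head(3).iterrows():
            assert planted in (row["marker1"], row["marker2"])

    def test_marker_cap_enforced(self):
        gmap = uniform_map(n_chrom=4, markers_per_chrom=10, spacing_cM=5.0)
        geno = simulate_ri_genotypes(gmap, 20, seed=1)
        pheno = pd.Series(np.zeros(20), index=geno.strains)
        with pytest.raises(ValueError, match="cap"):
            pairwise_scan(pheno, geno, thin_cM=5.0, max_markers=10)


class TestVarianceExplained:
    def test_deterministic_marker_explains_all(self):
        geno = make_geno(["B", "B", "D", "D"] * 2)
        x = geno.dosage("m0")
        pheno = pd.Series(3.0 * x + 1.0, index=geno.strains)
        assert variance_explained(pheno, geno, "m0") == pytest.approx(1.0)

    def test_worked_r2(self):
        # duplicated [1,2,3,4] vs [B,B,D,D] design: R^2 = 1 - RSS1/RSS0
        # = 1 - 1/5 = 0.8 (duplication preserves the ratio)
        geno8 = make_geno(["B", "B", "D", "D"] * 2)
        pheno8 = pd.Series([1.0, 2, 3, 4] * 2, index=geno8.strains)
        assert variance_explained(pheno8, geno8, "m0") == pytest.approx(0.8)

    def test_degenerate_marker_rejected(self):
        geno = make_geno(["B"] * 8)
        pheno = pd.Series(np.arange(8.0), index=geno.strains)
        with pytest.raises(ValueError, match="degenerate"):
            variance_explained(pheno, geno, "m0")
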