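import numpy as np
import pandas as pd
import pytest

from longqtl import gwas
from longqtl.behavior import normalize_endpoint
from longqtl.panel import GenotypePanel, compute_grm
from longqtl.simulate import PanelDesign, TruthRecord, simulate_genotypes, simulate_longitudinal

from oracles import dense_gls_snp_test


def _panel_from_matrix(geno, bp=None, chrom="1"):
    n_strains, m = geno.shape
    snps = pd.DataFrame(
        {"chrom": chrom, "bp": bp if bp is not None else np.arange(1, m + 1) * 1000},
        index=pd.Index([f"s{j}" for j in range(m)], name="snp"),
    )
    return GenotypePanel(
        strain_ids=[f"st{i}" for i in range(n_strains)], snps=snps, genotypes=geno
    )


class TestFilterSnps:
    def test_maf_and_missing_thresholds(self):
        rng = np.random.default_rng(0)
        # 20 strains; col0 MAF 0.04 (below), col1 15% missing (above), col2 fine
        g0 = np.zeros(25)
        g0[0] = 2.0  # MAF 0.04
        g1 = rng.choice([0.0, 2.0], 25)
        g1[:4] = np.nan  # 16% missing
        g2 = rng.choice([0.0, 2.0], 25)
        panel = _panel_from_matrix(np.column_stack([g0, g1, g2]))
        out = gwas.filter_snps(panel)
        assert list(out.snps.index) == ["s2"]

    def test_count_by_enumeration(self):
        rng = np.random.default_rng(1)
        cols = [rng.choice([0.0, 2.0], 30) for _ in range(8)]
        bad_maf = np.zeros(30)
        bad_maf[0] = 2.0
        bad_miss = rng.choice([0.0, 2.0], 30)
        bad_miss[:5] = np.nan
        panel = _panel_from_matrix(np.column_stack(cols + [bad_maf, bad_miss]))
        out = gwas.filter_snps(panel)
        assert out.n_snps == 8
        assert out.filter_log["n_kept"] == 8

    def test_nothing_survives_errors(self):
        panel = _panel_from_matrix(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="no SNP"):
            gwas.filter_snps(panel)


@pytest.fixture(scope="module")
def fitted_null(tiny_panel, tiny_design, tiny_grm):
    truth = TruthRecord()
    table = simulate_longitudinal(tiny_panel, truth, tiny_design, grm=tiny_grm, seed=21)
    table = normalize_endpoint(table, "value")
    null = gwas.fit_null_model(table, tiny_grm, endpoint_col="value_norm")
    return table, null


class TestWaldScan:
    def test_matches_dense_gls_oracle(self, fitted_null, tiny_panel, tiny_grm):
        """Z agrees with brute-force GLS on the full dense covariance,
        including SNPs whose missing calls drop mice."""
        table, null = fitted_null
        scan = gwas.wald_scan(null, tiny_panel).set_index("snp")

        tab = table.dropna(subset=["value_norm"]).sort_values(["mouse_id", "day"])
        tab = tab.reset_index(drop=True)
        from longqtl.behavior import _design_matrix

        X, _ = _design_matrix(tab)
        y = tab["value_norm"].to_numpy()
        day = tab["day"].to_numpy(float)
        mouse_idx = pd.factorize(tab["mouse_id"])[0]
        mice = tab.drop_duplicates("mouse_id")
        K = tiny_grm.expand(mice["strain"].tolist())
        strain_of_mouse = mice["strain"].tolist()
        checked_complete = checked_missing = 0
        for snp in tiny_panel.snps.index[:25]:
            g_s = tiny_panel.dosage(snp)
            lookup = dict(zip(tiny_panel.strain_ids, g_s))
            g_mouse = np.array([lookup[s] for s in strain_of_mouse])
            g_obs = np.repeat(g_mouse, len(null.day))
            if np.nanstd(g_mouse) == 0:
                assert scan.loc[snp, "flag"] == "monomorphic"
                continue
            _, _, z_oracle = dense_gls_snp_test(
                y, X, g_obs, mouse_idx, day, K, null.fit.components
            )
            assert scan.loc[snp, "z"] == pytest.approx(z_oracle, abs=1e-6)
            if np.isnan(g_mouse).any():
                checked_missing += 1
            else:
                checked_complete += 1
        assert checked_complete > 0 and checked_missing > 0

    def test_duplicate_snp_identical_results(self, fitted_null, tiny_panel):
        _, null = fitted_null
        geno = tiny_panel.genotypes[:, [5, 5]].copy()
        bp = np.array([1000, 2000])
        dup = _panel_from_matrix(geno, bp=bp)
        dup.strain_ids = list(tiny_panel.strain_ids)
        scan = gwas.wald_scan(null, dup)
        assert scan["z"].iloc[0] == scan["z"].iloc[1]
        assert scan["p"].iloc[0] == scan["p"].iloc[1]

    def test_monomorphic_flagged_p1(self, fitted_null, tiny_panel):
        _, null = fitted_null
        geno = np.zeros((tiny_panel.n_strains, 1))
        mono = _panel_from_matrix(geno)
        mono.strain_ids = list(tiny_panel.strain_ids)
        scan = gwas.wald_scan(null, mono)
        assert scan["flag"].iloc[0] == "monomorphic"
        assert scan["p"].iloc[0] == 1.0


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum_of_maxima(self, fitted_null, tiny_panel):
        _, null = fitted_null
        thr, maxima = gwas.permutation_threshold(
            null, tiny_panel, alpha=1.0, n_perm=100, seed=1, return_maxima=True
        )
        assert thr == pytest.approx(maxima.min())

    def test_seed_reproducible(self, fitted_null, tiny_panel):
        _, null = fitted_null
        a = gwas.permutation_threshold(null, tiny_panel, n_perm=100, seed=5)
        b = gwas.permutation_threshold(null, tiny_panel, n_perm=100, seed=5)
        assert a == b

    def test_too_few_permutations_rejected(self, fitted_null, tiny_panel):
        _, null = fitted_null
        with pytest.raises(ValueError, match="at least 100"):
            gwas.permutation_threshold(null, tiny_panel, n_perm=50)
        with pytest.raises(ValueError, match="too small"):
            gwas.permutation_threshold(null, tiny_panel, alpha=0.005, n_perm=100)

    def test_implied_per_snp_threshold_near_sidak(self):
        """On an LD-free panel the implied per-SNP p threshold is within 2x
        of the Sidak bound 1 - 0.95^(1/m).

        A single permutation threshold is conditional on the realized
        phenotype draw, so the comparison averages (geometric mean) over
        replicate datasets.
        """
        from scipy.stats import norm as norm_dist

        ratios = []
        for seed in range(5):
            design = PanelDesign(
                n_inbred=100, n_ri=0, mice_per_strain=3, n_days=4,
                chrom_lengths=(("1", 40_000_000),), snp_spacing=100_000,
                ld_block_snps=1, ld_rho=0.0, missing_rate=0.0,
                strains_per_cohort=10, seed=31 + seed,
            )
            panel = simulate_genotypes(design)
            grm = compute_grm(panel)
            table = simulate_longitudinal(panel, TruthRecord(), design, grm=grm,
                                          seed=132 + seed)
            table = normalize_endpoint(table, "value")
            null = gwas.fit_null_model(table, grm, endpoint_col="value_norm")
            panel_f = gwas.filter_snps(panel)
            thr = gwas.permutation_threshold(
                null, panel_f, alpha=0.05, n_perm=1000, seed=33 + seed
            )
            p_implied = 2.0 * norm_dist.sf(thr)
            p_sidak = 1.0 - 0.95 ** (1.0 / panel_f.n_snps)
            ratios.append(p_implied / p_sidak)
        geomean = float(np.exp(np.mean(np.log(ratios))))
        assert 0.5 <= geomean <= 2.0


class TestGenomicInflation:
    def test_uniform_p_lambda_near_one(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(10_000)
        assert gwas.genomic_inflation(z) == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(500)
        assert gwas.genomic_inflation(2 * z) == pytest.approx(
            4 * gwas.genomic_inflation(z)
        )

    def test_constant_zero(self):
        assert gwas.genomic_inflation(np.zeros(200)) == 0.0

    def test_too_few_results_rejected(self):
        with pytest.raises(ValueError):
            gwas.genomic_inflation(np.ones(50))


class TestMergeLoci:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["snp", "chrom", "bp", "beta", "se", "z", "p", "n_used", "flag"]
        )

    def test_hits_within_2mb_merge(self):
        res = self._results([
            ("a", "1", 1_000_000, 1, 0.2, 5.0, 1e-7, 10, ""),
            ("b", "1", 2_500_000, 1, 0.2, 6.0, 1e-9, 10, ""),
        ])
        loci = gwas.merge_loci(res, threshold=4.0)
        assert len(loci) == 1
        assert loci["peak_snp"].iloc[0] == "b"

    def test_hits_beyond_2mb_split(self):
        res = self._results([
            ("a", "1", 1_000_000, 1, 0.2, 5.0, 1e-7, 10, ""),
            ("b", "1", 3_500_000, 1, 0.2, 6.0, 1e-9, 10, ""),
        ])
        assert len(gwas.merge_loci(res, threshold=4.0)) == 2

    def test_chaining_across_consecutive_gaps(self):
        res = self._results([
            ("a", "1", 0, 1, 0.2, 5.0, 1e-7, 10, ""),
            ("b", "1", 1_900_000, 1, 0.2, 5.5, 1e-8, 10, ""),
            ("c", "1", 3_800_000, 1, 0.2, 5.2, 2e-8, 10, ""),
        ])
        loci = gwas.merge_loci(res, threshold=4.0)
        assert len(loci) == 1
        assert loci["start_bp"].iloc[0] == 0 and loci["end_bp"].iloc[0] == 3_800_000

    def test_peak_tie_lowest_bp(self):
        res = self._results([
            ("a", "1", 1_000_000, 1, 0.2, 5.0, 1e-7, 10, ""),
            ("b", "1", 1_200_000, 1, 0.2, -5.0, 1e-7, 10, ""),
        ])
        loci = gwas.merge_loci(res, threshold=4.0)
        assert loci["peak_snp"].iloc[0] == "a"

    def test_empty_allowed(self):
        res = self._results([])
        assert len(gwas.merge_loci(res, threshold=4.0)) == 0
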