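import numpy as np
import pandas as pd
import pytest

from longqtl import molqtl
from longqtl.panel import compute_grm
from longqtl.simulate import PanelDesign, TruthRecord, simulate_expression, simulate_genotypes

from oracles import fisher_exact_enumeration, poisson_tail_sum


class TestFilterTranscripts:
    def _mats(self, counts, tpm):
        idx = [f"t{i}" for i in range(len(counts))]
        cols = [f"s{j}" for j in range(len(counts[0]))]
        return (
            pd.DataFrame(counts, index=idx, columns=cols),
            pd.DataFrame(tpm, index=idx, columns=cols),
        )

    def test_boundary_fraction_inclusive(self):
        # passes in exactly 2 of 10 samples -> kept (>= 20%)
        counts = [[6, 6] + [0] * 8]
        tpm = [[0.5, 0.5] + [0.0] * 8]
        c, t = self._mats(counts, tpm)
        assert molqtl.filter_transcripts(c, t) == ["t0"]

    def test_tpm_strictly_greater(self):
        counts = [[10] * 10]
        tpm = [[0.1] * 10]
        c, t = self._mats(counts, tpm)
        assert molqtl.filter_transcripts(c, t) == []

    def test_toy_fixture_enumerated(self):
        """Five transcripts, keep set worked out by hand."""
        counts = [
            [6, 6, 6, 6, 6],   # all pass reads, tpm below -> drop
            [6, 6, 0, 0, 0],   # 2/5 = 40% pass -> keep
            [5, 5, 5, 5, 5],   # reads below 6 everywhere -> drop
            [9, 0, 0, 0, 0],   # 1/5 = 20% pass -> keep (boundary)
            [0, 0, 0, 0, 0],   # nothing -> drop
        ]
        tpm = [
            [0.1, 0.1, 0.1, 0.1, 0.1],
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
        ]
        c, t = self._mats(counts, tpm)
        assert molqtl.filter_transcripts(c, t) == ["t1", "t3"]

    def test_misaligned_rejected(self):
        c, t = self._mats([[6, 6]], [[1.0, 1.0]])
        with pytest.raises(ValueError, match="share"):
            molqtl.filter_transcripts(c, t.iloc[:, ::-1])


class TestComputePsi:
    @pytest.mark.parametrize(
        "inc,exc,expected", [(8, 2, 0.8), (0, 5, 0.0), (5, 0, 1.0)]
    )
    def test_values(self, inc, exc, expected):
        assert molqtl.compute_psi(inc, exc) == pytest.approx(expected)

    def test_zero_total_missing(self):
        assert np.isnan(molqtl.compute_psi(0, 0))


class TestSelectExon:
    def _fixture(self):
        idx = ["e1", "e2", "e3", "e4"]
        cols = ["s1", "s2", "s3"]
        psi = pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.4, 0.5, 0.6], [0.5, 0.5, 0.5], [0.2, 0.6, 0.9]],
            index=idx, columns=cols,
        )
        reads = pd.DataFrame(
            [[10, 10, 10], [10, 10, 10], [10, 10, 10], [10, 4, 10]],
            index=idx, columns=cols,
        )
        mapping = {"e1": "tx1", "e2": "tx1", "e3": "tx2", "e4": "tx3"}
        return psi, reads, mapping

    def test_max_sd_exon_chosen_per_transcript(self):
        psi, reads, mapping = self._fixture()
        out = molqtl.select_exon_per_transcript(psi, reads, mapping)
        # tx1: e1 (higher SD); tx2: constant psi dropped; tx3: low reads dropped
        assert list(out.index) == ["e1"]

    def test_low_read_exon_dropped(self):
        psi, reads, mapping = self._fixture()
        out = molqtl.select_exon_per_transcript(psi, reads, mapping)
        assert "e4" not in out.index

    def test_quantile_normalization_preserves_order(self):
        psi, reads, mapping = self._fixture()
        out = molqtl.select_exon_per_transcript(psi, reads, mapping)
        raw = psi.loc["e1"].to_numpy()
        norm = out.loc["e1"].to_numpy()
        assert (np.argsort(raw) == np.argsort(norm)).all()


class TestFilterEditing:
    def _sites(self, det_rows):
        idx = [f"site{i}" for i in range(len(det_rows))]
        cols = [f"s{j}" for j in range(len(det_rows[0]))]
        det = pd.DataFrame(det_rows, index=idx, columns=cols)
        rng = np.random.default_rng(0)
        ratios = pd.DataFrame(rng.uniform(size=det.shape), index=idx, columns=cols)
        return ratios, det

    def test_detection_boundary(self):
        ratios, det = self._sites([
            [True] + [False] * 19,   # 1/20 = 5% -> dropped
            [True, True] + [False] * 18,  # 2/20 = 10% -> kept
        ])
        out = molqtl.filter_editing(ratios, det)
        assert list(out.index) == ["site1"]

    def test_empty_mask_empty_output(self):
        ratios, det = self._sites([[False] * 10])
        out = molqtl.filter_editing(ratios, det)
        assert len(out) == 0


class TestAscertainmentRate:
    def test_direct_average(self):
        det = pd.DataFrame(
            [[True] * 4 + [False] * 6, [True] * 6 + [False] * 4]
        )
        assert molqtl.ascertainment_rate(det) == pytest.approx(50.0)

    def test_all_detected_is_100(self):
        det = pd.DataFrame([[True] * 5] * 3)
        assert molqtl.ascertainment_rate(det) == pytest.approx(100.0)

    def test_toy_mask_hand_average(self):
        rows = [[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1], [0, 0, 0, 1]]
        det = pd.DataFrame(np.array(rows, dtype=bool))
        expected = np.mean([0.5, 0.25, 0.75, 1.0, 0.25]) * 100
        assert molqtl.ascertainment_rate(det) == pytest.approx(expected)

    def test_no_sites_errors(self):
        with pytest.raises(ValueError):
            molqtl.ascertainment_rate(pd.DataFrame())


@pytest.fixture(scope="module")
def expr_setup():
    design = PanelDesign(
        n_inbred=20, n_ri=20, n_founders=6, mice_per_strain=2,
        chrom_lengths=(("1", 10_000_000), ("2", 10_000_000)), snp_spacing=100_000,
        missing_rate=0.0, seed=5,
    )
    panel = simulate_genotypes(design)
    grm = compute_grm(panel)
    snp = panel.snps.index[30]
    truth = TruthRecord(
        cis_eqtl_truth=[("geneA", snp, 1.0), ("geneB", panel.snps.index[150], 0.0)]
    )
    values, traits, samples = simulate_expression(panel, truth, seed=9)
    return panel, grm, truth, snp, values, traits, samples


class TestMapQtl:
    def test_matches_dense_gls_oracle(self, expr_setup):
        panel, grm, truth, snp, values, traits, samples = expr_setup
        recs = molqtl.map_qtl(values, traits, samples, panel, grm)
        # dense oracle: explicit V = delta*K + I, GLS with SNP column
        y = values.loc["geneA"].to_numpy()
        strains = samples["strain"].tolist()
        K = grm.expand(strains)
        X = np.column_stack([
            np.ones(len(samples)), samples["sex"].to_numpy(float),
            pd.get_dummies(samples["batch"].astype("category"), drop_first=True)
            .to_numpy(float),
        ])
        ctx = molqtl._EmmaContext(K, X)
        delta = ctx.reml_delta(ctx.U.T @ y)
        Vi = np.linalg.inv(delta * K + np.eye(len(y)))
        poly = [
            s for s in panel.snps.index[30:120]
            if np.nanstd(panel.dosage(s)) > 0
        ][:4]
        for test_snp in poly:
            g = panel.dosage(test_snp)
            gm = np.array([g[panel.strain_ids.index(s)] for s in strains])
            Xs = np.column_stack([X, gm])
            A = Xs.T @ Vi @ Xs
            beta = np.linalg.solve(A, Xs.T @ Vi @ y)
            r = y - Xs @ beta
            sig2 = (r @ Vi @ r) / (len(y) - Xs.shape[1])
            se = np.sqrt(sig2 * np.linalg.inv(A)[-1, -1])
            z_oracle = beta[-1] / se
            z_pkg = recs[(recs.trait_id == "geneA") & (recs.snp == test_snp)]["z"].iloc[0]
            assert z_pkg == pytest.approx(z_oracle, abs=1e-6)

    def test_planted_cis_recovered(self, expr_setup):
        panel, grm, truth, snp, values, traits, samples = expr_setup
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            v, t, s = simulate_expression(panel, truth, seed=200 + rep)
            recs = molqtl.map_qtl(v, t, s, panel, grm)
            top = recs[recs.trait_id == "geneA"].sort_values("p").iloc[0]
            planted_bp = panel.snps.loc[snp, "bp"]
            same_block = (
                str(top["chrom"]) == str(panel.snps.loc[snp, "chrom"])
                and abs(top["bp"] - planted_bp) <= 20 * 100_000
            )
            hits += same_block
        assert hits / n_rep >= 0.9

    def test_cis_trans_labeling(self, expr_setup):
        panel, grm, truth, snp, values, traits, samples = expr_setup
        recs = molqtl.map_qtl(values, traits, samples, panel, grm)
        ga = recs[recs.trait_id == "geneA"]
        anchor = int(traits.loc["geneA", "anchor_bp"])
        chrom = str(traits.loc["geneA", "chrom"])
        cis = ga[ga["cis"]]
        assert (cis["chrom"].astype(str) == chrom).all()
        assert (np.abs(cis["bp"] - anchor) < 2_000_000).all()
        far = ga[(ga["chrom"].astype(str) == chrom) & (np.abs(ga["bp"] - anchor) >= 2_000_000)]
        assert (~far["cis"]).all()

    def test_zero_variance_trait_skipped(self, expr_setup):
        panel, grm, truth, snp, values, traits, samples = expr_setup
        v = values.copy()
        v.loc["geneA"] = 1.0
        recs = molqtl.map_qtl(v, traits, samples, panel, grm)
        assert "geneA" not in set(recs["trait_id"])

    def test_identity_kinship_matches_ols_when_delta_zero(self, expr_setup):
        """With no strain effect, z is close to ordinary regression z."""
        panel, grm, truth, snp, values, traits, samples = expr_setup
        from longqtl.panel import KinshipMatrix

        eye = KinshipMatrix(list(panel.strain_ids), np.eye(panel.n_strains))
        v, t, s = simulate_expression(
            panel, truth, strain_var=0.0, seed=77, grm=eye
        )
        recs = molqtl.map_qtl(v, t, s, panel, eye)
        import statsmodels.api as sm

        y = v.loc["geneB"].to_numpy()
        X = np.column_stack([
            np.ones(len(s)), s["sex"].to_numpy(float),
            pd.get_dummies(s["batch"].astype("category"), drop_first=True).to_numpy(float),
        ])
        g = panel.dosage(panel.snps.index[10])
        gm = np.array([g[panel.strain_ids.index(x)] for x in s["strain"]])
        ols = sm.OLS(y, np.column_stack([X, gm])).fit()
        z_pkg = recs[(recs.trait_id == "geneB") & (recs.snp == panel.snps.index[10])]["z"].iloc[0]
        assert z_pkg == pytest.approx(ols.tvalues[-1], rel=0.05)


class TestHotspots:
    CHROMS = (("1", 20_000_000), ("2", 20_000_000))

    def _qtls(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "bp", "cis"])

    def test_uniform_scatter_no_hotspot(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"g{i}", rng.choice(["1", "2"]), int(rng.integers(1, 20_000_000)), False)
            for i in range(40)
        ]
        out = molqtl.detect_hotspots(self._qtls(rows), self.CHROMS, min_genes=5)
        assert len(out) == 0

    def test_concentrated_bin_detected_and_tail_exact(self):
        rows = [(f"g{i}", "1", 100_000 + i, False) for i in range(30)]
        rows += [(f"h{i}", "2", int(1e6 + i * 2e6), False) for i in range(5)]
        qtls = self._qtls(rows)
        out = molqtl.detect_hotspots(qtls, self.CHROMS, min_genes=20)
        assert len(out) == 1
        lam = 35 / 20  # 35 genes over 20 bins
        assert out["p"].iloc[0] == pytest.approx(poisson_tail_sum(30, lam), abs=1e-12)

    def test_thresholds_off_reports_every_nonempty_bin(self):
        rows = [("g1", "1", 500_000, False), ("g2", "2", 4_500_000, False)]
        out = molqtl.detect_hotspots(
            self._qtls(rows), self.CHROMS, min_genes=0, fdr=1.1
        )
        assert (out["n_genes"] > 0).sum() == 2

    def test_zero_associations_empty(self):
        out = molqtl.detect_hotspots(self._qtls([]), self.CHROMS)
        assert len(out) == 0

    @pytest.mark.parametrize("k,lam", [(5, 2.0), (30, 2.0), (100, 50.0), (1, 0.5)])
    def test_poisson_tail_matches_mass_summation(self, k, lam):
        assert molqtl.poisson_tail(k, lam) == pytest.approx(
            poisson_tail_sum(k, lam), abs=1e-12
        )


class TestFisherEnrichment:
    @pytest.mark.parametrize(
        "table", [(10, 10, 10, 10), (8, 2, 2, 8), (12, 3, 4, 11), (1, 9, 9, 1), (0, 5, 5, 5)]
    )
    def test_p_matches_full_enumeration(self, table):
        out = molqtl._fisher_2x2(*table)
        assert out["p"] == pytest.approx(fisher_exact_enumeration(*table), abs=1e-10)

    def test_balanced_table_no_association(self):
        out = molqtl._fisher_2x2(10, 10, 10, 10)
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_zero_cell_continuity_flagged(self):
        out = molqtl._fisher_2x2(0, 5, 5, 5)
        assert out["continuity_corrected"]
        assert out["odds_ratio"] == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))


class TestCoincidence:
    def _cis(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "bp"])

    def test_coincident_within_window(self):
        a = self._cis([("g1", "1", 1_000_000), ("g2", "1", 5_000_000)])
        b = self._cis([("g1", "1", 2_500_000), ("g3", "2", 1_000_000)])
        out = molqtl.coincidence_enrichment(a, b, universe=[f"g{i}" for i in range(1, 9)])
        assert out["a"] == 1  # g1 coincident (1.5 Mb apart)
        assert out["b"] == 1  # g2 has A only
        assert out["c"] == 1  # g3 has B only
        assert out["d"] == 5

    def test_window_zero_requires_colocation(self):
        a = self._cis([("g1", "1", 1_000_000), ("g2", "1", 3_000_000)])
        b = self._cis([("g1", "1", 1_000_000), ("g2", "1", 3_000_100)])
        out = molqtl.coincidence_enrichment(a, b, universe=["g1", "g2", "g3"], window_bp=0)
        assert out["a"] == 1  # only the exactly co-located peak counts
        assert out["b"] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            molqtl.coincidence_enrichment(self._cis([]), self._cis([]), universe=[])


class TestRegionEnrichment:
    def test_balanced(self):
        sites = pd.DataFrame({
            "region": ["cds"] * 10 + ["intronic"] * 10,
            "coincident": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5,
        })
        out = molqtl.region_enrichment(sites)
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_exact_hypergeometric(self):
        sites = pd.DataFrame({
            "region": ["5utr"] * 15 + ["intergenic"] * 15,
            "coincident": [True] * 12 + [False] * 3 + [True] * 4 + [False] * 11,
        })
        out = molqtl.region_enrichment(sites)
        assert out["p"] == pytest.approx(fisher_exact_enumeration(12, 3, 4, 11), abs=1e-10)

    def test_single_class_rejected(self):
        sites = pd.DataFrame({"region": ["cds"] * 4, "coincident": [True, False] * 2})
        with pytest.raises(ValueError, match="classes"):
            molqtl.region_enrichment(sites)
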