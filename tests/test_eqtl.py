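"""Mixed-model association machinery: kinship, LMM scan, intervals,
cis/trans calls and the phenome scan."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bxdprio import (
    AssociationScan,
    GeneticMap,
    KinshipMatrix,
    SimulationConfig,
    StrainGenotypes,
    classify_eqtl,
    kinship_matrix,
    lmm_scan,
    phenome_scan,
    qtl_interval,
    simulate_expression,
    simulate_ri_genotypes,
    simulate_traits,
)


def tiny_genotypes(allele_rows, chroms=None):
    n_markers = len(allele_rows[0])
    chroms = chroms or ["1"] * n_markers
    table = pd.DataFrame({
        "marker": [f"m{i}" for i in range(n_markers)],
        "chromosome": chroms,
        "position_mb": [
            10.0 * (1 + sum(1 for c in chroms[: i + 1] if c == chroms[i]))
            for i in range(n_markers)
        ],
    })
    # rebuild positions per chromosome so they increase within each
    pos = {}
    positions = []
    for c in chroms:
        pos[c] = pos.get(c, 0) + 10.0
        positions.append(pos[c])
    table["position_mb"] = positions
    alleles = pd.DataFrame(
        np.asarray(allele_rows), columns=table["marker"],
        index=[f"s{i}" for i in range(len(allele_rows))],
    )
    return StrainGenotypes(alleles=alleles, genetic_map=GeneticMap(table))


class TestKinship:
    def test_hand_computed_centered_relatedness(self):
        geno = tiny_genotypes([(0, 0), (1, 1), (0, 1)])
        X = np.array([[0, 0], [1, 1], [0, 1]], dtype=float)
        Xc = X - X.mean(axis=0)
        expected = Xc @ Xc.T / 2  # direct evaluation of the estimator
        K = kinship_matrix(geno).K
        assert np.allclose(K, expected, atol=1e-12)

    def test_identical_strains_share_diagonal_entry(self):
        geno = tiny_genotypes([(0, 1, 0), (0, 1, 0), (1, 0, 1)])
        K = kinship_matrix(geno).K
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_loco_excludes_exactly_that_chromosome(self):
        geno = tiny_genotypes(
            [(0, 1, 0, 1), (1, 0, 1, 0), (0, 0, 1, 1), (1, 1, 0, 0)],
            chroms=["1", "1", "2", "2"],
        )
        K_loco = kinship_matrix(geno, exclude_chromosome="2").K
        X = geno.alleles[["m0", "m1"]].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        assert np.allclose(K_loco, Xc @ Xc.T / 2, atol=1e-12)

    def test_all_markers_excluded_rejected(self):
        geno = tiny_genotypes([(0, 1), (1, 0), (0, 0)], chroms=["1", "1"])
        with pytest.raises(ValueError):
            kinship_matrix(geno, exclude_chromosome="1")

    def test_psd_enforced(self):
        with pytest.raises(ValueError):
            KinshipMatrix(strains=["a", "b"], K=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLmmScan:
    def test_identity_kinship_reduces_to_ols(self, small_genotypes, small_config):
        expr = simulate_expression(small_genotypes, small_config)
        y = expr.gene_values(small_config.focal_gene)
        kin = KinshipMatrix(strains=small_genotypes.strains,
                            K=np.eye(small_genotypes.n_strains))
        scan = lmm_scan(y, small_genotypes, kinship=kin)
        yv = y.to_numpy()
        for _, row in scan.records.iterrows():
            x = small_genotypes.alleles[row["marker"]].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            p_ols = stats.linregress(x, yv).pvalue
            assert row["logp"] == pytest.approx(-np.log10(p_ols), abs=1e-6)

    def test_peak_lands_on_planted_chromosome(self, small_genotypes, small_config):
        expr = simulate_expression(small_genotypes, small_config)
        scan = lmm_scan(expr.gene_values(small_config.focal_gene),
                        small_genotypes, loco=True)
        assert scan.peak["chromosome"] == small_config.focal_chromosome

    def test_reorder_invariance(self, small_genotypes, small_config):
        expr = simulate_expression(small_genotypes, small_config)
        y = expr.gene_values(small_config.focal_gene)
        scan_a = lmm_scan(y, small_genotypes, loco=False)
        perm = np.random.default_rng(0).permutation(len(y))
        y_perm = y.iloc[perm]
        geno_perm = StrainGenotypes(
            alleles=small_genotypes.alleles.iloc[perm],
            genetic_map=small_genotypes.genetic_map,
        )
        scan_b = lmm_scan(y_perm, geno_perm, loco=False)
        assert np.allclose(scan_a.records["logp"], scan_b.records["logp"], atol=1e-8)

    def test_permuted_phenotype_rarely_significant(self, small_genotypes, small_config):
        expr = simulate_expression(small_genotypes, small_config)
        y = expr.gene_values(small_config.focal_gene).to_numpy()
        rng = np.random.default_rng(42)
        clean = 0
        n_rep = 10
        for _ in range(n_rep):
            y_perm = pd.Series(rng.permutation(y), index=small_genotypes.strains)
            scan = lmm_scan(y_perm, small_genotypes, loco=True)
            clean += (scan.records["logp"] < 4.0).all()
        assert clean >= n_rep - 1

    def test_constant_phenotype_rejected(self, small_genotypes):
        y = pd.Series(np.full(small_genotypes.n_strains, 3.0),
                      index=small_genotypes.strains)
        with pytest.raises(ValueError):
            lmm_scan(y, small_genotypes)

    def test_unmatched_strains_named(self, small_genotypes):
        y = pd.Series(np.arange(12.0), index=[f"zz{i}" for i in range(12)])
        with pytest.raises(ValueError, match="zz0"):
            lmm_scan(y, small_genotypes)


def make_scan(markers):
    """markers: list of (marker, chrom, pos, logp)."""
    return AssociationScan(records=pd.DataFrame(
        markers, columns=["marker", "chromosome", "position_mb", "logp"]
    ).assign(beta=0.1)[["marker", "chromosome", "position_mb", "beta", "logp"]])


class TestInterval:
    def test_all_below_threshold_none(self):
        scan = make_scan([("a", "1", 10.0, 1.0), ("b", "1", 20.0, 2.2)])
        assert qtl_interval(scan, 4.0) is None

    def test_single_marker_zero_width(self):
        scan = make_scan([("a", "1", 10.0, 1.0), ("b", "1", 20.0, 5.0),
                          ("c", "1", 30.0, 1.0)])
        assert qtl_interval(scan, 4.0) == ("1", 20.0, 20.0)

    def test_contiguous_run_spans_60_to_80(self):
        rows = [("m1", "2", 50.0, 2.0)]
        rows += [(f"m{i+2}", "2", 60.0 + 5.0 * i, 4.5 + 0.1 * i) for i in range(5)]
        rows += [("m7", "2", 90.0, 1.0)]
        scan = make_scan(rows)
        assert qtl_interval(scan, 4.0) == ("2", 60.0, 80.0)

    def test_run_is_local_to_peak(self):
        # a separate above-threshold island does not extend the interval
        scan = make_scan([("a", "1", 10.0, 4.2), ("b", "1", 20.0, 1.0),
                          ("c", "1", 30.0, 6.0), ("d", "1", 40.0, 4.5)])
        assert qtl_interval(scan, 4.0) == ("1", 30.0, 40.0)


class TestClassify:
    def test_peak_at_gene_position_is_cis(self):
        scan = make_scan([("a", "3", 42.0, 6.0), ("b", "3", 60.0, 1.0)])
        call = classify_eqtl(scan, "g", ("3", 42.0))
        assert call.classification == "cis"

    def test_other_chromosome_is_trans(self):
        scan = make_scan([("a", "5", 42.0, 6.0), ("b", "3", 60.0, 1.0)])
        assert classify_eqtl(scan, "g", ("3", 42.0)).classification == "trans"

    def test_no_significance_is_none(self):
        scan = make_scan([("a", "3", 42.0, 2.0)])
        assert classify_eqtl(scan, "g", ("3", 42.0)).classification == "none"

    def test_hippocampus_style_interval_containing_gene_is_cis(self):
        # interval 64.4-80.6 Mb on chr 11 around a gene at 70.439877 Mb
        scan = make_scan([("a", "11", 64.4, 4.5), ("b", "11", 70.0, 6.1),
                          ("c", "11", 80.6, 4.2), ("d", "11", 95.0, 1.0)])
        call = classify_eqtl(scan, "Arrb2", ("11", 70.439877))
        assert call.interval == ("11", 64.4, 80.6)
        assert call.classification == "cis"

    def test_nearby_interval_within_window_is_cis(self):
        scan = make_scan([("a", "3", 50.0, 6.0)])
        assert classify_eqtl(scan, "g", ("3", 42.0), cis_window_mb=10.0).classification == "cis"
        assert classify_eqtl(scan, "g", ("3", 30.0), cis_window_mb=10.0).classification == "trans"


class TestPhenomeScan:
    def test_single_trait_q_equals_p(self, small_genotypes):
        rng = np.random.default_rng(3)
        x = small_genotypes.alleles["m2_3"].to_numpy(dtype=float)
        t = pd.Series(x + rng.normal(0, 1.0, x.size), index=small_genotypes.strains)
        from bxdprio import TraitTable

        res = phenome_scan(small_genotypes, "m2_3", TraitTable(values=t.to_frame("t")))
        assert res.records["q"].iloc[0] == pytest.approx(res.records["p"].iloc[0])

    def test_strong_signal_survives_stringent_threshold(self):
        cfg = SimulationConfig(n_strains=60, n_background_genes=5, seed=77)
        geno = simulate_ri_genotypes(cfg)
        rng = np.random.default_rng(7)
        x = geno.alleles["m11_7"].to_numpy(dtype=float)
        data = {"signal": x + rng.normal(0, 0.5, x.size)}
        for j in range(50):
            data[f"null{j}"] = rng.normal(50, 10, x.size)
        from bxdprio import TraitTable

        traits = TraitTable(values=pd.DataFrame(data, index=geno.strains))
        res = phenome_scan(geno, "m11_7", traits)
        assert "signal" in res.stringent

    def test_no_usable_traits_rejected(self, small_genotypes):
        from bxdprio import TraitTable

        sparse = pd.DataFrame(
            {"t": [1.0] * 3 + [np.nan] * (small_genotypes.n_strains - 3)},
            index=small_genotypes.strains,
        )
        with pytest.raises(ValueError):
            phenome_scan(small_genotypes, "m1_1", TraitTable(values=sparse))
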