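import numpy as np
import pandas as pd
import pytest
from pathlib import Path

from ppiclust.variants import (FilterThresholds, SampleSeedSet,
                               filter_pathogenic, flag_low_quality,
                               low_quality_flags, pathogenic_mask, pca_adjust,
                               read_variant_table, select_seed_genes,
                               trend_scan, trend_test)

DATA = Path(__file__).parent / "data"


def _variant(**kw):
    base = dict(Chr="1", Pos=1000, Gene="GENE1", DP=50, QUAL=60, QD=3.0, FS=10,
                AltMappings=1)
    base.update(kw)
    return pd.Series(base)


class TestLowQualityFlags:
    def test_low_coverage_fires_named_rule(self):
        flagged, rules = flag_low_quality(_variant(DP=9))
        assert flagged and rules == ["coverage<10"]

    def test_clean_variant_with_one_neighbor_not_flagged(self):
        flagged, rules = flag_low_quality(_variant(), neighborhood_positions=[1005])
        assert not flagged and rules == []

    def test_density_rule_flags_all_three_close_variants(self):
        # brute-force sliding-window oracle over the trio at 100/105/109
        positions = [100, 105, 109]
        for pos in positions:
            others = [q for q in positions if q != pos]
            window = sum(1 for q in others if abs(q - pos) <= 10) + 1
            assert window >= 3
            flagged, rules = flag_low_quality(_variant(Pos=pos), others)
            assert flagged and "density>=3in10bp" in rules

    @pytest.mark.parametrize("field,value,rule", [
        ("AltMappings", 4, "alt_mappings>=4"),
        ("QUAL", 29, "qual<30"),
        ("QD", 1.4, "qd<1.5"),
        ("FS", 201, "fs>200"),
    ])
    def test_each_rule_fires_on_its_metric(self, field, value, rule):
        flagged, rules = flag_low_quality(_variant(**{field: value}))
        assert flagged and rules == [rule]

    def test_missing_metrics_never_fire(self):
        v = _variant(DP=np.nan, QUAL=np.nan, QD=np.nan, FS=np.nan,
                     AltMappings=np.nan)
        flagged, rules = flag_low_quality(v)
        assert not flagged

    def test_table_level_flags_match_per_variant(self, rng):
        rows = []
        for i in range(60):
            rows.append(dict(
                Chr=str(rng.integers(1, 3)), Pos=int(rng.integers(1, 400)),
                Gene=f"G{i}", DP=int(rng.integers(5, 40)),
                QUAL=float(rng.uniform(10, 100)), QD=float(rng.uniform(0.5, 10)),
                FS=float(rng.uniform(0, 300)), AltMappings=int(rng.integers(1, 6)),
            ))
        df = pd.DataFrame(rows)
        table = low_quality_flags(df)
        for i, row in df.iterrows():
            others = df[(df["Chr"] == row["Chr"]) & (df.index != i)]["Pos"].tolist()
            flagged, rules = flag_low_quality(row, others)
            assert table.loc[i, "low_quality"] == flagged
            assert set(table.loc[i, "rules"].split(";")) - {""} == set(rules)


class TestPathogenicFilter:
    def test_damaging_reference_variant_passes(self):
        v = _variant(Polyphen2_HDIV_score=0.98, CADD_phred=18, SIFT_score=0.0,
                     ExAC_ALL=0.0074)
        assert filter_pathogenic(v)

    def test_common_variant_fails_on_maf(self):
        v = _variant(Polyphen2_HDIV_score=1.0, CADD_phred=21, SIFT_score=0.01,
                     ExAC_ALL=0.1172)
        assert not filter_pathogenic(v)
        # it passes once the MAF criterion is relaxed, so MAF is the failing one
        assert filter_pathogenic(v, FilterThresholds(max_maf=1.0))

    def test_polyphen_boundary_inclusive(self):
        v = _variant(Polyphen2_HDIV_score=0.957, CADD_phred=18, SIFT_score=0.0,
                     ExAC_ALL=0.001)
        assert filter_pathogenic(v)

    def test_missing_annotation_fails(self):
        v = _variant(Polyphen2_HDIV_score=np.nan, CADD_phred=18, SIFT_score=0.0,
                     ExAC_ALL=0.001)
        assert not filter_pathogenic(v)

    def test_reference_fixture_eight_of_nine_pass(self):
        """On the nine-variant reference fixture the damaging-variant filters
        pass exactly eight rows; AOAH fails only the MAF < 0.05 cutoff."""
        df = read_variant_table(DATA / "table3_variants.tsv")
        mask = pathogenic_mask(df)
        assert int(mask.sum()) == 8
        (failing,) = df.loc[~mask, "Gene"].tolist()
        assert failing == "AOAH"
        assert int(pathogenic_mask(df, FilterThresholds(max_maf=1.0)).sum()) == 9

    def test_filter_order_independence(self, rng):
        """QC flags then pathogenicity filtering commutes: the survivor set is
        the intersection of the two masks whatever the order."""
        df = read_variant_table(DATA / "table3_variants.tsv").copy()
        df.loc[2, "DP"] = 7  # make one row low-quality
        flags = low_quality_flags(df)["low_quality"]
        path_first = pathogenic_mask(df) & ~low_quality_flags(df)["low_quality"]
        qc_first_df = df.loc[~flags]
        qc_first = pathogenic_mask(qc_first_df)
        assert set(qc_first_df.index[qc_first]) == set(df.index[path_first])


class TestTrendTest:
    def test_identical_distributions_give_p_one(self):
        res = trend_test((10, 0, 0), (10, 0, 0))
        assert res.statistic == 0 and res.p == 1

    def test_opposite_homozygotes_highly_significant(self):
        res = trend_test((0, 0, 10), (10, 0, 0))
        assert res.p < 1e-4

    def test_symmetric_heterozygote_split_null(self):
        res = trend_test((5, 5, 0), (5, 5, 0))
        assert res.p == 1

    def test_against_permutation_null(self, rng):
        """The chi-square(1) p-value agrees with a 10,000-shuffle permutation
        distribution of the same statistic."""
        case_counts, control_counts = (2, 8, 10), (10, 8, 2)
        obs = trend_test(case_counts, control_counts)
        doses = np.repeat([0, 1, 2], np.add(case_counts, control_counts))
        # case indicators matching the observed margins, then permuted
        y = np.concatenate([
            np.r_[np.ones(c), np.zeros(s)]
            for c, s in zip(case_counts, control_counts)
        ])
        stat_obs = obs.statistic
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(y)
            r = np.corrcoef(doses, perm)[0, 1]
            if (doses.size - 1) * r * r >= stat_obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert abs(p_perm - obs.p) < 0.02

    def test_counts_api_matches_vectorised_scan(self):
        case_counts, control_counts = (3, 5, 2), (6, 3, 1)
        doses = np.concatenate([
            np.repeat([0, 1, 2], case_counts),
            np.repeat([0, 1, 2], control_counts),
        ]).astype(float)
        y = np.r_[np.ones(sum(case_counts)), np.zeros(sum(control_counts))]
        scan = trend_scan(doses[:, None], y, n_pcs=0)
        res = trend_test(case_counts, control_counts)
        assert scan["statistic"].iloc[0] == pytest.approx(res.statistic, rel=1e-12)
        assert scan["p"].iloc[0] == pytest.approx(res.p, rel=1e-12)

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            trend_test((1, 1, 1), (0, 0, 0))


class TestPcaAdjust:
    def test_zero_components_is_identity_test(self, rng):
        G = rng.binomial(2, 0.3, size=(40, 25)).astype(float)
        y = rng.binomial(1, 0.5, size=40).astype(float)
        plain = trend_scan(G, y, n_pcs=0)
        G_r, y_r = pca_adjust(G, y, n_pcs=0)
        assert np.allclose(G_r, G - G.mean(axis=0))
        assert np.allclose(y_r, y - y.mean())

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_adjust(np.zeros((5, 3)), np.zeros(5), n_pcs=5)

    def test_missing_genotypes_mean_imputed(self, rng):
        G = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        G[0, 0] = np.nan
        G_r, _ = pca_adjust(G, rng.binomial(1, 0.5, 30).astype(float), n_pcs=0)
        assert np.isfinite(G_r).all()
        # an imputed entry is centred to exactly zero
        assert G_r[0, 0] == pytest.approx(0.0)

    def test_stratified_null_unadjusted_inflated_adjusted_calibrated(self, rng):
        """On a confounded two-population null the raw trend test is inflated
        (genomic-control lambda well above 1) while the PCA-adjusted test is
        calibrated (lambda within [0.7, 1.3])."""
        from scipy.stats import chi2
        from ppiclust.simulate import simulate_stratified_genotypes
        G, y, _ = simulate_stratified_genotypes(60, 40, 500, rng)
        chi2_median_null = chi2.ppf(0.5, df=1)
        lam_un = np.median(trend_scan(G, y, n_pcs=0)["statistic"]) / chi2_median_null
        lam_adj = np.median(trend_scan(G, y, n_pcs=10)["statistic"]) / chi2_median_null
        assert lam_un > 1.0
        assert 0.7 <= lam_adj <= 1.3

    def test_single_population_adjustment_is_nearly_neutral(self, rng):
        """Without structure, adjusting changes p by < 0.5 on the log10 scale
        for at least 95% of variants."""
        n = 150
        freqs = rng.uniform(0.1, 0.4, size=400)
        G = rng.binomial(2, np.broadcast_to(freqs, (n, 400))).astype(float)
        y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        p0 = trend_scan(G, y, n_pcs=0)["p"].to_numpy()
        p1 = trend_scan(G, y, n_pcs=10)["p"].to_numpy()
        delta = np.abs(np.log10(p0) - np.log10(p1))
        assert np.mean(delta < 0.5) >= 0.95


class TestSelectSeedGenes:
    def _table(self, genes, pvals, carrier):
        df = pd.DataFrame({
            "Chr": "1", "Pos": range(1, len(genes) + 1), "Gene": genes,
            "S1": carrier,
        })
        return df, pd.Series(pvals, index=df.index)

    def test_ranked_truncation(self):
        df, p = self._table(["X", "Y", "Z"], [0.001, 0.01, 0.02], [1, 1, 2])
        ss = select_seed_genes("S1", "case", df, p, K=2)
        assert ss.seeds == ("X", "Y")

    def test_gene_p_is_min_over_its_variants(self):
        df, p = self._table(["W", "W"], [0.05, 0.001], [1, 1])
        ss = select_seed_genes("S1", "case", df, p, K=5)
        assert ss.seeds == ("W",) and ss.pvalues == (0.001,)

    def test_non_carried_variants_do_not_count(self):
        df, p = self._table(["X", "Y"], [0.001, 0.01], [0, 2])
        ss = select_seed_genes("S1", "case", df, p, K=5)
        assert ss.seeds == ("Y",)

    def test_alphabetical_tie_break_is_stable(self):
        genes = [f"G{i:02d}" for i in range(40)]
        df, p = self._table(genes, [0.01] * 40, [1] * 40)
        first = select_seed_genes("S1", "case", df, p, K=30)
        assert len(first.seeds) == 30
        assert list(first.seeds) == sorted(genes)[:30]
        for _ in range(3):
            assert select_seed_genes("S1", "case", df, p, K=30).seeds == first.seeds

    def test_invariant_to_row_order(self, rng):
        genes = [f"G{i:02d}" for i in rng.integers(0, 15, size=30)]
        df, p = self._table(genes, rng.uniform(size=30).round(3), rng.integers(0, 3, size=30))
        ss = select_seed_genes("S1", "case", df, p, K=10)
        perm = rng.permutation(df.index)
        ss2 = select_seed_genes("S1", "case", df.loc[perm], p.loc[perm], K=10)
        assert ss.seeds == ss2.seeds

    def test_empty_seed_set_for_noncarrier(self):
        df, p = self._table(["X"], [0.01], [0])
        ss = select_seed_genes("S1", "case", df, p)
        assert ss.seeds == ()
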