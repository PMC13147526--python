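import numpy as np
import pytest
from scipy import stats

from poolscan.data import FounderPanel, GeneticMap, PoolCounts, ValidationError
from poolscan.haplotypes import HaplotypeFreqTrack, Window, define_windows
from poolscan.scans import (
    bonferroni,
    cluster_score,
    cmh_2x2xK,
    cmh_general,
    compare_scans,
    group_pools_by_replicate,
    scan_direct_snp,
    scan_haplotype,
    scan_imputed_snp,
)


def cmh_oracle(tables, variant="classical"):
    """Independent matrix-arithmetic evaluation of the generalized CMH
    general-association statistic (explicit loops, no shared code path)."""
    K, _, J = tables.shape
    d = np.zeros(J)
    V = np.zeros((J, J))
    for k in range(K):
        row_case = tables[k, 0]
        n1 = row_case.sum()
        n2 = tables[k, 1].sum()
        T = n1 + n2
        m = tables[k].sum(axis=0)
        d += row_case - n1 * m / T
        tden = T - 1 if variant == "classical" else T
        for i in range(J):
            for j in range(J):
                if i == j:
                    cov = m[i] * (T - m[i])
                else:
                    cov = -m[i] * m[j]
                V[i, j] += n1 * n2 * cov / (T**2 * tden)
    dr = d[:-1]
    Vr = V[:-1, :-1]
    stat = float(dr @ np.linalg.solve(Vr, dr))
    return stat, J - 1, float(stats.chi2.sf(stat, J - 1))


class TestCMH2x2:
    def test_identical_proportions_null(self):
        a = np.array([20.0, 10.0])
        b = np.array([20.0, 10.0])
        c = np.array([40.0, 5.0])
        d = np.array([40.0, 5.0])
        stat, p, _ = cmh_2x2xK(a, b, c, d)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_single_stratum(self):
        # a=25 b=25 c=10 d=40: E = 50*35/100 = 17.5,
        # V = 50*50*35*65/(100^2*99) = 5687500/990000 ~ 5.7449,
        # stat = 7.5^2/V ~ 9.791
        stat, p, _ = cmh_2x2xK([25.0], [25.0], [10.0], [40.0])
        V = 50 * 50 * 35 * 65 / (100**2 * 99)
        assert V == pytest.approx(5.7449, abs=1e-4)
        assert stat == pytest.approx(7.5**2 / V, rel=1e-12)
        assert stat == pytest.approx(9.791, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)

    def test_duplicated_stratum_doubles_statistic(self):
        s1, _, _ = cmh_2x2xK([25.0], [25.0], [10.0], [40.0])
        s2, _, _ = cmh_2x2xK([25.0] * 2, [25.0] * 2, [10.0] * 2, [40.0] * 2)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_margin_stratum_is_skipped(self):
        stat_with, _, _ = cmh_2x2xK([25.0, 0.0], [25.0, 0.0], [10.0, 5.0], [40.0, 5.0])
        stat_single, _, _ = cmh_2x2xK([25.0], [25.0], [10.0], [40.0])
        assert stat_with == pytest.approx(stat_single, rel=1e-12)

    def test_all_degenerate_flagged(self):
        stat, p, degenerate = cmh_2x2xK([0.0], [0.0], [5.0], [5.0])
        assert degenerate and stat == 0.0 and p == 1.0

    def test_no_tminus1_scales_exactly_linearly(self):
        cells = ([25.0, 12.0], [25.0, 3.0], [10.0, 8.0], [40.0, 9.0])
        s1, _, _ = cmh_2x2xK(*cells, variant="no_tminus1")
        scaled = tuple([x * 7.0 for x in cell] for cell in cells)
        s7, _, _ = cmh_2x2xK(*scaled, variant="no_tminus1")
        assert s7 == pytest.approx(7 * s1, rel=1e-12)

    def test_classical_scaling_approaches_linear(self):
        # exact factor is (cT-1)/(T-1), slightly above c, converging as T grows
        cells = ([250.0], [250.0], [100.0], [400.0])
        s1, _, _ = cmh_2x2xK(*cells)
        c, T = 5.0, 1000.0
        sc, _, _ = cmh_2x2xK(*tuple([x * c for x in cell] for cell in cells))
        assert sc == pytest.approx(s1 * (c * T - 1) / (T - 1), rel=1e-12)
        assert abs(sc / s1 - c) / c < 0.01


class TestCMHGeneral:
    def test_reduces_to_2x2_within_1e9(self):
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            K = rng.integers(1, 5)
            tab = rng.uniform(0.5, 50, size=(K, 2, 2))
            s2, p2, _ = cmh_2x2xK(tab[:, 0, 0], tab[:, 0, 1], tab[:, 1, 0], tab[:, 1, 1])
            sg, df, pg, _ = cmh_general(tab)
            assert df == 1
            assert abs(sg - s2) < 1e-9 * max(1.0, s2)
            assert abs(pg - p2) < 1e-9

    def test_identical_category_proportions_null(self):
        tab = np.array([[[10.0, 20.0, 30.0], [20.0, 40.0, 60.0]]] * 3)
        stat, df, p, _ = cmh_general(tab)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_j3_k2_matches_independent_oracle(self):
        tab = np.array(
            [
                [[12.0, 5.0, 9.0], [7.0, 11.0, 3.0]],
                [[4.0, 14.0, 6.0], [9.0, 2.0, 10.0]],
            ]
        )
        stat, df, p, _ = cmh_general(tab)
        o_stat, o_df, o_p = cmh_oracle(tab)
        assert stat == pytest.approx(o_stat, rel=1e-10)
        assert df == o_df
        assert p == pytest.approx(o_p, rel=1e-10)

    def test_no_tminus1_variant_matches_oracle(self):
        tab = np.array([[[12.0, 5.0, 9.0], [7.0, 11.0, 3.0]]])
        stat, _, _, _ = cmh_general(tab, variant="no_tminus1")
        o_stat, _, _ = cmh_oracle(tab, variant="no_tminus1")
        assert stat == pytest.approx(o_stat, rel=1e-10)

    def test_no_tminus1_exact_linear_scaling(self):
        tab = np.array(
            [
                [[12.0, 5.0, 9.0], [7.0, 11.0, 3.0]],
                [[4.0, 14.0, 6.0], [9.0, 2.0, 10.0]],
            ]
        )
        s1, _, _, _ = cmh_general(tab, variant="no_tminus1")
        s3, _, _, _ = cmh_general(3.0 * tab, variant="no_tminus1")
        assert s3 == pytest.approx(3 * s1, rel=1e-12)

    def test_degenerate_table(self):
        tab = np.zeros((2, 2, 3))
        stat, df, p, flag = cmh_general(tab)
        assert flag == "degenerate" and p == 1.0

    def test_singular_covariance_uses_pseudo_inverse(self):
        # third category identically zero -> singular covariance
        tab = np.array([[[10.0, 5.0, 0.0], [5.0, 10.0, 0.0]]])
        stat, df, p, flag = cmh_general(tab)
        assert flag == "singular_covariance"
        assert df == 1
        assert stat > 0

    def test_null_calibration_under_label_permutation(self):
        """Rejection rate at alpha = .05 within binomial error of .05 when
        treatment labels carry no information."""
        rng = np.random.default_rng(7)
        n_tests, rejected = 3_000, 0
        for _ in range(n_tests):
            tab = np.empty((4, 2, 4))
            for k in range(4):
                # both rows drawn from one shared multinomial: null by design
                tab[k, 0] = rng.multinomial(400, [0.4, 0.3, 0.2, 0.1])
                tab[k, 1] = rng.multinomial(500, [0.4, 0.3, 0.2, 0.1])
            perm = rng.permutation(2)
            _, _, p, _ = cmh_general(tab[:, perm, :])
            rejected += p < 0.05
        rate = rejected / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < 4 * se


def _pools_from_freq_matrix(freqs, coverage, n_individuals, seed):
    """One case + one control pool per replicate from per-replicate freqs."""
    from poolscan.powersim import simulate_poolseq_counts

    pools = []
    rng = np.random.default_rng(seed)
    for rep, (f_case, f_ctrl) in enumerate(freqs, start=1):
        pools.append(
            simulate_poolseq_counts(
                f_case, coverage, int(rng.integers(2**62)),
                sample_id=f"r{rep}c", treatment="case", replicate=rep,
                n_individuals=n_individuals,
            )
        )
        pools.append(
            simulate_poolseq_counts(
                f_ctrl, coverage, int(rng.integers(2**62)),
                sample_id=f"r{rep}x", treatment="control", replicate=rep,
                n_individuals=n_individuals,
            )
        )
    return pools


def _panel(n_sites, seed=0):
    rng = np.random.default_rng(seed)
    panel = FounderPanel(
        founder_ids=["F1", "F2"],
        chrom=np.full(n_sites, "c1", dtype=object),
        positions_bp=np.arange(1, n_sites + 1) * 100,
        matrix=rng.integers(0, 2, size=(n_sites, 2)).astype(float),
    )
    gmap = GeneticMap(
        {"c1": (np.array([1, (n_sites + 1) * 100]), np.array([0.0, 5.0]))}
    )
    panel.attach_map(gmap)
    return panel


class TestDirectScan:
    def test_null_p_values_uniformish(self):
        S = 4_000
        rng = np.random.default_rng(3)
        base = rng.uniform(0.2, 0.8, S)
        freqs = [(base, base)] * 6
        pools = _pools_from_freq_matrix(freqs, 300, 100, seed=5)
        scan = scan_direct_snp(pools, _panel(S))
        p = scan["p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_doubling_counts_roughly_doubles_statistic(self):
        S = 50
        rng = np.random.default_rng(4)
        base = rng.uniform(0.3, 0.7, S)
        shifted = np.clip(base + 0.1, 0, 1)
        pools = _pools_from_freq_matrix([(shifted, base)] * 3, 500, 100, seed=6)
        doubled = [
            PoolCounts(p.sample_id, p.treatment, p.replicate, p.n_individuals,
                       p.ref_count * 2, p.alt_count * 2)
            for p in pools
        ]
        s1 = scan_direct_snp(pools, _panel(S))["statistic"].to_numpy()
        s2 = scan_direct_snp(doubled, _panel(S))["statistic"].to_numpy()
        ok = s1 > 1.0
        np.testing.assert_allclose(s2[ok], 2 * s1[ok], rtol=0.01)

    def test_replicate_missing_treatment_errors(self):
        pools = _pools_from_freq_matrix([(np.array([0.5]), np.array([0.5]))], 100, 10, 1)
        with pytest.raises(ValidationError):
            group_pools_by_replicate([pools[0]])

    def test_high_coverage_qtl_peak(self):
        S = 200
        rng = np.random.default_rng(8)
        base = rng.uniform(0.3, 0.7, S)
        shifted = base.copy()
        qtl = S // 2
        shifted[qtl] = np.clip(base[qtl] + 0.15, 0, 1)
        pools = _pools_from_freq_matrix([(shifted, base)] * 6, 5_000, 100, seed=9)
        scan = scan_direct_snp(pools, _panel(S))
        assert scan["neg_log10_p"].idxmax() == qtl


class TestHaplotypeScan:
    def _track(self, freqs, reps, treatments, n_individuals=100):
        n_samples, n_w, F = freqs.shape
        panel = _panel(10)
        wins = [
            Window("c1", float(i), 0.75, np.arange(10), np.arange(10))
            for i in range(n_w)
        ]
        return HaplotypeFreqTrack(
            windows=wins,
            sample_ids=[f"s{i}" for i in range(n_samples)],
            treatments=treatments,
            replicates=reps,
            n_individuals=[n_individuals] * n_samples,
            freqs=freqs,
            residual=np.zeros((n_samples, n_w)),
            flags=np.full((n_samples, n_w), "", dtype=object),
        )

    def test_identical_freqs_give_zero_statistic(self):
        f = np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (4, 3, 1))
        track = self._track(f, [1, 1, 2, 2], ["case", "control", "case", "control"])
        scan = scan_haplotype(track)
        np.testing.assert_allclose(scan["statistic"], 0.0, atol=1e-9)
        np.testing.assert_allclose(scan["p_value"], 1.0)

    def test_k_scales_statistic_and_preserves_ranking(self):
        rng = np.random.default_rng(10)
        f = rng.dirichlet(np.ones(4), size=(4, 5))
        f = f.reshape(4, 5, 4)
        track = self._track(f, [1, 1, 2, 2], ["case", "control", "case", "control"])
        s1 = scan_haplotype(track, efficiency_k=1.0, variant="no_tminus1")["statistic"]
        s07 = scan_haplotype(track, efficiency_k=0.7, variant="no_tminus1")["statistic"]
        np.testing.assert_allclose(s07, 0.7 * s1, rtol=1e-9)
        assert s1.idxmax() == s07.idxmax()

    def test_classical_k_scaling_is_asymptotic(self):
        rng = np.random.default_rng(11)
        f = rng.dirichlet(np.ones(4), size=(4, 2)).reshape(4, 2, 4)
        track = self._track(f, [1, 1, 2, 2], ["case", "control", "case", "control"],
                            n_individuals=10_000)
        s1 = scan_haplotype(track, efficiency_k=1.0)["statistic"]
        s07 = scan_haplotype(track, efficiency_k=0.7)["statistic"]
        np.testing.assert_allclose(s07, 0.7 * s1, rtol=0.01)


class TestImputedScan:
    def test_all_founders_share_allele_gives_zero(self):
        panel = _panel(5)
        panel.matrix[2, :] = 1.0
        wins = [Window("c1", 2.5, 2.5, np.arange(5), np.arange(5))]
        track = HaplotypeFreqTrack(
            windows=wins, sample_ids=["a", "b"], treatments=["case", "control"],
            replicates=[1, 1], n_individuals=[100, 100],
            freqs=np.random.default_rng(1).dirichlet(np.ones(2), size=(2, 1)),
            residual=np.zeros((2, 1)), flags=np.full((2, 1), "", dtype=object),
        )
        imputed = {
            "a": panel.matrix @ track.freqs[0, 0],
            "b": panel.matrix @ track.freqs[1, 0],
        }
        scan = scan_imputed_snp(imputed, track, panel)
        assert scan["statistic"].iloc[2] == pytest.approx(0.0, abs=1e-9)


class TestBonferroni:
    def test_single_test(self):
        assert bonferroni(1, 0.05) == pytest.approx(1.301, abs=1e-3)

    def test_million_tests(self):
        assert bonferroni(10**6, 0.05) == pytest.approx(7.301, abs=1e-3)

    def test_monotone_in_n(self):
        values = [bonferroni(n) for n in (1, 10, 100, 10**6)]
        assert values == sorted(values)

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            bonferroni(10, 1.5)


class TestCompareScans:
    def test_single_isolated_hit_cluster_zero(self):
        cm = np.array([0.0, 5.0, 10.0])
        nlp = np.array([1.0, 9.0, 1.0])
        assert cluster_score(cm, nlp, threshold=5.0) == 0.0

    def test_twenty_contiguous_hits_cluster_nineteen(self):
        cm = np.linspace(0, 0.95, 20)
        nlp = np.full(20, 8.0)
        assert cluster_score(cm, nlp, threshold=5.0) == 19.0

    def test_peak_never_exceeds_global_max(self):
        from poolscan.data import make_scan_frame

        rng = np.random.default_rng(2)
        S = 500
        scan = make_scan_frame(
            chrom=["c1"] * S, locus_id=np.arange(S), pos_bp=np.arange(S),
            cM=np.linspace(0, 10, S), statistic=rng.chisquare(1, S),
            df=np.ones(S, int), p_value=rng.uniform(1e-12, 1, S),
            scan_type="direct_snp",
        )
        rep = compare_scans({"direct_snp": scan}, "c1", 5.0, window_cM=1.5)
        row = rep.iloc[0]
        assert row["qtl_window_peak"] <= row["global_max"] + 1e-12
        assert row["gap"] == pytest.approx(row["qtl_window_peak"] - row["background_max"])
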