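"""TITAN unit and property tests: IndVal, partitions, change points,
bootstrap screening, community thresholds and alert extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ibdl import titan
from ibdl.io_tables import CalibrationError, CountMatrix
from ibdl.titan import (AlertTaxaSet, TitanTaxonResult, alert_taxa,
                        bootstrap_taxon, candidate_partitions, classify_taxa,
                        community_change_points, compute_indval, index_taxa,
                        taxon_change_point)


def _counts(rows, taxa):
    return CountMatrix(pd.DataFrame(rows, columns=taxa,
                                    index=[f"s{i}" for i in range(len(rows))],
                                    dtype=np.int64))


class TestIndexTaxa:
    def test_occurrence_threshold(self):
        m = _counts([[1, 1, 1], [2, 1, 0], [3, 0, 0], [0, 0, 0]], ["A", "B", "C"])
        assert index_taxa(m, 3) == ["A"]
        assert index_taxa(m, 2) == ["A", "B"]

    def test_all_rare_gives_empty_list(self):
        m = _counts([[1, 0], [0, 1]], ["A", "B"])
        assert index_taxa(m, 3) == []

    def test_empty_calibration_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            index_taxa([])


class TestComputeIndval:
    def test_perfect_indicator(self):
        abund = np.array([0, 0, 0, 0.2, 0.4, 0.3])
        high = np.array([False] * 3 + [True] * 3)
        ivl, ivh = compute_indval(abund, high)
        assert ivl[0] == 0.0 and ivh[0] == 100.0

    def test_equal_means_full_frequency_both_sides(self):
        abund = np.array([0.2, 0.2, 0.2, 0.2])
        high = np.array([False, False, True, True])
        ivl, ivh = compute_indval(abund, high)
        assert np.allclose([ivl[0], ivh[0]], [50.0, 50.0])

    def test_matches_direct_formula_on_toy_matrix(self, rng):
        abund = rng.uniform(0, 0.3, (6, 4)) * (rng.random((6, 4)) > 0.3)
        high = np.array([False, True, False, True, True, False])
        ivl, ivh = compute_indval(abund, high)
        for j in range(4):  # independent direct A*B*100 computation
            ml, mh = abund[~high, j].mean(), abund[high, j].mean()
            for side, (m, grp) in enumerate([(ml, ~high), (mh, high)]):
                a = m / (ml + mh) if ml + mh > 0 else 0.0
                b = (abund[grp, j] > 0).mean()
                expected = 100 * a * b
                assert np.isclose((ivl, ivh)[side][j], expected)

    def test_small_side_rejected(self):
        with pytest.raises(ValueError, match="minsplit"):
            compute_indval(np.ones(4), np.array([True, True, True, False]), minsplit=2)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_indval_bounds_and_specificity_sums(self, seed):
        r = np.random.default_rng(seed)
        abund = r.uniform(0, 1, (8, 3)) * (r.random((8, 3)) > 0.4)
        high = np.zeros(8, bool)
        high[r.choice(8, 4, replace=False)] = True
        ivl, ivh = compute_indval(abund, high)
        assert ((ivl >= 0) & (ivl <= 100) & (ivh >= 0) & (ivh <= 100)).all()
        ml = abund[~high].mean(axis=0)
        mh = abund[high].mean(axis=0)
        nonzero = ml + mh > 0
        a_sum = ml[nonzero] / (ml + mh)[nonzero] + mh[nonzero] / (ml + mh)[nonzero]
        assert np.allclose(a_sum, 1.0)


class TestCandidatePartitions:
    def test_forced_single_candidate(self):
        cands = candidate_partitions(np.array([1, 2, 3, 4, 5, 6.0]), minsplit=3)
        assert np.allclose(cands, [3.5])

    def test_degenerate_gradient_gives_no_candidates(self):
        assert candidate_partitions(np.ones(12), minsplit=3).size == 0

    def test_ties_never_split(self):
        env = np.array([1, 1, 1, 2, 2, 2.0])
        cands = candidate_partitions(env, minsplit=1)
        assert np.allclose(cands, [1.5])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            candidate_partitions(np.arange(5), minsplit=3)


class TestTaxonChangePoint:
    def test_planted_step_recovered(self, rng):
        env = rng.uniform(0, 1, 80)
        x0 = 0.5
        abund = np.where(env > x0, 0.2, 0.0) * rng.lognormal(0, 0.2, 80)
        cp, direction, z, ivmax = taxon_change_point(
            abund, env, n_perm=100, rng=np.random.default_rng(0), minsplit=5)
        cands = np.sort(candidate_partitions(env, 5))
        step = np.diff(cands).max()
        assert abs(cp - x0) <= step + 1e-12
        assert direction == "plus"
        assert z > 3

    def test_negation_flips_direction_exactly(self, rng):
        env = rng.uniform(0, 1, 60)
        abund = np.where(env > 0.4, 0.1, 0.01) * rng.lognormal(0, 0.3, 60)
        res = taxon_change_point(abund, env, 100, np.random.default_rng(7))
        neg = taxon_change_point(abund, -env, 100, np.random.default_rng(7))
        assert neg[1] == "minus" and res[1] == "plus"
        assert np.isclose(neg[0], -res[0])
        # z identical (not merely |z|) up to accumulation order
        assert np.isclose(neg[2], res[2], rtol=1e-9, atol=1e-9)

    def test_absent_taxon_flagged(self, rng):
        env = rng.uniform(0, 1, 40)
        with pytest.raises(ValueError, match="absent"):
            taxon_change_point(np.zeros(40), env, 100, np.random.default_rng(0))

    def test_n_perm_floor(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            taxon_change_point(np.ones(40), rng.uniform(0, 1, 40), n_perm=50)


class TestBootstrap:
    def test_strong_signal_pure_and_reliable(self, rng):
        env = rng.uniform(0, 1, 100)
        abund = np.where(env > 0.5, 0.2, 0.0) * rng.lognormal(0, 0.2, 100)
        purity, reliability, cp_q = bootstrap_taxon(
            abund, env, n_boot=200, rng=np.random.default_rng(1), n_perm=100)
        assert purity >= 0.95 and reliability >= 0.95
        assert cp_q[0] <= cp_q[1] <= cp_q[2]

    def test_noise_taxon_not_reliable(self, rng):
        env = rng.uniform(0, 1, 100)
        abund = rng.lognormal(0, 0.3, 100) * 0.02
        purity, reliability, _ = bootstrap_taxon(
            abund, env, n_boot=200, rng=np.random.default_rng(2), n_perm=100)
        assert reliability < 0.5

    def test_n_boot_zero_disallowed(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_taxon(np.ones(40), rng.uniform(0, 1, 40), n_boot=0)


def _mk_result(code, cp, direction, purity=0.99, reliability=0.99,
               thresholds=None, zp=None, zm=None):
    n = 5 if thresholds is None else len(thresholds)
    return TitanTaxonResult(
        taxon_code=code, change_point=cp, direction=direction, indval_max=80.0,
        z=5.0, p_value=0.001, purity=purity, reliability=reliability,
        cp_quantiles=(cp - 0.1, cp, cp + 0.1),
        thresholds=np.linspace(0, 1, n) if thresholds is None else thresholds,
        z_profile_plus=np.zeros(n) if zp is None else zp,
        z_profile_minus=np.zeros(n) if zm is None else zm,
    )


class TestClassify:
    def test_rule_application(self):
        r = classify_taxa([_mk_result("A", 0.4, "plus", 0.99, 0.97)])[0]
        assert r.group == "Zplus"

    def test_below_purity_indifferent(self):
        r = classify_taxa([_mk_result("A", 0.4, "plus", purity=0.80)])[0]
        assert r.group == "indifferent"

    def test_boundary_inclusive(self):
        r = classify_taxa([_mk_result("A", 0.4, "minus", 0.95, 0.95)])[0]
        assert r.group == "Zminus"


class TestCommunityAndAlert:
    def test_single_taxon_community_cp_equals_taxon_cp(self, rng):
        # scalar-normalized z profile peaks where the taxon's own IndVal does
        env = rng.uniform(0, 1, 60)
        abund = np.where(env > 0.5, 0.2, 0.0) * rng.lognormal(0, 0.2, 60)
        res = titan._analyze_taxon("A", abund, env, 100, 50,
                                   np.random.default_rng(3), 5)
        classify_taxa([res])
        assert res.group == "Zplus"
        comm = community_change_points([res])
        assert np.isclose(comm.cp_sumz_plus, res.change_point)

    def test_identical_profiles_share_cp(self):
        thr = np.linspace(0.1, 0.9, 9)
        zp = np.exp(-((thr - 0.6) ** 2) / 0.02)
        a = _mk_result("A", 0.6, "plus", thresholds=thr, zp=zp)
        b = _mk_result("B", 0.6, "plus", thresholds=thr, zp=zp)
        classify_taxa([a, b])
        comm = community_change_points([a, b])
        assert np.isclose(comm.cp_sumz_plus, thr[zp.argmax()])

    def test_no_responders_errors(self):
        r = _mk_result("A", 0.4, "plus", purity=0.2)
        classify_taxa([r])
        with pytest.raises(CalibrationError, match="no responders"):
            community_change_points([r])

    def test_alert_rule_default_keeps_early_shifters(self):
        thr = np.linspace(0.1, 0.9, 9)
        peak = np.exp(-((thr - 0.5) ** 2) / 0.02)
        early = _mk_result("EARL", 0.3, "plus", thresholds=thr, zp=peak)
        late = _mk_result("LATE", 0.7, "plus", thresholds=thr, zp=peak)
        indiff = _mk_result("INDF", 0.2, "plus", purity=0.1, thresholds=thr, zp=peak)
        results = classify_taxa([early, late, indiff])
        comm = community_change_points(results)
        assert np.isclose(comm.cp_sumz_plus, 0.5)
        alerts = alert_taxa(results, comm, variable="NKJ")
        assert alerts.taxa == (("EARL", "plus"),)
        # indifferent taxa never enter the alert set under any rule
        for rule in ("le_le", "le_ge", "ge_le", "ge_ge"):
            assert "INDF" not in alert_taxa(results, comm, rule=rule).codes()

    def test_alternative_rule_keeps_late_shifters(self):
        thr = np.linspace(0.1, 0.9, 9)
        peak = np.exp(-((thr - 0.5) ** 2) / 0.02)
        early = _mk_result("EARL", 0.3, "plus", thresholds=thr, zp=peak)
        late = _mk_result("LATE", 0.7, "plus", thresholds=thr, zp=peak)
        results = classify_taxa([early, late])
        comm = community_change_points(results)
        alerts = alert_taxa(results, comm, rule="le_ge")
        assert alerts.taxa == (("LATE", "plus"),)

    def test_empty_classified_set_gives_empty_alerts(self):
        r = classify_taxa([_mk_result("A", 0.4, "plus", purity=0.1)])
        alerts = alert_taxa(r, None, variable="Pt")
        assert alerts == AlertTaxaSet("Pt", ())


class TestScanOracle:
    def test_scan_matches_exhaustive_enumeration_small(self, rng):
        """Boundary-scan result equals brute force over all order-respecting
        splits on random 8-sample matrices."""
        for case in range(10):
            env = rng.uniform(0, 1, 8)
            abund = rng.uniform(0, 1, 8) * (rng.random(8) > 0.3)
            if not (abund > 0).any():
                continue
            cp, direction, _, ivmax = taxon_change_point(
                abund, env, 100, np.random.default_rng(case), minsplit=2)
            best = (-1.0, None, None)
            es = np.sort(env)
            for b in range(7):
                if es[b + 1] <= es[b] or b + 1 < 2 or 7 - b < 2:
                    continue
                thr = (es[b] + es[b + 1]) / 2
                hi = env > thr
                ml, mh = abund[~hi].mean(), abund[hi].mean()
                ivl = 100 * (ml / (ml + mh)) * (abund[~hi] > 0).mean() if ml + mh else 0
                ivh = 100 * (mh / (ml + mh)) * (abund[hi] > 0).mean() if ml + mh else 0
                stat = max(ivl, ivh)
                if stat > best[0]:
                    best = (stat, thr, "plus" if ivh >= ivl else "minus")
            assert np.isclose(ivmax, best[0])
            assert np.isclose(cp, best[1])
            assert direction == best[2]

    def test_kernel_and_numpy_paths_agree(self, rng):
        A = rng.lognormal(0, 1, (40, 20)) * (rng.random((40, 20)) > 0.4)
        vb = titan._valid_boundaries(np.sort(rng.uniform(0, 1, 20)), 3)
        VB = np.tile(vb, (40, 1))
        m1 = titan._scan_rows_numpy(A, VB)
        m2 = (titan._scan_kernel(A, VB) if titan._HAVE_NUMBA
              else titan._scan_rows_numpy(A, VB))
        assert np.allclose(m1[0], m2[0])
        assert (m1[1] == m2[1]).all() and (m1[2] == m2[2]).all()


class TestMonotoneTransformInvariance:
    def test_change_point_invariant_up_to_candidate_relocation(self, rng):
        env = rng.uniform(0, 1, 50)
        abund = np.where(env > 0.45, 0.15, 0.0) * rng.lognormal(0, 0.2, 50)
        cp1, d1, z1, iv1 = taxon_change_point(abund, env, 100,
                                              np.random.default_rng(5))
        cp2, d2, z2, iv2 = taxon_change_point(abund, np.exp(env), 100,
                                              np.random.default_rng(5))
        # the partition sequence is identical, so the chosen split is the
        # same sample boundary and the statistics match exactly
        assert d1 == d2 and np.isclose(z1, z2) and np.isclose(iv1, iv2)
        rank1 = (env <= cp1).sum()
        rank2 = (np.exp(env) <= cp2).sum()
        assert rank1 == rank2
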