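"""Metric chain (raw -> SES -> SESnor -> EQR), reference conditions,
selection screen and substrate test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ibdl.io_tables import CalibrationError
from ibdl.metrics import (eqr, group_stats, identify_reference_lakes,
                          raw_metric, reference_value, select_metrics, ses,
                          ses_normalize, substrate_effect_test)


class TestRawMetric:
    @pytest.mark.parametrize("present,alert,expected", [
        (20, 0, 1.0),    # no alert taxon present
        (15, 15, 0.0),   # species list entirely composed of alert taxa
        (12, 3, 0.75),
    ])
    def test_ratio(self, present, alert, expected):
        taxa = [f"T{i}" for i in range(present)]
        assert raw_metric(taxa, taxa[:alert], taxa) == pytest.approx(expected)

    def test_undefined_without_index_taxa(self):
        assert np.isnan(raw_metric(["X"], [], ["A", "B"]))

    def test_absent_alert_taxa_do_not_count(self):
        # alert taxon not present in the sample leaves the metric at 1
        assert raw_metric(["A"], ["B"], ["A", "B"]) == 1.0


class TestSESChain:
    @pytest.mark.parametrize("raw,m,sd,expected", [
        (0.6, 0.6, 0.1, 0.0),
        (0.7, 0.6, 0.1, 1.0),
        (0.8, 0.6, 0.1, 2.0),
    ])
    def test_ses(self, raw, m, sd, expected):
        assert ses(raw, m, sd) == pytest.approx(expected)

    def test_ses_requires_positive_sd(self):
        with pytest.raises(CalibrationError):
            ses(0.5, 0.5, 0.0)

    @pytest.mark.parametrize("value,expected", [(-2.0, 0.0), (1.0, 1.0), (-0.5, 0.5)])
    def test_normalization_bounds(self, value, expected):
        assert ses_normalize(value, (-2.0, 1.0)) == pytest.approx(expected)

    def test_normalization_degenerate_bounds(self):
        with pytest.raises(CalibrationError):
            ses_normalize(0.5, (1.0, 1.0))

    def test_clamped_out_of_calibration(self):
        assert ses_normalize(5.0, (-1.0, 1.0), clamp=True) == 1.0
        assert ses_normalize(-5.0, (-1.0, 1.0), clamp=True) == 0.0

    @pytest.mark.parametrize("sesnor,ref,expected", [
        (0.9, 0.9, 1.0),
        (0.45, 0.9, 0.5),
        (0.95, 0.9, 1.0),   # capped
    ])
    def test_eqr(self, sesnor, ref, expected):
        assert eqr(sesnor, ref) == pytest.approx(expected)

    def test_eqr_uncapped_available(self):
        assert eqr(0.95, 0.9, cap=False) == pytest.approx(0.95 / 0.9)

    def test_eqr_zero_reference(self):
        with pytest.raises(CalibrationError):
            eqr(0.5, 0.0)

    def test_chain_monotone_in_alert_count(self):
        # adding one alert taxon to the present list strictly lowers every
        # stage of the chain (until the EQR cap)
        taxa = [f"T{i}" for i in range(10)]
        values = []
        for n_alert in range(4):
            raw = raw_metric(taxa, taxa[:n_alert], taxa)
            s = ses(raw, 0.5, 0.2)
            sn = ses_normalize(s, (-3.0, 3.0))
            values.append((raw, s, sn, eqr(sn, 0.95, cap=False)))
        arr = np.array(values)
        assert (np.diff(arr, axis=0) < 0).all()


class TestReferenceConditions:
    def test_land_use_criteria(self):
        lakes = pd.DataFrame({
            "lake_id": ["A", "B", "C", "D"],
            "pct_artificial_landuse": [0.3, 0.5, 0.3, np.nan],
            "pct_agriculture": [10.0, 10.0, 25.0, 5.0],
        })
        flags = identify_reference_lakes(lakes)
        assert flags.tolist() == [True, False, False, False]

    def test_reference_value_mean_and_single(self):
        sesnor = pd.Series([0.9, 0.9, 0.5], index=["s1", "s2", "s3"])
        lakes = pd.Series(["A", "A", "B"], index=sesnor.index)
        flags = pd.Series([True, False], index=["A", "B"])
        assert reference_value(sesnor, lakes, flags) == pytest.approx(0.9)
        single = reference_value(sesnor.iloc[:1], lakes.iloc[:1], flags)
        assert single == pytest.approx(0.9)

    def test_empty_pool_errors(self):
        sesnor = pd.Series([0.9], index=["s1"])
        lakes = pd.Series(["B"], index=["s1"])
        flags = pd.Series([False], index=["B"])
        with pytest.raises(CalibrationError, match="reference pool"):
            reference_value(sesnor, lakes, flags)


def _exact_corr_pair(r, n=40, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std()
    return x, r * x + np.sqrt(1 - r * r) * z


class TestSelection:
    @pytest.mark.parametrize("r,kept", [
        (-1.0, True), (-0.553, False), (-0.61, True), (0.61, True), (0.3, False),
    ])
    def test_threshold_rule_absolute_value(self, r, kept):
        x, y = _exact_corr_pair(r)
        metric = pd.DataFrame({"VAR": y}, index=range(len(x)))
        env = pd.DataFrame({"VAR": x}, index=range(len(x)))
        rep = select_metrics(metric, env)
        assert rep.loc[0, "status"] == ("selected" if kept else "dropped")
        assert rep.loc[0, "pearson_r"] == pytest.approx(r)

    def test_too_few_pairs_skipped(self):
        metric = pd.DataFrame({"VAR": [0.1, 0.2, np.nan, np.nan]})
        env = pd.DataFrame({"VAR": [1.0, 2.0, 3.0, 4.0]})
        assert select_metrics(metric, env).loc[0, "status"] == "skipped"


class TestSubstrateEffect:
    def test_identical_pairs(self):
        x = pd.Series(np.linspace(0.2, 0.9, 10))
        stat, p, n = substrate_effect_test(x, x.copy())
        assert stat == 0.0 and p == 1.0 and n == 10

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(4)
        base = pd.Series(rng.uniform(0.3, 0.8, 20))
        stat, p, n = substrate_effect_test(base + 0.05, base)
        assert p < 0.01

    def test_too_few_pairs(self):
        x = pd.Series([0.1, 0.2, 0.3])
        stat, p, n = substrate_effect_test(x, x + 0.1)
        assert np.isnan(p) and n == 3

    def test_null_pairs_not_significant_typically(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(50):
            a = pd.Series(rng.uniform(0, 1, 15))
            b = pd.Series(rng.uniform(0, 1, 15))
            _, p, _ = substrate_effect_test(a, b)
            hits += p < 0.05
        assert hits <= 8  # ~binomial(50, 0.05)


class TestGroupStats:
    def test_group_centering_removes_group_means(self, rng):
        substrate = pd.Series(["mineral", "macrophyte"] * 30)
        metatype = pd.Series(["HA", "MA", "LA"] * 20)
        raw = pd.Series(rng.uniform(0.2, 1.0, 60))
        gs = group_stats(raw, substrate, metatype)
        keys = substrate + "|" + metatype
        s = (raw - keys.map({k: v[0] for k, v in gs.items()})) / \
            keys.map({k: v[1] for k, v in gs.items()})
        for _, grp in s.groupby(keys):
            assert abs(grp.mean()) < 1e-10

    def test_degenerate_group_rejected(self):
        raw = pd.Series([0.5, 0.5, 0.7, 0.8])
        substrate = pd.Series(["mineral"] * 2 + ["macrophyte"] * 2)
        metatype = pd.Series(["HA"] * 4)
        with pytest.raises(CalibrationError, match="no spread"):
            group_stats(raw, substrate, metatype)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
def test_ou_mean_inside_hull(eqrs):
    from ibdl.aggregation import ou_substrate_score
    score = ou_substrate_score(eqrs)
    assert min(eqrs) - 1e-12 <= score <= max(eqrs) + 1e-12
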