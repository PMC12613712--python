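import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cucurgrow import (
    accumulate_thermal_time,
    estimate_nfr,
    flower_distance_to_tip,
    node_increase,
)


def climate_from(temps, start=0):
    return pd.DataFrame(
        {"dat": np.arange(start, start + len(temps)), "t_mean": temps, "solar": 10.0}
    )


class TestThermalTime:
    def test_constant_temperature_sum(self):
        th = accumulate_thermal_time(climate_from([20.0] * 11), start_dat=0)
        assert th["at"].iloc[-1] == pytest.approx(200.0)
        assert th["at"].iloc[0] == 0.0

    def test_mixed_temperatures_match_cumsum_oracle(self):
        temps = [25.0, 18.0, 22.0, 20.0]
        th = accumulate_thermal_time(climate_from(temps), start_dat=0)
        # independent running-sum oracle over post-start days
        expected, acc = [0.0], 0.0
        for t in temps[1:]:
            acc += t
            expected.append(acc)
        assert np.allclose(th["at"], expected)
        assert list(th["at"]) == [0.0, 18.0, 40.0, 60.0]

    def test_at_non_decreasing(self):
        rng = np.random.default_rng(0)
        th = accumulate_thermal_time(climate_from(rng.uniform(10, 30, 50)), 5)
        assert (np.diff(th["at"]) >= 0).all()

    def test_start_outside_range_rejected(self):
        with pytest.raises(ValueError):
            accumulate_thermal_time(climate_from([20.0] * 5), start_dat=10)


class TestNodeIncrease:
    def test_baseline_subtraction(self):
        th = accumulate_thermal_time(climate_from([20.0] * 70), 38)
        obs = pd.DataFrame(
            {"plant": ["a", "a"], "dat": [38, 60], "node_count": [12, 20]}
        )
        curve = node_increase(obs, th, start_dat=38)
        assert list(curve["node_increase"]) == [0, 8]

    def test_single_observation_plant(self):
        th = accumulate_thermal_time(climate_from([20.0] * 70), 38)
        obs = pd.DataFrame({"plant": ["a"], "dat": [38], "node_count": [12]})
        curve = node_increase(obs, th, start_dat=38)
        assert list(curve["node_increase"]) == [0]

    def test_per_plant_baselines_independent(self):
        th = accumulate_thermal_time(climate_from([20.0] * 70), 38)
        obs = pd.DataFrame(
            {
                "plant": ["a", "a", "b", "b", "c", "c"],
                "dat": [38, 60, 38, 60, 38, 60],
                "node_count": [10, 18, 14, 22, 30, 38],
            }
        )
        curve = node_increase(obs, th, start_dat=38)
        # brute-force per-group subtraction oracle
        for plant, grp in obs.groupby("plant"):
            base = grp.loc[grp["dat"] == 38, "node_count"].iloc[0]
            got = curve.loc[curve["plant"] == plant, "node_increase"].to_numpy()
            assert np.array_equal(got, grp["node_count"].to_numpy() - base)

    def test_plant_without_baseline_dropped(self):
        th = accumulate_thermal_time(climate_from([20.0] * 120), 38)
        obs = pd.DataFrame(
            {
                "plant": ["a", "a", "b"],
                "dat": [38, 60, 90],
                "node_count": [10, 18, 30],
            }
        )
        curve = node_increase(obs, th, start_dat=38)
        assert set(curve["plant"]) == {"a"}

    def test_empty_table_rejected(self):
        th = accumulate_thermal_time(climate_from([20.0] * 70), 38)
        with pytest.raises(ValueError):
            node_increase(pd.DataFrame(columns=["plant", "dat", "node_count"]),
                          th, start_dat=38)


class TestEstimateNfr:
    def _linear_curve(self, slope=0.02, n_plants=1, offset=0.0):
        th = accumulate_thermal_time(climate_from([20.0] * 120, start=38), 38)
        rows = []
        for p in range(n_plants):
            for dat in (38, 60, 82, 104):
                at = float(th.loc[th["dat"] == dat, "at"].iloc[0])
                rows.append(
                    {
                        "plant": f"p{p}",
                        "dat": dat,
                        "node_count": 10 + p + offset + slope * at,
                        "node_increase": slope * at,
                        "at": at,
                    }
                )
        return pd.DataFrame(rows)

    def test_linear_curve_both_methods(self):
        curve = self._linear_curve(slope=0.02, n_plants=3)
        for method in ("mean", "windowed"):
            est = estimate_nfr(curve, method=method)
            assert est.estimate == pytest.approx(0.02, rel=1e-12)

    def test_constant_count_gives_zero(self):
        curve = self._linear_curve(slope=0.0, n_plants=2)
        assert estimate_nfr(curve).estimate == 0.0

    def test_mean_equals_at_weighted_windowed(self):
        """Telescoping identity: final/final slope equals the AT-weighted
        mean of inter-observation slopes."""
        rng = np.random.default_rng(3)
        th = accumulate_thermal_time(climate_from(rng.uniform(15, 28, 200), 38), 38)
        rows = []
        for p in range(4):
            counts = np.cumsum(rng.integers(0, 4, 8))
            dats = np.sort(rng.choice(np.arange(39, 230), 8, replace=False))
            at = np.interp(dats, th["dat"], th["at"])
            for d, a, c in zip(dats, at, counts):
                rows.append({"plant": f"p{p}", "dat": d, "node_increase": c, "at": a})
        curve = pd.DataFrame(rows)
        m = estimate_nfr(curve, "mean")
        w = estimate_nfr(curve, "windowed")
        assert m.estimate == pytest.approx(w.estimate, rel=1e-12)
        pd.testing.assert_series_equal(m.per_plant, w.per_plant, rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(shift=st.integers(-50, 50))
    def test_invariance_to_baseline_shift(self, shift):
        curve = self._linear_curve(slope=0.017, n_plants=2, offset=float(shift))
        est = estimate_nfr(curve)
        assert est.estimate == pytest.approx(0.017, rel=1e-9)

    def test_zero_at_span_raises(self):
        curve = pd.DataFrame(
            {"plant": ["a", "a"], "dat": [38, 39], "node_increase": [0, 1],
             "at": [0.0, 0.0]}
        )
        with pytest.raises(ZeroDivisionError):
            estimate_nfr(curve)


class TestFlowerDistance:
    def test_distances(self):
        obs = pd.DataFrame(
            {
                "plant": ["a", "a"],
                "dat": [60, 67],
                "node_count": [40, 42],
                "flower_nodes": ["34", "42;40"],
            }
        )
        out = flower_distance_to_tip(obs)
        # brute force: distances 6, 0, 2 -> mean 8/3
        assert out.loc[0, "mean_distance"] == pytest.approx(8.0 / 3.0)
        assert out.loc[0, "n_flowers"] == 3

    def test_flower_beyond_tip_rejected(self):
        obs = pd.DataFrame(
            {"plant": ["a"], "dat": [60], "node_count": [40], "flower_nodes": ["41"]}
        )
        with pytest.raises(ValueError):
            flower_distance_to_tip(obs)
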