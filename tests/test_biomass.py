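import numpy as np
import pandas as pd
import pytest

from cucurgrow import (
    compute_tdm,
    cumulative_fruit_fraction,
    estimate_lue,
    fruit_partition_fraction,
    interval_dm_production,
)
from cucurgrow.biomass import validate_terms


def destructive_row(plant, dat, leaf=0.0, stem=0.0, fruit=0.0, harv=0.0, trim=0.0):
    return {
        "plant": plant, "dat": dat, "leaf_dw": leaf, "stem_dw": stem,
        "fruit_dw": fruit, "harvested_fruit_dm": harv, "trimmed_leaf_dm": trim,
    }


class TestComputeTdm:
    def test_ledger_sum(self):
        obs = pd.DataFrame([destructive_row("a", 100, 120, 70, 10, 120, 30)])
        rec = compute_tdm(obs, density=4.444, stems_per_plant=2)
        assert rec["standing_dw"].iloc[0] == pytest.approx(200.0)
        assert rec["tdm"].iloc[0] == pytest.approx(350.0)
        assert rec["tdm_area"].iloc[0] == pytest.approx(350.0 * 4.444 / 2)

    def test_zero_ledgers(self):
        obs = pd.DataFrame([destructive_row("a", 100, 100, 100)])
        rec = compute_tdm(obs, density=2.0, stems_per_plant=2)
        assert rec["tdm"].iloc[0] == rec["standing_dw"].iloc[0]

    def test_missing_ledger_rejected(self):
        obs = pd.DataFrame([destructive_row("a", 100)]).drop(columns="trimmed_leaf_dm")
        with pytest.raises(ValueError):
            compute_tdm(obs, density=2.0)


class TestIntervalProduction:
    def _records(self):
        rows = [
            destructive_row("e1", 0, leaf=50.0),
            destructive_row("e2", 0, leaf=150.0),  # mean 100 at DAT 0 (area=x1)
            destructive_row("l1", 45, leaf=150.0),
            destructive_row("l2", 45, leaf=170.0),
        ]
        return compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)

    def test_later_minus_earlier_mean(self):
        out = interval_dm_production(self._records(), terms=[(0, 45)])
        assert sorted(out["d_tdm"]) == [50.0, 70.0]

    def test_identical_timepoints_give_zero(self):
        rows = [destructive_row("a", 0, leaf=80.0), destructive_row("b", 45, leaf=80.0)]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = interval_dm_production(rec, terms=[(0, 45)])
        assert out["d_tdm"].iloc[0] == 0.0

    def test_three_term_hand_oracle(self):
        vals = {0: [10.0, 20.0], 30: [100.0], 60: [200.0, 220.0], 90: [400.0]}
        rows = [
            destructive_row(f"p{d}{i}", d, leaf=v)
            for d, vs in vals.items()
            for i, v in enumerate(vs)
        ]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = interval_dm_production(rec, terms=[(0, 30), (30, 60), (60, 90)])
        by_term = out.groupby("term")["d_tdm"].apply(list).to_dict()
        assert by_term == {1: [85.0], 2: [100.0, 120.0], 3: [190.0]}

    def test_telescoping_sum(self):
        """Sum of term-mean DM production equals end-minus-start TDM."""
        rng = np.random.default_rng(5)
        rows = []
        for d in (0, 45, 66, 105, 142, 228):
            for i in range(3):
                rows.append(destructive_row(f"p{d}-{i}", d, leaf=d * 3.0 + rng.uniform(0, 30)))
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = interval_dm_production(rec)
        term_means = out.groupby("term")["d_tdm"].mean()
        start = rec.loc[rec["dat"] == 0, "tdm_area"].mean()
        end = rec.loc[rec["dat"] == 228, "tdm_area"].mean()
        assert term_means.sum() == pytest.approx(end - start, rel=1e-9)

    def test_missing_boundary_rejected(self):
        with pytest.raises(ValueError):
            interval_dm_production(self._records(), terms=[(0, 46)])

    def test_bad_terms_rejected(self):
        with pytest.raises(ValueError):
            validate_terms([(0, 45), (50, 66)])


class TestPartitionFraction:
    def test_simple_ratio(self):
        rows = [
            destructive_row("a", 0, leaf=100.0, harv=0.0),
            destructive_row("b", 45, leaf=150.0, harv=50.0),  # dTDM 100, fruit 50
        ]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = fruit_partition_fraction(rec, terms=[(0, 45)])
        assert out["fraction"].iloc[0] == pytest.approx(0.5)

    def test_no_fruit_growth_gives_zero(self):
        rows = [destructive_row("a", 0, leaf=50.0), destructive_row("b", 45, leaf=90.0)]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = fruit_partition_fraction(rec, terms=[(0, 45)])
        assert out["fraction"].iloc[0] == 0.0

    def test_nonpositive_production_reported_missing(self):
        rows = [destructive_row("a", 0, leaf=100.0), destructive_row("b", 45, leaf=80.0)]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = fruit_partition_fraction(rec, terms=[(0, 45)])
        assert out["undefined"].iloc[0]
        assert np.isnan(out["fraction"].iloc[0])


class TestCumulativeFraction:
    def test_ratio_and_dat0_convention(self):
        rows = [
            destructive_row("z", 0),  # TDM 0 -> fraction 0 by convention
            destructive_row("a", 228, leaf=300.0, stem=220.0, harv=480.0),
        ]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        out = cumulative_fruit_fraction(rec).set_index("dat")
        assert out.loc[0, "fraction"] == 0.0
        assert out.loc[228, "fraction"] == pytest.approx(0.48)


class TestEstimateLue:
    def _cum_il(self, n=240, rate=1.5):
        return pd.DataFrame({"dat": np.arange(n), "cum_il": rate * np.arange(n)})

    def test_exact_line_through_origin(self):
        cum = self._cum_il()
        rows = []
        for d in (0, 60, 120, 228):
            x = 1.5 * d
            rows.append(destructive_row(f"p{d}", d, leaf=4.0 * x + 10.0))
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        fit = estimate_lue(rec, cum)  # initial_dw defaults to TDM at DAT 0
        assert fit.slope == pytest.approx(4.0, rel=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-9)

    def test_flat_biomass_gives_zero_slope(self):
        rows = [destructive_row(f"p{d}", d, leaf=25.0) for d in (0, 60, 120)]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        fit = estimate_lue(rec, self._cum_il())
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_free_intercept_option(self):
        cum = self._cum_il()
        rows = [destructive_row(f"p{d}", d, leaf=3.0 * 1.5 * d + 40.0) for d in (0, 50, 100, 200)]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        fit = estimate_lue(rec, cum, initial_dw=0.0, through_origin=False)
        assert fit.slope == pytest.approx(3.0, rel=1e-9)
        assert fit.intercept == pytest.approx(40.0, rel=1e-6)

    def test_single_timepoint_rejected(self):
        rows = [destructive_row("a", 60, leaf=10.0)]
        rec = compute_tdm(pd.DataFrame(rows), density=1.0, stems_per_plant=1)
        with pytest.raises(ValueError):
            estimate_lue(rec, self._cum_il())
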