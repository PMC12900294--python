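import io

import numpy as np
import pandas as pd
import pytest

from eeldiet.trials import (
    PERIOD_EARLY,
    PERIOD_LATE,
    PERIOD_OVERALL,
    TankRecord,
    TrialDataError,
    chained_survival,
    pairwise_correlations,
    period_outcomes,
    read_tank_records,
    standardize_outcomes,
    standardize_z,
    survival_rate,
    write_tank_records,
)


class TestSurvivalRates:
    @pytest.mark.parametrize(
        "survivors,stocked,expected",
        [(250, 250, 100.0), (0, 250, 0.0), (125, 250, 50.0)],
    )
    def test_survival_rate(self, survivors, stocked, expected):
        assert survival_rate(survivors, stocked) == pytest.approx(expected)

    def test_zero_stocked_rejected(self):
        with pytest.raises(TrialDataError):
            survival_rate(0, 0)

    @pytest.mark.parametrize(
        "s40,stocked41,survivors,expected",
        [(80.0, 100, 100, 80.0), (80.0, 100, 50, 40.0), (0.0, 100, 50, 0.0)],
    )
    def test_chained_survival(self, s40, stocked41, survivors, expected):
        assert chained_survival(s40, stocked41, survivors) == pytest.approx(expected)

    def test_chained_equals_plain_without_restocking(self):
        # stocking at 41 dph = survivors at 40: chaining collapses to the
        # plain cumulative rate
        s40 = survival_rate(200, 250)
        assert chained_survival(s40, 200, 150) == pytest.approx(
            survival_rate(150, 250)
        )


class TestStandardize:
    def test_value_at_reference_mean_is_zero(self):
        vals = pd.Series({"FSD": 1.0, "FSY": 3.0, "A": 2.0})
        z = standardize_z(vals)
        assert z["A"] == pytest.approx(0.0)

    def test_two_reference_sample_sd(self):
        vals = pd.Series({"FSD": 1.0, "FSY": 3.0, "A": 4.0})
        z = standardize_z(vals)
        assert z["A"] == pytest.approx(2.0 / np.sqrt(2.0))

    def test_reference_z_symmetric_about_zero(self):
        vals = pd.Series({"FSD": 1.0, "FSY": 3.0, "A": 2.5})
        z = standardize_z(vals)
        assert z["FSD"] == pytest.approx(-z["FSY"])

    def test_equal_references_undefined(self):
        with pytest.raises(TrialDataError, match="zero"):
            standardize_z(pd.Series({"FSD": 2.0, "FSY": 2.0, "A": 3.0}))

    def test_shift_invariance(self):
        vals = pd.Series({"FSD": 1.0, "FSY": 3.0, "A": 4.0, "B": 0.5})
        shifted = vals + 17.3
        pd.testing.assert_series_equal(standardize_z(vals), standardize_z(shifted))

    def test_scale_free(self):
        vals = pd.Series({"FSD": 1.0, "FSY": 3.0, "A": 4.0})
        pd.testing.assert_series_equal(standardize_z(vals), standardize_z(vals * 7.0))

    def test_trial_sd_mode_uses_all_diets(self):
        vals = pd.Series({"FSD": 1.0, "FSY": 3.0, "A": 4.0})
        z = standardize_z(vals, sd_mode="trial")
        assert z["A"] == pytest.approx((4.0 - 2.0) / vals.std(ddof=1))

    def test_missing_reference_rejected(self):
        with pytest.raises(TrialDataError, match="FSY"):
            standardize_z(pd.Series({"FSD": 1.0, "A": 4.0}))


def _record(**kw):
    base = dict(trial_id="T1", diet_id="A", tank_id="t1", stocked=250)
    base.update(kw)
    return TankRecord(**base)


class TestTankRecord:
    def test_increasing_survivors_rejected(self):
        with pytest.raises(TrialDataError, match="non-increasing"):
            _record(survivors={20: 100, 40: 150})

    def test_survivors_above_stocked_rejected(self):
        with pytest.raises(TrialDataError):
            _record(survivors={20: 300})

    def test_post_restock_segment_capped_by_restocked_count(self):
        with pytest.raises(TrialDataError):
            _record(restocked_at_41=100, survivors={40: 200, 60: 150})

    def test_nonpositive_tl_rejected(self):
        with pytest.raises(TrialDataError, match="TL"):
            _record(survivors={40: 100}, mean_tl={40: 0.0})


class TestPeriodOutcomes:
    def test_early_survival_from_40dph_count(self):
        recs = [_record(survivors={40: 125, 80: 100},
                        mean_tl={40: 20.0, 80: 30.0})]
        out = period_outcomes(recs).set_index("period")
        assert out.loc[PERIOD_EARLY, "survival"] == pytest.approx(50.0)
        assert out.loc[PERIOD_EARLY, "mean_tl"] == pytest.approx(20.0)
        assert out.loc[PERIOD_LATE, "survival"] == pytest.approx(80.0)
        assert out.loc[PERIOD_OVERALL, "survival"] == pytest.approx(40.0)

    def test_missing_terminal_point_flagged_not_imputed(self):
        recs = [_record(survivors={40: 125}, mean_tl={40: 20.0})]
        out = period_outcomes(recs).set_index("period")
        assert np.isnan(out.loc[PERIOD_LATE, "survival"])
        assert np.isnan(out.loc[PERIOD_OVERALL, "survival"])

    def test_restocked_overall_survival_chains(self):
        recs = [_record(survivors={40: 200, 80: 75}, restocked_at_41=100,
                        mean_tl={40: 20.0, 80: 30.0})]
        out = period_outcomes(recs).set_index("period")
        # survival to 40 = 80%; 75 of 100 restocked -> overall 60%
        assert out.loc[PERIOD_OVERALL, "survival"] == pytest.approx(60.0)
        assert out.loc[PERIOD_LATE, "survival"] == pytest.approx(75.0)

    def test_replicate_tanks_averaged(self):
        recs = [
            _record(tank_id="t1", survivors={40: 100}, mean_tl={40: 20.0}),
            _record(tank_id="t2", survivors={40: 150}, mean_tl={40: 22.0}),
        ]
        out = period_outcomes(recs).set_index("period")
        assert out.loc[PERIOD_EARLY, "survival"] == pytest.approx(50.0)
        assert out.loc[PERIOD_EARLY, "mean_tl"] == pytest.approx(21.0)


class TestCorrelations:
    @staticmethod
    def _standardized(n=12, seed=0, anti=False):
        rng = np.random.default_rng(seed)
        rows = []
        zs = rng.normal(size=n)
        for i in range(n):
            for period in (PERIOD_EARLY, PERIOD_LATE, PERIOD_OVERALL):
                rows.append({
                    "trial_id": "T1", "diet_id": f"d{i}", "period": period,
                    "z_survival": zs[i],
                    "z_tl": -zs[i] if anti else rng.normal(),
                })
        return pd.DataFrame(rows)

    def test_matrix_symmetric_with_unit_diagonal(self):
        r, p = pairwise_correlations(self._standardized())
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        assert np.allclose(np.diag(r.values), 1.0)
        assert r.values[np.isfinite(r.values)].min() >= -1.0
        assert r.values[np.isfinite(r.values)].max() <= 1.0

    def test_perfect_anticorrelation(self):
        r, _ = pairwise_correlations(self._standardized(anti=True))
        assert r.loc[f"z_survival_{PERIOD_EARLY}", f"z_tl_{PERIOD_EARLY}"] == (
            pytest.approx(-1.0)
        )

    def test_too_few_pairs_undefined(self):
        df = self._standardized(n=2)
        r, _ = pairwise_correlations(df)
        assert np.isnan(
            r.loc[f"z_survival_{PERIOD_EARLY}", f"z_tl_{PERIOD_EARLY}"]
        )


class TestBatchStandardization:
    def test_standardize_outcomes_adds_z_columns(self):
        recs = []
        for diet, n40, n80, tl in (
            ("FSD", 100, 40, 19.0), ("FSY", 150, 90, 21.0), ("A", 200, 150, 23.0)
        ):
            recs.append(_record(diet_id=diet, survivors={40: n40, 80: n80},
                                mean_tl={40: tl, 80: tl + 10.0}))
        z = standardize_outcomes(period_outcomes(recs))
        early = z[z.period == PERIOD_EARLY].set_index("diet_id")
        assert early.loc["A", "z_survival"] == pytest.approx(
            (80.0 - 50.0) / (np.abs(60.0 - 40.0) / np.sqrt(2)), rel=1e-6
        )

    def test_zero_reference_sd_policy(self):
        recs = [
            _record(diet_id="FSD", survivors={40: 100}, mean_tl={40: 20.0}),
            _record(diet_id="FSY", survivors={40: 100}, mean_tl={40: 21.0}),
            _record(diet_id="A", survivors={40: 200}, mean_tl={40: 25.0}),
        ]
        out = period_outcomes(recs)
        with pytest.raises(TrialDataError):
            standardize_outcomes(out)
        z = standardize_outcomes(out, on_zero_sd="nan")
        early = z[z.period == PERIOD_EARLY].set_index("diet_id")
        assert np.isnan(early.loc["A", "z_survival"])
        assert np.isfinite(early.loc["A", "z_tl"])


def test_tank_record_csv_round_trip(tmp_path):
    recs = [
        _record(survivors={20: 200, 40: 125, 60: 110, 80: 100},
                mean_tl={20: 11.0, 40: 20.0, 60: 25.0, 80: 30.0}),
        _record(diet_id="B", tank_id="t2", restocked_at_41=100,
                survivors={40: 150, 80: 60}, mean_tl={40: 19.0, 80: 29.0}),
    ]
    path = tmp_path / "records.csv"
    write_tank_records(recs, path)
    back = read_tank_records(path)
    assert len(back) == 2
    assert back[0].survivors == recs[0].survivors
    assert back[1].restocked_at_41 == 100
    assert back[1].mean_tl == recs[1].mean_tl
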