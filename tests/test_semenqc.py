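"""QC cascade, trait aggregation, adjustment and fertility-index tests."""

import numpy as np
import pandas as pd
import pytest

from recessivescan.semenqc import (
    FilterConfig,
    adjust_traits,
    aggregate_traits,
    estimate_fertility,
    filter_ejaculates,
    trait_correlations,
)
from recessivescan.synthgen import SimConfig, simulate_inseminations

# maps generator injection labels to the cascade rule that must remove them
LABEL_TO_RULE = {
    "interval_missing": "interval_known",
    "age_out_of_range": "age_in_range",
    "volume_missing": "volume_recorded",
    "motility_missing": "motility_recorded",
    "rejection_cause": "no_rejection_cause",
    "low_motility": "min_motility",
    "low_volume": "min_volume",
    "low_concentration": "min_concentration",
    "pooled": "not_pooled",
    "duplicate_day": "first_per_day",
    "collector_missing": "collector_recorded",
    "bad_score": "plausible_scores",
    "straw_out_of_range": "straw_in_range",
}


def _record(**kwargs):
    base = {
        "bull_id": "B1",
        "collection_date": "2015-06-01",
        "ejaculate_no": 1,
        "age_days": 500,
        "interval_days": 7.0,
        "volume_ml": 4.0,
        "concentration_1e9_per_ml": 1.3,
        "motility_pct": 85.0,
        "head_score": 0,
        "tail_score": 0,
        "sperm_per_straw_mio": 16.0,
        "collector_id": "C1",
        "pooled_flag": False,
        "rejection_cause": "",
    }
    base.update(kwargs)
    return base


def _frame(rows):
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "kwargs, rule",
    [
        ({"motility_pct": 69.9}, "min_motility"),
        ({"age_days": 399}, "age_in_range"),
        ({"age_days": 1001}, "age_in_range"),
        ({"volume_ml": 1.0}, "min_volume"),
        ({"concentration_1e9_per_ml": 0.3}, "min_concentration"),
        ({"sperm_per_straw_mio": 25.01}, "straw_in_range"),
        ({"pooled_flag": True}, "not_pooled"),
        ({"rejection_cause": "impurities"}, "no_rejection_cause"),
        ({"interval_days": np.nan}, "interval_known"),
    ],
)
def test_single_violation_removed_at_named_rule(kwargs, rule):
    cfg = FilterConfig(min_ejaculates=1)
    records = _frame([_record(), _record(collection_date="2015-06-02", **kwargs)])
    filtered, log = filter_ejaculates(records, cfg)
    assert len(filtered) == 1
    drops = dict(zip(log["filter"], -log["n_records"].diff().fillna(0)))
    assert drops[rule] == 1


def test_boundary_values_kept():
    cfg = FilterConfig(min_ejaculates=1)
    records = _frame(
        [_record(motility_pct=70.0, age_days=400),
         _record(collection_date="2015-06-02", age_days=1000,
                 sperm_per_straw_mio=25.0)]
    )
    filtered, _ = filter_ejaculates(records, cfg)
    assert len(filtered) == 2


def test_implausible_score_warns_not_raises():
    cfg = FilterConfig(min_ejaculates=1)
    records = _frame([_record(), _record(collection_date="2015-06-02", head_score=7)])
    with pytest.warns(UserWarning, match="score"):
        filtered, _ = filter_ejaculates(records, cfg)
    assert len(filtered) == 1


def test_first_per_day_keeps_earliest():
    cfg = FilterConfig(min_ejaculates=1)
    records = _frame(
        [_record(ejaculate_no=2, motility_pct=90.0), _record(ejaculate_no=1)]
    )
    filtered, _ = filter_ejaculates(records, cfg)
    assert len(filtered) == 1
    assert filtered["ejaculate_no"].iloc[0] == 1


def test_attrition_matches_generator_manifest(small_cfg, small_sim, small_pedigree):
    import dataclasses

    from recessivescan.synthgen import simulate_records

    viol = {label: c for label, c in zip(LABEL_TO_RULE, [3, 4, 2, 2, 5, 7, 2, 2, 3, 4, 2, 1, 3])}
    cfg = dataclasses.replace(small_cfg, qc_violations=viol)
    _, status, _ = small_sim
    records, manifest = simulate_records(cfg, status, small_pedigree)
    with pytest.warns(UserWarning):
        _, log = filter_ejaculates(records, FilterConfig())
    drops = dict(zip(log["filter"], -log["n_records"].diff().fillna(0)))
    for label, count in manifest["injected_violations"].items():
        assert drops[LABEL_TO_RULE[label]] == count, label
    # cascade monotonicity
    assert (log["n_records"].diff().dropna() <= 0).all()
    assert (log["n_bulls"].diff().dropna() <= 0).all()


def test_filtering_is_idempotent(small_records):
    records, _ = small_records
    once, _ = filter_ejaculates(records, FilterConfig())
    twice, _ = filter_ejaculates(once, FilterConfig())
    assert len(once) == len(twice)


def test_min_ejaculates_rule_drops_sparse_bulls():
    rows = [_record(collection_date=f"2015-06-{d:02d}") for d in range(1, 10)]
    rows.append(_record(bull_id="B2"))
    filtered, log = filter_ejaculates(_frame(rows), FilterConfig(min_ejaculates=8))
    assert set(filtered["bull_id"]) == {"B1"}


class TestAggregation:
    def test_simple_mean(self):
        rows = [_record(motility_pct=80.0), _record(motility_pct=90.0,
                                                    collection_date="2015-06-02")]
        out = aggregate_traits(_frame(rows))
        assert out.loc["B1", "motility_pct"] == pytest.approx(85.0)
        assert out.loc["B1", "n_ejaculates"] == 2

    def test_grand_mean_close_to_generator_setting(self, small_records, small_cfg):
        records, _ = small_records
        filtered, _ = filter_ejaculates(records, FilterConfig())
        traits = aggregate_traits(filtered)
        # noncarriers dominate; grand mean near the configured noncarrier mean
        assert abs(traits["motility_pct"].mean() - small_cfg.trait_means_by_status[0]) < 1.5


class TestAdjustment:
    def test_null_effects_adjusted_tracks_raw(self):
        cfg = SimConfig(seed=21, n_bulls=120, n_snps_per_chrom=(120,),
                        qtl_window_index=0, qtl_ibd_markers=50,
                        collector_sd=0.0, season_sd=0.0,
                        age_slope_per_day=0.0, interval_slope_per_day=0.0)
        from recessivescan.synthgen import (
            simulate_panel, simulate_pedigree, simulate_records,
        )
        panel, status, _ = simulate_panel(cfg)
        rec, _ = simulate_records(cfg, status, simulate_pedigree(cfg))
        _, cors = adjust_traits(rec, traits=["motility_pct"])
        assert cors["motility_pct"] > 0.99

    def test_collector_effects_r_above_090(self, small_records):
        records, _ = small_records
        filtered, _ = filter_ejaculates(records, FilterConfig())
        _, cors = adjust_traits(filtered, traits=["motility_pct"])
        assert cors["motility_pct"] > 0.90

    def test_matches_saturated_dummy_ols_oracle(self, rng):
        n = 30
        df = _frame([
            _record(bull_id=f"B{i % 5}", collection_date=f"2015-06-{i + 1:02d}",
                    age_days=int(rng.integers(400, 1000)),
                    interval_days=float(rng.integers(2, 20)),
                    collector_id=f"C{i % 3}",
                    motility_pct=float(80 + rng.normal(0, 3)))
            for i in range(n)
        ])
        adj, _ = adjust_traits(df, traits=["motility_pct"])
        # independent oracle: explicit dummy design, pseudoinverse residuals
        season = pd.to_datetime(df["collection_date"]).dt.quarter
        Z = np.column_stack(
            [np.ones(n), df["age_days"], df["interval_days"]]
            + [(df["collector_id"] == c).astype(float) for c in ["C1", "C2"]]
            + [(season == s).astype(float) for s in sorted(season.unique())[1:]]
        )
        y = df["motility_pct"].to_numpy()
        resid = y - Z @ (np.linalg.pinv(Z) @ y)
        oracle = pd.Series(resid, index=df["bull_id"].to_numpy()).groupby(level=0).mean()
        assert np.allclose(adj["motility_pct"].sort_index(), oracle.sort_index(),
                           atol=1e-8)

    def test_single_collector_level_dropped_with_warning(self):
        df = _frame([_record(collection_date=f"2015-06-{d:02d}") for d in range(1, 9)])
        with pytest.warns(UserWarning, match="collector"):
            adjust_traits(df, traits=["motility_pct"])


class TestFertility:
    def test_all_equal_outcomes_give_flat_100(self):
        df = pd.DataFrame({
            "bull_id": np.repeat(["A", "B"], 250),
            "month": 1, "parity": "cow", "straw_price": "A",
            "breed_combination": "x", "technician_id": "t", "herd_id": "h",
            "outcome": 1,
        })
        res = estimate_fertility(df, min_inseminations=100)
        assert np.allclose(res.index["index"], 100.0)

    def test_standardization_exact_before_outlier_removal(self):
        cfg = SimConfig(seed=13, n_bulls=20, inseminations_per_bull=400)
        truth = pd.Series(np.random.default_rng(2).normal(0, 0.05, 20),
                          index=[f"B{i:04d}" for i in range(1, 21)])
        ins = simulate_inseminations(cfg, truth)
        res = estimate_fertility(ins, drop_outliers=False)
        idx = res.index["index"]
        assert idx.mean() == pytest.approx(100.0, abs=1e-6)
        assert idx.std(ddof=0) == pytest.approx(12.0, abs=1e-6)

    def test_recovery_of_simulated_truth(self):
        cfg = SimConfig(seed=3, n_bulls=20, inseminations_per_bull=2000)
        truth = pd.Series(np.random.default_rng(1).normal(0, 0.05, 20),
                          index=[f"B{i:04d}" for i in range(1, 21)])
        ins = simulate_inseminations(cfg, truth)
        res = estimate_fertility(ins, drop_outliers=False)
        idx = res.index["index"]
        assert np.corrcoef(idx, truth.reindex(idx.index))[0, 1] > 0.8

    def test_low_count_bulls_excluded_and_outliers_removed(self):
        cfg = SimConfig(seed=5, n_bulls=12, inseminations_per_bull=500)
        ids = [f"B{i:04d}" for i in range(1, 13)]
        truth = pd.Series(0.0, index=ids)
        truth["B0001"] = -0.45  # catastrophic fertility, far below -3 SD
        ins = simulate_inseminations(cfg, truth)
        ins = pd.concat([ins, pd.DataFrame([{
            "bull_id": "RARE", "month": 1, "parity": "cow", "straw_price": "A",
            "breed_combination": "x", "technician_id": "t", "herd_id": "h",
            "outcome": 1,
        }] * 5)], ignore_index=True)
        res = estimate_fertility(ins, min_inseminations=200)
        assert res.excluded_low_n == ["RARE"]
        assert "B0001" in res.outliers_removed
        assert "B0001" not in res.index.index


class TestCorrelations:
    def test_identity_diagonal_and_antisymmetry(self):
        df = pd.DataFrame({"volume_ml": [1.0, 2, 3, 4], "motility_pct": [4.0, 3, 2, 1]})
        corr = trait_correlations(df)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["volume_ml", "motility_pct"] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_oracle(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (20, 2)),
                          columns=["volume_ml", "motility_pct"])
        corr = trait_correlations(df)
        x, y = df["volume_ml"].to_numpy(), df["motility_pct"].to_numpy()
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r = cov / (x.std() * y.std())
        assert corr.loc["volume_ml", "motility_pct"] == pytest.approx(r, abs=1e-12)
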