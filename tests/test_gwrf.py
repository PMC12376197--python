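"""NSC time term, Gaussian kernel, splits, the GWRF and its baselines."""

import numpy as np
import pandas as pd
import pytest

from pmdecode import gwrf as gw
from pmdecode import synthdata as sd


def make_features(n_stations=10, days=400, response="smooth", noise=4.0, seed=3,
                  base_spread=0.25, scale=1.0):
    st, _ = sd.generate_station_network(n_stations, 4, seed=seed)
    dates = pd.date_range("2013-01-01", periods=days, freq="D")
    met = sd.generate_meteorology(st, dates, seed=seed + 1)
    em = sd.generate_emission_signal(st, dates, base_spread=base_spread, seed=seed + 2)
    resp = sd.make_met_response(st, response, scale=scale, seed=seed + 3)
    pm = sd.synthesize_pm(sd.SyntheticTruth(em, resp, noise_sd=noise), met, seed=seed + 4)
    return st, gw.build_features(pm, met, st)


class TestNSC:
    def test_constant_series_gives_unit_coefficients(self):
        dates = pd.date_range("2013-01-01", "2014-12-31", freq="D")
        pm = pd.DataFrame({"station_id": "s", "date": dates, "pm25": 42.0})
        nsc = gw.compute_nsc(pm)
        assert np.allclose(nsc["nsc"], 1.0)

    def test_winter_doubling_forces_sign(self):
        dates = pd.date_range("2013-01-01", "2014-12-31", freq="D")
        vals = np.where(dates.month.isin([12, 1, 2]), 80.0, 40.0)
        nsc = gw.compute_nsc(pd.DataFrame({"station_id": "s", "date": dates, "pm25": vals}))
        nsc = nsc.set_index("month")["nsc"]
        assert (nsc.loc[[12, 1, 2]] > 1).all() and (nsc.loc[[6, 7, 8]] < 1).all()

    def test_two_year_sinusoid_matches_analytic_monthly_means(self):
        dates = pd.date_range("2013-01-01", "2014-12-31", freq="D")
        doy = dates.dayofyear.to_numpy(dtype=float)
        series = 50.0 * (1.0 + 0.5 * np.cos(2 * np.pi * (doy - 1) / 365.25))
        nsc = gw.compute_nsc(pd.DataFrame({"station_id": "s", "date": dates, "pm25": series}))
        nsc = nsc.set_index("month")["nsc"]
        # independent oracle: closed-form integral of the cosine over month spans
        overall = series.mean()
        for month in range(1, 13):
            span = dates[dates.month == month]
            a = (span.dayofyear.min() - 1.0) * 2 * np.pi / 365.25
            b = span.dayofyear.max() * 2 * np.pi / 365.25
            analytic = 50.0 * (1.0 + 0.5 * (np.sin(b) - np.sin(a)) / (b - a)) / overall
            assert nsc.loc[month] == pytest.approx(analytic, abs=0.01)

    def test_count_weighted_mean_is_unity(self, small_world):
        nsc = gw.compute_nsc(small_world["pm"])
        pm = small_world["pm"].assign(month=pd.to_datetime(small_world["pm"]["date"]).dt.month)
        for sid, grp in pm.groupby("station_id"):
            weights = grp["month"].value_counts().sort_index()
            vals = nsc[nsc["station_id"] == sid].set_index("month")["nsc"].loc[weights.index]
            assert np.average(vals, weights=weights) == pytest.approx(1.0, abs=1e-9)

    def test_short_span_rejected(self):
        dates = pd.date_range("2013-01-01", periods=200, freq="D")
        with pytest.raises(ValueError):
            gw.compute_nsc(pd.DataFrame({"station_id": "s", "date": dates, "pm25": 1.0}))


class TestKernel:
    def test_zero_distance_gives_unit_weight(self):
        assert gw.gaussian_weight(0.0, 100.0) == 1.0

    def test_bandwidth_distance_closed_form(self):
        assert gw.gaussian_weight(250.0, 250.0) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_monotone_decay_to_zero(self):
        d = np.linspace(0, 5000, 50)
        w = gw.gaussian_weight(d, 300.0)
        assert (np.diff(w) < 0).all() and w[-1] < 1e-30

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gw.gaussian_weight(10.0, 0.0)
        with pytest.raises(ValueError):
            gw.gaussian_weight(-1.0, 10.0)


class TestSplits:
    def test_disjoint_and_complete(self):
        idx = gw.split_data(1000, seed=3)
        parts = [set(idx[k]) for k in ("train", "val", "test")]
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) and not (parts[1] & parts[2])
        assert len(parts[0] | parts[1] | parts[2]) == 1000
        assert len(idx["train"]) == 700 and len(idx["val"]) == 100

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            gw.split_data(100, fractions=(0.5, 0.2, 0.2))


class TestMetrics:
    def test_perfect_prediction(self):
        m = gw.compute_metrics([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert (m.r2, m.rmse, m.mape, m.mae, m.r) == (1.0, 0.0, 0.0, 0.0, 1.0)

    def test_hand_arithmetic(self):
        m = gw.compute_metrics([10.0, 20.0], [12.0, 18.0])
        assert m.mae == pytest.approx(2.0)
        assert m.rmse == pytest.approx(2.0)
        assert m.mape == pytest.approx(15.0)
        assert m.r2 == pytest.approx(1.0 - 8.0 / 50.0)

    def test_constant_prediction_gives_zero_r2(self):
        obs = np.array([5.0, 10.0, 15.0])
        m = gw.compute_metrics(obs, np.full(3, obs.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_zero_observation_excluded_from_mape(self):
        with pytest.warns(UserWarning):
            m = gw.compute_metrics([0.0, 10.0], [1.0, 11.0])
        assert m.mape == pytest.approx(10.0)


class TestModels:
    @pytest.fixture(scope="class")
    def world(self):
        st, feats = make_features(n_stations=8, days=400, noise=4.0)
        idx = gw.split_data(len(feats), seed=1)
        return st, feats.iloc[idx["train"]], feats.iloc[idx["test"]]

    def test_holistic_reproducible(self, world):
        _, train, test = world
        p1 = gw.HolisticModel(25, seed=5).fit(train).predict(test)
        p2 = gw.HolisticModel(25, seed=5).fit(train).predict(test)
        assert np.array_equal(p1, p2)

    def test_single_station_holistic_equals_pointwise(self):
        st, feats = make_features(n_stations=3, days=400)
        one = feats[feats["station_id"] == feats["station_id"].iloc[0]]
        hol = gw.HolisticModel(25, seed=2).fit(one)
        pw = gw.PointwiseModel(25, seed=2).fit(one)
        assert np.allclose(hol.predict(one), pw.predict(one))

    def test_weight_rescaling_leaves_predictions_unchanged(self, world):
        _, train, test = world
        w = np.linspace(0.2, 1.0, len(train))
        p1 = gw.HolisticModel(25, seed=5).fit(train, sample_weight=w).predict(test)
        p2 = gw.HolisticModel(25, seed=5).fit(train, sample_weight=17.3 * w).predict(test)
        assert np.allclose(p1, p2)

    def test_single_anchor_collapses_to_weighted_forest(self, world):
        st, train, test = world
        anchor = pd.DataFrame({"lat": [train["lat"].iloc[0]], "lon": [train["lon"].iloc[0]]})
        model = gw.fit_gwrf(train, 400.0, anchor, n_trees=25, seed=5, weight_floor=0.0)
        d = gw.haversine_km(
            train["lat"].to_numpy(), train["lon"].to_numpy(),
            anchor["lat"].iloc[0], anchor["lon"].iloc[0],
        )
        ref = gw.HolisticModel(25, seed=5).fit(
            train, sample_weight=gw.gaussian_weight(d, 400.0)
        )
        assert np.allclose(model.predict(test), ref.predict(test))

    def test_infinite_bandwidth_limit_matches_holistic(self, world):
        # weights approach 1 everywhere; near-tie splits deep in single
        # trees may still flip, so closeness is asserted at ensemble level
        st, train, test = world
        diam = gw.haversine_km(
            train["lat"].min(), train["lon"].min(), train["lat"].max(), train["lon"].max()
        )
        anchor = pd.DataFrame({"lat": [train["lat"].mean()], "lon": [train["lon"].mean()]})
        model = gw.fit_gwrf(train, 100.0 * diam, anchor, n_trees=25, seed=5)
        hol = gw.HolisticModel(25, seed=5).fit(train)
        pg, ph = model.predict(test), hol.predict(test)
        assert np.abs(pg - ph).mean() < 0.5 * 4.0  # below the observation noise SD
        assert np.corrcoef(pg, ph)[0, 1] > 0.99

    def test_anchor_with_too_few_samples_dropped(self, world):
        st, train, _ = world
        anchors = pd.DataFrame({"lat": [train["lat"].iloc[0], -60.0], "lon": [train["lon"].iloc[0], 0.0]})
        with pytest.warns(UserWarning):
            model = gw.fit_gwrf(train, 300.0, anchors, n_trees=10, seed=1)
        assert len(model.forests) == 1
        with pytest.raises(ValueError):
            far = pd.DataFrame({"lat": [-60.0], "lon": [0.0]})
            gw.fit_gwrf(train, 300.0, far, n_trees=10, seed=1)

    def test_partial_dependence_sign_recovered_across_regimes(self):
        """Anchor-local response slope of blh flips sign with the truth."""
        st, feats = make_features(
            n_stations=12, days=500, response="two_regime", noise=3.0,
            base_spread=0.05, scale=1.5, seed=11,
        )
        idx = gw.split_data(len(feats), seed=2)
        train = feats.iloc[idx["train"]]
        cut = np.median(st["lon"])
        anchors = pd.DataFrame(
            {"lat": [st["lat"].mean()] * 2, "lon": [cut - 12.0, cut + 12.0]}
        )
        model = gw.fit_gwrf(train, 500.0, anchors, n_trees=50, seed=2)
        probe = train.sample(300, random_state=0).copy()

        def slope(anchor_ix, delta=300.0):
            lo, hi = probe.copy(), probe.copy()
            lo["blh"] -= delta / 2
            hi["blh"] += delta / 2
            f = model.forests[anchor_ix]
            return (f.predict(hi[gw.FEATURES]) - f.predict(lo[gw.FEATURES])).mean()

        assert slope(0) < 0 < slope(1)  # west keeps -blh response, east flipped


class TestBandwidthSelection:
    def test_single_candidate_returned(self, small_world):
        st = small_world["stations"]
        feats = gw.build_features(small_world["pm"], small_world["met"], st)
        assert gw.select_bandwidth(feats, [123.0]) == 123.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            gw.select_bandwidth(pd.DataFrame(), [])

    def test_homogeneous_data_selects_largest_bandwidth(self):
        # spatially homogeneous response: more pooling only reduces variance
        hits = 0
        for seed in (1, 2, 3):
            st, feats = make_features(
                n_stations=10, days=380, response="zero", noise=6.0,
                base_spread=0.0, seed=seed,
            )
            sub = feats.sample(2500, random_state=seed).reset_index(drop=True)
            bw = gw.select_bandwidth(sub, [150.0, 6000.0], folds=3, seed=seed, n_trees=15)
            hits += bw == 6000.0
        assert hits >= 2

    def test_two_regime_data_selects_local_bandwidth(self, rng):
        # simulation oracle: met has the SAME distribution at every station
        # (no climatological fingerprints), and the t2m response flips sign
        # between two compact clusters ~4000 km apart; only a bandwidth
        # below the inter-cluster distance can keep the signs separate
        n_per, days = 6, 400
        lat = np.concatenate([30 + rng.uniform(0, 2, n_per), 32 + rng.uniform(0, 2, n_per)])
        lon = np.concatenate([80 + rng.uniform(0, 3, n_per), 125 + rng.uniform(0, 3, n_per)])
        sign = np.repeat([1.0, -1.0], n_per)
        rows = []
        for s in range(2 * n_per):
            t2m = 285 + rng.normal(0, 6, days)
            y = 55.0 + sign[s] * 1.2 * (t2m - 285) + rng.normal(0, 2.0, days)
            rows.append(
                pd.DataFrame(
                    {
                        "station_id": f"s{s}", "pm25": y, "t2m": t2m,
                        "msl": 101325 + rng.normal(0, 300, days),
                        "rh": rng.uniform(30, 90, days),
                        "u10": rng.normal(0, 2, days), "v10": rng.normal(0, 2, days),
                        "blh": rng.uniform(200, 1200, days),
                        "nsc": 1.0, "day_of_week": np.arange(days) % 7,
                        "unix_time": 1.36e9 + 86400 * np.arange(days),
                        "lat": lat[s], "lon": lon[s],
                    }
                )
            )
        data = pd.concat(rows, ignore_index=True).sample(4000, random_state=0)
        from pmdecode._spatial import pairwise_distances_km

        inter_regime = pairwise_distances_km(
            lat[:n_per], lon[:n_per], lat[n_per:], lon[n_per:]
        ).mean()
        bw = gw.select_bandwidth(
            data, [400.0, 3.0 * inter_regime], folds=3, seed=2, n_trees=15
        )
        assert bw < inter_regime
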