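"""Annotation against raster layers and the summary products."""

import numpy as np
import pandas as pd
import pytest

from sms import (
    BehaviourSeries,
    DrTrack,
    RasterLayer,
    SimConfig,
    annotate,
    block_features,
    compute_features,
    cumulative_series,
    grazing_intensity,
    simulate_deployment,
    temperature_profile,
    vedba_by_slope,
    vigilance_by_level,
)
from sms.synthetic_data import diel_temperature


def _track(n=100, x=None, y=None):
    t = np.arange(float(n))
    x = np.full(n, 5.0) if x is None else x
    y = np.full(n, 5.0) if y is None else y
    return DrTrack(t=t, x=x, y=y, lat=np.full(n, -41.0), lon=np.full(n, -71.0),
                   sigma=np.zeros(n), method="linear")


def _beh(n=100, name="grazing", bite_rate=None):
    return BehaviourSeries(np.arange(float(n)),
                           np.array([name] * n, dtype=object),
                           bite_rate)


def _feat(n=100, vedba=0.1, temp=15.0):
    return pd.DataFrame({"second": np.arange(n), "vedba": np.full(n, vedba),
                         "temp": np.full(n, temp)})


def _layer(values, name="slope", **kw):
    args = dict(x0=0.0, y0=100.0, cell=10.0)
    args.update(kw)
    return RasterLayer(name=name, values=np.asarray(values, float), **args)


class TestAnnotate:
    def test_constant_layer_gives_constant_column(self):
        annot = annotate(_track(), _beh(), _feat(), [_layer(np.full((10, 10), 7.0))])
        assert (annot["slope"] == 7.0).all()

    def test_outside_layer_is_nan(self, caplog):
        x = np.full(50, -20.0)   # west of the grid
        with caplog.at_level("INFO"):
            annot = annotate(_track(50, x=x), _beh(50), _feat(50),
                             [_layer(np.ones((10, 10)))])
        assert annot["slope"].isna().all()

    def test_row_count_is_temporal_overlap(self):
        annot = annotate(_track(100), _beh(60), _feat(80),
                         [_layer(np.ones((10, 10)))])
        assert len(annot) == 60

    def test_order_independent(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 50)
        y = rng.uniform(0, 100, 50)
        annot = annotate(_track(50, x=x, y=y), _beh(50), _feat(50),
                         [_layer(rng.normal(size=(10, 10)))])
        perm = rng.permutation(50)
        tr2 = _track(50, x=x, y=y)
        tr2.t = tr2.t[perm]; tr2.x = tr2.x[perm]; tr2.y = tr2.y[perm]
        tr2.lat = tr2.lat[perm]; tr2.lon = tr2.lon[perm]
        annot2 = annotate(tr2, _beh(50), _feat(50),
                          [_layer(rng.normal(size=(10, 10)), name="other")])
        np.testing.assert_array_equal(annot["t"].to_numpy(),
                                      annot2["t"].to_numpy())
        np.testing.assert_array_equal(annot["x"].to_numpy(),
                                      annot2["x"].to_numpy())

    def test_empty_overlap_rejected(self):
        beh = BehaviourSeries(np.arange(200.0, 260.0),
                              np.array(["resting"] * 60, dtype=object))
        with pytest.raises(ValueError, match="overlap"):
            annotate(_track(100), beh, _feat(100), [])


def test_annotated_geojson_round_trip(tmp_path):
    import json

    from sms.landscape import annotated_to_geojson

    annot = annotate(_track(5), _beh(5), _feat(5), [_layer(np.ones((10, 10)))])
    path = tmp_path / "annot.geojson"
    annotated_to_geojson(annot, path)
    doc = json.loads(path.read_text())
    assert doc["type"] == "FeatureCollection"
    assert len(doc["features"]) == 5
    assert doc["features"][0]["properties"]["behaviour"] == "grazing"


class TestGrazingIntensity:
    def test_single_cell_conservation(self):
        rate = np.linspace(0, 2, 100)
        annot = annotate(_track(100), _beh(100, bite_rate=rate), _feat(100),
                         [_layer(np.ones((10, 10)))])
        imap = grazing_intensity(annot, _layer(np.ones((10, 10))))
        nz = imap.layer.values[imap.layer.values > 0]
        assert len(nz) == 1
        assert imap.total == pytest.approx(rate.sum())

    def test_total_conserved_across_cells(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 100, 200)
        y = rng.uniform(0, 100, 200)
        rate = rng.uniform(0, 4, 200)
        annot = annotate(_track(200, x=x, y=y), _beh(200, bite_rate=rate),
                         _feat(200), [])
        imap = grazing_intensity(annot, _layer(np.ones((10, 10))))
        assert imap.total == pytest.approx(rate.sum())

    def test_meadow_gated_bites_land_on_meadow(self):
        # small banded paddock (200 m) so the walk crosses every class
        cfg = SimConfig(duration_s=14400, seed=14, raster_n=20,
                        veg_layout="bands", bites_only_on="meadow")
        dep = simulate_deployment(cfg)
        veg = dep.rasters["vegetation"]
        meadow_code = [c for c, n in veg.legend.items() if n == "meadow"][0]
        sec = np.floor(dep.truth.bite_times).astype(int)
        cls = veg.sample(dep.truth.x[sec], dep.truth.y[sec])
        assert len(dep.truth.bite_times) > 0
        assert np.mean(cls == meadow_code) >= 0.95


class TestVigilance:
    def test_no_vigilance_all_zero(self):
        annot = annotate(_track(50), _beh(50, "grazing"), _feat(50),
                         [_layer(np.ones((10, 10)), name="risk")])
        out = vigilance_by_level(annot, "risk")
        assert (out["mean_rate"] == 0.0).all()

    def test_onsets_count_bout_starts(self):
        beh = np.array(["grazing"] * 10 + ["vigilance"] * 5 + ["grazing"] * 10
                       + ["vigilance"] * 5, dtype=object)
        annot = annotate(_track(30), BehaviourSeries(np.arange(30.0), beh),
                         _feat(30), [_layer(np.ones((10, 10)), name="risk")])
        out = vigilance_by_level(annot, "risk", mode="onsets")
        assert out["total"].sum() == 2.0
        ind = vigilance_by_level(annot, "risk", mode="indicator")
        assert ind["total"].sum() == 10.0

    def test_monotone_with_risk_when_generated_so(self):
        cfg = SimConfig(duration_s=14400, seed=15, raster_n=40,
                        veg_layout="bands", vigilance_only_high_risk=True,
                        budget={"grazing": 0.3, "resting": 0.2, "search": 0.3,
                                "vigilance": 0.1, "fast_walk": 0.1})
        dep = simulate_deployment(cfg)
        risk = dep.rasters["risk"]
        n = len(dep.truth.behaviour)
        annot = pd.DataFrame({
            "t": np.arange(n),
            "behaviour": dep.truth.behaviour,
            "risk": risk.sample(dep.truth.x[:n], dep.truth.y[:n]),
        })
        out = vigilance_by_level(annot, "risk", mode="indicator").sort_values("level")
        assert (dep.truth.behaviour == "vigilance").sum() > 0
        rates = out["mean_rate"].to_numpy()
        assert np.all(np.diff(rates) >= 0)
        assert rates[-1] > rates[0]


class TestVedbaBySlope:
    def test_flat_landscape_single_bin(self):
        annot = annotate(_track(50), _beh(50), _feat(50),
                         [_layer(np.full((10, 10), 2.0))])
        out = vedba_by_slope(annot)
        assert len(out) == 1

    def test_cost_model_recovered(self):
        # synthetic cost model: vedba = 0.05 + 0.01·slope
        rng = np.random.default_rng(8)
        slope = rng.uniform(0, 30, 2000)
        annot = pd.DataFrame({
            "slope": slope,
            "vedba": 0.05 + 0.01 * slope + rng.normal(0, 0.01, 2000),
        })
        out = vedba_by_slope(annot).sort_values("slope_mid")
        assert np.all(np.diff(out["mean_vedba"]) > 0)

    def test_se_shrinks_with_occupancy(self):
        rng = np.random.default_rng(9)
        slope = np.concatenate([np.full(1000, 2.0), np.full(40, 12.0)])
        annot = pd.DataFrame({"slope": slope,
                              "vedba": rng.normal(0.1, 0.02, 1040)})
        out = vedba_by_slope(annot).set_index("slope_mid")
        assert out.loc[2.5, "se_vedba"] < out.loc[12.5, "se_vedba"]
        # SE ∝ n^{-1/2}
        ratio = out.loc[12.5, "se_vedba"] / out.loc[2.5, "se_vedba"]
        assert ratio == pytest.approx(np.sqrt(1000 / 40), rel=0.5)


class TestCumulative:
    def test_zero_bites_flat(self):
        annot = pd.DataFrame({"t": np.arange(10), "bite_rate": np.zeros(10),
                              "behaviour": ["resting"] * 10})
        out = cumulative_series(annot, "bites")
        assert (out["cumulative"] == 0.0).all()

    def test_final_value_and_monotone(self):
        rng = np.random.default_rng(1)
        rate = rng.uniform(0, 3, 50)
        annot = pd.DataFrame({"t": np.arange(50), "bite_rate": rate,
                              "behaviour": ["grazing"] * 50})
        out = cumulative_series(annot, "bites")
        assert out["cumulative"].iloc[-1] == pytest.approx(rate.sum())
        assert (np.diff(out["cumulative"]) >= 0).all()

    def test_flat_segments_match_non_grazing_bouts(self):
        # grazing-with-bites / resting alternation: one flat stretch per
        # non-grazing bout
        rate = np.concatenate([np.ones(10), np.zeros(5), np.ones(10),
                               np.zeros(5), np.ones(10)])
        annot = pd.DataFrame({"t": np.arange(40), "bite_rate": rate,
                              "behaviour": ["x"] * 40})
        out = cumulative_series(annot, "bites")
        inc = np.diff(out["cumulative"].to_numpy())
        flat = inc == 0
        n_flat_runs = int(np.sum(flat[1:] & ~flat[:-1]) + flat[0])
        assert n_flat_runs == 2


class TestTemperature:
    def test_constant_temp(self):
        annot = pd.DataFrame({"t": np.arange(7200), "temp": np.full(7200, 12.0)})
        out = temperature_profile(annot)
        assert (out["min"] == 12.0).all()
        assert (out["max"] == 12.0).all()

    def test_diel_extrema_hours(self):
        cfg = SimConfig(duration_s=60, seed=0)
        t = np.arange(86400)
        temp = diel_temperature(t / 3600.0, cfg)
        annot = pd.DataFrame({"t": t, "temp": temp})
        out = temperature_profile(annot)
        assert out.loc[out["mean"].idxmin(), "hour_of_day"] in (5, 6)
        assert out.loc[out["mean"].idxmax(), "hour_of_day"] in (13, 14)
        assert temp.min() == pytest.approx(10.0, abs=0.01)
        assert temp.max() == pytest.approx(23.0, abs=0.01)

    def test_hours_cover_span(self):
        annot = pd.DataFrame({"t": np.arange(3600, 10800),
                              "temp": np.full(7200, 5.0)})
        out = temperature_profile(annot)
        assert set(out["hour"]) == {1, 2}
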