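"""Station selection, IDW combination, seasonal series, ICV estimation."""

import numpy as np
import pandas as pd
import pytest

from climate_analogs import (
    ICVModel,
    InsufficientDataError,
    SingularityError,
    StationSeries,
    icv_covariance,
    idw_combine,
    monthly_to_seasonal_series,
    read_stations_csv,
    select_stations,
    write_stations_csv,
)
from climate_analogs.stations import SeasonalSeries
from climate_analogs.synthetic import make_station_series, make_urban_polygon

WINDOW = (1960, 1962)


def station_at(
    sid, lat, lon, years=range(1960, 1963), value=10.0, drop_month=None
) -> StationSeries:
    rows = []
    for y in years:
        for m in range(1, 13):
            if drop_month == (y, m):
                continue
            rows.append(
                {"year": y, "month": m, "tmin": value, "tmax": value + 8, "prcp": 50.0}
            )
    return StationSeries(station_id=sid, lat=lat, lon=lon, table=pd.DataFrame(rows))


def offset_latlon(center, north_km=0.0, east_km=0.0):
    lat = center[0] + north_km / 111.19492664455873
    lon = center[1] + east_km / (111.19492664455873 * np.cos(np.radians(center[0])))
    return lat, lon


class TestSelectStations:
    city = make_urban_polygon((40.0, -100.0), 400.0, name="Gridville")  # 20 km side

    def _inside(self, n, value=10.0):
        return [
            station_at(f"IN{i}", *offset_latlon(self.city.centroid, north_km=i * 0.5), value=value)
            for i in range(n)
        ]

    def _outside(self, n, start_km=20.0, step_km=5.0):
        return [
            station_at(f"OUT{i}", *offset_latlon(self.city.centroid, east_km=start_km + i * step_km))
            for i in range(n)
        ]

    def test_enough_inside_returns_all_inside(self):
        inside = self._inside(6)
        got = select_stations(inside + self._outside(3), self.city, window=WINDOW)
        assert sorted(s.station_id for s in got) == sorted(s.station_id for s in inside)

    def test_expansion_adds_nearest_outside_until_five(self):
        inside = self._inside(3)
        outside = self._outside(4)
        got = select_stations(inside + outside, self.city, window=WINDOW)
        ids = {s.station_id for s in got}
        assert len(got) == 5
        assert {s.station_id for s in inside} <= ids
        assert ids - {s.station_id for s in inside} == {"OUT0", "OUT1"}  # the two nearest

    def test_too_few_within_radius_raises(self):
        stations = self._inside(2) + self._outside(2) + self._outside(1, start_km=60.0)
        with pytest.raises(InsufficientDataError, match="Gridville"):
            select_stations(stations, self.city, window=WINDOW)

    def test_incomplete_stations_ignored(self):
        broken = [
            station_at(f"BAD{i}", *self.city.centroid, drop_month=(1961, 5))
            for i in range(5)
        ]
        with pytest.raises(InsufficientDataError):
            select_stations(broken + self._inside(2), self.city, window=WINDOW)

    def test_deterministic_under_shuffling(self):
        stations = self._inside(3) + self._outside(5)
        rng = np.random.default_rng(0)
        baseline = [s.station_id for s in select_stations(stations, self.city, window=WINDOW)]
        for _ in range(5):
            shuffled = list(stations)
            rng.shuffle(shuffled)
            got = [s.station_id for s in select_stations(shuffled, self.city, window=WINDOW)]
            assert got == baseline


class TestIdwCombine:
    center = (40.0, -100.0)

    def test_single_station_is_identity(self):
        st = station_at("A", *offset_latlon(self.center, east_km=3.0))
        out = idw_combine([st], self.center)
        pd.testing.assert_frame_equal(
            out.table[["year", "month", "tmin", "tmax", "prcp"]],
            st.table[["year", "month", "tmin", "tmax", "prcp"]],
            check_dtype=False,
        )

    def test_hand_computed_weighted_mean(self):
        near = station_at("N", *offset_latlon(self.center, north_km=1.0), value=10.0)
        far = station_at("F", *offset_latlon(self.center, north_km=-2.0), value=40.0)
        out = idw_combine([near, far], self.center, power=1.0)
        # weights 1 and 0.5: (10·1 + 40·0.5) / 1.5 = 20
        assert out.table.tmin.iloc[0] == pytest.approx(20.0, rel=1e-6)

    def test_equidistant_stations_average(self):
        a = station_at("A", *offset_latlon(self.center, east_km=5.0), value=0.0)
        b = station_at("B", *offset_latlon(self.center, east_km=-5.0), value=30.0)
        out = idw_combine([a, b], self.center)
        assert out.table.tmin.iloc[0] == pytest.approx(15.0, rel=1e-9)

    def test_order_invariance(self):
        sts = [
            station_at("A", *offset_latlon(self.center, east_km=2.0), value=5.0),
            station_at("B", *offset_latlon(self.center, north_km=7.0), value=12.0),
            station_at("C", *offset_latlon(self.center, north_km=-4.0), value=-3.0),
        ]
        fwd = idw_combine(sts, self.center)
        rev = idw_combine(sts[::-1], self.center)
        np.testing.assert_allclose(fwd.table.tmin, rev.table.tmin, rtol=1e-12)

    def test_station_on_centroid_uses_distance_floor(self):
        on = station_at("ON", *self.center, value=100.0)
        far = station_at("FAR", *offset_latlon(self.center, east_km=10.0), value=0.0)
        out = idw_combine([on, far], self.center)
        assert np.isfinite(out.table.tmin).all()
        assert out.table.tmin.iloc[0] > 99.0  # 1 m floor dominates the 10 km station

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            idw_combine([], self.center)


class TestMonthlyToSeasonalSeries:
    def test_constant_series(self):
        st = station_at("C", 40.0, -100.0, years=range(1960, 1965), value=4.0)
        out = monthly_to_seasonal_series(st)
        assert (out.table.filter(like="tmin") == 4.0).all().all()
        assert (out.table.filter(like="prcp") == 150.0).all().all()  # 3 × 50 mm

    def test_lagged_december_hand_case(self):
        st = station_at("L", 40.0, -100.0, years=range(1960, 1964), value=3.0)
        t = st.table
        t.loc[(t.year == 1960) & (t.month == 12), "tmin"] = 0.0  # Dec 1960
        out = monthly_to_seasonal_series(st)
        assert out.table.loc[1961, "tmin_DJF"] == pytest.approx(2.0)  # (0+3+3)/3

    def test_window_trims_first_year(self):
        st = station_at("W", 40.0, -100.0, years=range(1960, 1991))
        out = monthly_to_seasonal_series(st)
        assert out.n_years == 30
        assert out.table.index.min() == 1961

    def test_too_short_series_raises(self):
        st = station_at("S", 40.0, -100.0, years=range(1960, 1963))
        st.table.drop(st.table[st.table.year == 1962].index, inplace=True)
        with pytest.raises(InsufficientDataError):
            monthly_to_seasonal_series(st)


def seasonal_from_values(values, start_year=1961) -> SeasonalSeries:
    from climate_analogs import VARIABLE_KEYS

    idx = pd.Index(range(start_year, start_year + len(values)), name="year")
    return SeasonalSeries(table=pd.DataFrame(values, index=idx, columns=list(VARIABLE_KEYS)))


class TestIcvCovariance:
    def test_recovers_identity_covariance_at_large_n(self):
        rng = np.random.default_rng(21)
        series = seasonal_from_values(rng.standard_normal((10_000, 12)))
        model = icv_covariance(series)
        assert model.retained_dims == 12
        np.testing.assert_allclose(model.covariance, np.eye(12), atol=0.05)

    def test_recovers_planted_correlation(self):
        rng = np.random.default_rng(22)
        cov = np.eye(12)
        cov[0, 1] = cov[1, 0] = 0.8
        draws = rng.multivariate_normal(np.zeros(12), cov, size=10_000)
        model = icv_covariance(seasonal_from_values(draws))
        corr = model.covariance[0, 1] / np.sqrt(model.covariance[0, 0] * model.covariance[1, 1])
        assert corr == pytest.approx(0.8, abs=0.02)

    def test_constant_variable_raises_singularity(self):
        rng = np.random.default_rng(23)
        vals = rng.standard_normal((50, 12))
        vals[:, 4] = 7.0
        with pytest.raises(SingularityError, match="tmax_DJF"):
            icv_covariance(seasonal_from_values(vals))

    def test_output_symmetric_psd(self):
        rng = np.random.default_rng(24)
        for _ in range(10):
            vals = rng.standard_normal((30, 12)) @ rng.standard_normal((12, 12))
            model = icv_covariance(seasonal_from_values(vals), truncation=0.0)
            eig = np.linalg.eigvalsh(model.covariance)
            assert eig.min() >= -1e-10

    def test_detrending_matches_trend_free_residuals(self):
        rng = np.random.default_rng(25)
        resid = rng.standard_normal((40, 12))
        years = np.arange(40)[:, None]
        slopes = rng.normal(size=12)[None, :]
        trended = resid + slopes * years
        m_detrended = icv_covariance(seasonal_from_values(trended), detrend=True)
        m_resid = icv_covariance(seasonal_from_values(resid), detrend=True)
        np.testing.assert_allclose(m_detrended.covariance, m_resid.covariance, atol=1e-8)

    def test_truncation_reduces_dof_and_orthonormal_basis(self):
        rng = np.random.default_rng(26)
        # rank-3 signal + tiny noise: huge spread in axis standard deviations
        factors = rng.standard_normal((200, 3)) @ (5.0 * rng.standard_normal((3, 12)))
        vals = factors + 0.01 * rng.standard_normal((200, 12))
        model = icv_covariance(seasonal_from_values(vals), truncation=1.0)
        assert 1 <= model.retained_dims <= 3
        np.testing.assert_allclose(
            model.basis.T @ model.basis, np.eye(model.retained_dims), atol=1e-8
        )

    def test_short_series_needs_truncation(self):
        rng = np.random.default_rng(27)
        vals = rng.standard_normal((6, 12))
        model = icv_covariance(seasonal_from_values(vals), truncation=0.0)
        assert model.retained_dims <= 5  # rank ≤ n_years − 1


class TestStationCsvRoundtrip:
    def test_write_read_preserves_series(self, tmp_path):
        mean = np.zeros(12)
        stations = make_station_series(mean, np.eye(12), n_years=4, n_stations=2, seed=9)
        path = tmp_path / "stations.csv"
        write_stations_csv(stations, path)
        back = read_stations_csv(path)
        assert [s.station_id for s in back] == [s.station_id for s in stations]
        np.testing.assert_allclose(
            back[0].table.tmin.to_numpy(), stations[0].table.tmin.to_numpy(), rtol=1e-12
        )

    def test_sentinel_becomes_missing(self, tmp_path):
        st = station_at("S1", 40.0, -100.0)
        st.table.loc[0, "prcp"] = np.nan
        path = tmp_path / "s.csv"
        write_stations_csv([st], path)
        back = read_stations_csv(path)
        assert not back[0].is_complete((1960, 1962))
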