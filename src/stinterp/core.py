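"""Domain types, coordinate/distance conventions, and station/series I/O.

The package works on a fixed network of monitoring stations (typically a
regular lon/lat lattice extracted from a reanalysis product) observed at a
common sequence of monthly time steps.  Two containers carry all data:

``StationGrid``
    station ids with coordinates, plus the inferred lattice structure
    (row/column indices and spacings) when the stations form a regular grid.

``STSeries``
    the station × time concentration matrix together with its grid, integer
    time index and unit string.  All interpolation methods consume this.

Stations are numbered 1-based, row-major from the north-west corner: on a
7-row × 10-column grid the corners are stations 1, 10, 61 and 70.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("stinterp")

EARTH_RADIUS_KM = 6371.0

#: values this small are assumed to be kg/m3 and are rescaled to µg/m3
_KG_M3_THRESHOLD = 1e-4
_KG_TO_UG = 1e9

_LATTICE_TOL = 1e-9


@dataclass(frozen=True)
class DistanceConvention:
    """How station separations are measured.

    ``great_circle_km`` — haversine distance on a sphere of radius 6371 km
    (default; the study region spans several degrees where a degree of
    longitude and a degree of latitude differ materially in length).
    ``euclidean_degrees`` — plain Euclidean distance in degree space, for
    parity with workflows that treat coordinates as planar.
    """

    mode: str = "great_circle_km"
    description: str = ""

    _MODES = ("great_circle_km", "euclidean_degrees")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown distance mode {self.mode!r}; choose from {self._MODES}")

    def pairwise(self, lon1, lat1, lon2, lat2) -> np.ndarray:
        """Distance between every point of (lon1, lat1) and (lon2, lat2).

        Returns an (n1, n2) matrix; units are km or degrees per ``mode``.
        """
        lon1 = np.atleast_1d(np.asarray(lon1, float))
        lat1 = np.atleast_1d(np.asarray(lat1, float))
        lon2 = np.atleast_1d(np.asarray(lon2, float))
        lat2 = np.atleast_1d(np.asarray(lat2, float))
        if self.mode == "euclidean_degrees":
            return np.hypot(
                lon1[:, None] - lon2[None, :], lat1[:, None] - lat2[None, :]
            )
        return _haversine(lon1[:, None], lat1[:, None], lon2[None, :], lat2[None, :])


GREAT_CIRCLE = DistanceConvention("great_circle_km")
EUCLIDEAN_DEGREES = DistanceConvention("euclidean_degrees")


def _haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class StationGrid:
    """Monitoring stations with optional regular-lattice structure.

    For a regular grid, ``lon = lon0 + grid_col * spacing_lon`` and
    ``lat = lat0 - grid_row * spacing_lat`` (row 0 is the northernmost row,
    so station 1 sits at the north-west corner).
    """

    station_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    is_gridded: bool = False
    n_rows: int | None = None
    n_cols: int | None = None
    grid_row: np.ndarray | None = None
    grid_col: np.ndarray | None = None
    spacing_lon: float | None = None
    spacing_lat: float | None = None

    def __post_init__(self) -> None:
        self.station_id = np.asarray(self.station_id, dtype=int)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if len(set(self.station_id.tolist())) != self.station_id.size:
            raise ValueError("duplicate station ids")
        if not (np.isfinite(self.lon).all() and np.isfinite(self.lat).all()):
            raise ValueError("non-finite station coordinates")

    @property
    def n_stations(self) -> int:
        return self.station_id.size

    @property
    def lon0(self) -> float:
        if not self.is_gridded:
            raise ValueError("grid origin undefined for non-gridded stations")
        return float(self.lon[self.grid_col == 0][0])

    @property
    def lat0(self) -> float:
        if not self.is_gridded:
            raise ValueError("grid origin undefined for non-gridded stations")
        return float(self.lat[self.grid_row == 0][0])

    @classmethod
    def regular(
        cls,
        n_rows: int,
        n_cols: int,
        lon0: float = 52.0,
        lat0: float = 26.0,
        spacing_lon: float = 0.625,
        spacing_lat: float = 0.5,
    ) -> "StationGrid":
        """Build a regular lattice numbered 1-based row-major from (lon0, lat0)
        at the north-west corner."""
        rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
        return cls(
            station_id=np.arange(1, n_rows * n_cols + 1),
            lon=lon0 + cols * spacing_lon,
            lat=lat0 - rows * spacing_lat,
            is_gridded=True,
            n_rows=n_rows,
            n_cols=n_cols,
            grid_row=rows,
            grid_col=cols,
            spacing_lon=spacing_lon,
            spacing_lat=spacing_lat,
        )

    def subset(self, mask: np.ndarray) -> "StationGrid":
        """Stations selected by boolean mask; lattice structure is dropped."""
        return StationGrid(self.station_id[mask], self.lon[mask], self.lat[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"station_id": self.station_id, "lon": self.lon, "lat": self.lat}
        )


def detect_lattice(grid: StationGrid) -> StationGrid:
    """Infer row/column structure when station coordinates form a regular
    lon/lat lattice; otherwise return the grid flagged non-gridded.

    Detection is invariant to the ordering of the input rows: it works off the
    sets of unique longitudes and latitudes.
    """
    lons = np.unique(grid.lon)
    lats = np.unique(grid.lat)
    n_cols, n_rows = lons.size, lats.size
    if n_rows * n_cols != grid.n_stations or n_rows < 2 or n_cols < 2:
        return replace(grid, is_gridded=False)
    dlon = np.diff(lons)
    dlat = np.diff(lats)
    if (np.ptp(dlon) > _LATTICE_TOL) or (np.ptp(dlat) > _LATTICE_TOL):
        return replace(grid, is_gridded=False)
    col = np.searchsorted(lons, grid.lon)
    # row 0 = northernmost latitude
    row = n_rows - 1 - np.searchsorted(lats, grid.lat)
    if len({(r, c) for r, c in zip(row, col)}) != grid.n_stations:
        return replace(grid, is_gridded=False)
    return replace(
        grid,
        is_gridded=True,
        n_rows=n_rows,
        n_cols=n_cols,
        grid_row=row,
        grid_col=col,
        spacing_lon=float(dlon.mean()),
        spacing_lat=float(dlat.mean()),
    )


@dataclass
class STSeries:
    """Station × time concentration matrix.

    ``values[i, t]`` is the concentration at ``grid.station_id[i]`` and month
    ``time_index[t]``; the series must be complete (no gaps) and strictly
    positive before any log10 transform.
    """

    grid: StationGrid
    values: np.ndarray
    time_index: np.ndarray | None = None
    units: str = "µg/m³"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D station × time matrix")
        if self.values.shape[0] != self.grid.n_stations:
            raise ValueError(
                f"values has {self.values.shape[0]} rows for "
                f"{self.grid.n_stations} stations"
            )
        if np.isnan(self.values).any():
            i, t = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"series has gaps (first at station {self.grid.station_id[i]}, "
                f"time {t + 1}); the toolkit requires complete series"
            )
        if self.time_index is None:
            self.time_index = np.arange(1, self.values.shape[1] + 1)
        self.time_index = np.asarray(self.time_index, dtype=int)
        if self.time_index.size != self.values.shape[1]:
            raise ValueError("time_index length does not match values")

    @property
    def n_stations(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def drop_station(self, index: int) -> "STSeries":
        """Series with station at positional ``index`` removed (lattice
        structure is dropped — the remaining stations no longer tile it)."""
        mask = np.ones(self.n_stations, bool)
        mask[index] = False
        return STSeries(self.grid.subset(mask), self.values[mask], self.time_index, self.units)


@dataclass
class FoldResult:
    """Predicted vs observed series for one left-out station."""

    station_id: int
    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, float)
        self.predicted = np.asarray(self.predicted, float)
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed/predicted length mismatch")


def pairwise_distance(grid: StationGrid, convention: DistanceConvention = GREAT_CIRCLE) -> np.ndarray:
    """Symmetric station-distance matrix (zero diagonal)."""
    d = convention.pairwise(grid.lon, grid.lat, grid.lon, grid.lat)
    np.fill_diagonal(d, 0.0)
    return d


def compose_pm25(so4, bc, oc, ss25, dust25) -> np.ndarray:
    """PM2.5 mass from GOCART aerosol components:
    1.375*SO4 + BC + 1.6*OC + SS2.5 + Dust2.5 (all µg/m³)."""
    arrs = [np.asarray(a, float) for a in (so4, bc, oc, ss25, dust25)]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("component arrays must have equal shapes")
        if (a < 0).any():
            raise ValueError("negative aerosol component concentration")
    so4, bc, oc, ss25, dust25 = arrs
    return 1.375 * so4 + bc + 1.6 * oc + ss25 + dust25


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_station_table(path) -> StationGrid:
    """Read a station CSV with columns station_id, lon, lat and infer the
    lattice structure if the stations form a regular grid."""
    df = pd.read_csv(path)
    missing = {"station_id", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"station table missing columns: {sorted(missing)}")
    for col in ("lon", "lat"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric coordinates in column {col!r}")
    grid = StationGrid(df["station_id"].to_numpy(), df["lon"].to_numpy(), df["lat"].to_numpy())
    grid = detect_lattice(grid)
    if not grid.is_gridded:
        logger.info("station layout is not a regular lattice; flagged non-gridded")
    return grid


def _maybe_rescale_units(values: np.ndarray, units: str) -> tuple[np.ndarray, str]:
    if np.nanmedian(np.abs(values)) < _KG_M3_THRESHOLD and np.nanmax(np.abs(values)) > 0:
        logger.warning(
            "input values look like kg/m³ (median %.3g); converting to µg/m³ by 1e9",
            float(np.nanmedian(values)),
        )
        return values * _KG_TO_UG, "µg/m³"
    return values, units


def read_series(path, grid: StationGrid | None = None, format: str | None = None,
                variable: str | None = None, units: str = "µg/m³") -> STSeries:
    """Read a station × time series.

    ``format`` is one of ``csv_long`` (columns station_id,time_index,value),
    ``csv_wide`` (station_id then t1..tT columns) or ``netcdf`` (CF style,
    dims (time, station) or (time, lat, lon)); inferred from the file when
    omitted.  Every (station, time) cell must be present exactly once.
    """
    path = str(path)
    if format is None:
        if path.endswith(".nc"):
            format = "netcdf"
        else:
            head = pd.read_csv(path, nrows=1)
            format = "csv_long" if "time_index" in head.columns else "csv_wide"

    if format == "netcdf":
        return _read_series_netcdf(path, variable=variable, units=units)

    df = pd.read_csv(path)
    if format == "csv_long":
        need = {"station_id", "time_index", "value"}
        if need - set(df.columns):
            raise ValueError(f"long CSV missing columns: {sorted(need - set(df.columns))}")
        wide = df.pivot(index="station_id", columns="time_index", values="value")
        wide = wide.sort_index().sort_index(axis=1)
        if wide.isna().any().any():
            bad = [
                (int(i), int(t))
                for i, t in zip(*np.where(wide.isna().to_numpy()))
            ][:10]
            raise ValueError(f"series has gaps at (station_row, time_col) {bad}")
        ids = wide.index.to_numpy()
        times = wide.columns.to_numpy(int)
        values = wide.to_numpy(float)
    elif format == "csv_wide":
        if df.columns[0] != "station_id":
            raise ValueError("wide CSV must start with a station_id column")
        df = df.sort_values("station_id")
        ids = df["station_id"].to_numpy(int)
        times = np.array([int(str(c).lstrip("t")) for c in df.columns[1:]])
        values = df.iloc[:, 1:].to_numpy(float)
        if np.isnan(values).any():
            raise ValueError("series has gaps (NaN cells in wide CSV)")
    else:
        raise ValueError(f"unknown series format {format!r}")

    values, units = _maybe_rescale_units(values, units)
    sgrid = grid
    if sgrid is None:
        sgrid = StationGrid(ids, np.zeros_like(ids, float), np.zeros_like(ids, float))
    else:
        order = np.argsort(sgrid.station_id)
        if not np.array_equal(np.sort(sgrid.station_id), ids):
            raise ValueError("station ids in series do not match station table")
        # align value rows to the grid's station order
        pos = {sid: k for k, sid in enumerate(ids)}
        values = values[[pos[s] for s in sgrid.station_id]]
        del order
    return STSeries(sgrid, values, times, units)


def _read_series_netcdf(path, variable=None, units="µg/m³") -> STSeries:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    try:
        if variable is None:
            cands = [v for v in ds.data_vars if ds[v].ndim >= 2]
            if len(cands) != 1:
                raise ValueError(
                    f"cannot infer variable among {list(ds.data_vars)}; pass variable="
                )
            variable = cands[0]
        da = ds[variable]
        if set(da.dims) >= {"time", "station"}:
            da = da.transpose("station", "time")
            ids = ds["station"].to_numpy().astype(int)
            lon = ds["lon"].to_numpy() if "lon" in ds else np.zeros(ids.size)
            lat = ds["lat"].to_numpy() if "lat" in ds else np.zeros(ids.size)
            values = da.to_numpy().astype(float)
        elif set(da.dims) >= {"time", "lat", "lon"}:
            da = da.transpose("time", "lat", "lon")
            lats = ds["lat"].to_numpy()
            lons = ds["lon"].to_numpy()
            # stations numbered row-major from the northernmost row
            order = np.argsort(-lats)
            da = da.isel(lat=order)
            glat, glon = np.meshgrid(lats[order], lons, indexing="ij")
            lon, lat = glon.ravel(), glat.ravel()
            ids = np.arange(1, lon.size + 1)
            values = da.to_numpy().reshape(da.shape[0], -1).T.astype(float)
        else:
            raise ValueError(f"unsupported dims {da.dims} for variable {variable!r}")
        times = (
            ds["time"].to_numpy().astype(int)
            if np.issubdtype(ds["time"].dtype, np.integer)
            else np.arange(1, values.shape[1] + 1)
        )
        file_units = str(da.attrs.get("units", units))
        values, file_units = _maybe_rescale_units(values, file_units)
        grid = detect_lattice(StationGrid(ids, lon, lat))
        return STSeries(grid, values, times, file_units)
    finally:
        ds.close()


def write_series(series: STSeries, path, format: str = "csv_long") -> None:
    """Write a series as csv_long, csv_wide or CF-style NetCDF (scipy engine)."""
    path = str(path)
    if format == "csv_long":
        rows = pd.DataFrame(
            {
                "station_id": np.repeat(series.grid.station_id, series.n_times),
                "time_index": np.tile(series.time_index, series.n_stations),
                "value": series.values.ravel(),
            }
        )
        rows.to_csv(path, index=False)
    elif format == "csv_wide":
        df = pd.DataFrame(
            series.values,
            columns=[f"t{t}" for t in series.time_index],
        )
        df.insert(0, "station_id", series.grid.station_id)
        df.to_csv(path, index=False)
    elif format == "netcdf":
        import xarray as xr

        ds = xr.Dataset(
            {
                "concentration": (
                    ("station", "time"),
                    series.values,
                    {"units": series.units},
                )
            },
            coords={
                "station": series.grid.station_id,
                "time": series.time_index,
                "lon": ("station", series.grid.lon),
                "lat": ("station", series.grid.lat),
            },
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown series format {format!r}")


def write_stations(grid: StationGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)
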