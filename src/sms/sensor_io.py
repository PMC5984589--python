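"""Readers, writers and containers for the external data formats.

Everything downstream works on the containers defined here: a 40 Hz
:class:`SensorStream` (tri-axial acceleration in g, tri-axial magnetometry in
arbitrary calibrated counts, external temperature in °C), a ~1-fix-per-minute
:class:`GpsFixSeries`, focal-observation :class:`LabelledIntervals`, and
single-band :class:`RasterLayer` landscape grids.

Conventions fixed here and relied on everywhere else:

* **Time base** — float seconds since the deployment's first sensor sample.
  One monotone axis joins the 40 Hz sensor data, 1 Hz products and 1/60 Hz GPS.
* **Body axes** — x = sway (animal's right), y = surge (forward), z = heave
  (dorso-ventral), right-handed, z positive up when the animal stands level, so
  a level tag reads static acceleration ≈ (0, 0, 1) g.
* **Geographic** — GPS datum WGS84; local metric coordinates are an
  east/north tangent-plane projection anchored at a fixed origin (by default
  the first GPS fix), built from the WGS84 meridian and prime-vertical radii
  of curvature.  Rasters are north-up, sampled nearest-cell, cell-centre
  registered, and live in those local metric coordinates.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed behaviour vocabulary (agonistic interactions are deliberately absent;
#: rumination is folded into resting).
BEHAVIOURS = ("grazing", "resting", "search", "vigilance", "fast_walk")
UNCLASSIFIED = "unclassified"

RASTER_NAMES = ("vegetation", "elevation", "slope", "risk", "competition")

SENSOR_COLUMNS = ("time", "ax", "ay", "az", "mx", "my", "mz", "temp")

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_E2 = 6.69437999014e-3


# ---------------------------------------------------------------------------
# geographic helpers
# ---------------------------------------------------------------------------

def _radii(lat_deg: float) -> tuple[float, float]:
    """Meridian (M) and prime-vertical (N) radii of curvature at a latitude."""
    s2 = math.sin(math.radians(lat_deg)) ** 2
    w = math.sqrt(1.0 - _WGS84_E2 * s2)
    m = _WGS84_A * (1.0 - _WGS84_E2) / w**3
    n = _WGS84_A / w
    return m, n


def to_local_xy(lat, lon, origin: tuple[float, float]):
    """Project WGS84 coordinates to metres east (x) / north (y) of ``origin``.

    A tangent-plane (equidistant cylindrical about the origin latitude)
    projection: adequate for paddock-scale extents, exactly invertible by
    :func:`to_lat_lon`, and ``to_local_xy(*origin, origin) == (0, 0)``.
    """
    lat0, lon0 = origin
    m, n = _radii(lat0)
    y = np.radians(np.asarray(lat, dtype=float) - lat0) * m
    x = np.radians(np.asarray(lon, dtype=float) - lon0) * n * math.cos(math.radians(lat0))
    return x, y


def to_lat_lon(x, y, origin: tuple[float, float]):
    """Inverse of :func:`to_local_xy`."""
    lat0, lon0 = origin
    m, n = _radii(lat0)
    lat = lat0 + np.degrees(np.asarray(y, dtype=float) / m)
    lon = lon0 + np.degrees(np.asarray(x, dtype=float) / (n * math.cos(math.radians(lat0))))
    return lat, lon


# ---------------------------------------------------------------------------
# SensorStream
# ---------------------------------------------------------------------------

@dataclass
class SensorStream:
    """Uniformly sampled multi-sensor record for one animal/deployment."""

    animal_id: str
    t: np.ndarray          # seconds since deployment epoch, uniform grid
    fs: float              # Hz
    ax: np.ndarray         # sway acceleration, g
    ay: np.ndarray         # surge acceleration, g
    az: np.ndarray         # heave acceleration, g
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    temp: np.ndarray       # °C
    attachment: str = "head"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.attachment not in ("head", "collar"):
            raise ValueError(f"unknown attachment {self.attachment!r}")
        n = len(self.t)
        for name in ("ax", "ay", "az", "mx", "my", "mz", "temp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time length")
        for name in ("ax", "ay", "az"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite acceleration in {name}")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("non-monotone timestamps")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9:
                raise ValueError("time grid is not uniform at 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) acceleration matrix in body axes (sway, surge, heave)."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def mag(self) -> np.ndarray:
        return np.column_stack([self.mx, self.my, self.mz])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "ax": self.ax, "ay": self.ay, "az": self.az,
                "mx": self.mx, "my": self.my, "mz": self.mz,
                "temp": self.temp,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_sensor_log(path, attachment: str = "head", fs: float = 40.0,
                    animal_id: str | None = None) -> SensorStream:
    """Read a delimited sensor log onto a uniform 1/fs grid.

    Gaps of exactly one missing sample are linearly interpolated; larger gaps
    raise, as do duplicated or non-monotone timestamps.
    """
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor log missing channel(s): {', '.join(missing)}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError("empty sensor log")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone timestamps")

    step = 1.0 / fs
    idx = np.round((t - t[0]) / step).astype(np.int64)
    if np.any(np.diff(idx) < 1):
        raise ValueError("non-monotone timestamps")
    if np.any(np.diff(idx) > 2):
        raise ValueError("gap longer than one sample in sensor log")
    n = int(idx[-1]) + 1
    grid = t[0] + np.arange(n) * step

    channels: dict[str, np.ndarray] = {}
    for name in SENSOR_COLUMNS[1:]:
        col = np.full(n, np.nan)
        col[idx] = df[name].to_numpy(dtype=float)
        holes = np.isnan(col)
        if holes.any():
            # single-sample holes only (guaranteed by the gap check above)
            col[holes] = np.interp(grid[holes], grid[~holes], col[~holes])
        channels[name] = col

    return SensorStream(
        animal_id=animal_id or Path(str(path)).stem,
        t=grid, fs=fs, attachment=attachment, **channels,
    )


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------

@dataclass
class GpsFixSeries:
    """GPS fixes (~1 per minute) on the deployment time base."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    nominal_interval_s: float = 60.0

    def __post_init__(self) -> None:
        if len(self.t) != len(self.lat) or len(self.t) != len(self.lon):
            raise ValueError("t/lat/lon length mismatch")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("non-monotone GPS timestamps")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("GPS coordinates out of range")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "lat": self.lat, "lon": self.lon})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_gps_log(path, nominal_interval_s: float = 60.0) -> GpsFixSeries:
    """Read a CatLog-style CSV (``time,lat,lon``); sorts by time and drops
    out-of-range coordinates with a logged count."""
    df = pd.read_csv(path)
    for c in ("time", "lat", "lon"):
        if c not in df.columns:
            raise ValueError(f"GPS log missing column {c!r}")
    if len(df) == 0:
        raise ValueError("empty GPS log")
    df = df.sort_values("time")
    ok = (df["lat"].abs() <= 90) & (df["lon"].abs() <= 180)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d GPS fix(es) with out-of-range coordinates", dropped)
    df = df[ok]
    if len(df) == 0:
        raise ValueError("no valid GPS fixes after range filtering")
    return GpsFixSeries(
        t=df["time"].to_numpy(dtype=float),
        lat=df["lat"].to_numpy(dtype=float),
        lon=df["lon"].to_numpy(dtype=float),
        nominal_interval_s=nominal_interval_s,
    )


# ---------------------------------------------------------------------------
# Labelled behaviour intervals
# ---------------------------------------------------------------------------

@dataclass
class LabelledIntervals:
    """Focal-observation behaviour intervals, optionally with bite times."""

    start: np.ndarray
    end: np.ndarray
    behaviour: np.ndarray                     # strings from BEHAVIOURS
    bite_times: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.behaviour = np.asarray(self.behaviour, dtype=object)
        if not self.bite_times:
            self.bite_times = [np.empty(0) for _ in self.start]
        if not (len(self.start) == len(self.end) == len(self.behaviour)
                == len(self.bite_times)):
            raise ValueError("interval field length mismatch")
        if np.any(self.end <= self.start):
            raise ValueError("intervals must have end > start")
        order = np.argsort(self.start)
        s, e = self.start[order], self.end[order]
        if np.any(s[1:] < e[:-1] - 1e-9):
            raise ValueError("intervals overlap")
        bad = set(self.behaviour) - set(BEHAVIOURS)
        if bad:
            raise ValueError(f"unknown behaviour label(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.start)

    def subset(self, idx) -> "LabelledIntervals":
        idx = np.asarray(idx)
        return LabelledIntervals(
            self.start[idx], self.end[idx], self.behaviour[idx],
            [self.bite_times[i] for i in idx],
        )

    def all_bite_times(self) -> np.ndarray:
        if not self.bite_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.bite_times))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.start,
                "end": self.end,
                "behaviour": self.behaviour,
                "bite_times": [
                    " ".join(f"{b:.3f}" for b in bt) for bt in self.bite_times
                ],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_labels(path) -> LabelledIntervals:
    """Read a labels CSV (``start,end,behaviour[,bite_times]``)."""
    df = pd.read_csv(path)
    for c in ("start", "end", "behaviour"):
        if c not in df.columns:
            raise ValueError(f"labels file missing column {c!r}")
    bites = []
    if "bite_times" in df.columns:
        for v in df["bite_times"].fillna(""):
            parts = str(v).split()
            bites.append(np.array([float(p) for p in parts]))
    return LabelledIntervals(
        df["start"].to_numpy(float), df["end"].to_numpy(float),
        df["behaviour"].to_numpy(object), bites,
    )


# ---------------------------------------------------------------------------
# Raster layers
# ---------------------------------------------------------------------------

@dataclass
class RasterLayer:
    """Single-band, north-up landscape grid in local metric coordinates.

    ``values[0, 0]`` is the north-west cell.  ``x0``/``y0`` are the coordinates
    of the *outer corner* of that cell (west edge / north edge); a point (x, y)
    falls in column ``floor((x - x0)/cell)`` and row ``floor((y0 - y)/cell)``.
    """

    name: str
    values: np.ndarray
    x0: float
    y0: float
    cell: float
    kind: str = "continuous"             # or "categorical"
    nodata: float = -9999.0
    crs: str = "local-tangent-plane"
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be a non-empty 2-D array")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical" and not self.legend:
            codes = np.unique(self.values[self.values != self.nodata])
            self.legend = {int(c): str(int(c)) for c in codes}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        nr, nc = self.values.shape
        return (self.x0, self.y0 - nr * self.cell, self.x0 + nc * self.cell, self.y0)

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell sample; NaN outside the grid or on nodata cells."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - y) / self.cell).astype(int)
        nr, nc = self.values.shape
        inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.full(x.shape, np.nan)
        vals = self.values[row[inside], col[inside]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[inside] = vals
        return out

    # -- I/O ---------------------------------------------------------------

    def write(self, path) -> None:
        """Write ESRI ASCII grid (``.asc``) or GeoTIFF (``.tif``/``.tiff``),
        plus a JSON sidecar with name/kind/legend/CRS."""
        path = Path(str(path))
        if path.suffix.lower() == ".asc":
            nr, nc = self.values.shape
            header = (
                f"ncols {nc}\nnrows {nr}\n"
                f"xllcorner {float(self.x0)!r}\n"
                f"yllcorner {float(self.y0 - nr * self.cell)!r}\n"
                f"cellsize {float(self.cell)!r}\nNODATA_value {float(self.nodata)!r}\n"
            )
            body = "\n".join(
                " ".join(repr(float(v)) for v in row) for row in self.values
            )
            path.write_text(header + body + "\n")
        elif path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            nr, nc = self.values.shape
            tifffile.imwrite(
                path, self.values,
                extratags=[
                    (33550, "d", 3, (self.cell, self.cell, 0.0)),            # ModelPixelScale
                    (33922, "d", 6, (0.0, 0.0, 0.0, self.x0, self.y0, 0.0)), # ModelTiepoint
                ],
            )
        else:
            raise ValueError(f"unsupported raster format {path.suffix!r}")
        sidecar = {
            "name": self.name, "kind": self.kind, "crs": self.crs,
            "nodata": self.nodata,
            "legend": {str(k): v for k, v in self.legend.items()},
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_raster(path, name: str | None = None, kind: str | None = None) -> RasterLayer:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF) with nodata masked
    to NaN on sampling.  Multi-band or geotransform-less GeoTIFFs raise."""
    path = Path(str(path))
    meta: dict = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if path.suffix.lower() == ".asc":
        with open(path) as fh:
            header = {}
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nr = int(header["nrows"])
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + nr * cell
        nodata = header.get("nodata_value", -9999.0)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) != 1:
                raise ValueError("multi-band raster not supported")
            page = tf.pages[0]
            values = page.asarray()
            if values.ndim != 2:
                raise ValueError("multi-band raster not supported")
            tags = {t.code: t.value for t in page.tags.values()}
            if 33550 not in tags or 33922 not in tags:
                raise ValueError("GeoTIFF missing geotransform (ModelPixelScale/Tiepoint)")
            cell = float(tags[33550][0])
            x0 = float(tags[33922][3])
            y0 = float(tags[33922][4])
        nodata = float(meta.get("nodata", -9999.0))
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")

    crs = meta.get("crs")
    if crs is None:
        raise ValueError("raster missing CRS (no JSON sidecar)")
    legend = {int(k): v for k, v in meta.get("legend", {}).items()}
    return RasterLayer(
        name=name or meta.get("name", path.stem),
        values=values, x0=x0, y0=y0, cell=cell,
        kind=kind or meta.get("kind", "continuous"),
        nodata=nodata, crs=crs, legend=legend,
    )
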