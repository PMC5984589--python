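"""Fusion of the 1 Hz products with the landscape layers.

The annotated track — one row per second carrying position, behaviour, bite
rate, VeDBA, temperature and the raster layer values under the animal — is
the end product of the pipeline.  The summaries built from it map grazing
intensity onto the landscape, relate vigilance to predation-risk and
competition levels, relate movement cost (VeDBA) to slope, and profile the
thermal environment through the day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviour_classify import BehaviourSeries
from .dead_reckoning import DrTrack
from .sensor_io import RasterLayer

logger = logging.getLogger(__name__)


@dataclass
class IntensityMap:
    """Per-cell sums of bites (or behaviour-seconds) on a template grid."""

    layer: RasterLayer
    quantity: str

    @property
    def total(self) -> float:
        return float(np.nansum(self.layer.values))


# ---------------------------------------------------------------------------

def annotate(track: DrTrack, behaviours: BehaviourSeries,
             features_1hz: pd.DataFrame,
             layers: list[RasterLayer]) -> pd.DataFrame:
    """Join track, behaviour and 1 Hz features on integer seconds and sample
    every raster layer nearest-cell at each position.

    ``features_1hz`` is the block-feature table (needs columns ``second``,
    ``vedba`` and, if present, ``temp``).  Positions outside a layer get NaN
    (nodata) with a logged count.
    """
    tsec = track.t.astype(int)
    df = pd.DataFrame({
        "t": tsec, "x": track.x, "y": track.y,
        "lat": track.lat, "lon": track.lon,
    })
    beh = pd.DataFrame({
        "t": behaviours.t.astype(int),
        "behaviour": behaviours.behaviour,
        "bite_rate": behaviours.bite_rate,
    })
    df = df.merge(beh, on="t", how="inner")
    feats = features_1hz.rename(columns={"second": "t"})
    keep = ["t", "vedba"] + (["temp"] if "temp" in feats.columns else [])
    df = df.merge(feats[keep], on="t", how="inner")
    if len(df) == 0:
        raise ValueError("no temporal overlap between track, behaviours and features")
    df = df.sort_values("t").reset_index(drop=True)

    for layer in layers:
        vals = layer.sample(df["x"].to_numpy(), df["y"].to_numpy())
        n_missing = int(np.sum(np.isnan(vals)))
        if n_missing:
            logger.info("layer %s: %d location(s) outside coverage/nodata",
                        layer.name, n_missing)
        df[layer.name] = vals
    return df


def annotated_to_geojson(annot: pd.DataFrame, path=None) -> dict:
    """Annotated track as a GeoJSON FeatureCollection of per-second points."""
    import json

    feats = []
    cols = [c for c in annot.columns if c not in ("lat", "lon")]
    for _, row in annot.iterrows():
        props = {}
        for c in cols:
            v = row[c]
            if isinstance(v, (np.floating, np.integer)):
                v = None if (isinstance(v, np.floating) and np.isnan(v)) else float(v)
            props[c] = v
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["lon"]), float(row["lat"])]},
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh)
    return doc


def grazing_intensity(annot: pd.DataFrame, template: RasterLayer) -> IntensityMap:
    """Sum bite_rate·1 s per template cell: grazing intensity on the landscape.

    Conserves mass: the map total equals the summed bite rate of every second
    whose position falls on the grid.
    """
    grid = np.zeros(template.shape)
    x = annot["x"].to_numpy(dtype=float)
    y = annot["y"].to_numpy(dtype=float)
    w = annot["bite_rate"].to_numpy(dtype=float)
    col = np.floor((x - template.x0) / template.cell).astype(int)
    row = np.floor((template.y0 - y) / template.cell).astype(int)
    nr, nc = template.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    np.add.at(grid, (row[inside], col[inside]), w[inside])
    out = RasterLayer(name="grazing_intensity", values=grid,
                      x0=template.x0, y0=template.y0, cell=template.cell,
                      kind="continuous", nodata=template.nodata, crs=template.crs)
    return IntensityMap(layer=out, quantity="bites")


def _vigilance_rate(annot: pd.DataFrame, mode: str) -> np.ndarray:
    """Per-second vigilance rate: indicator seconds or interruption onsets."""
    vig = (annot["behaviour"].to_numpy() == "vigilance").astype(float)
    if mode == "indicator":
        return vig
    if mode == "onsets":
        onset = vig.copy()
        onset[1:] = vig[1:] * (1.0 - vig[:-1])  # first second of each bout
        return onset
    raise ValueError(f"unknown vigilance rate mode {mode!r}")


def vigilance_by_level(annot: pd.DataFrame, layer_name: str = "risk",
                       mode: str = "onsets") -> pd.DataFrame:
    """Mean ± SD vigilance rate per ordinal level of the risk or competition
    layer.  ``mode='onsets'`` counts vigilance-bout starts per second (the
    number of interruptions per second); ``'indicator'`` counts vigilant
    seconds.  Levels with zero seconds are omitted with a note."""
    if layer_name not in annot.columns:
        raise ValueError(f"annotated track has no layer column {layer_name!r}")
    rate = _vigilance_rate(annot, mode)
    level = annot[layer_name].to_numpy(dtype=float)
    ok = np.isfinite(level)
    rows = []
    for lv in np.unique(level[ok]):
        m = ok & (level == lv)
        rows.append({
            "level": lv, "n_seconds": int(m.sum()),
            "mean_rate": float(rate[m].mean()),
            "sd_rate": float(rate[m].std(ddof=0)),
            "total": float(rate[m].sum()),
        })
    if not rows:
        logger.info("no seconds on any level of %s", layer_name)
    return pd.DataFrame(rows)


def vedba_by_slope(annot: pd.DataFrame,
                   bin_edges: np.ndarray | None = None,
                   bin_width_deg: float = 5.0) -> pd.DataFrame:
    """Mean ± standard error of 1 s VeDBA per slope bin (default 5° bins).

    Empty bins are omitted; a flat landscape collapses to a single bin.
    """
    if "slope" not in annot.columns:
        raise ValueError("annotated track has no slope column")
    slope = annot["slope"].to_numpy(dtype=float)
    v = annot["vedba"].to_numpy(dtype=float)
    ok = np.isfinite(slope) & np.isfinite(v)
    slope, v = slope[ok], v[ok]
    if len(slope) == 0:
        raise ValueError("no finite slope samples")
    if bin_edges is None:
        hi = max(np.max(slope), bin_width_deg)
        bin_edges = np.arange(0.0, hi + bin_width_deg, bin_width_deg)
    idx = np.clip(np.digitize(slope, bin_edges) - 1, 0, len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        rows.append({
            "slope_lo": bin_edges[b], "slope_hi": bin_edges[b + 1],
            "slope_mid": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
            "n": n,
            "mean_vedba": float(v[m].mean()),
            "se_vedba": float(v[m].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def cumulative_series(annot: pd.DataFrame, quantity: str = "bites") -> pd.DataFrame:
    """Non-decreasing cumulative bites (or vigilance seconds) over time; flat
    stretches mark non-feeding (non-vigilant) periods."""
    if quantity == "bites":
        inc = annot["bite_rate"].to_numpy(dtype=float)
    elif quantity == "vigilance_seconds":
        inc = (annot["behaviour"].to_numpy() == "vigilance").astype(float)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return pd.DataFrame({"t": annot["t"].to_numpy(),
                         "cumulative": np.cumsum(inc)})


def temperature_profile(annot: pd.DataFrame) -> pd.DataFrame:
    """Hourly min/mean/max of tag temperature over the track span."""
    if "temp" not in annot.columns:
        raise ValueError("annotated track has no temp column")
    t = annot["t"].to_numpy(dtype=float)
    hour = np.floor(t / 3600.0).astype(int)
    df = pd.DataFrame({"hour": hour, "temp": annot["temp"].to_numpy(dtype=float)})
    out = df.groupby("hour")["temp"].agg(["min", "mean", "max"]).reset_index()
    out["hour_of_day"] = out["hour"] % 24
    return out
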