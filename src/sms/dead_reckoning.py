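"""Dead-reckoned path reconstruction and GPS drift correction.

A dead-reckoned (DR) path integrates per-step displacement vectors built from
compass heading and a speed proxy (linear in VeDBA, calibrated against GPS
segment speeds).  Uncorrected DR drifts — heading bias and speed error
accumulate — so two corrections against the ~1-per-minute GPS fixes are
provided:

* ``correct_linear`` — the conventional deterministic approach: the closure
  error of each inter-fix segment is distributed linearly in time, so the
  corrected path passes through every fix exactly.
* ``correct_melding`` — an anchored linear-Gaussian smoother: the DR offset is
  modelled as a per-axis random walk observed noisily at fix times
  (Kalman forward filter + RTS backward smoother), giving a posterior mean
  path *and* a per-point uncertainty that collapses near fixes and is widest
  between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .sensor_io import GpsFixSeries, to_lat_lon, to_local_xy

logger = logging.getLogger(__name__)


@dataclass
class DrTrack:
    """A reconstructed path in local metres and geographic coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    sigma: np.ndarray                  # per-point positional SD, m
    method: str = "uncorrected"        # uncorrected | linear | melding
    speed: np.ndarray | None = None    # m s⁻¹
    origin: tuple[float, float] = (0.0, 0.0)   # (lat, lon) of local origin

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "lat", "lon", "sigma"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "x": self.x, "y": self.y,
            "lat": self.lat, "lon": self.lon,
            "sigma": self.sigma, "method": self.method,
        })

    def to_geojson(self, path=None, properties: dict | None = None):
        """GeoJSON LineString with per-point sigma in the properties."""
        import json

        doc = {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(lo), float(la)]
                                for lo, la in zip(self.lon, self.lat)],
            },
            "properties": {
                "method": self.method,
                "t": [float(v) for v in self.t],
                "sigma_m": [float(v) for v in self.sigma],
                **(properties or {}),
            },
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh)
        return doc


@dataclass
class SpeedModel:
    """speed = clip(m · VeDBA + c, 0, v_max)."""

    m: float = 1.5         # (m s⁻¹) per g of VeDBA
    c: float = 0.0         # m s⁻¹
    v_max: float = 3.0     # m s⁻¹ clamp (brisk trot for sheep)

    def predict(self, vedba) -> np.ndarray:
        return np.clip(self.m * np.asarray(vedba, dtype=float) + self.c,
                       0.0, self.v_max)


# ---------------------------------------------------------------------------

def dr_propagate(t: np.ndarray, heading_deg: np.ndarray, speed: np.ndarray,
                 origin: tuple[float, float]) -> DrTrack:
    """Integrate heading + speed into an uncorrected DR track.

    x_{k+1} = x_k + v_k·dt·sin(h_k),  y_{k+1} = y_k + v_k·dt·cos(h_k);
    the first point sits at the local origin (the initial known location).
    """
    t = np.asarray(t, dtype=float)
    h = np.radians(np.asarray(heading_deg, dtype=float))
    v = np.asarray(speed, dtype=float)
    if not (len(t) == len(h) == len(v)):
        raise ValueError("t/heading/speed length mismatch")
    dt = np.diff(t)
    dx = v[:-1] * dt * np.sin(h[:-1])
    dy = v[:-1] * dt * np.cos(h[:-1])
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    lat, lon = to_lat_lon(x, y, origin)
    return DrTrack(t=t, x=x, y=y, lat=lat, lon=lon,
                   sigma=np.zeros(len(t)), method="uncorrected",
                   speed=v, origin=origin)


def calibrate_speed(t_vedba: np.ndarray, vedba: np.ndarray,
                    gps: GpsFixSeries, origin: tuple[float, float] | None = None,
                    v_max: float = 3.0) -> SpeedModel:
    """Least-squares fit of GPS segment speed against mean VeDBA per segment.

    Falls back to defaults (m=1.5, c=0) with a warning when the fitted slope
    is non-positive (e.g. a stationary animal where GPS jitter dominates).
    """
    if len(gps) < 3:
        raise ValueError("need at least 2 GPS segments to calibrate speed")
    if len(gps) - 1 < 10:
        logger.warning("only %d GPS segments for speed calibration", len(gps) - 1)
    if origin is None:
        origin = (float(gps.lat[0]), float(gps.lon[0]))
    gx, gy = to_local_xy(gps.lat, gps.lon, origin)
    seg_dt = np.diff(gps.t)
    seg_speed = np.hypot(np.diff(gx), np.diff(gy)) / seg_dt

    t_vedba = np.asarray(t_vedba, dtype=float)
    vedba = np.asarray(vedba, dtype=float)
    seg_vedba = np.full(len(seg_speed), np.nan)
    for i in range(len(seg_speed)):
        m = (t_vedba >= gps.t[i]) & (t_vedba < gps.t[i + 1])
        if np.any(m):
            seg_vedba[i] = vedba[m].mean()
    ok = np.isfinite(seg_vedba)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 GPS segments overlap the VeDBA series")
    vv, ss = seg_vedba[ok], seg_speed[ok]
    if np.ptp(vv) < 1e-12:
        logger.warning("constant VeDBA: speed slope undefined, using fallback")
        return SpeedModel(v_max=v_max)
    m, c = np.polyfit(vv, ss, 1)
    if m <= 0:
        logger.warning("non-positive VeDBA-speed slope (%.3g): using fallback", m)
        return SpeedModel(v_max=v_max)
    return SpeedModel(m=float(m), c=float(c), v_max=v_max)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def _gps_xy(gps: GpsFixSeries, origin) -> tuple[np.ndarray, np.ndarray]:
    return to_local_xy(gps.lat, gps.lon, origin)


def correct_linear(track: DrTrack, gps: GpsFixSeries) -> DrTrack:
    """Distribute each inter-fix closure error linearly in time.

    The corrected track passes through every GPS fix exactly; before the first
    and after the last fix the boundary error is applied as a constant shift.
    sigma is a diagnostic only: zero at fixes, peaking mid-segment at half the
    segment's closure-error magnitude.
    """
    inside = (gps.t >= track.t[0] - 1e-9) & (gps.t <= track.t[-1] + 1e-9)
    if not np.any(inside):
        logger.warning("no GPS fixes within the track span; returning input")
        return track
    gt = gps.t[inside]
    gx, gy = to_local_xy(gps.lat[inside], gps.lon[inside], track.origin)

    dr_x = np.interp(gt, track.t, track.x)
    dr_y = np.interp(gt, track.t, track.y)
    ex, ey = gx - dr_x, gy - dr_y
    # piecewise-linear error in time, constant beyond the end fixes
    cx = np.interp(track.t, gt, ex)
    cy = np.interp(track.t, gt, ey)

    sigma = np.zeros(len(track))
    if len(gt) >= 2:
        closure = np.hypot(np.diff(ex), np.diff(ey))
        for i in range(len(gt) - 1):
            m = (track.t >= gt[i]) & (track.t <= gt[i + 1])
            span = gt[i + 1] - gt[i]
            frac = (track.t[m] - gt[i]) / span
            sigma[m] = closure[i] * np.minimum(frac, 1 - frac)

    x, y = track.x + cx, track.y + cy
    lat, lon = to_lat_lon(x, y, track.origin)
    return replace(track, x=x, y=y, lat=lat, lon=lon, sigma=sigma, method="linear")


def correct_melding(track: DrTrack, gps: GpsFixSeries,
                    gps_sd_m: float = 10.0,
                    drift_sd_m_per_s: float | None = None) -> DrTrack:
    """Anchor the DR path on GPS fixes with a linear-Gaussian smoother.

    Per axis, the DR offset b_t (truth − DR) is modelled as a random walk with
    step SD ``drift_sd_m_per_s``·dt, observed at fix times with SD
    ``gps_sd_m``.  A Kalman forward pass + RTS backward pass yields the
    posterior mean offset and variance; the corrected track is DR + offset and
    sigma is the per-axis RMS posterior SD.  Limits: gps_sd→0 pins the path to
    the fixes; drift_sd→0 reduces to a single rigid shift.

    When ``drift_sd_m_per_s`` is None it is estimated from the data by the
    method of moments: the mean squared inter-fix closure-error increment,
    minus the 2·gps_sd² the fix noise contributes, divided by the fix
    interval.  DR drift is largely systematic (heading bias, speed-proxy
    error), so this matched diffusion rate is what lets the random-walk prior
    cover the actual inter-fix drift.
    """
    if gps_sd_m <= 0 or (drift_sd_m_per_s is not None and drift_sd_m_per_s < 0):
        raise ValueError("gps_sd_m must be > 0 and drift_sd_m_per_s >= 0")
    if not (np.all(np.isfinite(track.x)) and np.all(np.isfinite(track.y))
            and np.all(np.isfinite(gps.lat)) and np.all(np.isfinite(gps.lon))):
        raise ValueError("non-finite inputs")
    inside = (gps.t >= track.t[0] - 1e-9) & (gps.t <= track.t[-1] + 1e-9)
    if not np.any(inside):
        logger.warning("no GPS fixes within the track span; returning input")
        return track
    gt = gps.t[inside]
    gx, gy = to_local_xy(gps.lat[inside], gps.lon[inside], track.origin)

    # observation index: nearest track sample per fix
    obs_idx = np.searchsorted(track.t, gt)
    obs_idx = np.clip(obs_idx, 0, len(track) - 1)
    left = np.clip(obs_idx - 1, 0, len(track) - 1)
    use_left = np.abs(track.t[left] - gt) < np.abs(track.t[obs_idx] - gt)
    obs_idx = np.where(use_left, left, obs_idx)

    z = {0: gx - track.x[obs_idx], 1: gy - track.y[obs_idx]}

    if drift_sd_m_per_s is None:
        if len(gt) >= 3:
            de2 = 0.5 * (np.diff(z[0]) ** 2 + np.diff(z[1]) ** 2)
            dtg = np.diff(gt)
            q2 = np.mean(np.maximum(de2 - 2.0 * gps_sd_m**2, 0.0) / dtg)
            drift_sd_m_per_s = max(np.sqrt(q2), 1e-2)
        else:
            drift_sd_m_per_s = 0.25
        logger.info("estimated drift_sd = %.3f m s^-0.5 per s", drift_sd_m_per_s)
    obs_at = {}
    for i, k in enumerate(obs_idx):
        obs_at.setdefault(int(k), []).append(i)

    n = len(track)
    dt = np.diff(track.t)
    r = gps_sd_m**2
    means, variances = [], []
    for axis in (0, 1):
        m_f = np.zeros(n)
        v_f = np.zeros(n)
        m_p = np.zeros(n)   # predicted (prior) mean/var per step, for RTS
        v_p = np.zeros(n)
        m, v = 0.0, 1e12    # diffuse initial offset
        for k in range(n):
            if k > 0:
                v = v + (drift_sd_m_per_s * dt[k - 1]) ** 2
            m_p[k], v_p[k] = m, v
            for i in obs_at.get(k, []):
                gain = v / (v + r)
                m = m + gain * (z[axis][i] - m)
                v = (1 - gain) * v
            m_f[k], v_f[k] = m, v
        # RTS backward smoother
        m_s = m_f.copy()
        v_s = v_f.copy()
        for k in range(n - 2, -1, -1):
            if v_p[k + 1] <= 0:
                continue
            c = v_f[k] / v_p[k + 1]
            m_s[k] = m_f[k] + c * (m_s[k + 1] - m_p[k + 1])
            v_s[k] = v_f[k] + c**2 * (v_s[k + 1] - v_p[k + 1])
        means.append(m_s)
        variances.append(np.maximum(v_s, 0.0))

    x = track.x + means[0]
    y = track.y + means[1]
    sigma = np.sqrt(0.5 * (variances[0] + variances[1]))
    lat, lon = to_lat_lon(x, y, track.origin)
    return replace(track, x=x, y=y, lat=lat, lon=lon, sigma=sigma, method="melding")


def thin_track(track: DrTrack) -> DrTrack:
    """Take the position at each integer second (no averaging); identity on a
    track already at 1 Hz on integer seconds."""
    t0 = np.ceil(track.t[0] - 1e-9)
    t1 = np.floor(track.t[-1] + 1e-9)
    secs = np.arange(t0, t1 + 0.5)
    idx = np.searchsorted(track.t, secs - 1e-9)
    idx = np.clip(idx, 0, len(track) - 1)
    return replace(
        track, t=track.t[idx], x=track.x[idx], y=track.y[idx],
        lat=track.lat[idx], lon=track.lon[idx], sigma=track.sigma[idx],
        speed=None if track.speed is None else track.speed[idx],
    )
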