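"""Per-sample features derived from the raw 40 Hz channels.

The behaviour classifier and the dead reckoner both consume quantities built
here:

* the static (postural) / dynamic (movement) split of acceleration — a
  centred running mean and its residual,
* VeDBA, the Euclidean norm of the three dynamic components (proxy for
  movement-related energy expenditure),
* head pitch from the static vector,
* activity counts (a windowed mean-absolute-deviation movement summary),
* tilt-compensated compass heading from static acceleration + magnetometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sensor_io import SensorStream

logger = logging.getLogger(__name__)


@dataclass
class FeatureSeries:
    """Per-sample derived features at the native sampling rate."""

    t: np.ndarray
    fs: float
    static: np.ndarray        # (n, 3) g
    dyn: np.ndarray           # (n, 3) g; static + dyn == raw exactly
    vedba: np.ndarray         # g, per sample
    pitch: np.ndarray         # degrees in [-90, 90]
    ac: np.ndarray            # activity counts, per-sample broadcast of windows
    heading: np.ndarray       # degrees clockwise from north, [0, 360)
    heading_low_confidence: np.ndarray = field(default=None)  # bool, |pitch|>85°
    temp: np.ndarray = field(default=None)
    mag: np.ndarray = field(default=None)   # raw magnetometry carried through
    acc: np.ndarray = field(default=None)   # raw acceleration carried through

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------

def _running_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centred running mean with window 2*half+1, shrinking at the edges."""
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def decompose(stream: SensorStream, window_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Split raw acceleration into static and dynamic components.

    Static = centred running mean over ``window_s`` per axis (edges shrink the
    window); dynamic = raw − static, so the two reconstruct the raw signal
    bit-exactly.  The 2 s default spans several locomotion cycles at sheep
    stride rates, so gait ends up in the dynamic component and posture in the
    static one.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    nwin = int(round(window_s * stream.fs))
    if nwin < 3:
        raise ValueError("decomposition window shorter than 3 samples")
    half = nwin // 2
    raw = stream.acc
    static = np.column_stack([_running_mean(raw[:, i], half) for i in range(3)])
    return static, raw - static


def vedba(dyn_x, dyn_y, dyn_z, smooth_s: float | None = None,
          fs: float | None = None) -> np.ndarray:
    """VeDBA = sqrt(dx² + dy² + dz²) per sample, optionally boxcar-smoothed."""
    v = np.sqrt(np.asarray(dyn_x) ** 2 + np.asarray(dyn_y) ** 2
                + np.asarray(dyn_z) ** 2)
    if smooth_s is not None:
        if fs is None:
            raise ValueError("fs required for smoothing")
        half = max(int(round(smooth_s * fs)) // 2, 1)
        v = _running_mean(v, half)
    return v


def head_pitch(static_x, static_y, static_z) -> np.ndarray:
    """Head pitch in degrees from the static vector.

    pitch = atan2(sy, hypot(sx, sz)); positive when the surge (forward) axis
    tilts upward.  A zero static vector is undefined and yields NaN.
    """
    sx = np.asarray(static_x, dtype=float)
    sy = np.asarray(static_y, dtype=float)
    sz = np.asarray(static_z, dtype=float)
    norm = np.sqrt(sx**2 + sy**2 + sz**2)
    zero = norm == 0
    if np.any(zero):
        logger.warning("zero static vector at %d sample(s); pitch set to NaN",
                       int(np.sum(zero)))
    with np.errstate(invalid="ignore"):
        p = np.degrees(np.arctan2(sy, np.hypot(sx, sz)))
    return np.where(zero, np.nan, p)


def activity_counts(stream: SensorStream, window_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Activity counts per window: Σ |raw − window mean| over the three axes.

    A windowed mean-absolute-deviation movement summary (the commercial
    biologging definition is unpublished; this proxy is documented as such).
    Returns (window start times, counts); windows are non-overlapping and the
    trailing partial window is dropped.
    """
    nwin = int(round(window_s * stream.fs))
    if nwin < 1:
        raise ValueError("window shorter than one sample")
    raw = stream.acc
    nfull = len(raw) // nwin
    blocks = raw[: nfull * nwin].reshape(nfull, nwin, 3)
    dev = np.abs(blocks - blocks.mean(axis=1, keepdims=True))
    ac = dev.sum(axis=(1, 2))
    tw = stream.t[: nfull * nwin : nwin]
    return tw, ac


def _broadcast_windows(n: int, nwin: int, values: np.ndarray) -> np.ndarray:
    out = np.repeat(values, nwin)
    if len(out) < n:
        pad = values[-1] if len(values) else np.nan
        out = np.concatenate([out, np.full(n - len(out), pad)])
    return out[:n]


def tilt_compensated_heading(static: np.ndarray, mag: np.ndarray,
                             declination_deg: float = 0.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Compass heading of the surge (forward) axis, degrees CW from north.

    Standard e-compass tilt compensation: pitch p = atan2(sy, hypot(sx, sz))
    and roll r = atan2(−sx, sz) are read off the static vector, the
    magnetometer vector is de-rotated by roll about the surge axis and then by
    pitch about the sway axis, and heading = atan2(−m_x, m_y) + declination,
    wrapped to [0, 360).  With body axes x=right/sway, y=forward/surge, the
    minus sign reflects that the Earth field appears rotated by −heading in
    body coordinates (the compass-needle convention: a level tag facing
    geographic east with declination 0 reads 90°).

    Returns (heading, low_confidence) where low_confidence flags samples with
    |pitch| > 85° (gimbal-adjacent geometry).
    """
    static = np.atleast_2d(np.asarray(static, dtype=float))
    mag = np.atleast_2d(np.asarray(mag, dtype=float))
    g = static / np.linalg.norm(static, axis=1, keepdims=True)

    r = np.arctan2(-g[:, 0], g[:, 2])
    sr, cr = np.sin(r), np.cos(r)
    # de-roll about the surge axis
    mx1 = cr * mag[:, 0] + sr * mag[:, 2]
    my1 = mag[:, 1]
    mz1 = -sr * mag[:, 0] + cr * mag[:, 2]
    p = np.arctan2(g[:, 1], np.hypot(g[:, 0], g[:, 2]))
    sp, cp = np.sin(p), np.cos(p)
    # de-pitch about the sway axis
    my2 = cp * my1 - sp * mz1
    m_lev = np.column_stack([mx1, my2])

    heading = (np.degrees(np.arctan2(-m_lev[:, 0], m_lev[:, 1]))
               + declination_deg) % 360.0
    pitch = head_pitch(static[:, 0], static[:, 1], static[:, 2])
    low_conf = np.abs(pitch) > 85.0
    if np.any(low_conf):
        logger.info("heading flagged low-confidence at %d sample(s) (|pitch|>85°)",
                    int(np.sum(low_conf)))
    return heading, low_conf


# ---------------------------------------------------------------------------

def compute_features(stream: SensorStream, window_s: float = 2.0,
                     ac_window_s: float = 1.0,
                     declination_deg: float = 0.0) -> FeatureSeries:
    """Run the full per-sample feature derivation on one stream."""
    static, dyn = decompose(stream, window_s)
    v = vedba(dyn[:, 0], dyn[:, 1], dyn[:, 2])
    pitch = head_pitch(static[:, 0], static[:, 1], static[:, 2])
    tw, ac = activity_counts(stream, ac_window_s)
    ac_full = _broadcast_windows(len(stream), int(round(ac_window_s * stream.fs)), ac)
    heading, low_conf = tilt_compensated_heading(static, stream.mag, declination_deg)
    return FeatureSeries(
        t=stream.t, fs=stream.fs, static=static, dyn=dyn, vedba=v,
        pitch=pitch, ac=ac_full, heading=heading,
        heading_low_confidence=low_conf, temp=stream.temp,
        mag=stream.mag, acc=stream.acc,
    )


def circular_mean_deg(angles_deg: np.ndarray, axis=None) -> np.ndarray:
    """Mean of angles via unit vectors (correct across the 0/360 wrap)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.degrees(np.arctan2(np.sin(a).mean(axis=axis),
                                 np.cos(a).mean(axis=axis))) % 360.0


def block_features(features: FeatureSeries) -> pd.DataFrame:
    """Summarise per-sample features into 1 Hz blocks on integer seconds.

    Per block (aligned to integer seconds of the deployment clock): means of
    pitch, VeDBA, raw acceleration axes and temperature; activity counts; the
    summed variance of the magnetometer axes ("mag_var", the magnetometer
    variability the classifier uses); and the circular mean heading.
    """
    fs = int(round(features.fs))
    first = int(np.ceil(features.t[0] - 1e-9))
    offset = int(round((first - features.t[0]) * features.fs))
    n = (len(features) - offset) // fs
    if n <= 0:
        raise ValueError("stream shorter than one full second")
    sl = slice(offset, offset + n * fs)

    def blk(x):
        return np.asarray(x)[sl].reshape(n, fs)

    out = pd.DataFrame({
        "second": first + np.arange(n),
        "pitch": blk(features.pitch).mean(axis=1),
        "vedba": blk(features.vedba).mean(axis=1),
        "ac": blk(features.ac).mean(axis=1),
        "ax_mean": blk(features.acc[:, 0]).mean(axis=1),
        "ay_mean": blk(features.acc[:, 1]).mean(axis=1),
        "az_mean": blk(features.acc[:, 2]).mean(axis=1),
        "mag_var": (blk(features.mag[:, 0]).var(axis=1)
                    + blk(features.mag[:, 1]).var(axis=1)
                    + blk(features.mag[:, 2]).var(axis=1)),
        "heading": circular_mean_deg(blk(features.heading), axis=1),
    })
    if features.temp is not None:
        out["temp"] = blk(features.temp).mean(axis=1)
    return out
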