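"""End-to-end convenience wrappers used by the CLI and the acceptance script.

Nothing here adds behaviour beyond composing the public module functions in
the canonical order: features → classification/bites → dead reckoning →
correction → annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (
    Deployment,
    FeatureSeries,
    GpsFixSeries,
    block_features,
    calibrate_speed,
    classify,
    compute_features,
    correct_linear,
    correct_melding,
    detect_bites,
    dr_propagate,
    fit_threshold_trees,
    split_training,
    train_bite_threshold,
)



def per_second_heading_speed(features: FeatureSeries, blocks: pd.DataFrame,
                             gps: GpsFixSeries, origin) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1 Hz circular-mean heading and VeDBA-calibrated speed."""
    heading = blocks["heading"].to_numpy(dtype=float)
    model = calibrate_speed(blocks["second"].to_numpy(dtype=float),
                            blocks["vedba"].to_numpy(dtype=float), gps, origin)
    speed = model.predict(blocks["vedba"].to_numpy(dtype=float))
    return blocks["second"].to_numpy(dtype=float), heading, speed


def reconstruct_track(features: FeatureSeries, gps: GpsFixSeries,
                      method: str = "melding", gps_sd_m: float = 10.0,
                      drift_sd_m_per_s: float | None = None,
                      origin: tuple[float, float] | None = None):
    """Dead-reckon at 1 Hz and correct against GPS by the chosen method."""
    if origin is None:
        origin = (float(gps.lat[0]), float(gps.lon[0]))
    blocks = block_features(features)
    t, heading, speed = per_second_heading_speed(features, blocks, gps, origin)
    track = dr_propagate(t, heading, speed, origin)
    if method == "uncorrected":
        return track
    if method == "linear":
        return correct_linear(track, gps)
    if method == "melding":
        return correct_melding(track, gps, gps_sd_m, drift_sd_m_per_s)
    raise ValueError(f"unknown correction method {method!r}")


def classify_deployment(dep: Deployment, split_fraction: float = 0.5,
                        seed: int = 0, quantiles=(0.025, 0.975)):
    """Train/validate split, tree fit, full classification and bite detection
    for a synthetic deployment.  Returns (features, blocks, trees, behaviours
    with bite rates, train, validate)."""
    features = compute_features(dep.stream)
    blocks = block_features(features)
    train, validate = split_training(dep.labels, split_fraction, seed)
    trees = fit_threshold_trees(blocks, train, quantiles=quantiles,
                                fs=dep.stream.fs)
    behaviours = classify(blocks, trees)
    theta = train_bite_threshold(features, train)
    events, behaviours = detect_bites(features, behaviours, theta)
    return features, blocks, trees, behaviours, train, validate, events
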