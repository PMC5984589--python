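"""Replication experiments on synthetic deployments.

Each function runs one parameter-recovery experiment end to end — generate a
ground-truthed deployment, run the pipeline, measure the recovered quantity —
and returns plain numbers.  They are used by the validation suite and the
reproduction script; nothing here is stubbed or pre-computed.
"""

from __future__ import annotations

import numpy as np

from .behaviour_classify import (
    BehaviourSeries,
    detect_bites,
    evaluate,
    match_bite_times,
    train_bite_threshold,
)
from .behaviour_classify import _labelled_seconds
from .dead_reckoning import correct_linear, correct_melding
from .pipeline import classify_deployment, reconstruct_track
from .sensor_io import BEHAVIOURS, UNCLASSIFIED
from .signal_features import compute_features
from .synthetic_data import SimConfig, simulate_deployment


def budget_recovery(seed: int, duration_s: float = 86400.0) -> dict[str, float]:
    """Fit trees on a labelled half of a deployment generated with the default
    activity budget, classify the held-out half, and return the recovered
    proportion of classified time per behaviour."""
    cfg = SimConfig(duration_s=duration_s, seed=seed)
    dep = simulate_deployment(cfg)
    _, blocks, _, behaviours, _, validate, _ = classify_deployment(dep, seed=seed)
    val_truth = _labelled_seconds(validate, behaviours.t.astype(int))
    held_out = val_truth != None  # noqa: E711
    pred = behaviours.behaviour[held_out]
    classified = pred != UNCLASSIFIED
    n_cls = int(classified.sum())
    return {b: float(np.sum(pred == b)) / n_cls for b in BEHAVIOURS}


def bite_rate_recovery(seed: int, duration_s: float = 7200.0) -> tuple[float, int]:
    """Detected mean bites per grazing second on grazing-only bouts generated
    at the default (field-mean) bite rate; returns (rate, n grazing seconds)."""
    cfg = SimConfig(duration_s=duration_s, seed=seed, budget={"grazing": 1.0})
    dep = simulate_deployment(cfg)
    features = compute_features(dep.stream)
    truth_beh = BehaviourSeries(np.arange(len(dep.truth.behaviour), dtype=float),
                                dep.truth.behaviour)
    theta = train_bite_threshold(features, dep.labels)
    _, beh = detect_bites(features, truth_beh, theta)
    grazing = beh.behaviour == "grazing"
    return float(beh.bite_rate[grazing].mean()), int(grazing.sum())


def noiseless_bite_match(seed: int, duration_s: float = 600.0) -> tuple[float, int]:
    """Percent of ground-truth bites matched within 0.5 s on a noiseless
    stereotyped 2 s⁻¹ bite train; returns (percent, n bites)."""
    cfg = SimConfig(duration_s=duration_s, seed=seed, budget={"grazing": 1.0},
                    noise_scale=0.0, bite_rate=2.0, bite_deterministic=True)
    dep = simulate_deployment(cfg)
    features = compute_features(dep.stream)
    truth_beh = BehaviourSeries(np.arange(len(dep.truth.behaviour), dtype=float),
                                dep.truth.behaviour)
    theta = train_bite_threshold(features, dep.labels)
    events, _ = detect_bites(features, truth_beh, theta)
    pct = match_bite_times(events, dep.truth.bite_times, tol_s=0.5)
    return float(pct), len(dep.truth.bite_times)


def accuracy_floor(seed: int, duration_s: float = 43200.0
                   ) -> tuple[float, dict[str, float], int]:
    """Train/validate split at default signal separations; returns
    (min per-behaviour accuracy %, all accuracies, n validation seconds)."""
    cfg = SimConfig(duration_s=duration_s, seed=seed)
    dep = simulate_deployment(cfg)
    _, _, _, behaviours, _, validate, _ = classify_deployment(dep, seed=seed)
    report = evaluate(behaviours, validate)
    accs = {b: float(a) for b, a in report.accuracy.items()}
    n = int(report.confusion.to_numpy().sum())
    return min(accs.values()), accs, n


def correction_ordering(seed: int, n_tracks: int = 20,
                        duration_s: float = 7200.0) -> dict[str, float]:
    """Mean RMSE against the true path of uncorrected, linearly corrected and
    smoother-anchored tracks over replicate deployments."""
    rmses = {"uncorrected": [], "linear": [], "melding": []}
    for k in range(n_tracks):
        cfg = SimConfig(duration_s=duration_s, seed=seed + k)
        dep = simulate_deployment(cfg)
        features = compute_features(dep.stream)
        base = reconstruct_track(features, dep.gps, "uncorrected")
        fi = base.t.astype(int)
        tx, ty = dep.truth.x[fi], dep.truth.y[fi]

        def rmse(tr):
            return float(np.sqrt(np.mean((tr.x - tx) ** 2 + (tr.y - ty) ** 2)))

        rmses["uncorrected"].append(rmse(base))
        rmses["linear"].append(rmse(correct_linear(base, dep.gps)))
        rmses["melding"].append(rmse(correct_melding(base, dep.gps,
                                                     gps_sd_m=cfg.gps_sd_m)))
    return {k: float(np.mean(v)) for k, v in rmses.items()}
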