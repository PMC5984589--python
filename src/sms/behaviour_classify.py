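"""Threshold-tree behaviour classification, bite detection and evaluation.

The classifier is a set of per-behaviour *feature envelopes*: for every
behaviour, the training data defines an allowed interval per feature
(by default the [0.025, 0.975] quantiles; set (0, 1) for a literal min/max
rule).  A 1 Hz block is assigned the first behaviour, in a fixed evaluation
order, whose envelopes all contain the block's summary features; if none
match the block stays *unclassified* — an explicit outcome, not an error.

Bites (vegetation-clipping events during grazing) are detected as local peaks
in the dynamic heave channel that exceed a trained threshold while the head is
down, with a 0.25 s refractory gap that caps the rate at 4 s⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from .sensor_io import BEHAVIOURS, UNCLASSIFIED, LabelledIntervals
from .signal_features import FeatureSeries, block_features

logger = logging.getLogger(__name__)

#: Most to least kinematically distinctive; ties between overlapping envelopes
#: are broken by testing in this order.
DEFAULT_ORDER = ("fast_walk", "grazing", "search", "vigilance", "resting")

#: Default tree features.  Raw-axis means (ax_mean/ay_mean/az_mean) can be
#: added via config but duplicate the posture information pitch carries while
#: increasing the envelope rejection rate, so they are off by default.
DEFAULT_FEATURES = ("pitch", "vedba", "ac", "mag_var")

MAX_BITE_RATE = 4.0          # s⁻¹, set by the 0.25 s refractory gap


@dataclass
class ThresholdTreeSet:
    """Per-behaviour feature envelopes plus the evaluation order."""

    envelopes: dict[str, dict[str, tuple[float, float]]]
    order: tuple[str, ...]
    features: tuple[str, ...]
    means: dict[str, dict[str, float]] = field(default_factory=dict)
    quantiles: tuple[float, float] = (0.025, 0.975)

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(self.envelopes):
            raise ValueError("evaluation order must permute the trained behaviours")
        for beh, env in self.envelopes.items():
            for feat, (lo, hi) in env.items():
                if lo > hi:
                    raise ValueError(f"envelope min > max for {beh}/{feat}")

    def to_yaml(self, path) -> None:
        doc = {
            "order": list(self.order),
            "features": list(self.features),
            "quantiles": list(self.quantiles),
            "envelopes": {
                b: {f: [float(lo), float(hi)] for f, (lo, hi) in env.items()}
                for b, env in self.envelopes.items()
            },
            "means": {b: {f: float(v) for f, v in m.items()}
                      for b, m in self.means.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdTreeSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            envelopes={b: {f: (v[0], v[1]) for f, v in env.items()}
                       for b, env in doc["envelopes"].items()},
            order=tuple(doc["order"]),
            features=tuple(doc["features"]),
            means=doc.get("means", {}),
            quantiles=tuple(doc.get("quantiles", (0.025, 0.975))),
        )


@dataclass
class BehaviourSeries:
    """1 Hz behaviour assignments with per-second bite rate."""

    t: np.ndarray                 # integer seconds
    behaviour: np.ndarray         # strings from BEHAVIOURS + "unclassified"
    bite_rate: np.ndarray = None  # bites s⁻¹, 0 outside grazing

    def __post_init__(self) -> None:
        if self.bite_rate is None:
            self.bite_rate = np.zeros(len(self.t))
        if np.any(self.bite_rate < 0) or np.any(self.bite_rate > MAX_BITE_RATE):
            raise ValueError("bite_rate outside [0, 4] s⁻¹")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "behaviour": self.behaviour,
                             "bite_rate": self.bite_rate})


@dataclass
class ClassificationReport:
    """Confusion matrix (observed × predicted seconds) and accuracies."""

    confusion: pd.DataFrame              # rows observed, cols predicted+unclassified
    accuracy: dict[str, float]           # per-behaviour, %
    overall: float                       # proportion correct over labelled seconds

    def summary(self) -> str:
        lines = [f"overall proportion correct: {self.overall:.3f}"]
        for b, a in self.accuracy.items():
            lines.append(f"  {b:<10s} {a:5.1f} %")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def split_training(labels: LabelledIntervals, fraction: float = 0.5,
                   seed: int = 0) -> tuple[LabelledIntervals, LabelledIntervals]:
    """Random disjoint/exhaustive split at interval granularity."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(labels)
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    train = labels.subset(np.sort(perm[:n_train]))
    validate = labels.subset(np.sort(perm[n_train:]))
    missing = set(labels.behaviour) - set(train.behaviour)
    if missing:
        raise ValueError(f"behaviour(s) absent from training split: {sorted(missing)}")
    return train, validate


def _labelled_seconds(labels: LabelledIntervals, seconds: np.ndarray) -> np.ndarray:
    """Label for each integer second fully inside an interval, else None."""
    out = np.full(len(seconds), None, dtype=object)
    for s, e, b in zip(labels.start, labels.end, labels.behaviour):
        mask = (seconds >= np.ceil(s - 1e-9)) & (seconds + 1 <= e + 1e-9)
        out[mask] = b
    return out


def fit_threshold_trees(features: FeatureSeries | pd.DataFrame,
                        train: LabelledIntervals,
                        quantiles: tuple[float, float] = (0.025, 0.975),
                        feature_names: tuple[str, ...] = DEFAULT_FEATURES,
                        order: tuple[str, ...] = DEFAULT_ORDER,
                        min_samples: int = 200,
                        fs: float = 40.0) -> ThresholdTreeSet:
    """Fit per-behaviour quantile envelopes from labelled 1 Hz blocks.

    ``min_samples`` counts native-rate samples (seconds × fs) per behaviour.
    A constant feature collapses to a zero-width envelope with a warning.
    """
    q_lo, q_hi = quantiles
    if not 0 <= q_lo < q_hi <= 1:
        raise ValueError("quantiles must satisfy 0 <= lo < hi <= 1")
    blocks = features if isinstance(features, pd.DataFrame) else block_features(features)
    labels_per_sec = _labelled_seconds(train, blocks["second"].to_numpy())

    present = [b for b in order if b in set(train.behaviour)]
    envelopes: dict[str, dict[str, tuple[float, float]]] = {}
    means: dict[str, dict[str, float]] = {}
    for beh in present:
        sub = blocks[labels_per_sec == beh]
        if len(sub) * fs < min_samples:
            raise ValueError(
                f"behaviour {beh!r} has {len(sub)} labelled second(s); "
                f"needs >= {min_samples} samples at {fs} Hz")
        env, mu = {}, {}
        for f in feature_names:
            vals = sub[f].to_numpy(dtype=float)
            lo, hi = np.quantile(vals, [q_lo, q_hi])
            if hi - lo == 0:
                logger.warning("degenerate (constant) feature %s for %s: "
                               "zero-width envelope", f, beh)
            env[f] = (float(lo), float(hi))
            mu[f] = float(vals.mean())
        envelopes[beh] = env
        means[beh] = mu
    return ThresholdTreeSet(envelopes=envelopes, order=tuple(present),
                            features=tuple(feature_names), means=means,
                            quantiles=quantiles)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(features: FeatureSeries | pd.DataFrame,
             trees: ThresholdTreeSet) -> BehaviourSeries:
    """Assign each 1 Hz block the first behaviour whose envelopes all contain
    its summary features; blocks matching none stay unclassified."""
    blocks = features if isinstance(features, pd.DataFrame) else block_features(features)
    n = len(blocks)
    out = np.full(n, UNCLASSIFIED, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for beh in trees.order:
        env = trees.envelopes[beh]
        ok = unassigned.copy()
        for f, (lo, hi) in env.items():
            v = blocks[f].to_numpy(dtype=float)
            ok &= (v >= lo) & (v <= hi)
        out[ok] = beh
        unassigned &= ~ok
    return BehaviourSeries(t=blocks["second"].to_numpy(dtype=float), behaviour=out)


# ---------------------------------------------------------------------------
# bites
# ---------------------------------------------------------------------------

def train_bite_threshold(features: FeatureSeries, labels: LabelledIntervals,
                         bg_quantile: float = 0.9, bite_quantile: float = 0.1,
                         match_tol_s: float = 0.15) -> float:
    """Train θ_bite from the labelled bite times.

    Within labelled grazing, |dyn heave| local peaks are split into *bite
    peaks* (within ``match_tol_s`` of a labelled bite time) and *background
    peaks* (everything else).  θ is the midpoint between the ``bg_quantile``
    of the background heights and the ``bite_quantile`` of the bite heights;
    when the two populations overlap the rule falls back to the bite-height
    quantile alone so that ≥ 90 % of true bite peaks stay above threshold.
    """
    heave = np.abs(features.dyn[:, 2])
    bite_h, bg_h = [], []
    obs = labels.all_bite_times()
    for s, e, b in zip(labels.start, labels.end, labels.behaviour):
        if b != "grazing":
            continue
        mask = (features.t >= s) & (features.t < e)
        seg = heave[mask]
        tt = features.t[mask]
        if len(seg) < 3:
            continue
        pk, _ = find_peaks(seg)
        if len(pk) == 0:
            continue
        pk_t, pk_h = tt[pk], seg[pk]
        if len(obs):
            near = np.min(np.abs(pk_t[:, None] - obs[None, :]), axis=1)
            # one height per labelled bite: the tallest peak in its window
            lo = np.searchsorted(pk_t, obs - match_tol_s)
            hi = np.searchsorted(pk_t, obs + match_tol_s)
            heights = [pk_h[a:b].max() for a, b in zip(lo, hi) if b > a]
            bite_h.append(np.asarray(heights))
            bg_h.append(pk_h[near > match_tol_s])
        else:
            bg_h.append(pk_h)
    if not bite_h and not bg_h:
        raise ValueError("no grazing intervals to train the bite threshold on")
    bite_h = np.concatenate(bite_h) if bite_h else np.empty(0)
    bg_h = np.concatenate(bg_h) if bg_h else np.empty(0)
    if len(bite_h) == 0:
        raise ValueError("no labelled bite peaks to train the bite threshold on")
    lo_bite = float(np.quantile(bite_h, bite_quantile))
    if len(bg_h) == 0:
        return lo_bite
    hi_bg = float(np.quantile(bg_h, bg_quantile))
    if hi_bg < lo_bite:
        return 0.5 * (hi_bg + lo_bite)
    logger.warning("bite and background peak heights overlap "
                   "(bg q%.2f=%.3g >= bite q%.2f=%.3g); using the bite quantile",
                   bg_quantile, hi_bg, bite_quantile, lo_bite)
    return lo_bite


def detect_bites(features: FeatureSeries, behaviours: BehaviourSeries,
                 threshold: float, pitch_max_deg: float = 0.0,
                 min_gap_s: float = 0.25) -> tuple[np.ndarray, BehaviourSeries]:
    """Detect bite events within grazing seconds and derive per-second rates.

    A bite is a local peak in |dyn heave| with height ≥ ``threshold``, head
    down (pitch < ``pitch_max_deg``), inside a grazing-classified second, and
    at least ``min_gap_s`` after the previous accepted bite (rate cap
    1/min_gap_s = 4 s⁻¹ at the default).  Returns (event times, behaviour
    series with bite_rate filled in).
    """
    grazing_secs = set(behaviours.t[behaviours.behaviour == "grazing"].astype(int))
    heave = np.abs(features.dyn[:, 2])
    rate = np.zeros(len(behaviours))
    if not grazing_secs:
        return np.empty(0), BehaviourSeries(behaviours.t, behaviours.behaviour, rate)

    distance = max(int(round(min_gap_s * features.fs)), 1)
    pk, _ = find_peaks(heave, height=threshold, distance=distance)
    if len(pk):
        times = features.t[pk]
        ok = np.isin(np.floor(times).astype(int), list(grazing_secs))
        ok &= features.pitch[pk] < pitch_max_deg
        events = times[ok]
    else:
        events = np.empty(0)

    sec0 = behaviours.t.astype(int)
    counts = pd.Series(np.floor(events).astype(int)).value_counts()
    idx = {s: i for i, s in enumerate(sec0)}
    for s, c in counts.items():
        if s in idx:
            rate[idx[s]] = min(float(c), MAX_BITE_RATE)
    return events, BehaviourSeries(behaviours.t, behaviours.behaviour, rate)


def match_bite_times(detected: np.ndarray, observed: np.ndarray,
                     tol_s: float = 0.5) -> float:
    """Percent of observed bites with a one-to-one detection within tol_s
    (greedy matching in time order)."""
    observed = np.sort(np.asarray(observed, dtype=float))
    detected = np.sort(np.asarray(detected, dtype=float))
    if len(observed) == 0:
        return 100.0
    if len(detected) == 0:
        return 0.0
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    j = 0
    for ob in observed:
        # advance to the first unused detection that could still match
        while j < len(detected) and (used[j] or detected[j] < ob - tol_s):
            j += 1
        if j < len(detected) and abs(detected[j] - ob) <= tol_s:
            used[j] = True
            matched += 1
    return 100.0 * matched / len(observed)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(predicted: BehaviourSeries,
             validate: LabelledIntervals) -> ClassificationReport:
    """Confusion matrix and per-behaviour accuracy over validation seconds."""
    secs = predicted.t.astype(int)
    truth = _labelled_seconds(validate, secs)
    have = truth != None  # noqa: E711  (object array)
    if not np.any(have):
        raise ValueError("no overlap between predictions and validation intervals")
    obs = truth[have].astype(str)
    pred = predicted.behaviour[have].astype(str)

    cols = list(BEHAVIOURS) + [UNCLASSIFIED]
    conf = pd.DataFrame(0, index=list(BEHAVIOURS), columns=cols, dtype=int)
    for o, p in zip(obs, pred):
        conf.loc[o, p] += 1
    accuracy = {}
    for b in BEHAVIOURS:
        n = conf.loc[b].sum()
        if n > 0:
            accuracy[b] = 100.0 * conf.loc[b, b] / n
    overall = float(np.mean(obs == pred))
    return ClassificationReport(confusion=conf, accuracy=accuracy, overall=overall)


def activity_budget(behaviours: BehaviourSeries) -> pd.DataFrame:
    """Proportion of time per behaviour, over classified-only and all seconds."""
    if len(behaviours) == 0:
        raise ValueError("empty behaviour series")
    n_all = len(behaviours)
    labels = behaviours.behaviour
    n_cls = int(np.sum(labels != UNCLASSIFIED))
    rows = []
    for b in list(BEHAVIOURS) + [UNCLASSIFIED]:
        c = int(np.sum(labels == b))
        rows.append({
            "behaviour": b,
            "seconds": c,
            "proportion_all": c / n_all,
            "proportion_classified": (c / n_cls if (n_cls and b != UNCLASSIFIED)
                                      else (0.0 if b != UNCLASSIFIED else np.nan)),
        })
    return pd.DataFrame(rows).set_index("behaviour")
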