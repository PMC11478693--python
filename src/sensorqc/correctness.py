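"""Correctness metrics: SNR and anomalous point density (APD).

SNR follows the amplitude convention ``20 * log10(MAV / sigma)`` per channel,
with the mean absolute value standing in for the desired signal and the
standard deviation for the noise; the record value is the median over
channels.  Note this makes SNR a measure of how "peaky" a record is: a
purely Gaussian record scores 20*log10(sqrt(2/pi)) ~ -1.96 dB, and only
heavy-tailed (burst/impulse dominated) records fall far below that.

APD counts points whose ensemble outlier decision score exceeds the record
mean plus three standard deviations of the scores (z-score 3).  Scores come
from feature bagging: each round scores a random feature subset with a
local-outlier-factor detector, and the rounds' normalized scores are
averaged.  Per-round normalization is two-regime: ranks are mapped through
the inverse normal CDF (van der Waerden normal scores), which Gaussianizes
the bulk so the z-score-3 rule is calibrated (raw LOF scores are so
leptokurtic that 1-2% of perfectly clean points would exceed it, and
bounded plain ranks can make the threshold exceed their maximum and flag
nothing); gross outliers — whose LOF sits far beyond the bulk on the
bulk's own IQR scale — additionally keep an unbounded magnitude term, so
the threshold still clears even when anomalies inflate the score variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.neighbors import LocalOutlierFactor

from .sensor_records import SensorRecord, UndefinedMetricError

__all__ = [
    "CorrectnessResult",
    "snr_db",
    "point_features",
    "anomaly_scores",
    "apd",
    "SNR_CAP_DB",
    "MIN_POINTS_FOR_SCORING",
]

SNR_CAP_DB = 120.0
MIN_POINTS_FOR_SCORING = 20
ROLLING_WINDOW = 11
# bulk-scaled LOF z beyond which the magnitude term activates; clean records
# stay well below it (their bulk-scaled tail reaches ~30), gross spikes are
# orders of magnitude beyond
TAIL_KNEE = 60.0
TAIL_GAIN = 2.0


@dataclass
class CorrectnessResult:
    snr_db: float
    apd: float
    apc: int
    decision_scores: np.ndarray


def snr_db(record: SensorRecord) -> float:
    """Record SNR in dB: median over channels of ``20*log10(MAV/sigma)``.

    A zero-variance channel is capped at +120 dB (no noise); an all-zero
    channel with noise is capped at -120 dB.
    """
    if record.length < 2:
        raise UndefinedMetricError("SNR undefined for RL < 2")
    per_channel = []
    for c in range(record.n_channels):
        x = record.channels[:, c]
        mav = np.abs(x).mean()
        sigma = x.std()
        if sigma == 0:
            per_channel.append(SNR_CAP_DB)
        elif mav == 0:
            per_channel.append(-SNR_CAP_DB)
        else:
            per_channel.append(
                float(np.clip(20.0 * np.log10(mav / sigma), -SNR_CAP_DB, SNR_CAP_DB))
            )
    if not per_channel:
        raise UndefinedMetricError("SNR undefined without channels")
    return float(np.median(per_channel))


def point_features(record: SensorRecord, window: int = ROLLING_WINDOW) -> np.ndarray:
    """Per-point feature matrix for outlier scoring.

    Three features per channel: the value itself (level outliers), the
    local z-score — deviation from a centered rolling median scaled by the
    rolling MAD (edge-replicated window) — and the local impulse difference
    (the smaller-magnitude of the backward and forward first differences of
    the local z, large only at the anomalous point itself, not at its
    successor).  Local scaling makes anomalies detectable relative to the
    noise context around them, which matters for bursty, non-stationary
    sensor noise where a global scale would swallow quiet-region spikes.
    """
    x = record.channels
    n, d = x.shape
    feats = np.empty((n, 3 * d), dtype=float)
    half = window // 2
    pad = np.pad(x, ((half, half), (0, 0)), mode="edge")
    for c in range(d):
        col = x[:, c]
        win = np.lib.stride_tricks.sliding_window_view(pad[:, c], window)
        med = np.median(win, axis=1)
        mad = np.median(np.abs(win - med[:, None]), axis=1) * 1.4826
        scale = np.maximum(mad, 1e-3 * col.std() + 1e-12)
        u = (col - med) / scale
        back = np.empty(n)
        back[0] = 0.0
        back[1:] = np.diff(u)
        fwd = np.empty(n)
        fwd[-1] = 0.0
        fwd[:-1] = np.diff(u)
        impulse = np.where(np.abs(back) <= np.abs(fwd), back, fwd)
        feats[:, 3 * c] = col
        feats[:, 3 * c + 1] = u
        feats[:, 3 * c + 2] = impulse
    return feats


def anomaly_scores(
    record: SensorRecord,
    rounds: int = 8,
    seed: int | np.random.Generator = 0,
    *,
    n_neighbors: int = 60,
) -> np.ndarray:
    """Feature-bagging ensemble decision scores, one per data point.

    Each round draws a feature subset of size between ceil(d/2) and d,
    scores it with a local-outlier-factor detector (k = 60, capped at RL-1;
    large enough that moderately dense anomaly clusters cannot mask
    themselves as each other's neighborhood), and the ensemble score is the
    mean of the rounds' two-regime normalized scores.  Deterministic given
    the seed.
    """
    if record.length < MIN_POINTS_FOR_SCORING:
        raise UndefinedMetricError(
            f"anomaly scoring undefined for RL < {MIN_POINTS_FOR_SCORING}"
        )
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    max_train = 500  # density fitted on a subsample for long records
    feats = point_features(record)
    n, d = feats.shape
    # constant features carry no outlier information and destabilize distances
    keep = feats.std(axis=0) > 0
    if keep.any():
        feats = feats[:, keep]
        d = feats.shape[1]
        feats = (feats - feats.mean(axis=0)) / feats.std(axis=0)
    else:
        return np.zeros(n)
    k = min(n_neighbors, n - 1)
    lo = int(np.ceil(d / 2))
    total = np.zeros(n, dtype=float)
    for _ in range(rounds):
        m = int(rng.integers(lo, d + 1))
        cols = rng.choice(d, size=m, replace=False)
        with warnings.catch_warnings():
            # duplicate points (e.g. constant stretches) are expected input
            warnings.simplefilter("ignore", UserWarning)
            if n > max_train:
                sub = rng.choice(n, size=max_train, replace=False)
                lof = LocalOutlierFactor(
                    n_neighbors=min(k, max_train - 1), novelty=True
                )
                lof.fit(feats[sub][:, cols])
                base = -lof.score_samples(feats[:, cols])
            else:
                lof = LocalOutlierFactor(n_neighbors=k)
                lof.fit(feats[:, cols])
                base = -lof.negative_outlier_factor_  # larger = more outlying
        score = norm.ppf((rankdata(base, method="average") - 0.5) / n)
        q25, med, q75 = np.percentile(base, [25, 50, 75])
        bulk_scale = (q75 - q25) / 1.349
        if bulk_scale > 0:
            z_bulk = (base - med) / bulk_scale
            # log-compressed so gross outliers of very different raw
            # magnitude still land close together, above the 3-sigma bar
            score = score + TAIL_GAIN * np.log1p(np.maximum(0.0, z_bulk - TAIL_KNEE))
        total += score
    return total / rounds


def apd(record: SensorRecord, decision_scores: np.ndarray) -> tuple[float, int]:
    """Anomalous point density: (APD, APC) under the z-score-3 rule.

    APC counts points whose decision score exceeds mean + 3*sigma of the
    record's scores; APD divides by the observed point count.  Zero-variance
    scores flag nothing.
    """
    ds = np.asarray(decision_scores, dtype=float)
    if ds.size == 0:
        raise UndefinedMetricError("APD undefined without decision scores")
    sigma = ds.std()
    if sigma == 0:
        return 0.0, 0
    apc = int(np.sum(ds > ds.mean() + 3.0 * sigma))
    return apc / ds.size, apc
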