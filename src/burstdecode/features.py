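"""Spectral feature extraction, standardization and ReliefF selection.

Each 100 ms analysis window yields one feature per contact per band: the mean
baseline-normalized power over the band's 1 Hz rows and the window's time
samples.  The nine bands span 8-500 Hz with deliberate gaps at 46-55 and
96-105 Hz (line-noise guards); activity below 7 Hz is never used because a
100 ms window cannot estimate it reliably.  Features are standardized on the
training folds only, and ranked per training fold with ReliefF; a feature's
importance is the fraction of folds in which it entered the top six.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

#: the nine spectral feature bands, Hz (inclusive edges on the 1 Hz grid)
FEATURE_BANDS: tuple[tuple[float, float], ...] = (
    (8, 12), (13, 20), (21, 30), (31, 45), (56, 95),
    (106, 200), (201, 300), (301, 349), (350, 500),
)

BAND_NAMES = tuple(f"{int(lo)}-{int(hi)}Hz" for lo, hi in FEATURE_BANDS)

MIN_FEATURE_FREQ = 7.0  # activity below this is excluded from features


@dataclass
class FeatureMatrix:
    """Windows x features with row metadata and labels.

    ``X`` has shape ``(n_rows, n_features)``; ``meta`` carries one row per
    window (``trial, period, state, t_center_s``); ``labels`` is the limb
    class per row; ``feature_names`` names the columns (contact x band).
    """

    X: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(self.X) != len(self.labels) or len(self.X) != len(self.meta):
            raise ValueError("rows, labels and metadata must align")

    def to_frame(self) -> pd.DataFrame:
        df = self.meta.reset_index(drop=True).copy()
        df["label"] = self.labels
        for j, name in enumerate(self.feature_names):
            df[name] = self.X[:, j]
        return df


def band_average(power: np.ndarray, freqs: np.ndarray,
                 bands: tuple = FEATURE_BANDS) -> np.ndarray:
    """Average TF power over each band's rows: ``(..., n_f, n_t) -> (..., n_bands, n_t)``."""
    out = []
    for lo, hi in bands:
        if lo < MIN_FEATURE_FREQ:
            lo = MIN_FEATURE_FREQ
        rows = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if rows.size == 0:
            raise ValueError(f"band {lo}-{hi} Hz not covered by frequency grid")
        out.append(power[..., rows, :].mean(axis=-2))
    return np.stack(out, axis=-2)


def extract_features(
    band_power: np.ndarray,
    times: np.ndarray,
    centers: np.ndarray,
    window_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean band power inside a 100 ms window around each centre.

    ``band_power`` is ``(..., n_bands, n_times)`` at the decimated TF rate.
    Returns ``(features, valid)`` where ``features`` is
    ``(..., n_bands, n_centers)`` and ``valid`` marks centres whose window is
    fully covered by finite samples; rows of invalid windows should be
    dropped (and counted) by the caller.
    """
    half = window_s / 2
    feats = np.full(band_power.shape[:-1] + (len(centers),), np.nan,
                    dtype=band_power.dtype)
    valid = np.zeros(len(centers), dtype=bool)
    dt = times[1] - times[0] if len(times) > 1 else window_s
    n_expect = max(1, int(round(window_s / dt)))
    for i, c in enumerate(centers):
        sel = (times >= c - half - 1e-9) & (times < c + half - 1e-9)
        if sel.sum() < n_expect:
            continue
        block = band_power[..., sel]
        if not np.isfinite(block).all():
            continue
        feats[..., i] = block.mean(axis=-1)
        valid[i] = True
    return feats, valid


def standardize(
    X: np.ndarray, fit_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Zero-mean/unit-variance scaling fitted on ``fit_rows`` only.

    Uses the population standard deviation (ddof=0).  Returns
    ``(X_scaled, mean, std, zero_var)`` where ``zero_var`` flags constant
    columns (their std is replaced by 1 so they pass through untouched; they
    must be excluded from selection).
    """
    fit = X[fit_rows]
    if len(fit) == 0:
        raise ValueError("fit_rows must be non-empty")
    mu = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance feature column(s)", int(zero.sum()))
    sd = np.where(zero, 1.0, sd)
    return (X - mu) / sd, mu, sd, zero


def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 10,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """ReliefF feature weights (all instances iterated, no subsampling).

    For every row, the k nearest hits (same class) and k nearest misses per
    other class are found by Euclidean distance; each feature's weight is
    decreased by its mean normalized difference to hits and increased by its
    (class-prior-weighted) mean normalized difference to misses.  Higher
    weight means more discriminative.  With every instance iterated the
    result is deterministic.  ``exclude`` masks columns (e.g. zero-variance
    ones) out of both the distance metric and the output (weight 0).

    If a class has fewer than ``n_neighbors + 1`` rows the neighbour count is
    reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    k = int(n_neighbors)
    if counts.min() <= k:
        k = int(counts.min()) - 1
        logger.warning("reducing ReliefF neighbours to %d (smallest class)", k)
    if k < 1:
        raise ValueError("a class has too few rows for any neighbours")

    use = np.ones(p, dtype=bool) if exclude is None else ~np.asarray(exclude)
    Xu = X[:, use]
    rng_ = Xu.max(axis=0) - Xu.min(axis=0)
    rng_[rng_ == 0] = 1.0
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    d2 = np.sum((Xu[:, None, :] - Xu[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(use.sum())
    for i in range(n):
        same = y == y[i]
        hits = np.flatnonzero(same)
        hits = hits[hits != i]
        hit_idx = hits[np.argsort(d2[i, hits], kind="stable")[:k]]
        w -= np.abs(Xu[hit_idx] - Xu[i]).sum(axis=0) / rng_ / (n * k)
        for c in classes:
            if c == y[i]:
                continue
            miss = np.flatnonzero(y == c)
            miss_idx = miss[np.argsort(d2[i, miss], kind="stable")[:k]]
            scale = priors[c] / (1.0 - priors[y[i]])
            w += scale * np.abs(Xu[miss_idx] - Xu[i]).sum(axis=0) / rng_ / (n * k)
    out = np.zeros(p)
    out[use] = w
    return out


def top_features(weights: np.ndarray, top_n: int = 6) -> np.ndarray:
    """Indices of the ``top_n`` features, ties broken by feature order."""
    if top_n > len(weights):
        logger.warning("top_n clamped from %d to %d", top_n, len(weights))
        top_n = len(weights)
    order = np.lexsort((np.arange(len(weights)), -weights))
    return np.sort(order[:top_n])


def stratified_group_folds(
    groups: np.ndarray, labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Assign *groups* (trials) to k folds, stratified by class.

    Rows sharing a group always land in the same fold, so windows from one
    trial are never split between training and validation.  Returns per-fold
    boolean row masks.  Every row is validated exactly once.
    """
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    ug, first = np.unique(groups, return_index=True)
    glabel = labels[first]
    fold_of: dict = {}
    for c in np.unique(glabel):
        gs = ug[glabel == c]
        gs = gs[rng.permutation(len(gs))]
        for i, g in enumerate(gs):
            fold_of[g] = i % k
    return [np.array([fold_of[g] == f for g in groups]) for f in range(k)]


@dataclass
class SelectionResult:
    """Per-fold ReliefF selections and the resulting importance scores."""

    fold_masks: list[np.ndarray]  # validation mask per fold
    selected: list[np.ndarray]  # feature indices per fold
    weights: list[np.ndarray]  # ReliefF weights per fold
    importance: np.ndarray  # selection count / k per feature
    scalers: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def select_and_score(
    X: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    k_folds: int = 4,
    top_n: int = 6,
    n_neighbors: int = 10,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """ReliefF feature selection inside stratified cross-validation.

    ReliefF runs on each training split only (standardized on that split);
    the top ``top_n`` features per fold are recorded and a feature's
    importance is its selection count divided by ``k_folds``.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = rng or np.random.default_rng()
    n = len(X)
    if groups is None:
        groups = np.arange(n)
    masks = stratified_group_folds(groups, labels, k_folds, rng)
    selected, weights, scalers = [], [], []
    count = np.zeros(X.shape[1])
    for val in masks:
        train = ~val
        Xs, mu, sd, zero = standardize(X, np.flatnonzero(train))
        w = relieff_weights(Xs[train], labels[train],
                            n_neighbors=n_neighbors, exclude=zero)
        sel = top_features(w, top_n)
        count[sel] += 1
        selected.append(sel)
        weights.append(w)
        scalers.append((mu, sd))
    return SelectionResult(fold_masks=masks, selected=selected,
                           weights=weights, importance=count / k_folds,
                           scalers=scalers)


# ---------------------------------------------------------------------------
# optional higher-order time-domain features (disabled by default)
# ---------------------------------------------------------------------------

HIGHER_ORDER_NAMES = ("entropy", "kurtosis", "activity", "mobility",
                      "complexity", "skewness", "max", "min", "mean", "std")


def higher_order_features(window: np.ndarray) -> dict[str, float]:
    """Time-domain descriptors of one raw 100 ms window.

    Entropy is the Shannon entropy (nats) of a 16-bin amplitude histogram;
    activity/mobility/complexity are the Hjorth parameters.  Degenerate
    statistics of a constant window are reported as NaN rather than raised.
    These features are excluded from the main analyses by default.
    """
    x = np.asarray(window, dtype=float)
    out: dict[str, float] = {
        "max": float(x.max()), "min": float(x.min()),
        "mean": float(x.mean()), "std": float(x.std(ddof=0)),
    }
    var = x.var(ddof=0)
    out["activity"] = float(var)
    if var == 0:
        out.update({k: float("nan") for k in
                    ("entropy", "kurtosis", "mobility", "complexity",
                     "skewness")})
        return out
    dx = np.diff(x)
    mob = float(np.sqrt(dx.var(ddof=0) / var))
    out["mobility"] = mob
    ddx = np.diff(dx)
    out["complexity"] = (float(np.sqrt(ddx.var(ddof=0) / dx.var(ddof=0)) / mob)
                         if dx.var(ddof=0) > 0 else float("nan"))
    out["kurtosis"] = float(sstats.kurtosis(x, fisher=True, bias=True))
    out["skewness"] = float(sstats.skew(x, bias=True))
    hist, _ = np.histogram(x, bins=16)
    p = hist[hist > 0] / hist.sum()
    out["entropy"] = float(-(p * np.log(p)).sum())
    return out
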