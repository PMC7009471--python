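"""Oscillatory burst detection and burst-state window construction.

A burst is a transient elevation of band power: the smoothed band envelope
exceeds its 75th percentile for at least 100 ms.  Alpha (8-12 Hz) and beta
(13-30 Hz) bursts are the objects of interest; low-gamma (35-45 Hz) bursts
are detected with the same rule but are used solely to exclude time from the
non-burst periods, since at the 100 ms minimum duration they are too
short-lived to accumulate in useful numbers.  Alpha and beta bursts that
overlap each other in time are removed (both members of the pair), so the
surviving burst sets are mutually disjoint, and a single 100 ms analysis
window is centred on the midpoint of every surviving burst and of every
burst-free period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

#: detection bands, Hz (inclusive edges on the 1 Hz grid)
DETECTION_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "low_gamma": (35.0, 45.0),
}

#: bands whose bursts are classified (low_gamma is exclusion-only)
CLASSIFIED_BANDS = ("alpha", "beta")

WINDOW_HALF_WIDTH_S = 0.05  # analysis windows are exactly 100 ms


@dataclass(frozen=True)
class StateWindow:
    """A 100 ms analysis window attached to one burst state."""

    center: float  # seconds, in the coordinate frame of the analysed span
    state: str  # 'non_burst' | 'alpha_burst' | 'beta_burst'
    channel: str
    trial: object = None
    period: str = "pre_cue"

    @property
    def start(self) -> float:
        return self.center - WINDOW_HALF_WIDTH_S

    @property
    def end(self) -> float:
        return self.center + WINDOW_HALF_WIDTH_S


def band_envelope(
    power: np.ndarray,
    freqs: np.ndarray,
    band: str | tuple[float, float],
    dt: float,
    smooth_s: float = 0.2,
) -> np.ndarray:
    """Smoothed band-power envelope from a time-frequency map.

    ``power`` is ``(n_freqs, n_times)`` (or ``(..., n_freqs, n_times)``);
    the envelope is the mean over the band's 1 Hz rows, smoothed with a
    ``smooth_s`` moving average.
    """
    lo, hi = DETECTION_BANDS[band] if isinstance(band, str) else band
    rows = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if rows.size == 0:
        raise ValueError(f"band {band} outside the decomposed frequency grid")
    env = np.asarray(power)[..., rows, :].mean(axis=-2)
    n = max(1, int(round(smooth_s / dt)))
    return uniform_filter1d(env, size=n, axis=-1, mode="nearest")


def detect_bursts(
    envelope: np.ndarray,
    dt: float,
    percentile: float = 75.0,
    min_duration: float = 0.1,
    threshold: float | None = None,
) -> np.ndarray:
    """Maximal supra-threshold runs of an envelope lasting >= ``min_duration``.

    The threshold defaults to the given percentile of ``envelope`` itself;
    pass ``threshold`` to reuse a percentile computed over a wider span (e.g.
    all pre-cue periods of a block).  Comparison is strict (``>``), so a
    constant envelope yields no bursts.  Intervals are half-open in samples
    and returned in seconds as an ``(n, 2)`` array.
    """
    env = np.asarray(envelope, dtype=float)
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    if threshold is None:
        if env.size * dt < 1.0:
            raise ValueError("need at least 1 s of envelope to set a threshold")
        threshold = float(np.percentile(env, percentile))
    above = env > threshold
    if not above.any():
        return np.empty((0, 2))
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, env.size]
    iv = np.column_stack([starts, ends]).astype(float) * dt
    keep = (iv[:, 1] - iv[:, 0]) >= min_duration - 1e-12
    return iv[keep]


def _overlaps(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean per row of ``a``: does it intersect any interval of ``b``?

    Half-open convention: touching intervals do not overlap.
    """
    if len(a) == 0 or len(b) == 0:
        return np.zeros(len(a), dtype=bool)
    return np.array([bool(np.any((b[:, 0] < e) & (b[:, 1] > s)))
                     for s, e in a])


def resolve_overlaps(
    alpha: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove every alpha/beta burst pair that intersects in time.

    Both members of an overlapping pair are removed, so the surviving sets are
    mutually disjoint.  Touching half-open intervals are kept.
    """
    alpha = np.asarray(alpha, dtype=float).reshape(-1, 2)
    beta = np.asarray(beta, dtype=float).reshape(-1, 2)
    return alpha[~_overlaps(alpha, beta)], beta[~_overlaps(beta, alpha)]


def nonburst_periods(
    burst_lists: list[np.ndarray],
    span: tuple[float, float],
    min_duration: float = 0.1,
) -> np.ndarray:
    """Complement of the union of all burst intervals within ``span``.

    ``burst_lists`` must include the low-gamma detections: non-burst time is
    time free of alpha, beta *and* low-gamma bursts.  Only segments at least
    ``min_duration`` long are eligible to host a window.
    """
    lo, hi = span
    ivs = [np.asarray(b, dtype=float).reshape(-1, 2) for b in burst_lists]
    allb = np.vstack([iv for iv in ivs if len(iv)]) if any(len(iv) for iv in ivs) \
        else np.empty((0, 2))
    if len(allb) == 0:
        return np.array([[lo, hi]]) if hi - lo >= min_duration else np.empty((0, 2))
    allb = allb[np.argsort(allb[:, 0])]
    merged = [list(allb[0])]
    for s, e in allb[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps, cur = [], lo
    for s, e in merged:
        if s > cur:
            gaps.append([cur, min(s, hi)])
        cur = max(cur, e)
    if cur < hi:
        gaps.append([cur, hi])
    gaps = np.array([g for g in gaps if lo <= g[0] < g[1] <= hi and
                     g[1] - g[0] >= min_duration - 1e-12])
    return gaps.reshape(-1, 2)


def make_state_windows(
    alpha: np.ndarray,
    beta: np.ndarray,
    nonburst: np.ndarray,
    span: tuple[float, float],
    channel: str = "",
    trial: object = None,
    period: str = "pre_cue",
) -> list[StateWindow]:
    """One 100 ms window centred on the midpoint of every interval.

    Windows extending beyond the analysed span are dropped.
    """
    out: list[StateWindow] = []
    for state, ivs in (("alpha_burst", alpha), ("beta_burst", beta),
                       ("non_burst", nonburst)):
        for s, e in np.asarray(ivs, dtype=float).reshape(-1, 2):
            c = 0.5 * (s + e)
            if (c - WINDOW_HALF_WIDTH_S >= span[0] - 1e-12 and
                    c + WINDOW_HALF_WIDTH_S <= span[1] + 1e-12):
                out.append(StateWindow(center=float(c), state=state,
                                       channel=channel, trial=trial,
                                       period=period))
    return out


def burst_statistics(
    bursts: np.ndarray,
    span_s: float,
    other: np.ndarray | None = None,
) -> dict:
    """Rate, mean duration, occupancy and cross-band overlap proportion.

    ``span_s`` is the total analysed time.  The overlap proportion (fraction
    of these bursts intersecting any burst of the ``other`` band) is computed
    on the sets *before* overlap removal, matching how it is reported.
    An empty burst set has rate 0 and missing (NaN) duration.
    """
    if span_s <= 0:
        raise ValueError("span must be positive")
    bursts = np.asarray(bursts, dtype=float).reshape(-1, 2)
    n = len(bursts)
    durs = bursts[:, 1] - bursts[:, 0]
    stats = {
        "n": n,
        "rate": n / span_s,
        "mean_duration": float(durs.mean()) if n else float("nan"),
        "occupancy": float(durs.sum() / span_s),
    }
    if other is not None:
        stats["overlap_proportion"] = (
            float(_overlaps(bursts, np.asarray(other).reshape(-1, 2)).mean())
            if n else float("nan"))
    return stats


def bursts_to_frame(table: dict[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    """Flatten ``{(channel, band): intervals}`` into a tidy BurstTable."""
    rows = [
        {"channel": ch, "band": band, "start_s": s, "end_s": e}
        for (ch, band), ivs in table.items()
        for s, e in np.asarray(ivs).reshape(-1, 2)
    ]
    return pd.DataFrame(rows, columns=["channel", "band", "start_s", "end_s"])
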