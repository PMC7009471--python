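"""Signal conditioning, trial segmentation, time-frequency decomposition.

The conditioning chain mirrors standard intraoperative LFP practice: the raw
multi-contact recording is high-pass filtered at 2 Hz (zero-phase Butterworth),
linearly detrended and z-scored per channel *before* any trial segmentation,
so that epoch boundaries never influence the normalization.  Time-frequency
decomposition uses complex Morlet wavelets on a 1 Hz grid and the resulting
power is expressed, per trial and per frequency, relative to a 500 ms baseline
taken early in the trial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: columns every event table must carry (times in seconds from recording start)
EVENT_COLUMNS = ["trial", "block_type", "cue_s", "move_on_s", "move_off_s", "limb"]


class SessionValidationError(ValueError):
    """An event table or session file violates a structural invariant."""


@dataclass
class Recording:
    """Multi-contact LFP recording.

    Parameters
    ----------
    signal
        Array of shape ``(n_contacts, n_samples)``, arbitrary units.
    fs
        Sampling rate in Hz.
    contact_labels
        One identifier per row of ``signal`` (``c2`` … ``c7`` by convention).
    excluded
        Labels of contacts dropped during conditioning (flat or clipped).
    """

    signal: np.ndarray
    fs: float
    contact_labels: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (contacts x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.contact_labels) != self.signal.shape[0]:
            raise ValueError("one contact label per signal row required")

    @property
    def n_contacts(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class TrialSet:
    """Equal-length epochs cut around per-trial alignment points.

    ``epochs`` has shape ``(n_trials, n_contacts, n_samples)`` and covers
    ``[-pre_s - pad_s, post_s + pad_s)`` around the alignment point (the cue,
    or a pseudo-cue for rest chunks).  The padding exists solely to absorb
    wavelet edge effects; analysis windows live in the nominal
    ``[-pre_s, post_s)`` span.
    """

    epochs: np.ndarray
    fs: float
    contact_labels: list[str]
    pre_s: float
    post_s: float
    pad_s: float
    meta: pd.DataFrame  # per-epoch: trial, limb, cue_s, move_on_s, move_off_s
    baseline: tuple[float, float]
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def times(self) -> np.ndarray:
        n = self.epochs.shape[2]
        return -(self.pre_s + self.pad_s) + np.arange(n) / self.fs


@dataclass
class TimeFrequencyMap:
    """Morlet power, ``(n_epochs, n_contacts, n_freqs, n_times)``.

    ``times`` are seconds relative to the epoch alignment point; ``valid`` is a
    per-frequency/time mask that is False wherever the wavelet support would
    extend past the true (unpadded) data edges.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    contact_labels: list[str]
    valid: np.ndarray  # (n_freqs, n_times) bool
    baseline_invalid: np.ndarray | None = None  # (n_epochs, n_contacts, n_freqs)

    @property
    def hop_s(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def band_rows(self, lo: float, hi: float) -> np.ndarray:
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table schema and ordering invariants.

    Raises :class:`SessionValidationError` naming the offending field.  An
    empty table (header only) is valid.
    """
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise SessionValidationError(f"event table missing column '{col}'")
    if len(events) == 0:
        return events
    for col in ("cue_s", "move_on_s", "move_off_s"):
        if not np.isfinite(events[col]).all():
            raise SessionValidationError(f"non-finite value in column '{col}'")
    if (events["move_on_s"] < events["cue_s"]).any():
        raise SessionValidationError("move_on_s before cue_s")
    if (events["move_off_s"] < events["move_on_s"]).any():
        raise SessionValidationError("move_off_s before move_on_s")
    bad = ~events["limb"].isin(["upper", "lower"])
    if bad.any():
        raise SessionValidationError("limb must be 'upper' or 'lower'")
    return events


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def condition_signal(
    recording: Recording,
    highpass_hz: float = 2.0,
    order: int = 4,
    clip_fraction: float = 0.05,
) -> Recording:
    """High-pass filter (zero-phase), detrend and z-score each channel.

    Channels that are flat, or saturated (more than ``clip_fraction`` of
    samples pinned at the channel extremum, as happens when an amplifier
    clips), are excluded from the returned recording and listed in
    ``Recording.excluded``.

    Requires at least 10 s of signal for filter stability.
    """
    if recording.duration < 10.0:
        raise ValueError("need at least 10 s of signal to condition")
    x = np.asarray(recording.signal, dtype=np.float64)

    keep, excluded = [], []
    for i, lab in enumerate(recording.contact_labels):
        ch = x[i]
        if np.ptp(ch) == 0:
            logger.warning("contact %s is flat; excluding", lab)
            excluded.append(lab)
            continue
        pinned = np.mean((ch == ch.max()) | (ch == ch.min()))
        if pinned > clip_fraction:
            logger.warning("contact %s clipped (%.1f%% pinned); excluding",
                           lab, 100 * pinned)
            excluded.append(lab)
            continue
        keep.append(i)
    if not keep:
        raise ValueError("all contacts excluded during conditioning")
    x = x[keep]

    sos = sps.butter(order, highpass_hz, btype="highpass", fs=recording.fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    x = sps.detrend(x, axis=1, type="linear")
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    return Recording(
        signal=x,
        fs=recording.fs,
        contact_labels=[recording.contact_labels[i] for i in keep],
        excluded=recording.excluded + excluded,
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_trials(
    recording: Recording,
    events: pd.DataFrame,
    pre_s: float = 4.0,
    post_s: float = 3.0,
    pad_s: float = 0.5,
    baseline: tuple[float, float] = (-2.0, -1.5),
) -> TrialSet:
    """Cut cue-aligned epochs ``[-pre_s, post_s)`` (plus wavelet padding).

    Trials whose padded epoch exceeds the recording bounds are dropped with a
    logged warning; sample indexing is 0-based and epochs are half-open.
    Overlapping epochs of consecutive trials produce a warning only.
    """
    validate_events(events)
    fs = recording.fs
    n_samp = int(round((pre_s + post_s + 2 * pad_s) * fs))
    n_total = recording.signal.shape[1]

    rows, kept_meta = [], []
    prev_end = -np.inf
    n_dropped = 0
    for _, ev in events.iterrows():
        start = int(round((ev["cue_s"] - pre_s - pad_s) * fs))
        if start < 0 or start + n_samp > n_total:
            logger.warning("trial %s epoch out of bounds; dropped", ev["trial"])
            n_dropped += 1
            continue
        if start < prev_end:
            warnings.warn(
                f"epoch of trial {ev['trial']} overlaps the previous trial",
                stacklevel=2,
            )
        prev_end = start + n_samp
        rows.append(recording.signal[:, start:start + n_samp])
        kept_meta.append(ev)

    epochs = (np.stack(rows) if rows
              else np.empty((0, recording.n_contacts, n_samp)))
    meta = (pd.DataFrame(kept_meta).reset_index(drop=True) if kept_meta
            else pd.DataFrame(columns=events.columns))
    if n_dropped:
        logger.info("dropped %d/%d trials at recording bounds",
                    n_dropped, len(events))
    return TrialSet(
        epochs=epochs, fs=fs, contact_labels=list(recording.contact_labels),
        pre_s=pre_s, post_s=post_s, pad_s=pad_s, meta=meta,
        baseline=baseline, n_dropped=n_dropped,
    )


def segment_rest(
    recording: Recording,
    rest_end_s: float,
    chunk_s: float = 7.0,
    pre_s: float = 4.0,
    pad_s: float = 0.5,
    start_s: float = 0.5,
) -> TrialSet:
    """Cut non-overlapping pseudo-trials from the dedicated rest segment.

    Each ``chunk_s`` chunk is framed like a task trial (pseudo-cue ``pre_s``
    into the chunk) and is baseline-normalized against its own leading 500 ms,
    mirroring how task trials are treated.
    """
    fs = recording.fs
    post_s = chunk_s - pre_s
    cues = []
    t = start_s + pre_s
    while t + post_s + pad_s <= rest_end_s and t - pre_s - pad_s >= 0:
        cues.append(t)
        t += chunk_s
    meta = pd.DataFrame({
        "trial": [f"rest{i}" for i in range(len(cues))],
        "block_type": "rest",
        "cue_s": cues,
        "move_on_s": np.nan,
        "move_off_s": np.nan,
        "limb": "",
    })
    n_samp = int(round((chunk_s + 2 * pad_s) * fs))
    rows = [
        recording.signal[:, int(round((c - pre_s - pad_s) * fs)):
                         int(round((c - pre_s - pad_s) * fs)) + n_samp]
        for c in cues
    ]
    epochs = (np.stack(rows) if rows
              else np.empty((0, recording.n_contacts, n_samp)))
    return TrialSet(
        epochs=epochs, fs=fs, contact_labels=list(recording.contact_labels),
        pre_s=pre_s, post_s=post_s, pad_s=pad_s, meta=meta,
        baseline=(-pre_s, -pre_s + 0.5),
    )


# ---------------------------------------------------------------------------
# Morlet decomposition
# ---------------------------------------------------------------------------

def _morlet_wavelet(freq: float, fs: float, n_cycles: float,
                    trunc_sd: float = 3.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet truncated at +-trunc_sd sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(trunc_sd * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t ** 2) / (2 * sigma_t ** 2)) * np.exp(2j * np.pi * freq * t)
    w -= w.mean()  # zero-mean correction (negligible at >= 5 cycles)
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    return w.astype(np.complex64)


def morlet_decompose(
    trials: TrialSet,
    freqs: np.ndarray | None = None,
    n_cycles: float | np.ndarray = 7.0,
    hop_s: float = 0.01,
    out_span: tuple[float, float] | None = None,
) -> TimeFrequencyMap:
    """Decimated complex-Morlet power of every epoch.

    Power is evaluated only at window centres spaced ``hop_s`` apart (10 ms by
    default): the wavelet inner product is computed directly at those centres
    by a banded matrix product, with wavelets of similar length grouped so the
    work per output sample scales with the wavelet support rather than the
    epoch length.  This is numerically identical to convolving at the full
    rate and then decimating.

    Output samples whose wavelet support crosses the true data edge are marked
    invalid in ``TimeFrequencyMap.valid``.  Power is linear in squared input
    amplitude.  The effective time resolution at frequency f is
    ``n_cycles / (2 pi f)`` seconds (one wavelet standard deviation).
    ``n_cycles`` may be a per-frequency array: ``n_cycles = f / B`` gives a
    constant-bandwidth transform with frequency resolution ``B`` Hz at every
    row, the appropriate trade-off for temporally localizing narrow-band
    bursts.
    """
    fs = trials.fs
    if freqs is None:
        freqs = np.arange(8.0, 501.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() <= 2.0 or freqs.max() > 0.45 * fs:
        raise ValueError("frequency grid must lie within (2 Hz, 0.45*fs]")

    if out_span is None:
        out_span = (-trials.pre_s, trials.post_s)
    lo, hi = out_span
    hop = hop_s
    n_out = int(round((hi - lo) / hop))
    centers = lo + (np.arange(n_out) + 0.5) * hop

    n_ep, n_ch, n_samp = trials.epochs.shape
    t0 = -(trials.pre_s + trials.pad_s)  # time of sample 0
    center_idx = np.round((centers - t0) * fs).astype(int)

    # group wavelets of similar length; one bank per group
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)
    wavelets = [_morlet_wavelet(f, fs, nc) for f, nc in zip(freqs, n_cycles)]
    halves = np.array([len(w) // 2 for w in wavelets])
    buckets: dict[int, list[int]] = {}
    for j, h in enumerate(halves):
        buckets.setdefault(int(np.ceil(np.log(max(h, 1)) / np.log(1.5))), []).append(j)

    max_half = int(halves.max())
    power = np.empty((n_ep, n_ch, len(freqs), n_out), dtype=np.float32)
    valid = np.ones((len(freqs), n_out), dtype=bool)
    for j, h in enumerate(halves):
        valid[j] = (center_idx - h >= 0) & (center_idx + h < n_samp)

    pad = np.zeros((n_ch, n_samp + 2 * max_half), dtype=np.float32)
    for b in sorted(buckets):
        idx = buckets[b]
        lb_half = int(max(halves[idx]))
        lb = 2 * lb_half + 1
        bank = np.zeros((lb, len(idx)), dtype=np.complex64)
        for col, j in enumerate(idx):
            off = lb_half - halves[j]
            bank[off:off + len(wavelets[j]), col] = np.conj(wavelets[j][::-1])
        bank_r = np.ascontiguousarray(bank.real)
        bank_i = np.ascontiguousarray(bank.imag)
        starts = center_idx + max_half - lb_half
        for e in range(n_ep):
            pad[:, max_half:max_half + n_samp] = trials.epochs[e]
            view = sliding_window_view(pad, lb, axis=1)
            win = np.ascontiguousarray(view[:, starts, :]).reshape(-1, lb)
            re = win @ bank_r
            im = win @ bank_i
            p = (re * re + im * im).reshape(n_ch, n_out, len(idx))
            power[e, :, idx, :] = np.transpose(p, (2, 0, 1))

    return TimeFrequencyMap(
        power=power, freqs=freqs, times=centers,
        contact_labels=list(trials.contact_labels), valid=valid,
    )


def baseline_normalize(
    tfmap: TimeFrequencyMap,
    baseline: tuple[float, float] = (-2.0, -1.5),
) -> TimeFrequencyMap:
    """Express power as relative change with respect to a per-trial baseline.

    Every 1 Hz component of every trial is divided by the mean power of that
    component inside ``baseline`` (seconds relative to the alignment point) of
    the *same* trial, so the baseline-window mean of normalized power is 1 per
    frequency per trial.  Frequencies with zero baseline power are flagged in
    ``baseline_invalid`` and set to NaN for that trial.
    """
    sel = (tfmap.times >= baseline[0]) & (tfmap.times < baseline[1])
    if not sel.any():
        raise ValueError("baseline window outside the decomposed span")
    base = tfmap.power[:, :, :, sel].mean(axis=3)  # (ep, ch, f)
    bad = base <= 0
    safe = np.where(bad, 1.0, base)
    norm = tfmap.power / safe[:, :, :, None]
    if bad.any():
        norm = norm.copy()
        norm[bad] = np.nan
        logger.warning("%d trial/contact/frequency baselines were zero",
                       int(bad.sum()))
    return TimeFrequencyMap(
        power=norm, freqs=tfmap.freqs, times=tfmap.times,
        contact_labels=tfmap.contact_labels, valid=tfmap.valid,
        baseline_invalid=bad,
    )
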