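"""Synthetic multi-contact LFP sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 1/f background noise per contact, stochastic alpha and beta bursts
(Poisson onsets, Gamma-distributed durations, Hanning-windowed band-centre
carriers), a class-dependent multi-band power contrast tied to the trial
structure, and attenuation of that contrast while a burst is ongoing
(controlled by the gating factor gamma).  A session consists of a rest
segment followed by cued upper/lower-limb trials with jittered intertrial
intervals.

Because the feature pipeline divides every trial's power by a baseline taken
*inside* the trial, a time-constant multiplicative contrast would cancel
exactly and carry no decodable information.  The contrast therefore follows a
temporal profile: with ``contrast_onset='at_instruction'`` it builds up as a
convex (quadratic) preparatory ramp from the trial start to the cue and holds
through the movement, so it is applied from the trial start onward; with
``'at_cue'`` it switches on only after the cue (0.3 s rise).  Burst gating
relaxes the profile toward its level inside the baseline window, so at
gamma=0 a burst renders the window/baseline power ratio exactly
class-independent.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import fft as spfft

from .bursts import CLASSIFIED_BANDS, DETECTION_BANDS
from .features import FEATURE_BANDS
from .preprocess import (EVENT_COLUMNS, Recording, SessionValidationError,
                         validate_events)

#: corner of the recording chain's anti-alias low-pass, Hz
RECORDING_LOWPASS_HZ = 550.0


class ConfigurationError(ValueError):
    """A generator configuration violates one of its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic session.

    Defaults encode the recording and task conditions the analysis targets:
    six directional contacts sampled at 2048 Hz, a ~100 s rest segment,
    cued trials with a 7.7 s mean intertrial interval, and pre-cue alpha/beta
    bursting at ~1.01 and ~0.73 bursts/s with ~0.17 and ~0.20 s mean
    durations.  ``class_contrast`` is the fractional band-power offset of
    "upper" trials over the nine feature bands; ``burst_gating_factor``
    (gamma) is the fraction of that contrast surviving while a burst is
    ongoing (1 = bursts carry full information, 0 = bursts erase it).
    """

    n_contacts: int = 6
    fs: float = 2048.0
    n_trials_per_class: int = 16
    intertrial_interval: float = 7.7
    intertrial_jitter: float = 1.6
    block_design: str = "fixed_limb"
    rest_duration: float = 100.0
    background_exponent: float = 1.5
    alpha_burst_rate: float = 1.0125
    alpha_burst_mean_duration: float = 0.1672
    beta_burst_rate: float = 0.7342
    beta_burst_mean_duration: float = 0.2015
    burst_amplitude_gain: float = 12.0
    burst_gate_margin: float = 0.05
    class_contrast: tuple[float, ...] = (
        0.0, 0.0, 0.0, 0.0, 2.0, 2.0, 2.0, 4.0, 4.0)
    burst_gating_factor: float = 0.5
    contrast_onset: str | None = None  # derived from block_design if None
    contact_contrast_weights: tuple[float, ...] | None = None
    move_onset_range: tuple[float, float] = (0.3, 1.0)
    move_duration_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_design not in ("fixed_limb", "random_limb"):
            raise ConfigurationError("block_design must be fixed_limb or random_limb")
        if self.contrast_onset is None:
            self.contrast_onset = ("at_instruction"
                                   if self.block_design == "fixed_limb"
                                   else "at_cue")
        if self.contrast_onset not in ("at_instruction", "at_cue"):
            raise ConfigurationError("contrast_onset must be at_instruction or at_cue")
        if self.fs <= 2 * RECORDING_LOWPASS_HZ:
            raise ConfigurationError(
                f"fs must exceed twice the {RECORDING_LOWPASS_HZ:g} Hz low-pass")
        for name in ("n_contacts", "n_trials_per_class", "intertrial_interval",
                     "rest_duration", "alpha_burst_rate", "beta_burst_rate",
                     "alpha_burst_mean_duration", "beta_burst_mean_duration",
                     "burst_amplitude_gain"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for band in ("alpha", "beta"):
            rate = getattr(self, f"{band}_burst_rate")
            dur = getattr(self, f"{band}_burst_mean_duration")
            if dur <= 0.1:
                raise ConfigurationError(
                    f"{band} mean burst duration must exceed the 0.1 s "
                    "minimum burst length")
            if rate * dur >= 1.0:
                raise ConfigurationError(
                    f"{band} burst occupancy (rate x duration) must stay below 1")
        if self.burst_gate_margin < 0:
            raise ConfigurationError("burst_gate_margin must be non-negative")
        g = self.burst_gating_factor
        if not 0.0 <= g <= 1.0:
            raise ConfigurationError("burst_gating_factor must lie in [0, 1]")
        cc = np.asarray(self.class_contrast, dtype=float)
        if cc.shape != (len(FEATURE_BANDS),):
            raise ConfigurationError(
                f"class_contrast must have {len(FEATURE_BANDS)} entries")
        if not np.isfinite(cc).all() or (cc <= -1).any():
            raise ConfigurationError("class_contrast must be finite and > -1")
        if self.contact_contrast_weights is None:
            self.contact_contrast_weights = tuple([1.0] * self.n_contacts)
        if len(self.contact_contrast_weights) != self.n_contacts:
            raise ConfigurationError("one contrast weight per contact required")


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``bursts`` maps ``(contact_label, band)`` to an ``(n, 2)`` array of
    merged burst intervals in seconds.  ``class_gate`` samples (at ~100 Hz,
    on ``gate_times``) the ungated preparatory profile g(t) of the "upper"
    trials; ``applied_gate`` is the per-contact profile actually applied
    after burst gating (inside a burst the profile is relaxed toward the
    trial's tonic baseline level by a factor 1-gamma), so the band-power
    contrast applied to contact ``i`` in band ``b`` at time ``t`` is
    ``class_contrast[b] * weight[i] * applied_gate[i](t)``.
    """

    bursts: dict[tuple[str, str], np.ndarray]
    gate_times: np.ndarray
    class_gate: np.ndarray
    applied_gate: np.ndarray
    class_contrast: np.ndarray
    contact_weights: np.ndarray

    def __post_init__(self) -> None:
        for key, iv in self.bursts.items():
            iv = np.asarray(iv).reshape(-1, 2)
            if len(iv) and (iv[:, 1] < iv[:, 0]).any():
                raise ValueError(f"negative burst duration in {key}")


def _poisson_bursts(rng: np.random.Generator, rate: float, mean_dur: float,
                    t_max: float) -> np.ndarray:
    """Poisson burst onsets with 0.1 s + Gamma(shape 2) durations, merged.

    The 0.1 s offset guarantees every planted burst satisfies the detector's
    minimum-duration definition of a burst; the configured mean is the mean
    of the full duration.
    """
    n = rng.poisson(rate * t_max)
    onsets = np.sort(rng.uniform(0.0, t_max, size=n))
    durs = 0.1 + rng.gamma(2.0, (mean_dur - 0.1) / 2.0, size=n)
    iv = np.column_stack([onsets, np.minimum(onsets + durs, t_max)])
    merged: list[list[float]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=float).reshape(-1, 2)


def _make_events(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = 2 * cfg.n_trials_per_class
    gaps = rng.normal(cfg.intertrial_interval, cfg.intertrial_jitter, size=n)
    gaps = np.clip(gaps, max(cfg.intertrial_interval - 1.7, 5.5),
                   cfg.intertrial_interval + 4.2)
    cues = cfg.rest_duration + 5.0 + np.concatenate([[0.0], np.cumsum(gaps[1:])])
    move_on = cues + rng.uniform(*cfg.move_onset_range, size=n)
    move_off = move_on + rng.uniform(*cfg.move_duration_range, size=n)
    if cfg.block_design == "fixed_limb":
        limbs = ["upper"] * cfg.n_trials_per_class + ["lower"] * cfg.n_trials_per_class
    else:
        limbs = ["upper", "lower"] * cfg.n_trials_per_class
        limbs = [limbs[i] for i in rng.permutation(n)]
    return pd.DataFrame({
        "trial": np.arange(n),
        "block_type": cfg.block_design,
        "cue_s": cues,
        "move_on_s": move_on,
        "move_off_s": move_off,
        "limb": limbs,
    })


def _contrast_profile(cfg: GeneratorConfig, events: pd.DataFrame,
                      t: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Contrast profile and trial-active indicator for 'upper' trials.

    Returns ``(g, on, g_baseline)``: ``g`` is the preparatory profile (0
    outside upper trials), ``on`` marks the spans of upper trials, and
    ``g_baseline`` is the profile's mean inside the per-trial baseline
    window ([-2, -1.5] s before the cue) — the tonic level the burst gating
    relaxes the contrast toward.
    """
    g = np.zeros_like(t)
    on = np.zeros_like(t)
    # the profile's minimum is anchored at the centre of the per-trial
    # baseline window: the baseline then measures the tonic (class-free)
    # level, every window's power ratio deviates from 1 with a single sign,
    # and "contrast at baseline level" (full burst gating) is exactly
    # "no decodable contrast"
    t_min_rel = -1.75
    if cfg.contrast_onset == "at_instruction":
        u = np.linspace(-2.0, -1.5, 101)
        left = ((u - t_min_rel) / (t_min_rel + 4.0)) ** 2
        right = ((u - t_min_rel) / (-t_min_rel)) ** 2
        g_baseline = float(np.mean(np.where(u < t_min_rel, left, right)))
    else:
        g_baseline = 0.0
    for _, ev in events.iterrows():
        if ev["limb"] != "upper":
            continue
        cue, off = ev["cue_s"], ev["move_off_s"]
        if cfg.contrast_onset == "at_instruction":
            # released at the trial start, transiently back to tonic level
            # mid-delay, re-engaging toward the cue
            start = cue - 4.0
            tmin = cue + t_min_rel
            sel = (t >= start) & (t < tmin)
            g[sel] = ((t[sel] - tmin) / (tmin - start)) ** 2
            sel = (t >= tmin) & (t < cue)
            g[sel] = ((t[sel] - tmin) / (cue - tmin)) ** 2
        else:
            start = cue
            sel = (t >= cue) & (t < cue + 0.3)
            g[sel] = (t[sel] - cue) / 0.3
        hold = (t >= (cue if cfg.contrast_onset == "at_instruction"
                      else cue + 0.3)) & (t < off)
        g[hold] = 1.0
        decay = (t >= off) & (t < off + 0.5)
        g[decay] = 1.0 - (t[decay] - off) / 0.5
        on[(t >= start) & (t < off + 0.5)] = 1.0
    return g, on, g_baseline


def generate_session(
    cfg: GeneratorConfig,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Simulate one session: recording, event table and ground truth.

    Identical configurations (including the seed) yield bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    events = _make_events(cfg, rng)
    t_total = float(events["move_off_s"].iloc[-1]) + 4.0
    # pad to an FFT-friendly length; the extra tail is kept in the recording
    n = spfft.next_fast_len(int(round(t_total * cfg.fs)), real=True)
    t_total = n / cfg.fs
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)

    # spectral shaping: 1/f^beta power above 1 Hz, recording low-pass at 550 Hz
    shape = np.zeros_like(freqs)
    nz = freqs >= 0.5
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-cfg.background_exponent / 2.0)
    shape *= 1.0 / np.sqrt(1.0 + (freqs / RECORDING_LOWPASS_HZ) ** 16)

    t = np.arange(n) / cfg.fs
    labels = [f"c{i + 2}" for i in range(cfg.n_contacts)]
    class_gate, class_on, g_base = _contrast_profile(cfg, events, t)
    cc = np.asarray(cfg.class_contrast, dtype=float)
    weights = np.asarray(cfg.contact_contrast_weights, dtype=float)
    gamma = cfg.burst_gating_factor

    # only bands that actually carry contrast need their own component; the
    # rest of the spectrum is synthesized in one shot
    scaled = [b for b in range(len(FEATURE_BANDS)) if cc[b] != 0]
    band_masks = {b: (freqs >= FEATURE_BANDS[b][0]) &
                  (freqs <= FEATURE_BANDS[b][1]) for b in scaled}
    rest_mask = ~np.logical_or.reduce(list(band_masks.values())) \
        if scaled else np.ones_like(freqs, dtype=bool)

    signal = np.empty((cfg.n_contacts, n), dtype=np.float32)
    gt_bursts: dict[tuple[str, str], np.ndarray] = {}
    decim = max(1, int(round(cfg.fs / 100.0)))
    gate_times = t[::decim]
    applied_gate = np.empty((cfg.n_contacts, len(gate_times)))

    for ci, lab in enumerate(labels):
        spec = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs))) * shape
        spec[0] = 0.0
        # normalize to unit time-domain variance (Parseval, without a
        # round-trip transform)
        spec /= np.sqrt(2.0 * np.sum(np.abs(spec) ** 2)) / n

        # planted bursts: band-centre carrier under a Hanning envelope
        burst_sig = np.zeros(n)
        in_burst = np.zeros(n, dtype=bool)
        for band in CLASSIFIED_BANDS:
            lo, hi = DETECTION_BANDS[band]
            rate = getattr(cfg, f"{band}_burst_rate")
            mdur = getattr(cfg, f"{band}_burst_mean_duration")
            ivs = _poisson_bursts(rng, rate, mdur, t_total)
            gt_bursts[(lab, band)] = ivs
            bmask = (freqs >= lo) & (freqs <= hi)
            band_rms = float(np.sqrt(np.sum(np.abs(spec[bmask]) ** 2)) *
                             np.sqrt(2.0) / n)
            fc = 0.5 * (lo + hi)
            for s, e in ivs:
                i0, i1 = int(round(s * cfg.fs)), int(round(e * cfg.fs))
                if i1 <= i0:
                    continue
                seg = np.arange(i1 - i0) / cfg.fs
                env = np.hanning(i1 - i0)
                phase = rng.uniform(0, 2 * np.pi)
                burst_sig[i0:i1] += (cfg.burst_amplitude_gain * band_rms * env *
                                     np.cos(2 * np.pi * fc * seg + phase))
                # gating extends a short margin beyond the waveform: the
                # suppression of preparatory modulation outlasts the burst
                m = int(round(cfg.burst_gate_margin * cfg.fs))
                in_burst[max(0, i0 - m):min(n, i1 + m)] = True

        # while a burst is ongoing the preparatory modulation is relaxed
        # toward the trial's tonic baseline level: gamma=1 leaves it intact,
        # gamma=0 freezes the circuit at the level the per-trial baseline
        # normalization divides out (bursts then carry no class information)
        eff = np.where(in_burst,
                       gamma * class_gate + (1.0 - gamma) * g_base * class_on,
                       class_gate)
        applied_gate[ci] = eff[::decim]

        if scaled and np.any(eff != 0):
            sig = spfft.irfft(spec * rest_mask, n)
            for b in scaled:
                comp = spfft.irfft(spec * band_masks[b], n)
                sig += comp * np.sqrt(1.0 + cc[b] * weights[ci] * eff)
        else:
            sig = spfft.irfft(spec, n)
        signal[ci] = sig + burst_sig

    recording = Recording(signal=signal, fs=cfg.fs, contact_labels=labels)
    gt = GroundTruth(
        bursts=gt_bursts, gate_times=gate_times,
        class_gate=class_gate[::decim], applied_gate=applied_gate,
        class_contrast=cc, contact_weights=weights,
    )
    return recording, events, gt


# ---------------------------------------------------------------------------
# session container I/O
# ---------------------------------------------------------------------------

def write_session(recording: Recording, events: pd.DataFrame,
                  path: str | Path) -> None:
    """Write a session directory: ``session.h5`` (signal) + ``events.csv``."""
    validate_events(events)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "session.h5", "w") as f:
        f.create_dataset("signal", data=np.asarray(recording.signal,
                                                   dtype=np.float32))
        f.attrs["fs"] = recording.fs
        f.attrs["contact_labels"] = [str(c) for c in recording.contact_labels]
        f.attrs["excluded"] = [str(c) for c in recording.excluded]
    events[EVENT_COLUMNS].to_csv(path / "events.csv", index=False)


def read_session(path: str | Path) -> tuple[Recording, pd.DataFrame]:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`SessionValidationError` naming the offending field if the
    event table is malformed.
    """
    path = Path(path)
    with h5py.File(path / "session.h5", "r") as f:
        if "signal" not in f:
            raise SessionValidationError("session.h5 missing dataset 'signal'")
        sig = f["signal"][()]
        if "fs" not in f.attrs:
            raise SessionValidationError("session.h5 missing attribute 'fs'")
        rec = Recording(
            signal=sig, fs=float(f.attrs["fs"]),
            contact_labels=[str(c) for c in f.attrs["contact_labels"]],
            excluded=[str(c) for c in f.attrs.get("excluded", [])],
        )
    events = pd.read_csv(path / "events.csv")
    validate_events(events)
    if len(events):
        events["limb"] = events["limb"].astype(str)
        events["block_type"] = events["block_type"].astype(str)
    return rec, events
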