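"""End-to-end orchestration: session -> conditioned signal -> TF power ->
windows/bursts -> features -> cross-validated AUC tables.

Two analyses are provided.  ``decode_periods`` reproduces the task-period
decoding: one AUC per contact per 100 ms window position (cue-aligned across
trials), summarized as the mean over a period's windows and then over
contacts.  ``decode_burst_states`` reproduces the burst-conditioned
decoding of the pre-cue period: windows are classed as alpha-burst,
beta-burst or non-burst, decoded per contact per state, and summarized under
the same/different best-three-contact configurations.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as bst
from . import evaluate as ev
from . import features as feat
from . import preprocess as pp

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (YAML-serializable)."""

    epoch_pre_s: float = 4.0
    epoch_post_s: float = 3.0
    pad_s: float = 0.5
    baseline_start_s: float = -2.0
    baseline_len_s: float = 0.5
    rest_chunk_s: float = 7.0
    hop_s: float = 0.01
    window_s: float = 0.1
    n_cycles: float = 7.0
    freq_lo: float = 8.0
    freq_hi: float = 500.0
    burst_percentile: float = 75.0
    min_burst_s: float = 0.1
    envelope_smooth_s: float = 0.2
    #: spectral resolution (Morlet sigma_f, Hz) of the burst-detection
    #: envelope.  Detection uses a constant-bandwidth transform
    #: (n_cycles = f / bandwidth): sigma_f = 2 Hz keeps the adjacent alpha
    #: and beta bands separated (a band-centre carrier cannot bleed across),
    #: while the implied sigma_t of ~0.08 s localizes 0.1-0.2 s bursts far
    #: better than the constant-Q 7-cycle map used for spectral features
    burst_bandwidth_hz: float = 2.0
    k_folds: int = 4
    top_n: int = 6
    n_neighbors: int = 10
    min_state_windows: int = 8
    #: 'pooled': one model per contact scores all pre-cue windows, AUC is
    #: computed per state from that state's out-of-fold scores (training set
    #: identical across states).  'per_state': separate models per state,
    #: with window counts subsampled to the smallest state so training-set
    #: size cannot masquerade as a burst effect.
    state_training: str = "pooled"
    seed: int = 0

    @property
    def baseline(self) -> tuple[float, float]:
        return (self.baseline_start_s,
                self.baseline_start_s + self.baseline_len_s)

    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)


@dataclass
class PeriodDecodingResult:
    window_auc: pd.DataFrame  # contact, period, t_center_s, auc
    period_summary: pd.Series  # period -> AUC
    importance: pd.DataFrame  # contact, period, band, importance
    n_dropped_windows: int = 0


@dataclass
class BurstDecodingResult:
    state_auc: pd.DataFrame  # contact, state, auc, n_windows
    configurations: dict  # mode -> ev.ContactConfiguration
    burst_stats: pd.DataFrame  # contact, band, rate, duration, occupancy, ...
    burst_table: pd.DataFrame
    combined_occupancy: float = float("nan")
    n_windows: int = 0


def _rest_end(events: pd.DataFrame, recording: pp.Recording) -> float:
    if len(events) == 0:
        return recording.duration
    return float(events["cue_s"].min()) - 5.0


def _assign_rest_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced pseudo-labels for rest chunks (rest carries no true limb)."""
    labels = np.array(["upper", "lower"] * ((n + 1) // 2))[:n]
    return labels[rng.permutation(n)]


def _window_centers(lo: float, hi: float, window_s: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / window_s + 1e-9))
    return lo + (np.arange(n) + 0.5) * window_s


def _decode_stream(
    trials: pp.TrialSet,
    labels: np.ndarray,
    cfg: PipelineConfig,
    span: tuple[float, float],
    period_of,
    rng: np.random.Generator,
    win_span: tuple[float, float] | None = None,
) -> tuple[list[dict], list[dict], int]:
    """Per-contact per-window-position cross-validated AUC for one stream."""
    t0 = time.perf_counter()
    tf = pp.morlet_decompose(trials, freqs=cfg.freqs(), n_cycles=cfg.n_cycles,
                             hop_s=cfg.hop_s, out_span=span)
    norm = pp.baseline_normalize(tf, trials.baseline)
    bp = feat.band_average(norm.power, norm.freqs)
    logger.info("TF decomposition of %d epochs took %.1f s",
                trials.n_trials, time.perf_counter() - t0)

    win_span = win_span or span
    centers = _window_centers(win_span[0], win_span[1], cfg.window_s)
    feats, valid = feat.extract_features(bp, norm.times, centers,
                                         window_s=cfg.window_s)
    groups = trials.meta["trial"].to_numpy()
    rows, imp_rows = [], []
    n_dropped = 0
    t0 = time.perf_counter()
    for pi, c in enumerate(centers):
        period = period_of(c)
        if period is None:
            continue
        for ci, contact in enumerate(trials.contact_labels):
            X = feats[:, ci, :, pi]
            ok = np.isfinite(X).all(axis=1)
            if not valid[pi] or ok.sum() < len(X):
                X = X[ok]
            if len(X) < 2 * cfg.k_folds or len(np.unique(labels[ok])) < 2:
                n_dropped += 1
                continue
            scores, sel = ev.crossval_scores(
                X, labels[ok], groups=groups[ok], k_folds=cfg.k_folds,
                top_n=cfg.top_n, n_neighbors=cfg.n_neighbors, rng=rng)
            rows.append({"contact": contact, "period": period,
                         "t_center_s": float(c),
                         "auc": ev.auc(scores, labels[ok])})
            for b, name in enumerate(feat.BAND_NAMES):
                imp_rows.append({"contact": contact, "period": period,
                                 "band": name,
                                 "importance": sel.importance[b]})
    logger.info("decoding %d window positions took %.1f s",
                len(centers), time.perf_counter() - t0)
    return rows, imp_rows, n_dropped


def decode_periods(
    recording: pp.Recording,
    events: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    periods: tuple[str, ...] = ev.TASK_PERIODS,
    rng: np.random.Generator | None = None,
    conditioned: bool = False,
) -> PeriodDecodingResult:
    """Task-period decoding: AUC per contact per 100 ms window position.

    ``periods`` restricts the analysed task periods (and with them the span
    that is decomposed, which dominates the run time).  The rest period is
    analysed as 7 s pseudo-trials from the dedicated rest segment with
    balanced pseudo-labels, since rest carries no true limb association.
    """
    cfg = cfg or PipelineConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    rec = recording if conditioned else pp.condition_signal(recording)

    all_rows: list[dict] = []
    all_imp: list[dict] = []
    n_dropped = 0

    if "rest" in periods:
        rest = pp.segment_rest(rec, _rest_end(events, rec),
                               chunk_s=cfg.rest_chunk_s,
                               pre_s=cfg.epoch_pre_s, pad_s=cfg.pad_s)
        if rest.n_trials >= 2 * cfg.k_folds:
            labels = _assign_rest_labels(rest.n_trials, rng)
            rest.meta["limb"] = labels
            span = (-cfg.epoch_pre_s, rest.post_s)
            # windows start after the chunk's leading 500 ms baseline
            rows, imp, nd = _decode_stream(
                rest, labels, cfg, span, lambda c: "rest", rng,
                win_span=(-cfg.epoch_pre_s + 0.5, rest.post_s))
            all_rows += rows
            all_imp += imp
            n_dropped += nd
        else:
            logger.warning("rest segment too short for decoding; skipped")

    task = [p for p in periods if p != "rest"]
    if task and len(events) > 0:
        post = cfg.epoch_post_s if {"pre_move", "post_move"} & set(task) else 0.0
        trials = pp.segment_trials(rec, events, pre_s=cfg.epoch_pre_s,
                                   post_s=post, pad_s=cfg.pad_s,
                                   baseline=cfg.baseline)
        labels = trials.meta["limb"].to_numpy()
        mean_on = float((trials.meta["move_on_s"] - trials.meta["cue_s"]).mean())
        mean_off = float((trials.meta["move_off_s"] - trials.meta["cue_s"]).mean())

        def period_of(c: float) -> str | None:
            if c < 0:
                p = "pre_cue"
            elif c < mean_on:
                p = "pre_move"
            elif c < mean_off:
                p = "post_move"
            else:
                return None
            return p if p in task else None

        span = (-cfg.epoch_pre_s, post)
        rows, imp, nd = _decode_stream(trials, labels, cfg, span,
                                       period_of, rng)
        all_rows += rows
        all_imp += imp
        n_dropped += nd

    window_auc = pd.DataFrame(
        all_rows, columns=["contact", "period", "t_center_s", "auc"])
    importance = (pd.DataFrame(all_imp)
                  .groupby(["contact", "period", "band"], as_index=False)
                  ["importance"].mean()
                  if all_imp else
                  pd.DataFrame(columns=["contact", "period", "band",
                                        "importance"]))
    summary = (ev.period_auc(window_auc) if len(window_auc)
               else pd.Series(dtype=float))
    return PeriodDecodingResult(window_auc=window_auc, period_summary=summary,
                                importance=importance,
                                n_dropped_windows=n_dropped)


def detect_session_bursts(
    trials: pp.TrialSet,
    cfg: PipelineConfig,
    span: tuple[float, float],
) -> tuple[dict, dict, pd.DataFrame, float]:
    """Detect bursts per trial/contact/band with a shared percentile threshold.

    Band envelopes come from a dedicated constant-bandwidth Morlet
    decomposition of the detection bands only (``burst_bandwidth_hz``).  The threshold for each
    contact and band is the configured percentile of that contact's envelope
    concatenated over all analysed (pre-cue) spans, so movement-related power
    changes never contaminate it.  Returns
    ``(per_trial_bursts, envelopes, stats_frame, combined_occupancy)``
    where ``per_trial_bursts`` maps ``(trial_index, contact)`` to interval
    arrays keyed by band.
    """
    lo = min(b[0] for b in bst.DETECTION_BANDS.values())
    hi = max(b[1] for b in bst.DETECTION_BANDS.values())
    freqs = np.arange(lo, hi + 1.0)
    tf = pp.morlet_decompose(trials, freqs=freqs,
                             n_cycles=freqs / cfg.burst_bandwidth_hz,
                             hop_s=cfg.hop_s, out_span=span)
    dt = tf.hop_s
    n_ep, n_ch = tf.power.shape[:2]
    span_len = span[1] - span[0]
    envs = {band: bst.band_envelope(tf.power, tf.freqs, band, dt,
                                    cfg.envelope_smooth_s)
            for band in bst.DETECTION_BANDS}  # (n_ep, n_ch, n_t)

    per_trial: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    for e in range(n_ep):
        for ci in range(n_ch):
            per_trial[(e, tf.contact_labels[ci])] = {}
    for band, env in envs.items():
        for ci, contact in enumerate(tf.contact_labels):
            thr = float(np.percentile(env[:, ci, :], cfg.burst_percentile))
            for e in range(n_ep):
                iv = bst.detect_bursts(env[e, ci], dt,
                                       percentile=cfg.burst_percentile,
                                       min_duration=cfg.min_burst_s,
                                       threshold=thr)
                iv = iv + span[0]  # envelope starts at span[0]
                per_trial[(e, contact)][band] = iv

    stats_rows = []
    union_time = 0.0
    for ci, contact in enumerate(tf.contact_labels):
        pooled = {band: [per_trial[(e, contact)][band] for e in range(n_ep)]
                  for band in bst.DETECTION_BANDS}
        counts = {}
        for band in bst.CLASSIFIED_BANDS:
            other = "beta" if band == "alpha" else "alpha"
            n_tot, dur_sum, n_overlap = 0, 0.0, 0
            for e in range(n_ep):
                iv = pooled[band][e]
                n_tot += len(iv)
                dur_sum += float((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0.0
                n_overlap += int(bst._overlaps(iv, pooled[other][e]).sum())
            counts[band] = (n_tot, n_overlap)
            stats_rows.append({
                "contact": contact, "band": band,
                "rate": n_tot / (n_ep * span_len) if n_ep else float("nan"),
                "mean_duration": dur_sum / n_tot if n_tot else float("nan"),
                "occupancy": dur_sum / (n_ep * span_len) if n_ep else float("nan"),
                "overlap_proportion": n_overlap / n_tot if n_tot else float("nan"),
            })
        # combined alpha+beta occupancy of this contact (union of intervals)
        for e in range(n_ep):
            both = [pooled["alpha"][e], pooled["beta"][e]]
            free = bst.nonburst_periods(both, span, min_duration=0.0)
            free_t = float((free[:, 1] - free[:, 0]).sum()) if len(free) else 0.0
            union_time += span_len - free_t

    combined_occ = union_time / (n_ep * n_ch * span_len) if n_ep else float("nan")
    return per_trial, envs, pd.DataFrame(stats_rows), combined_occ


def decode_burst_states(
    recording: pp.Recording,
    events: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
    conditioned: bool = False,
) -> BurstDecodingResult:
    """Burst-conditioned decoding of the pre-cue period.

    Alpha/beta/low-gamma bursts are detected in each trial's 4 s pre-cue
    span; overlapping alpha/beta bursts are removed; 100 ms windows centred
    on every surviving burst and non-burst period are decoded per contact and
    per state (windows inherit the trial's limb label; folds group by trial),
    then summarized under both contact configurations.
    """
    cfg = cfg or PipelineConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    rec = recording if conditioned else pp.condition_signal(recording)
    span = (-cfg.epoch_pre_s, 0.0)

    trials = pp.segment_trials(rec, events, pre_s=cfg.epoch_pre_s,
                               post_s=0.0, pad_s=cfg.pad_s,
                               baseline=cfg.baseline)
    labels = trials.meta["limb"].to_numpy()
    per_trial, _, stats, combined_occ = detect_session_bursts(trials, cfg, span)

    tf = pp.morlet_decompose(trials, freqs=cfg.freqs(), n_cycles=cfg.n_cycles,
                             hop_s=cfg.hop_s, out_span=span)
    norm = pp.baseline_normalize(tf, trials.baseline)
    bp = feat.band_average(norm.power, norm.freqs)  # (ep, ch, 9, t)
    times = norm.times
    nwin = max(1, int(round(cfg.window_s / cfg.hop_s)))

    windows: list[bst.StateWindow] = []
    burst_rows = []
    state_rows: dict[str, dict[str, list]] = {
        c: {} for c in trials.contact_labels}
    for (e, contact), bands in per_trial.items():
        alpha_c, beta_c = bst.resolve_overlaps(bands["alpha"], bands["beta"])
        nb = bst.nonburst_periods(
            [bands["alpha"], bands["beta"], bands["low_gamma"]], span,
            min_duration=cfg.min_burst_s)
        trial_id = trials.meta["trial"].iloc[e]
        for band, iv in bands.items():
            for s, t_end in iv:
                burst_rows.append({"channel": contact, "band": band,
                                   "trial": trial_id, "start_s": s,
                                   "end_s": t_end})
        wins = bst.make_state_windows(alpha_c, beta_c, nb, span,
                                      channel=contact, trial=trial_id)
        windows.extend(wins)
        ci = trials.contact_labels.index(contact)
        for w in wins:
            i0 = int(np.searchsorted(times, w.start - 1e-9))
            if i0 + nwin > len(times):
                continue
            x = bp[e, ci, :, i0:i0 + nwin]
            if not np.isfinite(x).all():
                continue
            rec_list = state_rows[contact].setdefault(
                w.state, {"X": [], "y": [], "g": []})
            rec_list["X"].append(x.mean(axis=1))
            rec_list["y"].append(labels[e])
            rec_list["g"].append(trial_id)

    auc_rows = []
    states = ("non_burst", "alpha_burst", "beta_burst")
    for contact in trials.contact_labels:
        per_state = state_rows[contact]
        if cfg.state_training == "pooled":
            X = np.concatenate([np.asarray(d["X"]).reshape(-1, bp.shape[2])
                                for d in per_state.values()]) \
                if per_state else np.empty((0, bp.shape[2]))
            y = np.concatenate([np.asarray(d["y"]) for d in per_state.values()]) \
                if per_state else np.empty(0)
            g = np.concatenate([np.asarray(d["g"]) for d in per_state.values()]) \
                if per_state else np.empty(0)
            tag = np.concatenate([np.full(len(d["y"]), s)
                                  for s, d in per_state.items()]) \
                if per_state else np.empty(0)
            scores = None
            cls, cnt = (np.unique(y, return_counts=True) if len(y)
                        else (np.array([]), np.array([])))
            if (len(cls) == 2
                    and min(len(np.unique(g[y == c])) for c in cls)
                    >= cfg.k_folds):
                scores, _ = ev.crossval_scores(
                    X, y, groups=g, k_folds=cfg.k_folds, top_n=cfg.top_n,
                    n_neighbors=cfg.n_neighbors, rng=rng)
            for state in states:
                sel = tag == state
                value, nw = float("nan"), int(sel.sum())
                if scores is not None and nw:
                    ys = y[sel]
                    c2, n2 = np.unique(ys, return_counts=True)
                    if len(c2) == 2 and n2.min() >= cfg.min_state_windows:
                        value = ev.auc(scores[sel], ys)
                    else:
                        logger.warning("state %s on %s has too few windows",
                                       state, contact)
                auc_rows.append({"contact": contact, "state": state,
                                 "auc": value, "n_windows": nw})
            continue
        # per-state training: equalize window counts across states so the
        # comparison is not confounded by training-set size (non-burst
        # periods outnumber bursts roughly 3:1)
        counts = [len(d["X"]) for d in per_state.values()]
        n_min = min(counts) if len(counts) == 3 else None
        if n_min:
            for d in per_state.values():
                if len(d["X"]) > n_min:
                    pick = np.sort(rng.choice(len(d["X"]), n_min,
                                              replace=False))
                    for key in ("X", "y", "g"):
                        d[key] = [d[key][i] for i in pick]
        for state in states:
            d = per_state.get(state)
            value, nw = float("nan"), 0
            if d is not None:
                X = np.asarray(d["X"])
                y = np.asarray(d["y"])
                g = np.asarray(d["g"])
                nw = len(X)
                cls, cnt = np.unique(y, return_counts=True)
                if (len(cls) == 2 and cnt.min() >= cfg.min_state_windows
                        and min(len(np.unique(g[y == c])) for c in cls)
                        >= cfg.k_folds):
                    scores, _ = ev.crossval_scores(
                        X, y, groups=g, k_folds=cfg.k_folds,
                        top_n=cfg.top_n, n_neighbors=cfg.n_neighbors, rng=rng)
                    value = ev.auc(scores, y)
                else:
                    logger.warning("state %s on %s has too few windows",
                                   state, contact)
            auc_rows.append({"contact": contact, "state": state,
                             "auc": value, "n_windows": nw})

    state_auc = pd.DataFrame(auc_rows)
    configs = ev.burst_conditioned_auc(state_auc[["contact", "state", "auc"]])
    return BurstDecodingResult(
        state_auc=state_auc, configurations=configs, burst_stats=stats,
        burst_table=pd.DataFrame(
            burst_rows, columns=["channel", "band", "trial", "start_s",
                                 "end_s"]),
        combined_occupancy=combined_occ, n_windows=len(windows),
    )


def run_session(
    recording: pp.Recording,
    events: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    periods: tuple[str, ...] = ev.TASK_PERIODS,
    burst_analysis: bool = True,
) -> dict:
    """Full single-session analysis; optionally persist tidy CSV results."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    rec = pp.condition_signal(recording)
    out: dict = {}
    res = decode_periods(rec, events, cfg, periods=periods, rng=rng,
                         conditioned=True)
    out["periods"] = res
    if burst_analysis and len(events) > 0:
        out["bursts"] = decode_burst_states(rec, events, cfg, rng=rng,
                                            conditioned=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "pipeline_config.yaml")
        res.window_auc.to_csv(out_dir / "window_auc.csv", index=False)
        res.period_summary.rename("auc").to_csv(out_dir / "period_auc.csv")
        res.importance.to_csv(out_dir / "importance.csv", index=False)
        if "bursts" in out:
            b = out["bursts"]
            b.state_auc.to_csv(out_dir / "state_auc.csv", index=False)
            b.burst_stats.to_csv(out_dir / "burst_stats.csv", index=False)
            b.burst_table.to_csv(out_dir / "burst_table.csv", index=False)
            rows = [{"config": mode, "state": s, "auc": a}
                    for mode, c in b.configurations.items()
                    for s, a in c.state_auc.items()]
            pd.DataFrame(rows).to_csv(out_dir / "state_config_auc.csv",
                                      index=False)
    return out
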