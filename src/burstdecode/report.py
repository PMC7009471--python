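"""Figure and table assembly from tidy result files.

Figures are derived artefacts only: every panel is regenerated
deterministically from the CSVs a pipeline run wrote (plus the stored
configuration snapshot), and report generation never mutates the result
files.  Missing sections are skipped with a notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)


class ReportError(RuntimeError):
    """A result file could not be parsed."""


@dataclass
class ReportBundle:
    """Paths of everything one report run produced."""

    figures: list[Path] = field(default_factory=list)
    tables: list[Path] = field(default_factory=list)
    summary: Path | None = None
    notices: list[str] = field(default_factory=list)


def _read(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # propagate with the file named
        raise ReportError(f"malformed result file {path}: {exc}") from exc


def build_report(results_dir: str | Path,
                 out_dir: str | Path | None = None) -> ReportBundle:
    """Assemble the figure families from a results directory.

    Produces (when the corresponding CSV exists): AUC-by-task-period bars,
    burst rate/duration/occupancy histograms, burst-state AUC bars for both
    contact configurations, and feature-importance bars.  Re-running on the
    same inputs yields byte-identical tables.
    """
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    lines = ["# Decoding report", ""]

    def notice(msg: str) -> None:
        bundle.notices.append(msg)
        logger.info(msg)

    p = results_dir / "period_auc.csv"
    if p.exists():
        df = _read(p)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df.iloc[:, 0].astype(str), df["auc"], color="0.4")
        ax.axhline(0.5, color="r", ls="--", lw=1)
        ax.set_ylabel("AUC")
        ax.set_ylim(0.3, 1.0)
        ax.set_title("Decoding by task period")
        fig.tight_layout()
        out = out_dir / "auc_by_period.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        bundle.figures.append(out)
        lines.append("## Task-period AUC\n")
        lines += [f"- {r.iloc[0]}: {r['auc']:.3f}" for _, r in df.iterrows()]
        lines.append("")
    else:
        notice("period_auc.csv missing; task-period section skipped")

    p = results_dir / "burst_stats.csv"
    if p.exists():
        df = _read(p)
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        for ax, col in zip(axes, ("rate", "mean_duration", "occupancy")):
            for band, sub in df.groupby("band"):
                ax.hist(sub[col].dropna(), bins=10, alpha=0.6, label=band)
            ax.set_xlabel(col)
            ax.legend(fontsize=7)
        fig.tight_layout()
        out = out_dir / "burst_statistics.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        bundle.figures.append(out)
        agg = df.groupby("band")[["rate", "mean_duration",
                                  "occupancy"]].mean()
        tab = out_dir / "burst_stats_summary.csv"
        agg.to_csv(tab)
        bundle.tables.append(tab)
        lines.append("## Burst statistics (mean over contacts)\n")
        lines.append(agg.to_string())
        lines.append("")
    else:
        notice("burst_stats.csv missing; burst section skipped")

    p = results_dir / "state_config_auc.csv"
    if p.exists():
        df = _read(p)
        fig, ax = plt.subplots(figsize=(4.5, 3))
        states = ["non_burst", "alpha_burst", "beta_burst"]
        width = 0.35
        for i, (mode, sub) in enumerate(df.groupby("config")):
            vals = [sub.loc[sub["state"] == s, "auc"].mean() for s in states]
            ax.bar([x + i * width for x in range(len(states))], vals,
                   width=width, label=mode)
        ax.axhline(0.5, color="r", ls="--", lw=1)
        ax.set_xticks([x + width / 2 for x in range(len(states))])
        ax.set_xticklabels(states, fontsize=8)
        ax.set_ylabel("AUC")
        ax.legend(fontsize=7)
        ax.set_title("Pre-cue AUC by burst state")
        fig.tight_layout()
        out = out_dir / "auc_by_burst_state.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        bundle.figures.append(out)
        lines.append("## Burst-state AUC\n")
        lines.append(df.to_string(index=False))
        lines.append("")
    else:
        notice("state_config_auc.csv missing; burst-state section skipped")

    p = results_dir / "importance.csv"
    if p.exists():
        df = _read(p)
        agg = df.groupby("band", sort=False)["importance"].mean()
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(agg.index.astype(str), agg.to_numpy(), color="0.4")
        ax.set_ylabel("feature importance")
        ax.tick_params(axis="x", rotation=60, labelsize=7)
        fig.tight_layout()
        out = out_dir / "feature_importance.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        bundle.figures.append(out)
        lines.append("## Feature importance (selection fraction)\n")
        lines += [f"- {b}: {v:.3f}" for b, v in agg.items()]
        lines.append("")
    else:
        notice("importance.csv missing; importance section skipped")

    for msg in bundle.notices:
        lines.append(f"> note: {msg}")
    summary = out_dir / "summary.md"
    summary.write_text("\n".join(lines) + "\n")
    bundle.summary = summary
    return bundle
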