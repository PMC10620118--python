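"""Figure output: growth curves, waterfall plots, time-to-progression bars.

All functions write files and return the written paths; rendering is
deterministic given the inputs (no rcParams dependence beyond the Agg
backend chosen at import).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .cohort import ModelCohort  # noqa: E402
from .growth import model_mean_curve  # noqa: E402

logger = logging.getLogger(__name__)

PD_GUIDE = 20.0   # percent change marking progression
PR_GUIDE = -30.0  # percent change marking partial response
EVAL_DAY = 28


def plot_growth_curves(cohorts: Sequence[ModelCohort], out_dir: str | Path,
                       fmt: str = "png") -> list[Path]:
    """One panel per model and arm: mean relative volume ± SEM.

    A vertical gray bar marks the day-28 end of the primary observational
    period; a ``#`` glyph marks each tumor removal day.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for cohort in cohorts:
        arms = cohort.arms
        if not arms:
            logger.warning("model %s: no tumors, panel skipped", cohort.model_id)
            continue
        fig, axes = plt.subplots(1, len(arms), figsize=(4 * len(arms), 3.2),
                                 squeeze=False, sharey=True)
        for ax, (arm, courses) in zip(axes[0], sorted(arms.items())):
            if not courses:
                logger.warning("model %s arm %s empty, panel skipped",
                               cohort.model_id, arm)
                continue
            curve = model_mean_curve(courses)
            ax.errorbar(curve.days, curve.relative_volume, yerr=curve.sem_at_day,
                        marker="o", ms=3, lw=1.2, capsize=2)
            ax.axvline(EVAL_DAY, color="0.6", lw=4, alpha=0.4, zorder=0)
            ax.axhline(1.0, color="0.8", lw=0.8, ls=":")
            for course in courses:
                if course.removal_day is not None:
                    ax.annotate("#", (course.removal_day, ax.get_ylim()[1]),
                                ha="center", va="top", fontsize=9)
            ax.set_title(f"{cohort.model_id} — {arm}", fontsize=9)
            ax.set_xlabel("days from treatment start")
            ax.set_ylabel("relative tumor volume")
        fig.tight_layout()
        path = out_dir / f"growth_{cohort.model_id}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def plot_waterfall(values: Sequence[tuple[str, float]], out_path: str | Path
                   ) -> Path:
    """Sorted per-tumor percent-change bars with PD/PR guide lines."""
    if not values:
        raise ValueError("waterfall requires at least one value")
    ordered = sorted(values, key=lambda kv: kv[1], reverse=True)
    labels = [k for k, _ in ordered]
    heights = [v for _, v in ordered]
    fig, ax = plt.subplots(figsize=(max(4.0, 0.25 * len(ordered)), 3.2))
    colors = ["#b2182b" if h >= PD_GUIDE else "#2166ac" if h <= PR_GUIDE
              else "0.55" for h in heights]
    ax.bar(range(len(heights)), heights, color=colors)
    ax.axhline(PD_GUIDE, ls=":", color="k", lw=0.9)
    ax.axhline(PR_GUIDE, ls=":", color="k", lw=0.9)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("volume change from baseline (%)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_ttp(results: Sequence[dict], out_path: str | Path) -> Path:
    """Horizontal time-to-progression bars; censored models get an arrow.

    ``results`` rows need ``model_id``, ``days`` and ``censored`` keys (the
    ``ttp`` block of a trial report).
    """
    if not results:
        raise ValueError("ttp plot requires at least one result")
    ordered = sorted(results, key=lambda r: r["days"])
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(ordered) + 1.2))
    for y, row in enumerate(ordered):
        ax.barh(y, row["days"], color="0.6" if row["censored"] else "#b2182b",
                height=0.6)
        if row["censored"]:
            ax.annotate("", xy=(row["days"] * 1.06, y), xytext=(row["days"], y),
                        arrowprops=dict(arrowstyle="->", lw=1.1))
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([r["model_id"] for r in ordered], fontsize=7)
    ax.set_xlabel("days to confirmed progression")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_protocol_course(obs: Sequence[tuple[int, float]], events,
                         out_path: str | Path) -> Path:
    """Volume course under intermittent treatment with shaded pauses."""
    days = [d for d, _ in obs]
    vols = [v for _, v in obs]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(days, vols, marker="o", ms=3, lw=1.2, color="k")
    # shade: blue while on treatment, gray while paused
    bounds = [(ev.day, ev.action) for ev in events] + [(days[-1], "end")]
    for (d0, action), (d1, _) in zip(bounds, bounds[1:]):
        color = "#c6dbef" if action in ("start", "resume") else "0.85"
        ax.axvspan(d0, d1, color=color, zorder=0)
    ax.set_xlabel("days from first treatment")
    ax.set_ylabel("tumor volume (mm³)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
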