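"""Evaluation of classifications against ground truth.

The central metric is per-activity *sensitivity*: among predicted timepoints
whose true label is a given activity, the proportion predicted as that
activity.  The full per-activity distribution of predicted labels
(row-normalized confusion proportions) and multi-setting grids — one cell
per (sensor, metric, data type) combination, averaged over subjects — mirror
how the method's performance is usually summarized.  All proportions weight
each predicted timepoint equally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import Classification
from .io import LabelTrack, ValidationError

__all__ = [
    "sensitivity_table",
    "prediction_distribution",
    "setting_grid",
    "filtered_evaluation",
    "plot_setting_grid",
]


def _aligned(
    cls: Classification, track: LabelTrack, mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Predicted/true label pairs for labeled (and optionally unexcluded)
    timepoints."""
    truth = [track.label_at(float(t)) for t in cls.times]
    frame = pd.DataFrame(
        {"t": cls.times, "predicted": cls.labels, "truth": truth}
    )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != len(cls):
            raise ValidationError("exclusion mask length must match predictions")
        frame = frame[~mask]
    frame = frame.dropna(subset=["truth"])
    if frame.empty:
        raise ValidationError("no overlap between predictions and labels")
    return frame


def sensitivity_table(
    cls: Classification,
    track: LabelTrack,
    activities: list[str] | tuple[str, ...] | None = None,
    boundary_trim: float = 0.0,
    _mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-activity sensitivity: P(predicted == a | truth == a).

    Returns a frame with columns ``activity, sensitivity, n``; activities
    never observed as the truth get NaN (missing, not 0).  ``boundary_trim``
    drops timepoints within that many seconds of a label-interval boundary,
    where annotation of transitions is inherently fuzzy.
    """
    frame = _aligned(cls, track, _mask)
    if boundary_trim > 0.0:
        keep = np.ones(len(frame), dtype=bool)
        for i, t in enumerate(frame["t"].to_numpy()):
            for iv in track.intervals:
                if iv.start <= t < iv.end:
                    keep[i] = (t - iv.start >= boundary_trim) and (
                        iv.end - t >= boundary_trim
                    )
                    break
        frame = frame[keep]
        if frame.empty:
            raise ValidationError("boundary_trim removed every timepoint")
    if activities is None:
        activities = sorted(frame["truth"].unique())
    rows = []
    for a in activities:
        sub = frame[frame["truth"] == a]
        if sub.empty:
            rows.append((a, float("nan"), 0))
        else:
            rows.append((a, float((sub["predicted"] == a).mean()), len(sub)))
    return pd.DataFrame(rows, columns=["activity", "sensitivity", "n"])


def prediction_distribution(
    cls: Classification,
    track: LabelTrack,
    activities: list[str] | tuple[str, ...] | None = None,
    _mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Row-normalized confusion proportions: rows are true activities,
    columns predicted labels; each observed row sums to 1."""
    frame = _aligned(cls, track, _mask)
    table = pd.crosstab(frame["truth"], frame["predicted"], normalize="index")
    if activities is not None:
        table = table.reindex(index=[a for a in activities if a in table.index])
        cols = [a for a in activities if a in table.columns] + [
            c for c in table.columns if c not in activities
        ]
        table = table[cols]
    table.index.name = "truth"
    table.columns.name = "predicted"
    return table


def setting_grid(
    results: dict[tuple[str, str, str], dict[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Average per-activity sensitivity across subjects for each setting.

    ``results`` maps (sensor_kind, metric, data_type) -> subject ->
    sensitivity table (as returned by :func:`sensitivity_table`).  Cells
    average, unweighted, over the subjects with data for the activity;
    ``n_subjects`` records how many that was.  Long format, one row per
    (setting, activity), ready for heatmap rendering.
    """
    rows = []
    for (sensor, metric, data_type), by_subject in results.items():
        acc: dict[str, list[float]] = {}
        for table in by_subject.values():
            for r in table.itertuples():
                if np.isfinite(r.sensitivity):
                    acc.setdefault(r.activity, []).append(r.sensitivity)
        for activity, values in acc.items():
            rows.append(
                (
                    sensor,
                    metric,
                    data_type,
                    activity,
                    float(np.mean(values)),
                    len(values),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sensor",
            "metric",
            "data_type",
            "activity",
            "mean_sensitivity",
            "n_subjects",
        ],
    )


def filtered_evaluation(
    cls: Classification,
    track: LabelTrack,
    excluded: np.ndarray,
    activities: list[str] | tuple[str, ...] | None = None,
) -> dict:
    """Sensitivity and prediction distribution over non-excluded timepoints.

    Returns ``{"sensitivity": frame, "distribution": frame,
    "n_excluded": int, "n_total": int}``.  Excluding everything is an error.
    """
    excluded = np.asarray(excluded, dtype=bool)
    if excluded.all():
        raise ValidationError("all timepoints excluded; nothing to evaluate")
    return {
        "sensitivity": sensitivity_table(cls, track, activities, _mask=excluded),
        "distribution": prediction_distribution(cls, track, activities, _mask=excluded),
        "n_excluded": int(excluded.sum()),
        "n_total": int(len(cls)),
    }


def plot_setting_grid(grid: pd.DataFrame, path) -> None:
    """Render a setting-by-activity sensitivity heatmap (darker = higher)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid.assign(
        setting=grid["sensor"].str[:4]
        + "/"
        + grid["metric"].str[:3]
        + "/"
        + grid["data_type"].str[:3]
    ).pivot_table(index="setting", columns="activity", values="mean_sensitivity")
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2, 0.5 * len(pivot) + 2))
    im = ax.imshow(pivot.to_numpy(), cmap="Greys", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    fig.colorbar(im, ax=ax, label="mean sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
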