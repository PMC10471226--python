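"""Minimal diagnostic plots: per-GO CV distributions by class and group."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


def plot_cv_by_group(
    go_cv: pd.DataFrame,
    path,
    *,
    group_col: str = "go_class",
    value_col: str = "cv",
    title: str | None = None,
) -> None:
    """Box plot with jittered per-GO points of CV by group.

    One dot per GO term, matching how the response-variance comparisons
    are read. Styling is intentionally plain.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if group_col not in go_cv.columns or value_col not in go_cv.columns:
        raise ValidationError(
            f"plot needs columns {group_col!r} and {value_col!r}"
        )
    groups = sorted(go_cv[group_col].dropna().unique())
    if not groups:
        raise ValidationError("nothing to plot: no groups")
    data = [go_cv.loc[go_cv[group_col] == g, value_col].dropna().to_numpy()
            for g in groups]

    rng = np.random.default_rng(0)  # jitter only; cosmetic
    fig, ax = plt.subplots(figsize=(1.6 + 1.2 * len(groups), 4.0))
    ax.boxplot(data, tick_labels=[str(g) for g in groups], showfliers=False)
    for i, values in enumerate(data, start=1):
        x = i + rng.uniform(-0.18, 0.18, size=values.size)
        ax.plot(x, values, "o", markersize=3, alpha=0.45)
    ax.set_ylabel(value_col)
    ax.set_xlabel(group_col)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
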