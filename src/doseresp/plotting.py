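"""Per-series dose-response plots: mean +/- SEM and the fitted curve."""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np

os.environ.setdefault("MPLBACKEND", "Agg")

__all__ = ["plot_fit", "save_record_plot"]


def plot_fit(results, ax=None, n_curve_points: int = 200, **kwargs):
    """Plot one fit: mean inhibition vs log10 concentration, SEM bars, curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    model = results.model
    x = np.log10(model.concentrations)
    y = model.response
    ax.errorbar(
        x,
        y,
        yerr=model.sem,
        fmt="o",
        color="black",
        capsize=3,
        label="mean response",
    )
    if results.converged:
        xs = np.linspace(x.min(), x.max(), n_curve_points)
        ax.plot(xs, results.predict(10.0**xs), color="tab:red", label="4PL fit")
    name = f"{model.sample_id} / {model.drug_id}".strip(" /")
    ax.set_title(name or "dose-response")
    ax.set_xlabel("log10 concentration (M)")
    ax.set_ylabel("inhibition (%)")
    ax.legend(frameon=False)
    return ax


def save_record_plot(record, directory) -> Path | None:
    """Save one batch record's plot as PNG; skipped when analysis failed early."""
    import matplotlib.pyplot as plt

    if record.fit is None:
        return None
    ax = plot_fit(record.fit)
    name = f"{record.series.sample_id}_{record.series.drug_id}.png".replace(os.sep, "-")
    path = Path(directory) / name
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
    return path
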