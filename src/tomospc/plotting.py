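"""Minimal X-chart rendering: points, CL/UCL/LCL, and the ±action band."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .control_charts import ControlLimits
from .qa_log_io import QASeries


def plot_xchart(
    series: QASeries,
    limits: ControlLimits,
    action_limit_mm: float | None = 2.0,
    path=None,
    title: str | None = None,
):
    """Render an individuals chart; writes to ``path`` if given, else returns
    the figure."""
    fig, ax = plt.subplots(figsize=(10, 4))
    x = range(series.n)
    ax.plot(x, series.values, ".-", lw=0.6, ms=3, color="0.3", label="offset")
    ax.axhline(limits.CL, color="k", lw=1.5, label="CL")
    ax.axhline(limits.UCL, color="tab:red", lw=1, ls="-", label="UCL/LCL")
    ax.axhline(limits.LCL, color="tab:red", lw=1, ls="-")
    if action_limit_mm is not None:
        ax.axhline(action_limit_mm, color="tab:blue", lw=1, ls="--", label="action limit")
        ax.axhline(-action_limit_mm, color="tab:blue", lw=1, ls="--")
    out = (series.values > limits.UCL) | (series.values < limits.LCL)
    if out.any():
        idx = [i for i, o in enumerate(out) if o]
        ax.plot(idx, series.values[out], "o", color="tab:red", ms=5, mfc="none")
    ax.set_xlabel("observation")
    ax.set_ylabel("offset (mm)")
    ax.set_title(title or f"{series.unit_id} {series.axis} individuals chart")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
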