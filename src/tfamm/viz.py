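"""A small plotting helper for scenario comparisons."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .burden import BurdenResult


def plot_scenario_totals(
    results: Mapping[str, BurdenResult],
    column: str = "dpp",
    ax: "plt.Axes | None" = None,
):
    """Bar chart of one total (dpp/yll/ypll/cost) across scenarios."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    labels = list(results)
    values = [results[k].total(column) for k in labels]
    ax.bar(labels, values, color="#4477aa")
    ax.set_ylabel({"dpp": "deaths prevented or postponed",
                   "yll": "years of life lost averted",
                   "ypll": "years of productive life lost averted",
                   "cost": "productivity savings"}.get(column, column))
    ax.set_xlabel("scenario")
    ax.figure.tight_layout()
    return ax
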