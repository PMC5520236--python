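"""Posterior-utility density plots and overlap diagnostics.

Plots of the posterior density of each dose's utility make dose
ambivalence visible: when two doses' densities largely occupy the same
space, the design cannot reliably choose between them, however
precisely the posterior integral is computed. The density data behind
every figure is also written as CSV, and a numeric *overlap
coefficient* (integral of the pointwise minimum of two densities, 1 =
identical, 0 = disjoint) summarises how entangled two doses are.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import EffToxResults

__all__ = ["utility_density_frame", "density_overlap", "plot_posterior_utility"]

_GRID_SIZE = 512


def _kde(values: np.ndarray, weights: np.ndarray) -> gaussian_kde:
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("need at least two distinct utility draws for a density")
    return gaussian_kde(values, weights=weights)


def _common_grid(results: EffToxResults, doses: Sequence[int]) -> np.ndarray:
    draws = [results.utility_draws(d)[0] for d in doses]
    lo = min(float(np.min(d)) for d in draws)
    hi = max(float(np.max(d)) for d in draws)
    pad = 0.1 * (hi - lo if hi > lo else 1.0)
    return np.linspace(lo - pad, hi + pad, _GRID_SIZE)


def utility_density_frame(results: EffToxResults, doses: Sequence[int]) -> pd.DataFrame:
    """Smoothed posterior utility densities on a shared grid.

    Returns a long-format frame with columns ``utility``, ``density``,
    ``dose_level``.
    """
    grid = _common_grid(results, doses)
    parts = []
    for d in doses:
        values, weights = results.utility_draws(d)
        dens = _kde(values, weights)(grid)
        parts.append(pd.DataFrame({"utility": grid, "density": dens, "dose_level": d}))
    return pd.concat(parts, ignore_index=True)


def density_overlap(results: EffToxResults, dose_a: int, dose_b: int) -> float:
    """Overlap coefficient of two doses' posterior utility densities."""
    grid = _common_grid(results, [dose_a, dose_b])
    da = _kde(*results.utility_draws(dose_a))(grid)
    db = _kde(*results.utility_draws(dose_b))(grid)
    return float(np.trapezoid(np.minimum(da, db), grid))


def plot_posterior_utility(
    results: EffToxResults,
    doses: Sequence[int],
    figure_path: str | Path,
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write a posterior-utility density figure (and its data as CSV).

    Returns the density frame that was plotted.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = utility_density_frame(results, doses)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for d in doses:
        sub = frame[frame["dose_level"] == d]
        ax.plot(sub["utility"], sub["density"], label=f"dose {d}")
        ax.fill_between(sub["utility"], sub["density"], alpha=0.2)
    ax.set_xlabel("utility")
    ax.set_ylabel("posterior density")
    ax.set_title(f"Posterior utility after {results.model.n_patients} patients")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    return frame
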