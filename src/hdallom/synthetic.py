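"""Synthetic forest-plot generator.

Emulates the statistical structure of tropical inventory plots that the
pipeline assumes: reverse-J (exponential-tail) diameter distributions
of stems >= 10 cm, plot-to-plot variation in the true height-diameter
relationship (drawn from both asymptotic families so form-comparison
experiments are not rigged), multiplicative log-normal height
measurement noise calibrated so residual prediction error is a few
metres on typical stands, realistic wood densities, and a small rate
of stem defects (broken / leaning / fallen stems, implausible heights)
to exercise the inclusion filters.

The per-plot true allometry is returned in a separate truth manifest so
pipeline code cannot accidentally condition on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hdallom.hd_models import _mm, _weibull
from hdallom.plot_data import PlotData, Tree

_MIN_HEIGHT_M = 1.5  # floor on observed heights after noise


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a stand of 200-600 stems >= 10 cm diameter with
    an exponential diameter tail (mean excess 12 cm, truncated at
    250 cm), a 50:50 mix of Weibull and Michaelis-Menten true
    allometries with plot-specific parameters, log-normal height noise
    of sigma = 0.13 (roughly 13% of height, i.e. ~4 m on tall stands),
    truncated-normal wood densities, and 1% defective stems.
    """

    n_plots: int = 30
    trees_per_plot: tuple[int, int] = (200, 600)
    diameter_tail_mean: float = 12.0  # cm above the 10 cm census threshold
    diameter_max: float = 250.0  # cm, upper truncation
    p_weibull: float = 0.5  # probability the true allometry is Weibull
    weibull_a_range: tuple[float, float] = (25.0, 50.0)
    weibull_b_range: tuple[float, float] = (0.02, 0.08)
    weibull_c_range: tuple[float, float] = (0.7, 1.1)
    mm_a_range: tuple[float, float] = (30.0, 60.0)
    mm_b_range: tuple[float, float] = (15.0, 40.0)
    noise_sigma_log: float = 0.13
    density_mean: float = 0.60  # g/cm^3
    density_sd: float = 0.10
    density_bounds: tuple[float, float] = (0.25, 0.95)
    defect_rate: float = 0.01
    E_range: tuple[float, float] = (-0.1, 0.1)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.trees_per_plot[0] < 150:
            raise ValueError("plots must allow >= 150 trees")
        if not 0.0 <= self.p_weibull <= 1.0:
            raise ValueError("p_weibull must lie in [0, 1]")
        if self.noise_sigma_log < 0 or self.defect_rate < 0 or self.defect_rate > 1:
            raise ValueError("invalid noise or defect settings")
        for lo, hi in (
            self.trees_per_plot,
            self.weibull_a_range,
            self.weibull_b_range,
            self.weibull_c_range,
            self.mm_a_range,
            self.mm_b_range,
            self.density_bounds,
            self.E_range,
        ):
            if lo > hi:
                raise ValueError("range bounds must be ordered")


def _truncated(draw, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample a vectorised draw into [lo, hi]."""
    out = draw(rng)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = draw(rng)[bad]
        bad = (out < lo) | (out > hi)
    return out


def _draw_truth(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    if rng.random() < config.p_weibull:
        return {
            "form": "weibull",
            "a": rng.uniform(*config.weibull_a_range),
            "b": rng.uniform(*config.weibull_b_range),
            "c": rng.uniform(*config.weibull_c_range),
        }
    return {
        "form": "michaelis_menten",
        "a": rng.uniform(*config.mm_a_range),
        "b": rng.uniform(*config.mm_b_range),
    }


def true_heights(truth: dict, diameters: np.ndarray) -> np.ndarray:
    """Evaluate a truth record's allometry at the given diameters."""
    d = np.asarray(diameters, float)
    if truth["form"] == "weibull":
        return _weibull(d, truth["a"], truth["b"], truth["c"])
    return _mm(d, truth["a"], truth["b"])


def generate_plot(
    config: GeneratorConfig, plot_index: int, seed
) -> tuple[PlotData, dict]:
    """Generate one plot and its truth record, deterministically.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    The truth record carries the plot's true allometry form and
    parameters for recovery tests; it is not stored on the plot.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(config.trees_per_plot[0], config.trees_per_plot[1] + 1))
    d = 10.0 + _truncated(
        lambda r: r.exponential(config.diameter_tail_mean, n),
        0.0,
        config.diameter_max - 10.0,
        rng,
    )
    truth = _draw_truth(config, rng)
    h_true = true_heights(truth, d)
    eps = rng.normal(0.0, config.noise_sigma_log, n)
    h_obs = np.maximum(h_true * np.exp(eps), _MIN_HEIGHT_M)
    rho = _truncated(
        lambda r: r.normal(config.density_mean, config.density_sd, n),
        config.density_bounds[0],
        config.density_bounds[1],
        rng,
    )
    defect = np.zeros(n, dtype=int)  # 0 none, 1 broken, 2 leaning, 3 fallen, 4 bad height
    n_def = rng.binomial(n, config.defect_rate)
    if n_def:
        which = rng.choice(n, size=n_def, replace=False)
        defect[which] = rng.integers(1, 5, size=n_def)
    E = float(rng.uniform(*config.E_range))

    plot_id = f"plot{plot_index:03d}"
    trees = []
    for i in range(n):
        height = float(h_obs[i])
        lean = 0.0
        if defect[i] == 2:
            lean = float(rng.uniform(10.0, 45.0))
        elif defect[i] == 4:
            height = float(rng.uniform(90.0, 120.0))
        trees.append(
            Tree(
                tree_id=f"{plot_id}-t{i:04d}",
                diameter=float(d[i]),
                height=height,
                height_method="clinometer",
                broken=defect[i] == 1,
                lean_pct=lean,
                fallen=defect[i] == 3,
                wood_density=float(rho[i]),
            )
        )
    plot = PlotData(plot_id=plot_id, trees=trees, E=E)
    record = {"plot_id": plot_id, **truth}
    return plot, record


def generate_dataset(config: GeneratorConfig) -> tuple[list[PlotData], pd.DataFrame]:
    """Generate the full dataset plus a truth manifest.

    Per-plot seeds derive from the master seed, so any plot can be
    regenerated in isolation.  The manifest (one row per plot: true
    form and parameters) is returned separately from the plots.
    """
    plots, records = [], []
    for i in range(config.n_plots):
        ss = np.random.SeedSequence(config.master_seed, spawn_key=(i,))
        plot, rec = generate_plot(config, i, ss)
        plots.append(plot)
        records.append(rec)
    manifest = pd.DataFrame(records, columns=["plot_id", "form", "a", "b", "c"])
    return plots, manifest
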