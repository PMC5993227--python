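"""Tree-level above-ground biomass and stand-level AGB prediction error.

AGB follows the pan-tropical diameter-height-density allometry

    AGB (kg) = 0.0673 * (rho * D^2 * H)^0.976

with wood density rho in g/cm^3, diameter D in cm and height H in m.
The height component of stand biomass error is isolated by comparing
summed AGB computed with model-predicted heights against summed AGB
computed with the observed heights of the same trees.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from hdallom.plot_data import Tree

DEFAULT_WOOD_DENSITY = 0.6  # g/cm^3, used when no tree or plot value exists

_AGB_COEF = 0.0673
_AGB_EXP = 0.976


def estimate_agb(wood_density, diameter, height):
    """Tree AGB in kg: 0.0673 * (rho * D^2 * H)^0.976.

    Units follow the source allometry: rho g/cm^3, D cm, H m.
    Strictly increasing in each argument; inputs must be positive.
    """
    rho = np.asarray(wood_density, float)
    d = np.asarray(diameter, float)
    h = np.asarray(height, float)
    if np.any(rho <= 0) or np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("wood density, diameter and height must all be positive")
    out = _AGB_COEF * (rho * d**2 * h) ** _AGB_EXP
    return float(out) if out.ndim == 0 else out


def resolve_densities(
    trees: Sequence[Tree], default_density: float = DEFAULT_WOOD_DENSITY
) -> np.ndarray:
    """Per-tree wood density: tree value, else plot mean, else default."""
    vals = np.array(
        [t.wood_density if t.wood_density is not None else np.nan for t in trees]
    )
    if np.all(np.isnan(vals)):
        return np.full(len(trees), default_density)
    plot_mean = float(np.nanmean(vals))
    return np.where(np.isnan(vals), plot_mean, vals)


def stand_agb_error(
    predictor: Callable[[np.ndarray], np.ndarray],
    test_trees: Sequence[Tree],
    default_density: float = DEFAULT_WOOD_DENSITY,
) -> float:
    """Stand-level AGB error (kg) from using modelled heights.

    Sum of per-tree AGB with predicted heights minus the sum with
    observed heights, over the given test trees.  Positive values mean
    the height model overestimates stand biomass relative to
    observed-height biomass.  Additive over disjoint test subsets.
    """
    if len(test_trees) == 0:
        raise ValueError("empty test set")
    d = np.array([t.diameter for t in test_trees], float)
    h_obs = np.array([t.height for t in test_trees], float)
    if np.any(np.isnan(h_obs)):
        raise ValueError("all test trees must have an observed height")
    rho = resolve_densities(test_trees, default_density)
    h_pred = np.asarray(predictor(d), float)
    return float(np.sum(estimate_agb(rho, d, h_pred)) - np.sum(estimate_agb(rho, d, h_obs)))
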