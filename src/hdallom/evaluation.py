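"""Cross-validation engine for height-diameter model and sampling
strategy comparison.

Two experiments are run over a set of plots:

* the size experiment trains all five local model variants on random
  subsets of 10..100 trees and scores them - together with the regional
  and climate-based references - on an independent 50-tree test set,
  for many iterations;
* the strategy experiment trains the two asymptotic forms on samples
  drawn by each field strategy and scores them on every height-measured
  tree in the plot (a fixed test pool, so strategies that deplete parts
  of the diameter distribution are not advantaged by an easier test
  set).

Summaries are the probability of each competitor being the best in a
cell (plot x size x iteration) and cluster-bootstrap confidence
intervals for paired error differences, resampling plots as clusters.
All randomness derives from a single master seed via seed sequences,
so runs are reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hdallom.agb import estimate_agb, resolve_densities
from hdallom.hd_models import (
    LOCAL_FORMS,
    fit_hd_model,
    predict_height,
    predict_height_climate,
    predict_height_regional,
)
from hdallom.plot_data import PlotData
from hdallom.sampling import STRATEGY_NAMES, StrategySpec, draw_sample

logger = logging.getLogger(__name__)

DEFAULT_SIZES = tuple(range(10, 101, 10))
DEFAULT_TEST_SIZE = 50
REFERENCE_MODELS = ("regional", "climate")
STRATEGY_MODELS = ("weibull", "michaelis_menten")

RECORD_COLUMNS = [
    "plot_id",
    "n_train",
    "iteration",
    "model",
    "strategy",
    "rmse",
    "agb_error",
    "converged",
]


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-squared height prediction error in metres."""
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def split_train_test(
    trees, n_train: int, seed, test_size: int = DEFAULT_TEST_SIZE
):
    """Disjoint random train/test subsets, deterministic given seed.

    ``trees`` may be a sequence of trees (subsets of it are returned)
    or an integer count (index arrays are returned).  Both the
    training and test draws are fresh for every seed.
    """
    n_total = trees if isinstance(trees, (int, np.integer)) else len(trees)
    if n_total < n_train + test_size:
        raise ValueError(
            f"need >= {n_train + test_size} trees for split, have {n_total}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    tr = np.sort(perm[:n_train])
    te = np.sort(perm[n_train : n_train + test_size])
    if isinstance(trees, (int, np.integer)):
        return tr, te
    return [trees[i] for i in tr], [trees[i] for i in te]


def _cell_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass
class _PlotArrays:
    """Vectorised view of a plot's height-measured trees."""

    plot_id: str
    d: np.ndarray
    h: np.ndarray
    rho: np.ndarray
    agb_obs: np.ndarray
    E: float

    @classmethod
    def from_plot(cls, plot: PlotData, default_density: float) -> "_PlotArrays":
        trees = plot.height_measured_trees()
        d = np.array([t.diameter for t in trees], float)
        h = np.array([t.height for t in trees], float)
        rho = resolve_densities(trees, default_density)
        return cls(
            plot_id=plot.plot_id,
            d=d,
            h=h,
            rho=rho,
            agb_obs=estimate_agb(rho, d, h),
            E=plot.E if plot.E is not None else 0.0,
        )


def pooled_regional_params(
    plots: Iterable[PlotData], default_density: float = 0.6
) -> tuple[float, float, float]:
    """Weibull parameters fitted to all plots pooled.

    Used as the regional reference when no published regional
    parameters are supplied: a coarse-scale allometry that ignores
    plot-to-plot variation, exactly the role a biogeographical
    reference plays against local fits.
    """
    d = np.concatenate([[t.diameter for t in p.height_measured_trees()] for p in plots])
    h = np.concatenate([[t.height for t in p.height_measured_trees()] for p in plots])
    fit = fit_hd_model("weibull", (d, h))
    if not fit.converged:
        raise RuntimeError("pooled regional Weibull fit failed to converge")
    return (fit.params["a"], fit.params["b"], fit.params["c"])


def _eval_on(
    arr: _PlotArrays, idx: np.ndarray, h_pred: np.ndarray
) -> tuple[float, float]:
    """(rmse, stand AGB error) of predicted heights on trees ``idx``."""
    err = float(np.sqrt(np.mean((h_pred - arr.h[idx]) ** 2)))
    agb_pred = estimate_agb(arr.rho[idx], arr.d[idx], h_pred)
    return err, float(np.sum(agb_pred) - np.sum(arr.agb_obs[idx]))


def run_size_experiment(
    plots: Sequence[PlotData],
    sizes: Sequence[int] = DEFAULT_SIZES,
    iterations: int = 100,
    seed: int = 0,
    models: Sequence[str] = LOCAL_FORMS,
    test_size: int = DEFAULT_TEST_SIZE,
    regional_params: tuple[float, float, float] | None = None,
    include_references: bool = True,
    bias_correction: bool = True,
    default_density: float = 0.6,
) -> pd.DataFrame:
    """Random-sample cross-validation of local models against references.

    For every plot x training size x iteration: draw disjoint random
    train and test sets, fit each local model form on the training
    trees, and score every competitor (plus the fixed regional and
    climate references) on the same test trees.  Returns a tidy frame
    of one row per (cell x model) with height RMSE and stand-level AGB
    error; non-convergent fits carry ``converged=False`` and NaN
    scores.
    """
    plots = list(plots)
    if include_references and regional_params is None:
        regional_params = pooled_regional_params(plots, default_density)
    rows: list[tuple] = []
    for p_idx, plot in enumerate(plots):
        arr = _PlotArrays.from_plot(plot, default_density)
        n_total = arr.d.size
        ref_pred = {}
        if include_references:
            ref_pred["regional"] = predict_height_regional(arr.d, regional_params)
            ref_pred["climate"] = predict_height_climate(arr.d, arr.E)
        for size in sizes:
            for it in range(1, iterations + 1):
                split_seed = np.random.SeedSequence(seed, spawn_key=(p_idx, size, it))
                train, test = split_train_test(n_total, size, split_seed, test_size)
                d_tr, h_tr = arr.d[train], arr.h[train]
                for form in models:
                    fit = fit_hd_model(form, (d_tr, h_tr), bias_correction=bias_correction)
                    if fit.converged:
                        h_pred = predict_height(fit, arr.d[test])
                        err, agb_err = _eval_on(arr, test, h_pred)
                        rows.append(
                            (plot.plot_id, size, it, form, None, err, agb_err, True)
                        )
                    else:
                        rows.append(
                            (plot.plot_id, size, it, form, None, np.nan, np.nan, False)
                        )
                for ref in REFERENCE_MODELS if include_references else ():
                    err, agb_err = _eval_on(arr, test, ref_pred[ref][test])
                    rows.append(
                        (plot.plot_id, size, it, ref, None, err, agb_err, True)
                    )
        logger.info("size experiment: plot %s done (%d trees)", plot.plot_id, n_total)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_strategy_experiment(
    plots: Sequence[PlotData],
    strategies: Sequence[str] = STRATEGY_NAMES,
    sizes: Sequence[int] = DEFAULT_SIZES,
    iterations: int = 100,
    seed: int = 0,
    default_density: float = 0.6,
) -> pd.DataFrame:
    """Compare field sampling strategies for height measurement.

    For every plot x strategy x size x iteration, a training sample is
    drawn by the strategy and the two asymptotic forms (Weibull,
    Michaelis-Menten) are fitted and scored on all height-measured
    trees in the plot.  Deterministic strategies (Big; and the
    deterministic part of BigRand/BigStrat) are re-drawn per iteration
    but yield identical samples, hence identical scores, by
    construction.
    """
    plots = list(plots)
    rows: list[tuple] = []
    for p_idx, plot in enumerate(plots):
        trees = plot.height_measured_trees()
        arr = _PlotArrays.from_plot(plot, default_density)
        all_idx = np.arange(arr.d.size)
        for s_idx, strat_name in enumerate(strategies):
            for size in sizes:
                if strat_name in ("BigRand", "BigStrat") and size < 10:
                    continue
                big_cache: dict | None = None
                for it in range(1, iterations + 1):
                    if strat_name == "Big" and big_cache is not None:
                        for form, err, agb_err, conv in big_cache["scores"]:
                            rows.append(
                                (plot.plot_id, size, it, form, strat_name, err, agb_err, conv)
                            )
                        continue
                    cell_seed = int(
                        np.random.SeedSequence(
                            seed, spawn_key=(p_idx, s_idx, size, it)
                        ).generate_state(1)[0]
                    )
                    spec = StrategySpec(name=strat_name, n=size, seed=cell_seed)
                    sample = draw_sample(spec, trees)
                    d_tr = np.array([t.diameter for t in sample], float)
                    h_tr = np.array([t.height for t in sample], float)
                    scores = []
                    for form in STRATEGY_MODELS:
                        fit = fit_hd_model(form, (d_tr, h_tr))
                        if fit.converged:
                            h_pred = predict_height(fit, arr.d)
                            err, agb_err = _eval_on(arr, all_idx, h_pred)
                            scores.append((form, err, agb_err, True))
                        else:
                            scores.append((form, np.nan, np.nan, False))
                    for form, err, agb_err, conv in scores:
                        rows.append(
                            (plot.plot_id, size, it, form, strat_name, err, agb_err, conv)
                        )
                    if strat_name == "Big":
                        big_cache = {"scores": scores}
        logger.info("strategy experiment: plot %s done", plot.plot_id)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass
class TallyCurve:
    """Probability of one competitor being best, as a function of n."""

    competitor: str
    n_grid: np.ndarray
    probability_best: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    smoothed: np.ndarray | None = None
    smoothed_grid: np.ndarray | None = None


def _cell_scores(
    records: pd.DataFrame, group: str, criterion: str
) -> pd.DataFrame:
    """Long frame of one score per (plot, n_train, iteration, competitor)."""
    df = records.copy()
    value = df["rmse"] if criterion == "rmse" else df["agb_error"].abs()
    df["score"] = np.where(df["converged"], value, np.inf)
    df["score"] = df["score"].fillna(np.inf)
    if group == "model":
        df["competitor"] = df["model"]
    elif group == "strategy":
        if df["strategy"].isna().all():
            raise ValueError("records carry no strategy labels")
        df["competitor"] = df["strategy"]
        # a strategy's cell score is the best of its fitted forms
        df = (
            df.groupby(["plot_id", "n_train", "iteration", "competitor"], sort=False)[
                "score"
            ]
            .min()
            .reset_index()
        )
    else:
        raise ValueError(f"group must be 'model' or 'strategy', got {group!r}")
    return df[["plot_id", "n_train", "iteration", "competitor", "score"]]


def best_tally(
    records: pd.DataFrame,
    group: str = "model",
    criterion: str = "rmse",
    n_boot: int = 200,
    seed: int = 0,
    smooth: bool = True,
) -> list[TallyCurve]:
    """Per-sample-size probability of each competitor being the best.

    The winner of a cell (plot x size x iteration) is the competitor
    with the smallest criterion value; non-converged fits can never
    win, and exact ties are broken uniformly at random (so tied
    competitors split the cell's probability in expectation).
    Confidence bounds come from a cluster bootstrap resampling plots.
    A smoothed curve over n (penalised regression spline) is attached
    when at least four sizes are present.
    """
    from hdallom.thresholds import smooth_curve  # local import to avoid cycle

    scores = _cell_scores(records, group, criterion)
    wide = scores.pivot_table(
        index=["plot_id", "n_train", "iteration"],
        columns="competitor",
        values="score",
        aggfunc="first",
        sort=False,
    )
    competitors = list(wide.columns)
    vals = wide.to_numpy()
    all_failed = ~np.isfinite(vals).any(axis=1)
    if all_failed.any():
        logger.warning("%d cells had no converged competitor; excluded", all_failed.sum())
        wide = wide[~all_failed]
        vals = vals[~all_failed]
    idx = wide.index.to_frame(index=False)
    finite_min = np.nanmin(np.where(np.isfinite(vals), vals, np.inf), axis=1)
    winners = np.empty(vals.shape[0], dtype=int)
    for i in range(vals.shape[0]):
        tied = np.flatnonzero(vals[i] == finite_min[i])
        if tied.size == 1:
            winners[i] = tied[0]
        else:
            winners[i] = tied[_cell_rng(seed, 1, i).integers(tied.size)]
    cell = pd.DataFrame(
        {
            "plot_id": idx["plot_id"],
            "n_train": idx["n_train"],
            "winner": [competitors[w] for w in winners],
        }
    )
    sizes = np.sort(cell["n_train"].unique())
    plot_ids = cell["plot_id"].unique()
    # wins[c, s] summed per plot for fast bootstrap
    per_plot_wins = {
        c: np.zeros((len(plot_ids), len(sizes))) for c in competitors
    }
    per_plot_cells = np.zeros((len(plot_ids), len(sizes)))
    p_pos = {p: i for i, p in enumerate(plot_ids)}
    s_pos = {s: i for i, s in enumerate(sizes)}
    for (p, s), sub in cell.groupby(["plot_id", "n_train"], sort=False):
        per_plot_cells[p_pos[p], s_pos[s]] = len(sub)
        for c, k in sub["winner"].value_counts().items():
            per_plot_wins[c][p_pos[p], s_pos[s]] = k

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    boot_idx = rng.integers(len(plot_ids), size=(n_boot, len(plot_ids)))
    curves = []
    for c in competitors:
        wins = per_plot_wins[c]
        prob = wins.sum(axis=0) / per_plot_cells.sum(axis=0)
        boots = np.empty((n_boot, len(sizes)))
        for b in range(n_boot):
            sel = boot_idx[b]
            denom = per_plot_cells[sel].sum(axis=0)
            boots[b] = wins[sel].sum(axis=0) / np.maximum(denom, 1)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        smoothed = smoothed_grid = None
        if smooth and len(sizes) >= 4:
            trend = smooth_curve(sizes, prob)
            smoothed, smoothed_grid = trend.values, trend.n_grid
        curves.append(
            TallyCurve(
                competitor=str(c),
                n_grid=sizes,
                probability_best=prob,
                ci_low=lo,
                ci_high=hi,
                smoothed=smoothed,
                smoothed_grid=smoothed_grid,
            )
        )
    return curves


def mean_difference_ci(
    records: pd.DataFrame,
    model: str,
    reference: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean paired RMSE difference (model minus reference) with a 95%
    plot-cluster bootstrap interval.

    Cell-wise differences are averaged within each plot, then across
    plots; the interval resamples plots with replacement.  Negative
    values mean the local model predicts heights more accurately than
    the reference.  Cells where the model did not converge are
    dropped from the pairing.
    """
    wide = records.pivot_table(
        index=["plot_id", "n_train", "iteration"],
        columns="model",
        values="rmse",
        aggfunc="first",
    )
    for name in (model, reference):
        if name not in wide.columns:
            raise ValueError(f"no records for competitor {name!r}")
    diff = (wide[model] - wide[reference]).dropna()
    if diff.empty:
        raise ValueError("no paired cells between model and reference")
    per_plot = diff.groupby(level="plot_id").mean()
    mean = float(per_plot.mean())
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    vals = per_plot.to_numpy()
    boots = vals[rng.integers(vals.size, size=(n_boot, vals.size))].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return mean, float(lo), float(hi)
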