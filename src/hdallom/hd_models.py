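"""Height-diameter model forms, fitting, and reference allometries.

Three local model forms relate total height H (m) to trunk diameter
D (cm):

* Weibull:           H = a * (1 - exp(-b * D**c))
* Michaelis-Menten:  H = a * D / (b + D)
* log-log power law: ln H = a + b * ln D

The Weibull and Michaelis-Menten parameter ``a`` is the asymptotic
maximum height.  Both asymptotic forms may be fitted with case weights
proportional to stem volume (D^2 * H), which emphasises the large trees
that dominate stand biomass.  Two reference allometries serve as the
no-local-data baseline: a regional Weibull with fixed published
parameters, and the pan-tropical climate-based model driven by the
bioclimatic stress scalar E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from hdallom.plot_data import Tree

LOCAL_FORMS = ("weibull", "michaelis_menten", "loglog", "weibull_weighted", "mm_weighted")

_MIN_POINTS = {"weibull": 3, "michaelis_menten": 2, "loglog": 2}

_MAX_RESTARTS = 5


class NotConvergedError(RuntimeError):
    """Prediction was requested from a fit that did not converge."""


@dataclass
class HDModelFit:
    """A fitted height-diameter model.

    ``params`` holds (a, b, c) for weibull, (a, b) for michaelis_menten
    and (a, b) on the ln scale for loglog.  ``residual_se_log`` is the
    ln-scale residual standard error (loglog only), used for the
    back-transformation bias correction factor exp(s^2 / 2).
    ``converged`` is a recorded outcome, never an exception: failed
    nonlinear fits are tallied as failures downstream.
    """

    form: str
    params: dict[str, float]
    converged: bool
    n_train: int
    sse: float = float("nan")
    residual_se_log: float = 0.0
    bias_correction: bool = True
    weighted: bool = False

    @property
    def base_form(self) -> str:
        return {"weibull_weighted": "weibull", "mm_weighted": "michaelis_menten"}.get(
            self.form, self.form
        )

    def to_record(self) -> dict:
        """Serialisable record of the fit (for manifests and the CLI)."""
        return {
            "form": self.form,
            "params": dict(self.params),
            "converged": self.converged,
            "n_train": self.n_train,
            "sse": self.sse,
            "residual_se_log": self.residual_se_log,
            "bias_correction": self.bias_correction,
        }


@dataclass
class ReferenceModel:
    """A no-local-data reference allometry.

    kind='regional_weibull' carries published (a, b, c) for a
    biogeographical region; kind='climate' carries the plot's
    bioclimatic scalar E.
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def predict(self, diameter) -> np.ndarray | float:
        if self.kind == "regional_weibull":
            return predict_height_regional(
                diameter, (self.params["a"], self.params["b"], self.params["c"])
            )
        if self.kind == "climate":
            return predict_height_climate(diameter, self.params["E"])
        raise ValueError(f"unknown reference kind {self.kind!r}")


def _weibull(d, a, b, c):
    # optimiser trial steps can push b or c into overflow territory;
    # inf/nan trial residuals are handled by the restart logic
    with np.errstate(over="ignore", invalid="ignore"):
        return a * (1.0 - np.exp(-b * d**c))


def _mm(d, a, b):
    return a * d / (b + d)


def _extract_dh(trees: Iterable[Tree] | tuple) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a collection of Tree or a (D, H) array pair."""
    if isinstance(trees, tuple) and len(trees) == 2:
        return np.asarray(trees[0], float), np.asarray(trees[1], float)
    d = np.array([t.diameter for t in trees], float)
    h = np.array([t.height for t in trees], float)
    if np.any(np.isnan(h)):
        raise ValueError("all training trees must have a height")
    return d, h


def _volume_weights(d: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Case weights proportional to stem volume D^2*H, normalised to mean 1."""
    w = d**2 * h
    return w / w.mean()


def _fit_nonlinear(
    form: str, d: np.ndarray, h: np.ndarray, weights: np.ndarray | None
) -> tuple[dict[str, float], bool, float]:
    sqw = np.sqrt(weights) if weights is not None else np.ones_like(d)

    if form == "weibull":
        def model(p):
            return _weibull(d, *p)

        def fun(p):
            return sqw * (model(p) - h)

        def jac(p):
            a, b, c = p
            e = np.exp(-b * d**c)
            J = np.empty((d.size, 3))
            J[:, 0] = 1.0 - e
            J[:, 1] = a * d**c * e
            J[:, 2] = a * b * d**c * np.log(d) * e
            return sqw[:, None] * J

        x0 = np.array([1.1 * h.max(), 0.03, 1.0])
        bounds_ok = lambda p: p[0] > 0 and p[1] > 0
    elif form == "michaelis_menten":
        def model(p):
            return _mm(d, *p)

        def fun(p):
            return sqw * (model(p) - h)

        def jac(p):
            a, b = p
            J = np.empty((d.size, 2))
            J[:, 0] = d / (b + d)
            J[:, 1] = -a * d / (b + d) ** 2
            return sqw[:, None] * J

        # Lineweaver-Burk linearisation seed: 1/H = 1/a + (b/a)(1/D)
        A = np.vstack([np.ones_like(d), 1.0 / d]).T
        coef, *_ = np.linalg.lstsq(A, 1.0 / h, rcond=None)
        if coef[0] > 0 and coef[1] > 0:
            x0 = np.array([1.0 / coef[0], coef[1] / coef[0]])
        else:
            x0 = np.array([1.2 * h.max(), float(np.median(d))])
        bounds_ok = lambda p: p[0] > 0 and p[1] > 0
    else:  # pragma: no cover - guarded by caller
        raise ValueError(form)

    best_p, best_sse, ok = None, np.inf, False
    rng = np.random.default_rng(12345)
    for attempt in range(1 + _MAX_RESTARTS):
        start = x0 if attempt == 0 else x0 * rng.lognormal(0.0, 0.3, size=x0.size)
        try:
            # near-power-law samples walk the a->inf ridge slowly; give
            # LM room before declaring failure
            res = optimize.least_squares(
                fun, start, jac=jac, method="lm", max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and np.all(np.isfinite(res.x)) and bounds_ok(res.x):
            sse = float(np.sum((model(res.x) - h) ** 2))
            wsse = float(2.0 * res.cost)
            if wsse < best_sse - 1e-12 or best_p is None:
                best_p, best_sse, ok = res.x, wsse, True
            if attempt == 0:
                break  # default start converged; no restarts needed
    if not ok:
        names = ("a", "b", "c")[: x0.size]
        return dict(zip(names, x0)), False, float("nan")
    names = ("a", "b", "c")[: best_p.size]
    sse = float(np.sum((model(best_p) - h) ** 2))
    return dict(zip(names, best_p)), True, sse


def fit_hd_model(
    form: str,
    trees: Iterable[Tree] | tuple,
    weighted: bool = False,
    bias_correction: bool = True,
) -> HDModelFit:
    """Fit a height-diameter model to height-measured trees.

    Parameters
    ----------
    form : {'weibull', 'michaelis_menten', 'loglog'}
        Model form.  The aliases 'weibull_weighted' and 'mm_weighted'
        select the volume-weighted variants directly.
    trees
        Trees with heights, or a ``(diameters, heights)`` array pair.
    weighted : bool
        Fit with case weights proportional to stem volume (D^2 * H,
        normalised to mean 1).  Only valid for the nonlinear forms.
    bias_correction : bool
        For loglog predictions, apply the back-transformation
        correction factor exp(residual_se_log^2 / 2).

    The nonlinear forms use Levenberg-Marquardt with analytic
    Jacobians and jittered restarts; an optimiser failure is recorded
    as ``converged=False``, never raised.  The loglog form is ordinary
    least squares on (ln D, ln H).
    """
    if form == "weibull_weighted":
        form, weighted = "weibull", True
    elif form == "mm_weighted":
        form, weighted = "michaelis_menten", True
    if form not in _MIN_POINTS:
        raise ValueError(f"unknown model form {form!r}")
    d, h = _extract_dh(trees)
    if d.size < _MIN_POINTS[form]:
        raise ValueError(
            f"{form} fit needs >= {_MIN_POINTS[form]} trees, got {d.size}"
        )
    if weighted and form == "loglog":
        raise ValueError("volume weighting applies only to the nonlinear forms")

    if form == "loglog":
        if np.any(d <= 0) or np.any(h <= 0):
            raise ValueError("loglog requires strictly positive D and H")
        ld, lh = np.log(d), np.log(h)
        X = np.vstack([np.ones_like(ld), ld]).T
        coef, *_ = np.linalg.lstsq(X, lh, rcond=None)
        resid = lh - X @ coef
        dof = max(d.size - 2, 1)
        se_log = float(np.sqrt(np.sum(resid**2) / dof))
        params = {"a": float(coef[0]), "b": float(coef[1])}
        fit = HDModelFit(
            form="loglog",
            params=params,
            converged=True,
            n_train=int(d.size),
            residual_se_log=se_log,
            bias_correction=bias_correction,
        )
        pred = predict_height(fit, d)
        fit.sse = float(np.sum((pred - h) ** 2))
        return fit

    weights = _volume_weights(d, h) if weighted else None
    params, converged, sse = _fit_nonlinear(form, d, h, weights)
    name = {"weibull": "weibull", "michaelis_menten": "michaelis_menten"}[form]
    if weighted:
        name = {"weibull": "weibull_weighted", "michaelis_menten": "mm_weighted"}[form]
    return HDModelFit(
        form=name,
        params=params,
        converged=converged,
        n_train=int(d.size),
        sse=sse,
        weighted=weighted,
    )


def predict_height(fit: HDModelFit, diameter) -> np.ndarray | float:
    """Predict height (m) from diameter (cm) with a fitted model."""
    if not fit.converged:
        raise NotConvergedError(f"{fit.form} fit did not converge")
    d = np.asarray(diameter, float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    base = fit.base_form
    if base == "weibull":
        out = _weibull(d, fit.params["a"], fit.params["b"], fit.params["c"])
    elif base == "michaelis_menten":
        out = _mm(d, fit.params["a"], fit.params["b"])
    elif base == "loglog":
        cf = np.exp(fit.residual_se_log**2 / 2.0) if fit.bias_correction else 1.0
        out = np.exp(fit.params["a"] + fit.params["b"] * np.log(d)) * cf
    else:  # pragma: no cover
        raise ValueError(fit.form)
    return float(out) if np.isscalar(diameter) else out


def compute_E(T: float, C: float, P: float) -> float:
    """Bioclimatic stress scalar E from temperature seasonality T,
    climatological water deficit C and precipitation seasonality P:

        E = (0.178 * T - 0.938 * C - 6.61 * P) x 10^-3
    """
    return (0.178 * T - 0.938 * C - 6.61 * P) * 1e-3


def predict_height_climate(diameter, E: float) -> np.ndarray | float:
    """Pan-tropical climate-based height model:

        ln H = 0.893 - E + 0.760 ln D - 0.0340 (ln D)^2

    Higher bioclimatic stress E gives shorter trees at fixed diameter.
    """
    d = np.asarray(diameter, float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    ld = np.log(d)
    out = np.exp(0.893 - E + 0.760 * ld - 0.0340 * ld**2)
    return float(out) if np.isscalar(diameter) else out


def predict_height_regional(diameter, params: Sequence[float]) -> np.ndarray | float:
    """Regional Weibull reference: same evaluator as the local Weibull."""
    a, b, c = params
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("regional Weibull parameters must be positive")
    d = np.asarray(diameter, float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = _weibull(d, a, b, c)
    return float(out) if np.isscalar(diameter) else out


def grid_search_sse(
    form: str,
    trees: Iterable[Tree] | tuple,
    bounds: dict[str, tuple[float, float]],
    n_grid: int = 50,
) -> tuple[dict[str, float], float]:
    """Dense grid-search reference fitter (brute force).

    Evaluates the sum of squared height residuals on an ``n_grid``-point
    lattice over the given parameter box and returns the best lattice
    point and its SSE.  Used as an independent check on the
    Levenberg-Marquardt fitter: the optimiser's SSE should never exceed
    the best lattice SSE.
    """
    d, h = _extract_dh(trees)
    names = list(bounds)
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds.values()]
    grids = np.meshgrid(*axes, indexing="ij")
    flat = [g.ravel() for g in grids]
    if form == "weibull":
        pred = _weibull(d[:, None], flat[0][None, :], flat[1][None, :], flat[2][None, :])
    elif form == "michaelis_menten":
        pred = _mm(d[:, None], flat[0][None, :], flat[1][None, :])
    else:
        raise ValueError(f"grid search supports the nonlinear forms, not {form!r}")
    sse = np.sum((pred - h[:, None]) ** 2, axis=0)
    k = int(np.argmin(sse))
    return {n: float(f[k]) for n, f in zip(names, flat)}, float(sse[k])
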