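"""Domain types, tree-level inclusion filters and tabular I/O for plot data.

A plot is a census of every stem >= 10 cm diameter; a subset of trees
additionally carries a ground-based height measurement.  Heights enter
model fitting only if the stem is intact (not broken, leaning < 10%,
not fallen), the height is plausible (< 90 m) and the measurement
method is one of the accepted instruments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Height measurement methods whose values are trusted for model fitting.
ALLOWED_HEIGHT_METHODS = frozenset(
    {"clinometer", "laser_rangefinder", "laser_hypsometer", "climbed"}
)

#: Heights at or above this are treated as recording errors (metres).
MAX_CREDIBLE_HEIGHT_M = 90.0

#: Stems leaning by at least this percentage from vertical are excluded.
MAX_LEAN_PCT = 10.0

#: Minimum height-measured trees for a plot to enter the analysis.
DEFAULT_MIN_HEIGHTS = 150

# Canonical column order for reading and writing plot tables.
_COLUMNS = [
    "plot_id",
    "tree_id",
    "diameter",
    "height",
    "height_method",
    "broken",
    "lean_pct",
    "fallen",
    "wood_density",
]
_REQUIRED = ["plot_id", "tree_id", "diameter"]


class PlotTableFormatError(ValueError):
    """Raised when a plot table file cannot be interpreted."""


@dataclass(frozen=True)
class Tree:
    """One measured stem.

    Parameters
    ----------
    tree_id : str
        Opaque identifier, unique within a plot.
    diameter : float
        Trunk diameter in cm, measured at 1.3 m or above buttresses.
        The census convention admits only stems >= 10 cm.
    height : float or None
        Total height in m; ``None`` if the tree was not height-measured.
    height_method : str
        Instrument used for the height measurement.
    broken, fallen : bool
        Stem-condition flags; either disqualifies the height.
    lean_pct : float
        Deviation of the stem from vertical, in percent.
    wood_density : float or None
        Oven-dry wood density in g/cm^3; ``None`` if unknown.
    """

    tree_id: str
    diameter: float
    height: float | None = None
    height_method: str = "clinometer"
    broken: bool = False
    lean_pct: float = 0.0
    fallen: bool = False
    wood_density: float | None = None

    def __post_init__(self) -> None:
        if self.diameter < 10.0:
            raise ValueError(
                f"tree {self.tree_id}: diameter {self.diameter} cm < 10 cm census threshold"
            )
        if self.height is not None and self.height <= 0:
            raise ValueError(f"tree {self.tree_id}: non-positive height {self.height}")
        if self.wood_density is not None and not (0.0 < self.wood_density < 1.5):
            raise ValueError(
                f"tree {self.tree_id}: wood density {self.wood_density} outside (0, 1.5) g/cm3"
            )
        if self.lean_pct < 0:
            raise ValueError(f"tree {self.tree_id}: negative lean {self.lean_pct}")


@dataclass
class PlotData:
    """A plot (or pre-merged plot cluster) with its trees.

    ``E`` is the dimensionless bioclimatic stress scalar entering the
    pan-tropical climate-based height model; ``region`` tags the plot
    for regional Weibull reference parameters.  Tree order is the
    canonical order used for all deterministic tie-breaks downstream.
    """

    plot_id: str
    trees: list[Tree] = field(default_factory=list)
    E: float | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError(f"plot {self.plot_id}: empty tree list")

    def height_measured_trees(self) -> list[Tree]:
        """Trees passing all height-inclusion filters, in canonical order."""
        return apply_height_filters(self.trees)


def apply_height_filters(trees: Iterable[Tree]) -> list[Tree]:
    """Keep only trees whose height measurement is usable for modelling.

    A tree passes if it has a height, the stem is not broken or fallen,
    leans by less than 10%, the height is below 90 m, and the height
    was measured with an accepted instrument (clinometer, laser
    rangefinder, laser hypsometer, or by climbing).  Never raises;
    input order and tree objects are preserved.
    """
    return [
        t
        for t in trees
        if t.height is not None
        and not t.broken
        and not t.fallen
        and t.lean_pct < MAX_LEAN_PCT
        and t.height < MAX_CREDIBLE_HEIGHT_M
        and t.height_method in ALLOWED_HEIGHT_METHODS
    ]


def eligible_plots(
    plots: Iterable[PlotData], min_heights: int = DEFAULT_MIN_HEIGHTS
) -> list[PlotData]:
    """Plots with at least ``min_heights`` usable height measurements."""
    if min_heights < 1:
        raise ValueError(f"min_heights must be >= 1, got {min_heights}")
    return [p for p in plots if len(p.height_measured_trees()) >= min_heights]


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical field names to actual column names via the dialect."""
    dialect = dict(dialect or {})
    mapping: dict[str, str] = {}
    for name in _COLUMNS:
        actual = dialect.get(name, name)
        if actual in columns:
            mapping[name] = actual
    for name in _REQUIRED:
        if name not in mapping:
            raise PlotTableFormatError(f"required column '{name}' not found")
    return mapping


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    truthy = {"true", "1", "yes", "y", "t"}
    return series.astype(str).str.strip().str.lower().isin(truthy)


def load_plot_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    diameter_unit: str = "cm",
) -> list[PlotData]:
    """Read a delimited tree table into one :class:`PlotData` per plot.

    Parameters
    ----------
    path : path
        CSV with one row per tree.  Required columns (after dialect
        renaming): ``plot_id``, ``tree_id``, ``diameter``.  Optional:
        ``height``, ``height_method``, ``broken``, ``lean_pct``,
        ``fallen``, ``wood_density``, and per-plot ``E`` / ``region``.
    dialect : mapping
        Canonical name -> actual column name, for field databases with
        different headers.
    diameter_unit : {'cm', 'mm'}
        Unit of the diameter column; mm values are converted to cm.

    Rows with unparseable numeric fields are reported and dropped.
    Row order within a plot is preserved (it is the canonical order
    used for deterministic tie-breaks downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if diameter_unit not in ("cm", "mm"):
        raise ValueError(f"diameter_unit must be 'cm' or 'mm', got {diameter_unit!r}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise PlotTableFormatError(f"{path}: empty file") from exc
    if df.empty:
        raise PlotTableFormatError(f"{path}: no data rows")
    cols = _resolve_columns(df.columns, dialect)
    extra = dict(dialect or {})
    e_col = extra.get("E", "E") if extra.get("E", "E") in df.columns else None
    region_col = extra.get("region", "region") if extra.get("region", "region") in df.columns else None

    scale = 0.1 if diameter_unit == "mm" else 1.0
    plots: dict[str, PlotData] = {}
    n_dropped = 0
    for plot_id, group in df.groupby(cols["plot_id"], sort=False):
        trees: list[Tree] = []
        E_val: float | None = None
        region_val: str | None = None
        for idx, row in group.iterrows():
            try:
                diameter = float(row[cols["diameter"]]) * scale
                height_raw = row.get(cols.get("height", ""), None)
                height = (
                    float(height_raw)
                    if height_raw is not None and str(height_raw).strip() not in ("", "nan")
                    else None
                )
                wd_raw = row.get(cols.get("wood_density", ""), None)
                wood_density = (
                    float(wd_raw)
                    if wd_raw is not None and str(wd_raw).strip() not in ("", "nan")
                    else None
                )
                lean_raw = row.get(cols.get("lean_pct", ""), None)
                lean = (
                    float(lean_raw)
                    if lean_raw is not None and str(lean_raw).strip() not in ("", "nan")
                    else 0.0
                )
                method = row.get(cols.get("height_method", ""), None)
                method = str(method).strip() if method is not None and str(method).strip() not in ("", "nan") else "clinometer"
                broken = (
                    _to_bool(pd.Series([row[cols["broken"]]])).iloc[0]
                    if "broken" in cols
                    else False
                )
                fallen = (
                    _to_bool(pd.Series([row[cols["fallen"]]])).iloc[0]
                    if "fallen" in cols
                    else False
                )
                tree = Tree(
                    tree_id=str(row[cols["tree_id"]]),
                    diameter=diameter,
                    height=height,
                    height_method=method,
                    broken=bool(broken),
                    lean_pct=lean,
                    fallen=bool(fallen),
                    wood_density=wood_density,
                )
            except (ValueError, TypeError) as exc:
                n_dropped += 1
                logger.warning("%s row %d dropped: %s", path, idx, exc)
                continue
            trees.append(tree)
            if e_col is not None and E_val is None:
                try:
                    E_val = float(row[e_col])
                except (TypeError, ValueError):
                    pass
            if region_col is not None and region_val is None:
                raw = str(row[region_col]).strip()
                region_val = raw if raw not in ("", "nan") else None
        if trees:
            plots[str(plot_id)] = PlotData(
                plot_id=str(plot_id), trees=trees, E=E_val, region=region_val
            )
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} unparseable rows", stacklevel=2)
    if not plots:
        raise PlotTableFormatError(f"{path}: no valid rows")
    return list(plots.values())


def write_plot_table(plots: Iterable[PlotData], path: str | Path) -> None:
    """Write plots back to CSV with the stable canonical column order."""
    rows = []
    for plot in plots:
        for t in plot.trees:
            rows.append(
                {
                    "plot_id": plot.plot_id,
                    "tree_id": t.tree_id,
                    "diameter": t.diameter,
                    "height": t.height,
                    "height_method": t.height_method,
                    "broken": t.broken,
                    "lean_pct": t.lean_pct,
                    "fallen": t.fallen,
                    "wood_density": t.wood_density,
                    "E": plot.E,
                    "region": plot.region,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS + ["E", "region"]).to_csv(path, index=False)
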