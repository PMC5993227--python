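"""Field strategies for choosing which trees get height measurements.

Five strategies are compared, all drawing n trees without replacement
from a plot's height-measured pool:

* Rand     - simple random sample of n trees.
* Strat    - stratified random sample, allocated across diameter size
             classes (<200, 200-<300, 300-<500, >=500 mm) in proportion
             to class abundance.
* Big      - the n largest-diameter trees.
* BigRand  - the 10 largest trees plus a random sample of n-10 others.
* BigStrat - the 10 largest trees plus a stratified sample of n-10
             others (strata proportions over the remaining trees).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hdallom.plot_data import Tree

STRATEGY_NAMES = ("Rand", "Strat", "Big", "BigRand", "BigStrat")

#: Size-class boundaries in mm diameter, as used in the field protocol.
DEFAULT_STRATA_BOUNDS_MM = (200.0, 300.0, 500.0)

_N_BIG = 10  # largest-diameter trees always included by BigRand/BigStrat


@dataclass(frozen=True)
class StrategySpec:
    """A sampling strategy instance: name, sample size and seed."""

    name: str
    n: int
    seed: int = 0
    strata_bounds_mm: tuple[float, ...] = DEFAULT_STRATA_BOUNDS_MM

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if self.name in ("BigRand", "BigStrat") and self.n < _N_BIG:
            raise ValueError(f"{self.name} requires n >= {_N_BIG}")
        if list(self.strata_bounds_mm) != sorted(set(self.strata_bounds_mm)):
            raise ValueError("strata bounds must be strictly increasing")


def allocate_strata(stratum_counts: Sequence[int], n: int) -> list[int]:
    """Allocate n sample slots across strata proportionally to counts.

    Integerisation by the largest-remainder rule (ties to the earlier
    stratum).  An allocation never exceeds a stratum's count; any
    excess is reallocated over the remaining strata by the same rule.
    The allocations always sum to n.
    """
    counts = np.asarray(stratum_counts, dtype=int)
    if n > counts.sum():
        raise ValueError(f"cannot allocate {n} slots among {counts.sum()} trees")
    alloc = np.zeros_like(counts)
    open_strata = counts > 0
    remaining = n
    # iterate because capping a stratum frees slots for the others
    while remaining > 0:
        pool = counts[open_strata] - alloc[open_strata]
        quota = remaining * pool / pool.sum()
        take = np.floor(quota).astype(int)
        short = remaining - take.sum()
        if short > 0:
            remainder = quota - take
            # largest remainders win; ties to the earlier stratum
            order = np.lexsort((np.arange(remainder.size), -remainder))
            take[order[:short]] += 1
        alloc[open_strata] += take
        over = alloc > counts
        if not over.any():
            break
        excess = int((alloc - counts)[over].sum())
        alloc = np.minimum(alloc, counts)
        open_strata = counts > alloc
        remaining = excess
    return alloc.tolist()


def _stratum_index(diameter_cm: float, bounds_mm: Sequence[float]) -> int:
    bounds_cm = [b / 10.0 for b in bounds_mm]
    return int(np.searchsorted(bounds_cm, diameter_cm, side="right"))


def _largest(trees: Sequence[Tree], k: int) -> list[int]:
    """Indices of the k largest-diameter trees; ties by canonical row order."""
    order = sorted(range(len(trees)), key=lambda i: (-trees[i].diameter, i))
    return sorted(order[:k])


def _stratified_indices(
    trees: Sequence[Tree],
    pool: Sequence[int],
    n: int,
    bounds_mm: Sequence[float],
    rng: np.random.Generator,
) -> list[int]:
    n_strata = len(bounds_mm) + 1
    strata: list[list[int]] = [[] for _ in range(n_strata)]
    for i in pool:
        strata[_stratum_index(trees[i].diameter, bounds_mm)].append(i)
    alloc = allocate_strata([len(s) for s in strata], n)
    chosen: list[int] = []
    for members, k in zip(strata, alloc):
        if k:
            chosen.extend(rng.choice(members, size=k, replace=False).tolist())
    return chosen


def draw_sample(strategy: StrategySpec, trees: Sequence[Tree]) -> list[Tree]:
    """Draw a training sample of trees under a field strategy.

    All sampling is without replacement and deterministic given the
    strategy seed.  Diameter ties in the 'largest' selections are broken
    by canonical row order.  Returned trees preserve canonical order.
    """
    n = strategy.n
    if n > len(trees):
        raise ValueError(f"sample size {n} exceeds {len(trees)} available trees")
    rng = np.random.default_rng(strategy.seed)
    all_idx = list(range(len(trees)))
    if strategy.name == "Rand":
        chosen = rng.choice(all_idx, size=n, replace=False).tolist()
    elif strategy.name == "Strat":
        chosen = _stratified_indices(trees, all_idx, n, strategy.strata_bounds_mm, rng)
    elif strategy.name == "Big":
        chosen = _largest(trees, n)
    elif strategy.name == "BigRand":
        big = _largest(trees, _N_BIG)
        rest = [i for i in all_idx if i not in set(big)]
        extra = rng.choice(rest, size=n - _N_BIG, replace=False).tolist() if n > _N_BIG else []
        chosen = big + extra
    elif strategy.name == "BigStrat":
        big = _largest(trees, _N_BIG)
        rest = [i for i in all_idx if i not in set(big)]
        extra = (
            _stratified_indices(trees, rest, n - _N_BIG, strategy.strata_bounds_mm, rng)
            if n > _N_BIG
            else []
        )
        chosen = big + extra
    else:  # pragma: no cover - guarded by StrategySpec
        raise ValueError(strategy.name)
    return [trees[i] for i in sorted(set(chosen))]
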