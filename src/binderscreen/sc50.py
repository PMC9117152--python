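"""Apparent SC50 estimation from FACS-sorted yeast-display NGS counts.

A design displayed on yeast is collected in a sort with probability

    fraction_collected = concentration / (concentration + SC50)

times a per-design surface-expression constant observed to lie roughly in
[0.2, 0.7].  The SC50 is the apparent midpoint concentration of the binding
transition, a proxy for Kd distorted by expression level (and by avidity in
multivalent sorts, which are therefore never combined with monovalent ones).

Three estimators are provided:

* a per-sort *point* fraction-collected from NGS proportions and the FACS
  collection fraction,
* a binary *classification* (SC50 below a chosen reference) from one sort,
* a *grid/binomial* estimate combining an arbitrary number of sorts into a
  profile over candidate SC50 values with a confidence interval.

Each sort is modelled as a binomial: n cells of a design were sorted, x were
collected, and the collection probability under a candidate SC50 follows the
hyperbolic model above.  Because the expression constant is unknown per
design, the expected fraction for a candidate is not a single value but a
band: from ``expression_min`` times the model fraction up to the model
fraction, additionally capped at ``saturation_cap`` (observed fractions above
~0.2 are saturating for poorly expressing designs) and floored at the
doubly-transformed passenger-cell level.  Observations inside the band (or
inside a clipped region) have probability 1; outside it, a two-sided binomial
CDF probability against the nearest bound.  Per-sort probabilities multiply
across sorts into the profile.

Doubly transformed yeast cells carry a non-binding "passenger" plasmid
through the sorts alongside a strong binder.  Assuming each passenger arose
from a single double-transformation event, the largest cell count a passenger
can reach is

    max_possible_passenger_cells =
        (cells_collected_imax / cells_sorted_R1_imax) * cell_copies_before_first_sort

where imax is the design with the most collected cells in the round and
cell_copies_before_first_sort = 2^(number of divisions before round 1).
Designs below this floor in every sort are excluded as passenger suspects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import PoolCounts, SortRecord

DEFAULT_SATURATION_CAP = 0.2
DEFAULT_EXPRESSION_MIN = 0.2
DEFAULT_CI_THRESHOLD = 0.05
DEFAULT_GRID_POINTS = 40


class EstimationError(ValueError):
    """Raised for unusable inputs to the SC50 estimators."""


# ---------------------------------------------------------------------------
# The binding model


def fraction_collected(concentration, sc50):
    """Expected collected fraction at full expression (hyperbolic model).

    Accepts scalars or arrays; ``sc50`` may be ``inf`` for a non-binder
    (fraction 0).  Strictly increasing in concentration and decreasing in
    SC50; equals 0.5 when concentration == SC50.
    """
    conc = np.asarray(concentration, dtype=float)
    s = np.asarray(sc50, dtype=float)
    if np.any(conc < 0):
        raise EstimationError("concentration must be >= 0")
    if np.any(s <= 0):
        raise EstimationError("sc50 must be > 0")
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(s), 0.0, conc / (conc + s))
    if np.ndim(concentration) == 0 and np.ndim(sc50) == 0:
        return float(out)
    return out


def point_fraction_collected(child_prop, parent_prop, facs_fraction):
    """Per-design fraction collected in one sort from NGS proportions.

    (proportion in child pool / proportion in parent pool) x FACS collection
    fraction.  May exceed 1 for heavily enriched designs; callers flag rather
    than clip.
    """
    child = np.asarray(child_prop, dtype=float)
    parent = np.asarray(parent_prop, dtype=float)
    if np.any(parent <= 0):
        raise EstimationError("parent-pool proportion must be > 0")
    if not 0 < facs_fraction <= 1:
        raise EstimationError("facs_fraction must be in (0, 1]")
    out = child / parent * facs_fraction
    if np.ndim(child_prop) == 0 and np.ndim(parent_prop) == 0:
        return float(out)
    return out


def max_passenger_cells(
    cells_collected_imax: float, cells_sorted_r1_imax: float, cell_copies: float
) -> float:
    """Highest cell count expected for a doubly transformed passenger."""
    if cells_sorted_r1_imax <= 0:
        raise EstimationError("cells_sorted_R1 for the top design must be > 0")
    if cells_collected_imax <= 0 or cell_copies <= 0:
        raise EstimationError("inputs must be positive")
    return cells_collected_imax / cells_sorted_r1_imax * cell_copies


# ---------------------------------------------------------------------------
# Cell accounting


def estimate_cell_counts(
    child: PoolCounts,
    parent: PoolCounts,
    sort: SortRecord,
    design_ids=None,
) -> pd.DataFrame:
    """Approximate per-design sorted/collected cell numbers for one sort.

    cells_collected_i = total cells collected x proportion of the child
    pool; cells_sorted_i = cells fed x proportion of the parent pool.  With
    this pairing x/n reproduces the per-design point fraction collected
    (child/parent proportion ratio times the FACS collection fraction).
    When a design is missing from the parent pool but present in the child,
    cells_sorted_i falls back to cells_collected_i / FACS collection
    fraction (the pool-average enrichment; flagged).
    """
    if design_ids is None:
        design_ids = sorted(set(child.counts) | set(parent.counts))
    child_props = child.proportions()
    parent_props = parent.proportions()
    rows = []
    for design_id in design_ids:
        cp = child_props.get(design_id, 0.0)
        pp = parent_props.get(design_id, 0.0)
        collected = sort.cells_collected_total * cp
        if pp > 0:
            sorted_cells = sort.cells_fed * pp
            fallback = False
        else:
            sorted_cells = collected / sort.facs_collection_fraction
            fallback = True
        rows.append(
            {
                "design_id": design_id,
                "cells_collected": collected,
                "cells_sorted": sorted_cells,
                "fallback": fallback,
            }
        )
    return pd.DataFrame(rows).set_index("design_id")


@dataclass
class SortSeries:
    """An ordered chain of sorts with per-sort cell accounting and floors.

    ``sorts`` must form a single chain rooted at a pool (the naive library)
    that has counts but no sort record of its own.
    """

    pools: dict[str, PoolCounts]
    sorts: list[SortRecord]
    cell_copies: float
    include_avidity: bool = False

    accounting: list[pd.DataFrame] = field(init=False)
    floors: list[float] = field(init=False)
    design_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        chain = _order_chain(self.pools, self.sorts)
        if not self.include_avidity:
            chain = [s for s in chain if not s.avidity]
        if not chain:
            raise EstimationError("no usable (non-avidity) sorts")
        self.sorts = chain
        ids: set[str] = set()
        for pool in self.pools.values():
            ids.update(pool.counts)
        self.design_ids = sorted(ids)
        self.accounting = []
        for sort in self.sorts:
            if sort.parent_pool_id not in self.pools:
                raise EstimationError(
                    f"missing parent pool {sort.parent_pool_id!r}"
                )
            self.accounting.append(
                estimate_cell_counts(
                    self.pools[sort.pool_id],
                    self.pools[sort.parent_pool_id],
                    sort,
                    self.design_ids,
                )
            )
        # Eq. 3 floor per round: top collected design this round, its sorted
        # cells taken from round 1.
        acc1 = self.accounting[0]
        self.floors = []
        for acc in self.accounting:
            imax = acc["cells_collected"].idxmax()
            sorted_r1 = acc1.loc[imax, "cells_sorted"]
            self.floors.append(
                max_passenger_cells(
                    acc.loc[imax, "cells_collected"], sorted_r1, self.cell_copies
                )
            )

    def below_floor(self) -> pd.DataFrame:
        """Boolean (design x sort) table: collected cells under the floor."""
        data = {
            sort.pool_id: acc["cells_collected"] < floor
            for sort, acc, floor in zip(self.sorts, self.accounting, self.floors)
        }
        return pd.DataFrame(data)

    def passenger_suspects(self) -> set[str]:
        """Designs under the passenger floor in every sort."""
        below = self.below_floor()
        return set(below.index[below.all(axis=1)])


def _order_chain(
    pools: dict[str, PoolCounts], sorts: list[SortRecord]
) -> list[SortRecord]:
    by_pool = {s.pool_id: s for s in sorts}
    roots = [s for s in sorts if s.parent_pool_id not in by_pool]
    if len(roots) != 1:
        raise EstimationError(
            f"sorts must form one chain; found {len(roots)} roots"
        )
    chain = [roots[0]]
    children = {s.parent_pool_id: s for s in sorts}
    while chain[-1].pool_id in children:
        chain.append(children[chain[-1].pool_id])
    if len(chain) != len(sorts):
        raise EstimationError("sorts do not form a single linear chain")
    return chain


# ---------------------------------------------------------------------------
# Classification against a reference SC50


def classify_below_threshold(
    pools: dict[str, PoolCounts],
    sorts: list[SortRecord],
    sc50_0: float,
    cell_copies: float,
    pool_id: str | None = None,
    floor_cells: float | None = None,
) -> pd.DataFrame:
    """Mark designs whose apparent SC50 lies below ``sc50_0``.

    Classification uses a single sort (``pool_id``; default the last sort in
    the chain): a design is positive when its point fraction collected
    exceeds the model expectation at ``sc50_0``.  The sort must operate
    below the saturation regime (expected fraction < 0.2); designs under the
    passenger floor for that sort (whose round-1 denominator requires the
    full chain) are excluded, not negative.
    """
    series = SortSeries(pools, sorts, cell_copies)
    if pool_id is None:
        sort_idx = len(series.sorts) - 1
    else:
        sort_idx = [s.pool_id for s in series.sorts].index(pool_id)
    sort = series.sorts[sort_idx]
    expected = fraction_collected(sort.concentration, sc50_0)
    if expected >= DEFAULT_SATURATION_CAP:
        raise EstimationError(
            f"expected fraction {expected:.3f} >= {DEFAULT_SATURATION_CAP}; "
            "choose a lower concentration or higher sc50_0"
        )
    acc = series.accounting[sort_idx]
    if floor_cells is None:
        floor_cells = series.floors[sort_idx]
    child = pools[sort.pool_id]
    parent = pools[sort.parent_pool_id]
    child_props = child.proportions()
    parent_props = parent.proportions()
    rows = []
    for design_id in acc.index:
        pp = parent_props.get(design_id, 0.0)
        if pp <= 0:
            continue
        frac = point_fraction_collected(
            child_props.get(design_id, 0.0), pp, sort.facs_collection_fraction
        )
        excluded = acc.loc[design_id, "cells_collected"] < floor_cells
        rows.append(
            {
                "design_id": design_id,
                "fraction_collected": frac,
                "excluded": bool(excluded),
                "positive": bool(not excluded and frac > expected),
            }
        )
    return pd.DataFrame(rows).set_index("design_id")


# ---------------------------------------------------------------------------
# Grid / binomial full estimate


@dataclass
class SC50Estimate:
    """Grid-profile SC50 estimate for one design.

    ``grid_profile`` maps candidate SC50 (nM) to the renormalized combined
    probability in [0, 1].  ``sc50_point`` is NaN for censored estimates
    (no usable sorts); flags may include ``passenger_suspect``,
    ``censored_low``/``censored_high`` (CI touching a grid edge, i.e. the
    data only bound the SC50 from one side) and ``saturated`` (every sort
    cap-clipped).
    """

    design_id: str
    sc50_point: float
    ci_low: float
    ci_high: float
    grid_profile: dict[float, float]
    flags: set[str] = field(default_factory=set)


def default_grid(sorts: list[SortRecord], n_points: int = DEFAULT_GRID_POINTS):
    """Log-spaced candidate grid: 0.01x lowest to 100x highest concentration."""
    concs = [s.concentration for s in sorts if s.concentration > 0]
    if not concs:
        raise EstimationError("no positive sort concentrations")
    return np.geomspace(0.01 * min(concs), 100 * max(concs), n_points)


def _sort_log_probability(
    grid: np.ndarray,
    concentration: float,
    n: float,
    x: float,
    floor_cells: float,
    expression_min: float,
    saturation_cap: float,
) -> np.ndarray:
    """log10 probability of one sort's observation for each grid candidate.

    The expected collected fraction for a candidate lies in a band
    [expression_min * f0, min(f0, cap)] (f0 the full-expression model value),
    with the lower edge raised to the passenger floor.  Observations inside
    the band or inside a clipped region score probability 1; outside, a
    two-sided binomial CDF probability against the nearest band edge.
    """
    n_int = max(int(round(n)), 1)
    x_int = int(round(min(max(x, 0.0), n)))
    f0 = fraction_collected(concentration, grid)
    hi = np.minimum(f0, saturation_cap)
    lo = expression_min * f0
    floor_p = min(floor_cells / n_int, 1.0)
    floor_clipped = lo < floor_p
    lo = np.maximum(lo, np.minimum(floor_p, hi))
    lo = np.minimum(lo, hi)

    logp = np.zeros_like(f0)

    above = x_int > np.ceil(hi * n_int)
    # cap-clipped above: any saturating observation is consistent
    cap_clipped = f0 > saturation_cap
    hard_above = above & ~cap_clipped
    if np.any(hard_above):
        sf = stats.binom.sf(x_int - 1, n_int, hi[hard_above])
        logp[hard_above] = np.log10(np.minimum(2 * sf, 1.0) + 1e-300)

    below = x_int < np.floor(lo * n_int)
    hard_below = below & ~floor_clipped
    if np.any(hard_below):
        cdf = stats.binom.cdf(x_int, n_int, lo[hard_below])
        logp[hard_below] = np.log10(np.minimum(2 * cdf, 1.0) + 1e-300)
    return logp


def estimate_sc50_bayes(
    pools: dict[str, PoolCounts],
    sorts: list[SortRecord],
    cell_copies: float,
    design_ids=None,
    grid=None,
    expression_min: float = DEFAULT_EXPRESSION_MIN,
    saturation_cap: float = DEFAULT_SATURATION_CAP,
    ci_threshold: float = DEFAULT_CI_THRESHOLD,
) -> dict[str, SC50Estimate]:
    """Full grid/binomial SC50 estimate for each design.

    Combines every non-avidity sort in the chain; per-sort probabilities are
    multiplied under independence and the profile renormalized to max 1.
    The point estimate is the log-midpoint of the maximal-profile plateau;
    the confidence interval spans all candidates whose profile exceeds
    ``ci_threshold`` times the maximum.
    """
    series = SortSeries(pools, sorts, cell_copies)
    if grid is None:
        grid = default_grid(series.sorts)
    grid = np.asarray(grid, dtype=float)
    if design_ids is None:
        design_ids = series.design_ids
    suspects = series.passenger_suspects()

    estimates: dict[str, SC50Estimate] = {}
    for design_id in design_ids:
        log_profile = np.zeros_like(grid)
        n_used = 0
        for sort, acc, floor in zip(
            series.sorts, series.accounting, series.floors
        ):
            if design_id not in acc.index:
                continue
            n = acc.loc[design_id, "cells_sorted"]
            x = acc.loc[design_id, "cells_collected"]
            if n <= 0:
                continue
            log_profile += _sort_log_probability(
                grid,
                sort.concentration,
                n,
                x,
                floor,
                expression_min,
                saturation_cap,
            )
            n_used += 1
        flags: set[str] = set()
        if design_id in suspects:
            # below the passenger floor in every sort: the profile is still
            # reported, but the design must not be called a binder
            flags.add("passenger_suspect")
        if n_used == 0:
            estimates[design_id] = SC50Estimate(
                design_id,
                math.nan,
                float(grid[0]),
                float(grid[-1]),
                {float(s): 1.0 for s in grid},
                flags | {"no_usable_sorts", "censored_low", "censored_high"},
            )
            continue
        log_profile -= log_profile.max()
        profile = 10.0 ** log_profile
        at_max = profile >= 1.0 - 1e-12
        log_grid = np.log(grid)
        # Point estimate: log-midpoint of the maximal plateau.  When the
        # plateau runs into a grid edge the data only bound the SC50 from
        # one side; report the bounded edge of the plateau instead (the
        # "SC50 < x" / "SC50 > x" reading), with the censored flag set.
        max_idx = np.flatnonzero(at_max)
        if at_max[0] and not at_max[-1]:
            sc50_point = float(grid[max_idx[-1]])
        elif at_max[-1] and not at_max[0]:
            sc50_point = float(grid[max_idx[0]])
        else:
            sc50_point = float(np.exp(log_grid[at_max].mean()))
        in_ci = profile >= ci_threshold
        ci_low = float(grid[in_ci][0])
        ci_high = float(grid[in_ci][-1])
        if in_ci[0]:
            flags.add("censored_low")
        if in_ci[-1]:
            flags.add("censored_high")
        sat = all(
            fraction_collected(s.concentration, sc50_point) > saturation_cap
            for s in series.sorts
        )
        if sat:
            flags.add("saturated")
        estimates[design_id] = SC50Estimate(
            design_id,
            sc50_point,
            ci_low,
            ci_high,
            dict(zip(map(float, grid), map(float, profile))),
            flags,
        )
    return estimates


def estimates_to_frame(estimates: dict[str, SC50Estimate]) -> pd.DataFrame:
    """Tabulate estimates (one row per design) for TSV export."""
    rows = []
    for est in estimates.values():
        rows.append(
            {
                "design_id": est.design_id,
                "sc50_point": est.sc50_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flags": ",".join(sorted(est.flags)),
            }
        )
    return pd.DataFrame(rows).set_index("design_id")
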