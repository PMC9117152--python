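"""Synthetic yeast-display sorting experiments with known ground truth.

Every estimator in the package is validated by parameter recovery against
this simulator.  A library of designs is "transformed" into yeast: each
design receives a Poisson number of transformant cells, amplified by a fixed
number of cell divisions before the first sort.  Binders have a true SC50
drawn log-uniformly; non-binders have SC50 = +inf (collection probability 0).
Each design carries a multiplicative surface-expression factor drawn
uniformly from a configurable range (defaults [0.2, 0.7], the range observed
for real libraries).

A configurable fraction of designs are doubly transformed "passengers": a
non-binding plasmid co-residing in the cells of a uniformly chosen binder
(exactly one double-transformation event per passenger, so a passenger's
census is a single transformant's copies, paired cell-for-cell with its
carrier).  During a sort a passenger cell is collected iff its carrier cell
is collected, realized here as a hypergeometric draw of the carrier's
collected cells.

Sorting collects each displaying cell independently with probability

    expression_factor * concentration / (concentration + SC50)

(a binomial draw per design); pool NGS is a multinomial read draw with
probabilities proportional to cell counts.  Growth between sorts is uniform
amplification: no per-design fitness differences, so estimator error is
isolated from biology.  Avidity sorts divide the effective SC50 by a labelled
avidity factor; they are a synthetic convenience and are never mixed with
monovalent estimates downstream.

All stochastic operations take an explicit seed or Generator; there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_io import PoolCounts, SortRecord
from .sc50 import fraction_collected


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class DesignGroundTruth:
    """True parameters of one simulated design."""

    design_id: str
    sc50_true: float  # nM; +inf for a non-binder
    expression_factor: float
    passenger_of: str | None = None

    def __post_init__(self) -> None:
        if not self.sc50_true > 0:
            raise ConfigError("sc50_true must be > 0 (inf for non-binders)")
        if not 0 <= self.expression_factor <= 1:
            raise ConfigError("expression_factor must be in [0, 1]")
        if self.passenger_of == self.design_id:
            raise ConfigError("a design cannot be its own carrier")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated screen.

    Defaults describe a 200-design library sorted four times across a
    100-fold concentration range with ~1e4 cells per design and 1e6 reads
    per pool.
    """

    n_designs: int = 200
    sc50_range: tuple[float, float] = (1.0, 1000.0)  # nM, log-uniform
    nonbinder_fraction: float = 0.3
    expression_range: tuple[float, float] = (0.2, 0.7)
    double_transform_rate: float = 0.0
    mean_transformants: float = 625.0
    cell_copies_before_first_sort: int = 16  # 2^4 divisions
    concentrations: tuple[float, ...] = (1000.0, 215.44, 46.42, 10.0)  # nM
    reads_per_pool: int = 1_000_000
    regrowth_factor: int = 20
    avidity_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_designs <= 0 or self.mean_transformants <= 0:
            raise ConfigError("counts must be positive")
        if self.cell_copies_before_first_sort <= 0 or self.reads_per_pool <= 0:
            raise ConfigError("counts must be positive")
        if not 0 <= self.nonbinder_fraction <= 1:
            raise ConfigError("nonbinder_fraction must be in [0, 1]")
        if not 0 <= self.double_transform_rate < 1:
            raise ConfigError("double_transform_rate must be in [0, 1)")
        lo, hi = self.expression_range
        if not 0 <= lo <= hi <= 1:
            raise ConfigError("expression_range must satisfy 0 <= lo <= hi <= 1")
        if self.sc50_range[0] <= 0 or self.sc50_range[1] < self.sc50_range[0]:
            raise ConfigError("sc50_range must be positive and ordered")


def simulate_library(
    config: SimulationConfig, seed
) -> tuple[dict[str, DesignGroundTruth], dict[str, int]]:
    """Draw ground truth and the initial cell census.

    Passengers are drawn among non-binders and attached to uniformly chosen
    binders; a passenger's census is one transformant's copies.  All other
    designs get Poisson(mean_transformants) transformants, each amplified
    ``cell_copies_before_first_sort``-fold.
    """
    rng = np.random.default_rng(seed)
    n = config.n_designs
    ids = [f"design_{i:05d}" for i in range(n)]

    is_nonbinder = rng.random(n) < config.nonbinder_fraction
    lo, hi = config.sc50_range
    sc50 = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    sc50[is_nonbinder] = math.inf
    e_lo, e_hi = config.expression_range
    expression = rng.uniform(e_lo, e_hi, n)

    binder_idx = np.flatnonzero(~is_nonbinder)
    nonbinder_idx = np.flatnonzero(is_nonbinder)
    n_passengers = int(rng.binomial(n, config.double_transform_rate))
    n_passengers = min(n_passengers, len(nonbinder_idx))
    if n_passengers > 0 and len(binder_idx) == 0:
        raise ConfigError("cannot place passengers in a library of non-binders")
    passenger_idx = rng.choice(nonbinder_idx, size=n_passengers, replace=False)
    carriers = rng.choice(binder_idx, size=n_passengers)

    passenger_of: dict[int, str] = {
        int(p): ids[int(c)] for p, c in zip(passenger_idx, carriers)
    }
    truth: dict[str, DesignGroundTruth] = {}
    census: dict[str, int] = {}
    transformants = rng.poisson(config.mean_transformants, n)
    for i, design_id in enumerate(ids):
        carrier = passenger_of.get(i)
        truth[design_id] = DesignGroundTruth(
            design_id,
            float(sc50[i]),
            float(expression[i]),
            carrier,
        )
        if carrier is not None:
            census[design_id] = config.cell_copies_before_first_sort
        else:
            census[design_id] = (
                int(transformants[i]) * config.cell_copies_before_first_sort
            )
    return truth, census


def simulate_sort(
    census: dict[str, int],
    concentration: float,
    truth: dict[str, DesignGroundTruth],
    seed,
    avidity: bool = False,
    avidity_factor: float = 10.0,
) -> tuple[dict[str, int], float]:
    """Sort a census at one concentration; return collected census and the
    realized FACS collection fraction.

    Non-passenger cells are collected independently with probability
    expression * concentration / (concentration + SC50); passenger cells are
    collected iff their paired carrier cell was (hypergeometric draw of the
    carrier's collected cells).
    """
    if concentration < 0:
        raise ConfigError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    total_fed = sum(census.values())
    if total_fed <= 0:
        raise ConfigError("empty census")
    collected: dict[str, int] = {}
    for design_id, cells in census.items():
        gt = truth[design_id]
        if gt.passenger_of is not None:
            continue
        sc50 = gt.sc50_true / avidity_factor if avidity else gt.sc50_true
        p = gt.expression_factor * fraction_collected(concentration, sc50)
        collected[design_id] = int(rng.binomial(cells, p)) if cells > 0 else 0
    for design_id, cells in census.items():
        gt = truth[design_id]
        if gt.passenger_of is None:
            continue
        carrier_cells = census.get(gt.passenger_of, 0)
        carrier_collected = collected.get(gt.passenger_of, 0)
        paired = min(cells, carrier_cells)
        if paired <= 0 or carrier_cells <= 0:
            collected[design_id] = 0
            continue
        collected[design_id] = int(
            rng.hypergeometric(
                carrier_collected, carrier_cells - carrier_collected, paired
            )
        )
    realized = sum(collected.values()) / total_fed
    return collected, realized


def simulate_ngs(census: dict[str, int], reads_per_pool: int, seed) -> PoolCounts:
    """Multinomial NGS read draw with probabilities ~ cell counts."""
    total = sum(census.values())
    if total <= 0:
        raise ConfigError("empty census")
    rng = np.random.default_rng(seed)
    ids = sorted(census)
    probs = np.array([census[d] for d in ids], dtype=float) / total
    draws = rng.multinomial(reads_per_pool, probs)
    counts = {d: int(c) for d, c in zip(ids, draws) if c > 0}
    return PoolCounts("pool", counts)


def grow(census: dict[str, int], factor: int) -> dict[str, int]:
    """Uniform amplification between sorts (no fitness differences)."""
    return {d: c * factor for d, c in census.items()}


@dataclass
class SimulatedScreen:
    """A full simulated sort series with ground truth."""

    config: SimulationConfig
    truth: dict[str, DesignGroundTruth]
    sorts: list[SortRecord]
    pools: dict[str, PoolCounts]
    census_history: list[dict[str, int]] = field(repr=False, default_factory=list)


def simulate_screen(
    config: SimulationConfig, seed, avidity: bool = False
) -> SimulatedScreen:
    """Run a complete screen: library, sort chain, NGS of every pool.

    Pool "R0" is the naive library; sort r produces pool f"R{r}" from
    f"R{r-1}".  Deterministic for a fixed seed.
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=2 + 2 * len(config.concentrations))
    truth, census = simulate_library(config, int(seeds[0]))

    pools: dict[str, PoolCounts] = {}
    naive = simulate_ngs(census, config.reads_per_pool, int(seeds[1]))
    naive.pool_id = "R0"
    pools["R0"] = naive

    sorts: list[SortRecord] = []
    history = [dict(census)]
    for r, conc in enumerate(config.concentrations, start=1):
        cells_fed = sum(census.values())
        collected, realized = simulate_sort(
            census,
            conc,
            truth,
            int(seeds[2 * r]),
            avidity=avidity,
            avidity_factor=config.avidity_factor,
        )
        pool_id = f"R{r}"
        sorts.append(
            SortRecord(
                pool_id=pool_id,
                parent_pool_id=f"R{r - 1}",
                concentration=conc,
                facs_collection_fraction=max(realized, 1e-12),
                cells_fed=cells_fed,
                cells_collected_total=sum(collected.values()),
                avidity=avidity,
            )
        )
        pool = simulate_ngs(collected, config.reads_per_pool, int(seeds[2 * r + 1]))
        pool.pool_id = pool_id
        pools[pool_id] = pool
        history.append(dict(collected))
        census = grow(collected, config.regrowth_factor)
    return SimulatedScreen(config, truth, sorts, pools, history)


def ground_truth_frame(truth: dict[str, DesignGroundTruth]) -> pd.DataFrame:
    rows = [
        {
            "design_id": gt.design_id,
            "sc50_true": gt.sc50_true,
            "expression_factor": gt.expression_factor,
            "passenger_of": gt.passenger_of or "",
        }
        for gt in truth.values()
    ]
    return pd.DataFrame(rows).set_index("design_id")


def write_ground_truth(truth: dict[str, DesignGroundTruth], path) -> None:
    ground_truth_frame(truth).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SSM synthetic data


def simulate_ssm_counts(
    parent_sequence: str,
    region_labels: list[str],
    parent_sc50: float,
    seed,
    reads: int = 500_000,
    deleterious_logshift: float = 2.0,
    neutral_sd: float = 0.15,
    concentration: float | None = None,
):
    """Simulate one SSM pool's position x amino-acid count matrix.

    Mutations at ``monomer_core`` and ``interface_core`` positions are
    predominantly deleterious (log10 SC50 shifted up by
    ``deleterious_logshift`` on average); ``monomer_surface`` and ``other``
    mutations are near-neutral.  The pool is sorted once at a concentration
    tenfold below the parent SC50 (the pool used for entropy footprints);
    counts are a multinomial read draw over variants weighted by survival
    under the binding model.

    Returns (counts array of shape (L, 20), true per-variant log10 SC50
    shifts of the same shape).
    """
    from .ssm import AA_ORDER  # local import to avoid a cycle at import time

    rng = np.random.default_rng(seed)
    length = len(parent_sequence)
    if len(region_labels) != length:
        raise ConfigError("region_labels length must match the sequence")
    if concentration is None:
        concentration = parent_sc50 / 10.0

    aa_index = {aa: j for j, aa in enumerate(AA_ORDER)}
    shifts = np.zeros((length, 20))
    for i, label in enumerate(region_labels):
        for j in range(20):
            if AA_ORDER[j] == parent_sequence[i]:
                continue
            if label in ("monomer_core", "interface_core"):
                shifts[i, j] = rng.normal(deleterious_logshift, 0.5)
            else:
                shifts[i, j] = rng.normal(0.0, neutral_sd)

    sc50 = parent_sc50 * 10.0 ** shifts
    survival = fraction_collected(concentration, sc50)
    weights = survival.copy()
    parent_survival = fraction_collected(concentration, parent_sc50)
    # one shared parent variant; its count is reused at every native cell
    flat: list[float] = [parent_survival]
    cells: list[tuple[int, int]] = [(-1, -1)]
    for i in range(length):
        for j in range(20):
            if AA_ORDER[j] == parent_sequence[i]:
                continue
            flat.append(weights[i, j])
            cells.append((i, j))
    probs = np.array(flat)
    probs = probs / probs.sum()
    draws = rng.multinomial(reads, probs)
    counts = np.zeros((length, 20), dtype=int)
    parent_count = int(draws[0])
    for k in range(1, len(draws)):
        i, j = cells[k]
        counts[i, j] = int(draws[k])
    for i in range(length):
        counts[i, aa_index[parent_sequence[i]]] = parent_count
    return counts, shifts


def simulate_mutant_energies(
    n_mutations: int,
    dg_fold_true: float,
    seed,
    kT: float = 0.5961,
    ddg_mono_range: tuple[float, float] = (-1.0, 8.0),
    noise_sd: float = 0.3,
    interface_fraction: float = 0.0,
) -> pd.DataFrame:
    """Inverse-model dataset for the folding-stability fit.

    Draws per-mutation monomer destabilization energies and generates
    experimental binding shifts from the folded-fraction model at a known
    ``dg_fold_true`` (stability convention: positive = stable), plus
    Gaussian noise.  Returns a table with columns position, mutant_aa,
    ddg_monomer, ddg_interface, ddg_target, at_interface, ddg_experimental.
    """
    from .ssm import ddG_monomer_effect, p_fold

    rng = np.random.default_rng(seed)
    ddg_mono = rng.uniform(*ddg_mono_range, n_mutations)
    at_interface = rng.random(n_mutations) < interface_fraction
    p_native = p_fold(dg_fold_true, 0.0, kT)
    ddg_true = np.array(
        [
            ddG_monomer_effect(p_native, p_fold(dg_fold_true, -d, kT), kT)
            for d in ddg_mono
        ]
    )
    observed = ddg_true + rng.normal(0.0, noise_sd, n_mutations)
    return pd.DataFrame(
        {
            "position": np.arange(1, n_mutations + 1),
            "mutant_aa": ["A"] * n_mutations,
            "ddg_monomer": ddg_mono,
            "ddg_interface": np.zeros(n_mutations),
            "ddg_target": np.zeros(n_mutations),
            "at_interface": at_interface,
            "ddg_experimental": observed,
        }
    )
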