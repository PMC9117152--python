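"""Site-saturation mutagenesis (SSM) validation of designed binders.

Two orthogonal checks that a design binds through its designed, folded
interface:

**Entropy footprint.**  In a sorted SSM pool, positions that tolerate few
substitutions (low Shannon entropy) mark functionally constrained residues.
A correctly folded, correctly docked design conserves its monomer core and
interface core while its solvent-exposed surface drifts freely, so

    entropy_score = S_monomer_core + S_interface_core - S_monomer_surface

(each S the mean per-position entropy of the region) is strongly negative.
Significance comes from decoy datasets in which the observed counts are
randomly reassigned among all point mutations -- preserving the experimental
noise structure -- and a Normal CDF of the real score under the decoy
mean/SD.

**Energy-accuracy score.**  Predicted per-mutation energies (three
components: monomer, interface, target, from any forcefield) are compared to
experimental binding shifts derived from SC50 ratios.  A monomer
destabilization only affects binding through the folded fraction:

    P(fold) = exp((dG_fold + dG_mutant_effect) / kT)   clipped to <= 1
    ddG_monomer_effect = kT ln(P(fold)_native / P(fold)_mutant)
    ddG_predicted = ddG_monomer_effect + ddG_interface + ddG_target

dG_fold (stability convention: positive = stable, so the exponential clips
at 1 for stable natives) is not known a priori; it is fitted by least
squares over non-interface mutations, with a confidence band of all values
whose RMSE lies within 0.25 kcal/mol of the optimum.  A mutation is
"explained" when the predicted interval (over the dG_fold band) and the
experimental interval overlap within a 1 kcal/mol buffer; the overall score
is the explained fraction over monomer-core and interface-core mutations,
with a shuffled-decoy p-value as above.  kT is fixed at 300 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
KT_300 = 0.0019872041 * 300.0  # kcal/mol at 300 K

REGION_LABELS = ("interface_core", "monomer_core", "monomer_surface", "other")
SCORED_REGIONS = ("monomer_core", "interface_core", "monomer_surface")


class SSMError(ValueError):
    """Raised for unusable SSM inputs."""


# ---------------------------------------------------------------------------
# Data model


@dataclass
class SSMMatrix:
    """Position x amino-acid counts for one parent design in one pool."""

    parent_design_id: str
    parent_sequence: str
    counts: np.ndarray  # (L, 20) int, columns in AA_ORDER
    chosen_pool: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.parent_sequence), 20):
            raise SSMError(
                f"counts shape {self.counts.shape} does not match sequence "
                f"length {len(self.parent_sequence)}"
            )
        if np.any(self.counts < 0):
            raise SSMError("negative counts")

    @property
    def length(self) -> int:
        return len(self.parent_sequence)

    def native_mask(self) -> np.ndarray:
        """(L, 20) boolean mask of native-identity cells."""
        mask = np.zeros_like(self.counts, dtype=bool)
        for i, aa in enumerate(self.parent_sequence):
            mask[i, AA_ORDER.index(aa)] = True
        return mask


def validate_region_labels(labels, length: int) -> list[str]:
    labels = list(labels)
    if len(labels) != length:
        raise SSMError(f"expected {length} labels, got {len(labels)}")
    bad = set(labels) - set(REGION_LABELS)
    if bad:
        raise SSMError(f"unknown region labels: {sorted(bad)}")
    return labels


def choose_pool(pool_concentrations: dict[str, float], parent_sc50: float) -> str:
    """Pool with concentration closest (in log space) to SC50 / 10."""
    if not pool_concentrations:
        raise SSMError("no pools to choose from")
    target = math.log(parent_sc50 / 10.0)
    return min(
        pool_concentrations,
        key=lambda p: (abs(math.log(pool_concentrations[p]) - target), p),
    )


# ---------------------------------------------------------------------------
# Entropy footprint


def positional_entropy(ssm: SSMMatrix) -> np.ndarray:
    """Shannon entropy (bits) of amino-acid frequencies at each position.

    Positions with zero total counts yield NaN (flagged, not scored).
    """
    counts = ssm.counts
    if not np.any(counts > 0):
        raise SSMError("all-zero SSM matrix")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
        logf = np.where(freqs > 0, np.log2(freqs), 0.0)
    entropy = -(freqs * logf).sum(axis=1)
    entropy[totals[:, 0] == 0] = np.nan
    return entropy


def entropy_score(entropies: np.ndarray, labels) -> float:
    """S_monomer_core + S_interface_core - S_monomer_surface."""
    labels = validate_region_labels(labels, len(entropies))
    arr = np.asarray(entropies, dtype=float)
    means = {}
    for region in SCORED_REGIONS:
        mask = np.array([lab == region for lab in labels])
        vals = arr[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise SSMError(f"region {region!r} has no scored positions")
        means[region] = float(vals.mean())
    return means["monomer_core"] + means["interface_core"] - means["monomer_surface"]


def _decoy_matrices(ssm: SSMMatrix, n_decoys: int, rng) -> np.ndarray:
    """Decoy count tensors: non-native counts permuted among mutation cells."""
    native = ssm.native_mask()
    flat = ssm.counts[~native]
    decoys = np.empty((n_decoys,) + ssm.counts.shape)
    for k in range(n_decoys):
        shuffled = rng.permutation(flat)
        mat = ssm.counts.copy()
        mat[~native] = shuffled
        decoys[k] = mat
    return decoys


def entropy_pvalue(
    ssm: SSMMatrix, labels, n_decoys: int = 100, seed=0
) -> tuple[float, float, np.ndarray]:
    """P value of the entropy score against count-shuffled decoys.

    Returns (p_value, real_score, decoy_scores).  The decoys randomly
    reassign the observed counts among all SSM point mutations (native cells
    stay put), keeping experimental noise constant; p is the Normal CDF of
    the real score under the decoy mean/SD (low scores = conserved
    core/interface = small p).
    """
    if n_decoys < 2:
        raise SSMError("need at least 2 decoys")
    labels = validate_region_labels(labels, ssm.length)
    rng = np.random.default_rng(seed)
    real = entropy_score(positional_entropy(ssm), labels)
    decoys = _decoy_matrices(ssm, n_decoys, rng)
    scores = np.empty(n_decoys)
    for k in range(n_decoys):
        decoy = SSMMatrix(
            ssm.parent_design_id, ssm.parent_sequence, decoys[k], ssm.chosen_pool
        )
        scores[k] = entropy_score(positional_entropy(decoy), labels)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise SSMError("degenerate decoy null (zero variance)")
    p = float(norm.cdf((real - scores.mean()) / sd))
    return p, real, scores


# ---------------------------------------------------------------------------
# Folded-fraction model


def p_fold(
    dg_fold: float, dg_mutant_effect: float, kT: float = KT_300, form: str = "clipped_exp"
) -> float:
    """Probability the monomer is folded.

    ``clipped_exp`` (default): exp((dG_fold + dG_mutant_effect)/kT) clipped
    to (0, 1].  ``two_state``: 1 / (1 + exp(-(dG_fold + dG_mutant_effect)/kT)),
    the Boltzmann two-state alternative.  Stability convention: positive
    dG_fold = stable.
    """
    if kT <= 0:
        raise SSMError("kT must be > 0")
    dg = dg_fold + dg_mutant_effect
    if form == "clipped_exp":
        return float(min(1.0, math.exp(min(dg / kT, 0.0))))
    if form == "two_state":
        return float(1.0 / (1.0 + math.exp(-dg / kT)))
    raise SSMError(f"unknown p_fold form {form!r}")


def ddG_monomer_effect(p_native: float, p_mutant: float, kT: float = KT_300) -> float:
    """kT ln(P(fold)_native / P(fold)_mutant); antisymmetric, zero at equality."""
    if not (0 < p_native <= 1) or not (0 < p_mutant <= 1):
        raise SSMError("fold probabilities must be in (0, 1]")
    return float(kT * math.log(p_native / p_mutant))


def _predicted_ddg(
    dg_fold, ddg_monomer, ddg_interface, ddg_target, kT: float, form: str
) -> np.ndarray:
    """Vectorized predicted binding shift over (grid x mutations).

    The mutant stability effect is -ddg_monomer (a destabilizing mutation
    lowers the folding stability).
    """
    dg_fold = np.asarray(dg_fold, dtype=float).reshape(-1, 1)
    ddg_monomer = np.asarray(ddg_monomer, dtype=float).reshape(1, -1)
    if form == "clipped_exp":
        ln_p_nat = np.minimum(dg_fold / kT, 0.0)
        ln_p_mut = np.minimum((dg_fold - ddg_monomer) / kT, 0.0)
    elif form == "two_state":
        ln_p_nat = -np.log1p(np.exp(-dg_fold / kT))
        ln_p_mut = -np.log1p(np.exp(-(dg_fold - ddg_monomer) / kT))
    else:
        raise SSMError(f"unknown p_fold form {form!r}")
    monomer_effect = kT * (ln_p_nat - ln_p_mut)
    return monomer_effect + np.asarray(ddg_interface) + np.asarray(ddg_target)


@dataclass
class FoldModel:
    """Fitted folding stability of the native design."""

    dg_fold: float  # kcal/mol; NaN when censored
    dg_fold_ci: tuple[float, float]
    kT: float = KT_300
    rmse: float = math.nan
    censored: bool = False


def experimental_ddg(sc50_mut, sc50_parent: float, kT: float = KT_300):
    """Binding shift from SC50 ratio: kT ln(SC50_mut / SC50_parent)."""
    return kT * np.log(np.asarray(sc50_mut, dtype=float) / sc50_parent)


def fit_dG_fold(
    table: pd.DataFrame,
    kT: float = KT_300,
    grid=None,
    rmse_band: float = 0.25,
    min_mutations: int = 10,
    form: str = "clipped_exp",
) -> FoldModel:
    """Least-squares fit of the native folding stability.

    Uses all non-interface mutations with finite experimental shifts;
    the confidence interval contains every candidate whose RMSE is within
    ``rmse_band`` kcal/mol of the best.  Censored (NaN point, full-range CI)
    when too few mutations are usable.
    """
    if grid is None:
        grid = np.arange(-20.0, 20.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    usable = table[
        (~table["at_interface"].astype(bool))
        & np.isfinite(table["ddg_experimental"])
    ]
    if len(usable) < min_mutations:
        return FoldModel(
            math.nan, (float(grid[0]), float(grid[-1])), kT, math.nan, True
        )
    pred = _predicted_ddg(
        grid,
        usable["ddg_monomer"].to_numpy(),
        usable["ddg_interface"].to_numpy(),
        usable["ddg_target"].to_numpy(),
        kT,
        form,
    )
    resid = pred - usable["ddg_experimental"].to_numpy().reshape(1, -1)
    rmse = np.sqrt((resid**2).mean(axis=1))
    best = int(np.argmin(rmse))
    in_band = rmse <= rmse[best] + rmse_band
    ci = (float(grid[in_band][0]), float(grid[in_band][-1]))
    return FoldModel(float(grid[best]), ci, kT, float(rmse[best]), False)


# ---------------------------------------------------------------------------
# Accuracy score


@dataclass
class AccuracyResult:
    score: float
    p_value: float
    fold_model: FoldModel
    verdicts: pd.DataFrame
    decoy_scores: np.ndarray = field(repr=False, default=None)


def _mutation_score(
    table: pd.DataFrame,
    fold: FoldModel,
    buffer: float,
    kT: float,
    form: str,
) -> pd.DataFrame:
    scored = table[table["scored_region"]].copy()
    band = np.array([fold.dg_fold_ci[0], fold.dg_fold, fold.dg_fold_ci[1]])
    band = band[np.isfinite(band)]
    pred = _predicted_ddg(
        band,
        scored["ddg_monomer"].to_numpy(),
        scored["ddg_interface"].to_numpy(),
        scored["ddg_target"].to_numpy(),
        kT,
        form,
    )
    scored["pred_low"] = pred.min(axis=0)
    scored["pred_high"] = pred.max(axis=0)
    exp_low = scored.get("ddg_exp_low", scored["ddg_experimental"])
    exp_high = scored.get("ddg_exp_high", scored["ddg_experimental"])
    scored["explained"] = (scored["pred_low"] - buffer <= exp_high) & (
        exp_low <= scored["pred_high"] + buffer
    )
    return scored


def accuracy_score(
    table: pd.DataFrame,
    labels=None,
    buffer: float = 1.0,
    kT: float = KT_300,
    n_decoys: int = 100,
    seed=0,
    form: str = "clipped_exp",
    fold_model: FoldModel | None = None,
) -> AccuracyResult:
    """Fraction of core/interface-core mutations explained by the energies.

    ``table`` needs columns position, mutant_aa, ddg_monomer, ddg_interface,
    ddg_target, ddg_experimental (and optionally ddg_exp_low/ddg_exp_high
    interval bounds), plus either an ``at_interface`` boolean column and a
    ``region`` column, or per-position ``labels`` to derive them.  Mutations
    without a finite experimental value are skipped and reported.

    The decoy p-value shuffles the experimental values among mutations,
    refits dG_fold each time, and applies the Normal CDF (high real score =
    small p).
    """
    table = table.copy()
    if labels is not None:
        labels = list(labels)
        table["region"] = [labels[int(p) - 1] for p in table["position"]]
        if "at_interface" not in table:
            table["at_interface"] = table["region"] == "interface_core"
    if "region" not in table:
        raise SSMError("need a region column or explicit labels")
    table["scored_region"] = table["region"].isin(
        ("monomer_core", "interface_core")
    ) & np.isfinite(table["ddg_experimental"])
    table["skipped"] = table["region"].isin(
        ("monomer_core", "interface_core")
    ) & ~np.isfinite(table["ddg_experimental"])
    if table["scored_region"].sum() == 0:
        raise SSMError("no scorable core/interface-core mutations")

    if fold_model is None:
        fold_model = fit_dG_fold(table, kT=kT, form=form)
    verdicts = _mutation_score(table, fold_model, buffer, kT, form)
    score = float(verdicts["explained"].mean())

    rng = np.random.default_rng(seed)
    exp_cols = ["ddg_experimental"]
    for col in ("ddg_exp_low", "ddg_exp_high"):
        if col in table:
            exp_cols.append(col)
    decoy_scores = np.empty(n_decoys)
    for k in range(n_decoys):
        decoy = table.copy()
        perm = rng.permutation(len(decoy))
        for col in exp_cols:
            decoy[col] = decoy[col].to_numpy()[perm]
        decoy["scored_region"] = decoy["region"].isin(
            ("monomer_core", "interface_core")
        ) & np.isfinite(decoy["ddg_experimental"])
        decoy_fold = fit_dG_fold(decoy, kT=kT, form=form)
        decoy_scores[k] = _mutation_score(decoy, decoy_fold, buffer, kT, form)[
            "explained"
        ].mean()
    sd = decoy_scores.std(ddof=1)
    if sd == 0:
        p = 0.5 if score == decoy_scores.mean() else (0.0 if score > decoy_scores.mean() else 1.0)
    else:
        p = float(norm.sf((score - decoy_scores.mean()) / sd))
    return AccuracyResult(score, p, fold_model, verdicts, decoy_scores)
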