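# Methods

## The sorting binding model

A yeast cell displaying design *i* is collected in a FACS sort with
probability

    p_i = e_i · c / (c + SC50_i)

where *c* is the labelling concentration (nM), SC50_i the design's apparent
binding midpoint and e_i ∈ [0, 1] a per-design surface-expression constant.
The SC50 is deliberately *apparent*: the true titration curve has a
different shape and slope, and correcting it would rescale all SC50s by a
common factor without changing comparisons, so the package never claims to
estimate K_d. Avidity sorts (multivalent target–streptavidin labelling)
shift apparent affinities by an unknown amount; they are carried through the
data model with an `avidity` flag and are never combined with monovalent
sorts in any estimate.

## Grid/binomial SC50 estimation

Each sort contributes a binomial observation per design: *n* =
cells sorted, *x* = cells collected, both reconstructed from NGS
proportions and the sorter's totals:

* cells_collected_i = total cells collected × child-pool proportion;
* cells_sorted_i = cells fed × parent-pool proportion (so that x/n equals
  the per-sort point fraction `(child/parent) × FACS fraction`); when a
  design is absent from the parent pool the fallback
  cells_collected_i / FACS fraction is used and flagged.

For a candidate SC50 value *s*, the expected collected fraction is not a
point but a clipped band, because e_i is unknown:

    lower(s) = max(e_min · f(s), floor / n)      upper(s) = min(f(s), cap)

with f(s) = c/(c+s), e_min = 0.2 (the low end of the observed expression
range), cap = 0.2 (observed fractions above ~0.2 are saturating: they may
mean 90% collection of a weak expresser or 30% of a strong one), and
`floor` the passenger-cell floor described below. An observation inside the
band — or inside a clipped region (above the cap when the model saturates;
below the floor) — has probability 1; outside it, a two-sided binomial CDF
probability against the nearest band edge, p = min(1, 2·min(CDF, 1−CDF)).
The two-sided form is a conservative choice; the band makes the estimator
honest about expression rather than attributing the e_i attenuation to a
weaker SC50. Setting `expression_min = 1` collapses the band to the single
capped expectation.

Per-sort probabilities are multiplied across sorts under independence and
renormalized to maximum 1 over a log-spaced candidate grid (default 40
points from 0.01× the lowest to 100× the highest sort concentration). The
confidence interval spans all candidates with profile ≥ 0.05 of the
maximum (a ~95%-like band; configurable). The point estimate is the
log-midpoint of the maximal plateau; when the plateau touches a grid edge
the data only bound the SC50 from one side, so the bounded edge is reported
instead and the estimate is flagged `censored_low`/`censored_high`. All
computations use rounded cell counts; cell estimates are continuous
approximations, so sub-cell precision would be spurious.

The classification mode ("is SC50 below a reference s₀?") uses a single
sort chosen so the expected fraction at s₀ stays below the 0.2 cap, and
calls a design positive when its point fraction exceeds that expectation;
it refuses saturating configurations.

## Doubly transformed passengers

A non-binding plasmid co-transformed into a cell with a strong binder rides
through every sort at a greatly reduced absolute abundance. Assuming each
passenger arose from exactly one double-transformation event, its cell count
can never exceed

    floor = (cells_collected_imax / cells_sorted_R1_imax) × cell_copies_before_first_sort

where imax is the design with the most collected cells in the round being
analysed, its sorted-cell denominator is taken in round 1, and
cell_copies_before_first_sort = 2^(divisions before the first sort) is a
required experimental input. Designs below the floor in a given sort cannot
be distinguished from passengers there; the likelihood's floor clip makes
such observations uninformative, and a design below the floor in *every*
sort is flagged `passenger_suspect` and excluded from binder calls. This
trades sensitivity for specificity: poorly transformed true binders are
dropped, which is the intended behaviour.

## The simulator

The simulator exists so every estimator can be validated by parameter
recovery. Its defaults are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| designs | 200 | library scale at which per-design read depth (~5k reads) matches deep-sequenced pools |
| SC50 distribution | log-uniform 1–1000 nM, 30% non-binders | spans the sorted concentration range with mass outside it |
| expression e_i | Uniform[0.2, 0.7] | the observed range of the expression constant |
| sorts | 1000, 215, 46, 10 nM | four sorts spanning a 100-fold range |
| transformants/design | Poisson(625) | ×16 cell copies ≈ 1e4 cells/design entering round 1 |
| cell copies before sort 1 | 16 (2⁴ divisions) | a typical short outgrowth |
| reads/pool | 1e6 | deep-sequencing scale |
| regrowth between sorts | ×20, uniform | isolates estimator error from fitness differences |
| double-transform rate | 0 (tests use 0.05–0.1) | no generative model exists for the real frequency; the knob is a simulation convenience, not a claim |

Sorting is an exact binomial per design; passengers are paired cell-for-cell
with their carrier (hypergeometric draw of the carrier's collected cells);
NGS is a multinomial read draw proportional to cell counts. Avidity sorts
divide the effective SC50 by a labelled factor (default 10) — a synthetic
convenience, since the real mathematics of avidity is not established.

What the simulator does **not** model: FACS gating geometry, PCR
amplification bias, sequencing error, per-design growth differences, and
expression that varies between cells of one design. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to these real-data effects.

Recovery under these conditions (recomputed by the test suite, 200 seeds):
confidence intervals bracket the true SC50 for ≥ 90% of binders whose true
value lies inside the sorted concentration range, and ≥ 90% of point
estimates fall within 5-fold of truth — the documented fit variability of
the capped-expectation approach. Passengers fall below the per-pool floor
≥ 95% of the time while no simulated true binder is fully excluded.

## SSM entropy footprint

Per-position Shannon entropy (bits) is computed from amino-acid frequencies
in one SSM pool — the pool with concentration closest (in log space) to
one-tenth of the parent's SC50, where binding-competent variants are
enriched but not saturated. The footprint score is

    S_monomer_core + S_interface_core − S_monomer_surface

(mean per-position entropies of the three disjoint regions). A correctly
folded, correctly docked binder conserves its buried core and interface
while its exposed surface drifts, driving the score strongly negative. The
null distribution comes from 100 decoy datasets in which the observed
counts are randomly reassigned among all point-mutation cells (native cells
stay put), preserving the experimental noise structure; the p-value is the
Normal CDF of the real score under the decoy mean and SD. Positions with no
counts are NaN and excluded from region means.

## Energy-accuracy score

Monomer-destabilizing mutations affect binding only through the folded
fraction:

    P(fold) = exp((ΔG_fold + ΔG_mutant)/kT), clipped to ≤ 1
    ΔΔG_monomer = kT ln(P_native / P_mutant)
    ΔΔG_predicted = ΔΔG_monomer + ΔΔG_interface + ΔΔG_target

with kT fixed at 300 K (0.5962 kcal/mol). ΔG_fold uses the stability
convention (positive = stable), so the exponential saturates at 1 for
stable natives and a destabilization ΔΔG enters as ΔG_mutant = −ΔΔG; the
clipped exponential is equivalent to the two-state Boltzmann fraction in
its informative regime, and the exact two-state form
1/(1+exp(−ΔG/kT)) is selectable (`form="two_state"`). Energy components are
inputs (any forcefield); the package computes none of them.

ΔG_fold is unknown and is fitted by least squares over non-interface
mutations (≥ 10 required; otherwise the model is censored with a full-range
CI) against experimental shifts ΔΔG_exp = kT·ln(SC50_mut/SC50_parent) —
the standard thermodynamic reading of an SC50 ratio. The search grid is
−20 to +20 kcal/mol in 0.1 steps, wide enough that the reported CI (all
candidates within 0.25 kcal/mol RMSE of the best) is never clipped in
practice. A mutation is *explained* when the predicted interval (over the
ΔG_fold CI endpoints) and the experimental interval overlap within a
1 kcal/mol buffer; the accuracy score is the explained fraction over
monomer-core and interface-core mutations, with a 100-decoy
shuffled-experiment null (the fit is redone per decoy) and a Normal-CDF
p-value as above. Mutations without finite experimental values are skipped
and reported; censored SC50s can supply one-sided experimental bounds
through the interval columns without entering the least-squares fit.

## Dot surfaces and contact molecular surface

Molecular surfaces are Shrake–Rupley dot surfaces: each heavy atom carries
a quasi-uniform Fibonacci lattice of dots at radius r_vdw + probe (Bondi
radii; probe 1.4 Å; default density 5 dots/Å², minimum 32 dots/atom), each
dot owning area 4π(r+p)²/n, and dots inside any neighbour's expanded sphere
are discarded. Total dot area converges to the analytic solvent-accessible
area; the tests verify single spheres within 2% of the closed form and
sphere pairs within 3% of the spherical-cap formula.

The contact molecular surface downweights each binder surface element by
exp(−0.5·d²) of its distance to the nearest target element and sums the
weighted areas. Elements beyond 10 Å contribute < 1e−21 of their area and
are dropped by the KD-tree cutoff. Summation is over the binder side by
default — the quantity of interest is how much of the binder's contact
surface is genuinely engaged — with a symmetric mean mode available; exact
numeric parity with other implementations of the metric is not claimed, the
oracle checks here are the package's own closed forms.

## Interface selection, layers, RMSD protocols

Interface residues: binder residues with any target residue within a strict
Cβ–Cβ 8 Å cutoff (Cα substitutes for glycine; residues lacking both are
skipped with a warning). Burial layers use the angle-weighted side-chain
neighbour count (logistic distance term with 9 Å midpoint; squared angular
term about the Cα→Cβ direction; neighbours counted across the whole
complex) with the widely used thresholds core ≥ 5.2 and surface ≤ 2.0, both
configurable.

Three comparison protocols: (1) superimposed — Kabsch over the compared
atoms themselves, for unbound monomers; (2) target-aligned — Kabsch over
target Cα only, binder deviation measured without re-superposition, so the
binder's rigid-body placement error is included; (3) interface-core heavy —
the target-aligned protocol over heavy atoms of the interface∩core
selection, computed on the design model and applied to both structures.
Residue correspondence is positional for length-matched chains (identities
must agree) and exact-subsequence otherwise; anything unresolvable is an
error, never a silent drop. Altlocs are resolved to the highest-occupancy
conformer at parse time.

## Motif clustering

Motifs are maximal same-type secondary-structure segments (≥ 3 residues,
DSSP-style labels) whose summed binding energy passes a cutoff, expressed
in the shared target-aligned frame. Similarity is the TM-score sum
Σ 1/(1+(dᵢ/d₀)²) over Cα pairs at fixed frame (no superposition),
normalized by the shorter motif's length — which makes it symmetric — and
maximized over contiguous index offsets; d₀ follows the standard TM-score
length formula floored at 0.5 Å. Clustering is greedy: sort by total
energy (ties broken lexicographically, making the partition input-order
independent), take the lowest-energy unclustered motif as centre, absorb
everything within the 0.7 threshold of the centre, repeat. Membership is
measured against the centre only. Representatives minimize Σ w·E over
aligned positions, where members are anchored at their best offset against
the centre and w is the positive magnitude of the cluster-mean energy at
each position (favourable positions shared by many members count most);
with uniform weights this reduces to the plain lowest total energy. Ties
break by total energy, then input order; unanchorable members flag the
cluster and fall back to its centre.

## Predictor calibration and ranking

For each filter (a goal threshold on a final design metric, direction
`ge`/`le`), the calibration subset is binned into 20 equal-count bins of
the rapid metric (quantile edges; degenerate edges merge), and a
four-parameter logistic — floor and ceiling free in [0, 1], direction
auto-detected — is least-squares fitted to the per-bin pass fractions
weighted by bin counts. All-pass/all-fail calibrations degrade to a
constant with a warning. A candidate's final probability is the product of
per-filter probabilities — filters are treated as independent, a documented
approximation — and ranking is a stable descending sort with ties broken
by candidate id. No parity with any specific historical ranking is claimed;
the oracle tests check parameter recovery on synthetic logistic data and
enrichment of top-decile selections.

## Problem sizes in the test suite

The acceptance checks run 200 simulated screens of 200 designs for SC50
recovery, 20 screens for the passenger filter, 200 repetitions × 100
decoys for the entropy null calibration, 100 noisy simulations for the
folding-stability fit, and exact small fixtures for the geometry and
clustering oracles — sizes at which every binomial/multinomial population
is large enough for the claimed tolerances while the whole suite stays
fast. The crystal-structure benchmark comparisons additionally require
deposited PDB entries and published design-model coordinates that cannot be
redistributed with the package; with those files in
`tests/data/benchmarks/` the corresponding tests evaluate the three RMSD
protocols against their published values.

## Known limitations

* SC50s are apparent and scale-distorted; no expression-level estimation is
  attempted (it is ill-posed for weak binders).
* The product rule for combining per-sort probabilities assumes sort
  independence; shared upstream pools violate this mildly.
* The passenger floor assumes one double-transformation event per
  passenger plasmid.
* The dot surface is solvent-accessible (atom radius + probe); metrics that
  depend on the molecular (solvent-excluded) manifold proper will differ by
  a systematic, probe-dependent amount.
* Burial thresholds and the neighbour-count functional form are
  conventions; classifications near the thresholds are sensitive to them.
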