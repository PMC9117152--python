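"""Interface selection, burial layers, and design-vs-crystal RMSD protocols.

Three comparison protocols are used for designed binder/target complexes:

* ``rmsd_superimposed`` -- least-squares (Kabsch) superposition over the
  compared atoms themselves; the protocol for unbound monomer structures.
* ``rmsd_target_aligned`` -- the complex protocol: superpose on the target
  chains only, then measure the binder deviation without re-superposition,
  so rigid-body errors of the binder placement are included.
* ``interface_core_heavy_rmsd`` -- target-aligned RMSD over the heavy atoms
  of the interface-core residues (binder residues both contacting the target
  and buried), with the selection computed on the design model and applied
  to both structures.

Interface residues are binder residues with any target residue within an
8 A Cb-Cb distance (Ca substitutes for glycine).  Burial layers
(core/boundary/surface) use the side-chain-neighbour count: neighbours are
weighted by a logistic distance term and a squared angular term around the
Ca->Cb direction, with the widely used thresholds core >= 5.2 and
surface <= 2.0 (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Residue geometry helpers


def _residues(chain):
    return [r for r in chain if "CA" in r]


def cb_coord(residue) -> np.ndarray | None:
    """Cb coordinate; Ca for glycine; None when neither atom exists."""
    if "CB" in residue:
        return np.asarray(residue["CB"].coord, dtype=float)
    if "CA" in residue:
        return np.asarray(residue["CA"].coord, dtype=float)
    return None


def _pseudo_cb_direction(residue) -> np.ndarray | None:
    """Unit vector from Ca toward the side chain (ideal direction for Gly)."""
    if "CA" not in residue:
        return None
    ca = np.asarray(residue["CA"].coord, dtype=float)
    if "CB" in residue:
        v = np.asarray(residue["CB"].coord, dtype=float) - ca
    elif "N" in residue and "C" in residue:
        n = np.asarray(residue["N"].coord, dtype=float)
        c = np.asarray(residue["C"].coord, dtype=float)
        v = (ca - n) + (ca - c)
    else:
        return None
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else None


# ---------------------------------------------------------------------------
# Interface residues and burial layers


@dataclass
class InterfaceSelection:
    """Binder residues contacting the target, with burial layers."""

    residue_ids: list
    layers: dict  # residue id -> "core" | "boundary" | "surface"

    def core_residue_ids(self) -> list:
        return [r for r in self.residue_ids if self.layers.get(r) == "core"]


def interface_residues(model, binder_chain: str, target_chains, cb_cutoff: float = 8.0):
    """Binder residues with any target residue within the Cb-Cb cutoff (strict <)."""
    if isinstance(target_chains, str):
        target_chains = [target_chains]
    target_cbs = []
    for chain_id in target_chains:
        for res in _residues(model[chain_id]):
            cb = cb_coord(res)
            if cb is not None:
                target_cbs.append(cb)
    if not target_cbs:
        raise ComparisonError(f"no usable residues in target chains {target_chains}")
    target_cbs = np.array(target_cbs)
    selected = []
    for res in _residues(model[binder_chain]):
        cb = cb_coord(res)
        if cb is None:
            warnings.warn(f"residue {res.id} lacks Cb/Ca; skipped")
            continue
        d2 = np.sum((target_cbs - cb) ** 2, axis=1)
        if np.any(d2 < cb_cutoff**2):
            selected.append(res.id)
    return selected


def sidechain_neighbor_counts(model, chain_id: str, context_chains=None) -> dict:
    """Angle-weighted neighbour count per residue (burial measure).

    Neighbours are taken from ``context_chains`` (default: every chain in
    the model), so burial at an interface counts the partner molecule too.
    """
    if context_chains is None:
        context_chains = [c.id for c in model]
    residues = _residues(model[chain_id])
    context = [
        (chain_id_ctx, r)
        for chain_id_ctx in context_chains
        for r in _residues(model[chain_id_ctx])
    ]
    cas = np.array([r["CA"].coord for _, r in context], dtype=float)
    counts: dict = {}
    for res in residues:
        u = _pseudo_cb_direction(res)
        if u is None:
            counts[res.id] = 0.0
            continue
        origin = cb_coord(res)
        total = 0.0
        for j, (ctx_chain, ctx_res) in enumerate(context):
            if ctx_chain == chain_id and ctx_res.id == res.id:
                continue
            v = cas[j] - origin
            d = np.linalg.norm(v)
            if d < 1e-9:
                continue
            dist_term = 1.0 / (1.0 + np.exp(d - 9.0))
            cos_angle = float(np.dot(u, v / d))
            if cos_angle <= -0.5:
                continue
            angle_term = ((cos_angle + 0.5) / 1.5) ** 2
            total += dist_term * angle_term
        counts[res.id] = total
    return counts


def layer_classify(
    model,
    chain_id: str,
    core_cutoff: float = 5.2,
    surface_cutoff: float = 2.0,
    context_chains=None,
) -> dict:
    """Partition a chain's residues into core/boundary/surface by burial.

    Burial counts neighbours from ``context_chains`` (default: the whole
    model), so interface residues buried against the partner classify as
    core.
    """
    counts = sidechain_neighbor_counts(model, chain_id, context_chains)
    layers = {}
    for res_id, value in counts.items():
        if value >= core_cutoff:
            layers[res_id] = "core"
        elif value <= surface_cutoff:
            layers[res_id] = "surface"
        else:
            layers[res_id] = "boundary"
    return layers


def select_interface(
    model, binder_chain: str, target_chains, cb_cutoff: float = 8.0
) -> InterfaceSelection:
    ids = interface_residues(model, binder_chain, target_chains, cb_cutoff)
    layers = layer_classify(model, binder_chain)
    return InterfaceSelection(ids, {r: layers[r] for r in ids if r in layers})


# ---------------------------------------------------------------------------
# Residue correspondence


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def pair_residues(chain_a, chain_b) -> list[tuple]:
    """Pair residues of two chains.

    Length-matched chains pair in order (residue names must agree);
    otherwise the shorter sequence must occur exactly within the longer.
    Unresolvable correspondences raise, listing the mismatches.
    """
    res_a = _residues(chain_a)
    res_b = _residues(chain_b)
    if len(res_a) == len(res_b):
        mismatches = [
            (a.get_resname(), a.id, b.get_resname(), b.id)
            for a, b in zip(res_a, res_b)
            if a.get_resname() != b.get_resname()
        ]
        if mismatches:
            raise ComparisonError(f"residue identity mismatches: {mismatches}")
        return list(zip(res_a, res_b))
    seq_a = "".join(_THREE_TO_ONE.get(r.get_resname(), "X") for r in res_a)
    seq_b = "".join(_THREE_TO_ONE.get(r.get_resname(), "X") for r in res_b)
    if len(seq_a) < len(seq_b):
        offset = seq_b.find(seq_a)
        if offset < 0:
            raise ComparisonError(
                f"no exact sequence correspondence: {seq_a} vs {seq_b}"
            )
        return list(zip(res_a, res_b[offset : offset + len(res_a)]))
    offset = seq_a.find(seq_b)
    if offset < 0:
        raise ComparisonError(
            f"no exact sequence correspondence: {seq_a} vs {seq_b}"
        )
    return list(zip(res_a[offset : offset + len(res_b)], res_b))


def _atom_coords(pairs, atom_set) -> tuple[np.ndarray, np.ndarray]:
    """Matched coordinate arrays for a list of residue pairs.

    ``atom_set``: "CA" for alpha carbons, "heavy" for all shared
    non-hydrogen atoms (matched by atom name).
    """
    xs, ys = [], []
    for res_a, res_b in pairs:
        if atom_set == "CA":
            names = ["CA"]
        elif atom_set == "heavy":
            names_a = {a.get_name() for a in res_a if a.element != "H"}
            names_b = {a.get_name() for a in res_b if a.element != "H"}
            names = sorted(names_a & names_b)
        else:
            names = list(atom_set)
        for name in names:
            if name in res_a and name in res_b:
                xs.append(res_a[name].coord)
                ys.append(res_b[name].coord)
    if not xs:
        raise ComparisonError("no matched atoms")
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


# ---------------------------------------------------------------------------
# RMSD protocols


def _kabsch(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``moving`` onto ``fixed``."""
    sup = SVDSuperimposer()
    sup.set(fixed, moving)
    sup.run()
    return sup.get_rotran()


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_superimposed(model_a, model_b, chain_map: dict, atom_set="CA") -> float:
    """RMSD after Kabsch superposition over the compared atoms themselves."""
    pairs = []
    for chain_a_id, chain_b_id in chain_map.items():
        pairs.extend(pair_residues(model_a[chain_a_id], model_b[chain_b_id]))
    coords_a, coords_b = _atom_coords(pairs, atom_set)
    rot, tran = _kabsch(coords_a, coords_b)
    return _rmsd(coords_a, coords_b @ rot + tran)


def rmsd_target_aligned(
    design_model,
    crystal_model,
    target_chain_map: dict,
    binder_chain_map: dict,
    atom_set="CA",
    binder_pairs=None,
) -> float:
    """Superpose on the target chains, then RMSD over binder atoms as placed.

    No re-superposition of the binder: deviations include its rigid-body
    placement error relative to the target.
    """
    target_pairs = []
    for d_chain, c_chain in target_chain_map.items():
        target_pairs.extend(
            pair_residues(design_model[d_chain], crystal_model[c_chain])
        )
    t_design, t_crystal = _atom_coords(target_pairs, "CA")
    rot, tran = _kabsch(t_design, t_crystal)

    if binder_pairs is None:
        binder_pairs = []
        for d_chain, c_chain in binder_chain_map.items():
            binder_pairs.extend(
                pair_residues(design_model[d_chain], crystal_model[c_chain])
            )
    b_design, b_crystal = _atom_coords(binder_pairs, atom_set)
    return _rmsd(b_design, b_crystal @ rot + tran)


def interface_core_heavy_rmsd(
    design_model,
    crystal_model,
    target_chain_map: dict,
    binder_chain_map: dict,
    cb_cutoff: float = 8.0,
) -> tuple[float, int]:
    """Target-aligned heavy-atom RMSD over the interface-core residues.

    The selection (interface residues within the Cb-Cb cutoff on the design
    model, intersected with its core burial layer) is computed on the design
    model and applied to both structures.  Returns (rmsd, residue count).
    """
    (binder_chain, crystal_binder_chain), = binder_chain_map.items()
    selection = select_interface(
        design_model, binder_chain, list(target_chain_map), cb_cutoff
    )
    core_ids = set(selection.core_residue_ids())
    if not core_ids:
        raise ComparisonError("empty interface-core selection")
    pairs = [
        (a, b)
        for a, b in pair_residues(
            design_model[binder_chain], crystal_model[crystal_binder_chain]
        )
        if a.id in core_ids
    ]
    if not pairs:
        raise ComparisonError("interface-core residues have no correspondence")
    rmsd = rmsd_target_aligned(
        design_model,
        crystal_model,
        target_chain_map,
        binder_chain_map,
        atom_set="heavy",
        binder_pairs=pairs,
    )
    return rmsd, len(pairs)
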