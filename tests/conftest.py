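"""Shared fixtures: programmatic toy structures and motif factories."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.PDB.StructureBuilder import StructureBuilder
from hypothesis import settings

from binderscreen.motifs import Motif

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def build_structure(chains: dict):
    """Build a Bio.PDB structure from a chain spec.

    ``chains`` maps chain id to a list of residues; each residue is
    (resname, [(atom_name, element, (x, y, z)), ...]).
    """
    builder = StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    for chain_id, residues in chains.items():
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        for i, (resname, atoms) in enumerate(residues, start=1):
            builder.init_residue(resname, " ", i, " ")
            for name, element, coord in atoms:
                builder.init_atom(
                    name,
                    np.array(coord, dtype=float),
                    0.0,
                    1.0,
                    " ",
                    name.center(4),
                    element=element,
                )
    return builder.get_structure()


def backbone_residue(resname, ca, cb_dir=(0.0, 1.5, 0.0), with_cb=True):
    """A residue with N/CA/C (and optionally CB) around a Ca position."""
    ca = np.asarray(ca, dtype=float)
    atoms = [
        ("N", "N", tuple(ca + [-1.2, 0.8, 0.0])),
        ("CA", "C", tuple(ca)),
        ("C", "C", tuple(ca + [1.2, 0.8, 0.0])),
        ("O", "O", tuple(ca + [1.6, 1.9, 0.0])),
    ]
    if with_cb and resname != "GLY":
        atoms.append(("CB", "C", tuple(ca + np.asarray(cb_dir, dtype=float))))
    return (resname, atoms)


def extended_chain(n_residues: int, resname="ALA", spacing=3.8, z=0.0):
    """An extended peptide along x with alternating side-chain directions."""
    residues = []
    for i in range(n_residues):
        direction = (0.0, 1.5 if i % 2 == 0 else -1.5, 0.0)
        residues.append(
            backbone_residue(resname, (spacing * i, 0.0, z), direction)
        )
    return residues


@pytest.fixture
def toy_complex():
    """Two-chain complex: 6-residue binder near a 8-residue target."""
    binder = extended_chain(6, z=0.0)
    target = [
        backbone_residue("LEU", (3.8 * i, 5.0, 0.0), (0.0, -1.5, 0.0))
        for i in range(8)
    ]
    return build_structure({"A": binder, "B": target})


def make_motif(motif_id, ca_positions, energies=None, source="d0", segment="helix"):
    """Motif from Ca positions; N/C placed at fixed offsets."""
    ca = np.asarray(ca_positions, dtype=float)
    backbone = np.stack(
        [ca + [-1.0, 0.5, 0.0], ca, ca + [1.0, 0.5, 0.0]], axis=1
    )
    if energies is None:
        energies = -np.ones(len(ca))
    return Motif(motif_id, backbone, np.asarray(energies, dtype=float), source, segment)
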