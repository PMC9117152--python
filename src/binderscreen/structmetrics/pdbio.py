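"""PDB reading/writing with altloc resolution.

Thin wrappers over Bio.PDB: structures are parsed into standard Biopython
``Structure`` objects with alternate locations resolved to the
highest-occupancy conformer, so downstream geometry sees exactly one
location per atom.
"""

from __future__ import annotations

from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Atom import DisorderedAtom
from Bio.PDB.Structure import Structure


class PDBFormatError(ValueError):
    pass


def resolve_altlocs(structure: Structure) -> Structure:
    """Keep only the highest-occupancy conformer of every disordered atom."""
    for model in structure:
        for chain in model:
            for residue in list(chain):
                if residue.is_disordered() == 2:
                    # disordered residue (point mutation): keep selected child
                    selected = residue.selected_child
                    chain.detach_child(residue.id)
                    selected.id = residue.id
                    selected.disordered_flag = 0
                    chain.add(selected)
            for residue in chain:
                for atom in list(residue):
                    if isinstance(atom, DisorderedAtom):
                        best = max(
                            atom.disordered_get_list(),
                            key=lambda a: (a.get_occupancy() or 0.0),
                        )
                        residue.detach_child(atom.get_id())
                        best.disordered_flag = 0
                        best.set_altloc(" ")
                        residue.add(best)
    return structure


def read_pdb(path, structure_id: str = "model") -> Structure:
    """Parse a PDB file; altlocs resolved to the highest-occupancy conformer."""
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(structure_id, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise PDBFormatError(f"{path}: {exc}") from exc
    return resolve_altlocs(structure)


def write_pdb(structure: Structure, path) -> None:
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))


def heavy_atoms(entity):
    """Non-hydrogen atoms of a structure/model/chain/residue."""
    return [a for a in entity.get_atoms() if a.element != "H"]
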