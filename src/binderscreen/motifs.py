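"""Interface-motif extraction, TM-like clustering and representative selection.

During a focused design search, continuous secondary-structure segments
(helix, strand, loop) that interact favourably with the target are extracted
from a first round of designs, all expressed in a shared target-aligned
frame.  Motifs are clustered greedily: sort by total binding energy, take
the lowest-energy unclustered motif as a cluster centre, sweep in every
unclustered motif whose fixed-frame TM-style similarity to the centre
reaches a threshold (default 0.7), and repeat until the pool is empty.
Because the frame is shared, similarity needs no superposition.

The similarity of two motifs is the TM-score sum 1/(1 + (d_i/d0)^2) over
aligned Ca positions divided by the length of the shorter motif, maximized
over contiguous index offsets; d0 follows the standard TM-score length
formula floored at 0.5 A.  Normalizing by the shorter length makes the score
symmetric.

Cluster representatives are chosen by per-position weighted energy: the
weight at each aligned position is the cluster-mean energy there, and the
representative minimizes the weighted sum (favourable positions shared by
many members count most).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_TYPES = ("helix", "strand", "loop")
_SS_TO_TYPE = {"H": "helix", "G": "helix", "I": "helix", "E": "strand", "B": "strand"}


class MotifError(ValueError):
    pass


@dataclass
class Motif:
    """A continuous secondary-structure segment in the target-aligned frame.

    ``backbone``: (L, 3, 3) N/Ca/C coordinates; ``energies``: per-position
    binding energies (kcal/mol, favourable negative).
    """

    motif_id: str
    backbone: np.ndarray
    energies: np.ndarray
    source_design: str = ""
    segment_type: str = "loop"

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.backbone.ndim != 3 or self.backbone.shape[1:] != (3, 3):
            raise MotifError("backbone must have shape (L, 3, 3)")
        if len(self) < 3:
            raise MotifError("motifs need at least 3 residues")
        if len(self.energies) != len(self):
            raise MotifError("energies length must match residue count")
        if self.segment_type not in SEGMENT_TYPES:
            raise MotifError(f"unknown segment type {self.segment_type!r}")

    def __len__(self) -> int:
        return self.backbone.shape[0]

    @property
    def ca(self) -> np.ndarray:
        return self.backbone[:, 1, :]

    @property
    def total_energy(self) -> float:
        return float(self.energies.sum())


def extract_motifs(
    per_residue_energies,
    backbone,
    secondary_structure: str,
    min_len: int = 3,
    energy_cutoff: float = -1.0,
    source_design: str = "",
) -> list[Motif]:
    """Maximal same-type secondary-structure segments passing the energy cutoff.

    ``secondary_structure`` is a DSSP-style string (H/G/I helix, E/B strand,
    everything else loop).  A segment qualifies when its summed binding
    energy is at or below ``energy_cutoff``.  No qualifying segment is not
    an error: the result is simply empty.
    """
    energies = np.asarray(per_residue_energies, dtype=float)
    backbone = np.asarray(backbone, dtype=float)
    if len(secondary_structure) != len(energies) or backbone.shape[0] != len(energies):
        raise MotifError("energies, backbone and secondary structure must align")
    types = [_SS_TO_TYPE.get(c, "loop") for c in secondary_structure.upper()]
    motifs: list[Motif] = []
    start = 0
    for end in range(1, len(types) + 1):
        if end == len(types) or types[end] != types[start]:
            length = end - start
            total = energies[start:end].sum()
            if length >= min_len and total <= energy_cutoff:
                motifs.append(
                    Motif(
                        f"{source_design}:{start}-{end - 1}",
                        backbone[start:end],
                        energies[start:end],
                        source_design,
                        types[start],
                    )
                )
            start = end
    return motifs


def tm_d0(length: int) -> float:
    """Standard TM-score distance scale, floored at 0.5 A."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _offset_scores(short_ca: np.ndarray, long_ca: np.ndarray) -> np.ndarray:
    """TM-style score of the shorter motif at every contiguous offset."""
    ls, ll = len(short_ca), len(long_ca)
    d0 = tm_d0(ls)
    scores = np.empty(ll - ls + 1)
    for off in range(ll - ls + 1):
        d2 = np.sum((short_ca - long_ca[off : off + ls]) ** 2, axis=1)
        scores[off] = np.mean(1.0 / (1.0 + d2 / d0**2))
    return scores


def motif_similarity(a: Motif, b: Motif) -> float:
    """Fixed-frame TM-style similarity in [0, 1]; 1 for identical motifs.

    Both motifs must already live in the shared target-aligned frame; no
    superposition is performed.  Normalized by the shorter length and
    maximized over contiguous index offsets, hence symmetric.
    """
    if len(a) <= len(b):
        return float(_offset_scores(a.ca, b.ca).max())
    return float(_offset_scores(b.ca, a.ca).max())


def _best_offset(member: Motif, centre: Motif) -> tuple[int, int]:
    """(member_start, centre_start) anchoring the member onto the centre."""
    if len(member) <= len(centre):
        off = int(np.argmax(_offset_scores(member.ca, centre.ca)))
        return 0, off
    off = int(np.argmax(_offset_scores(centre.ca, member.ca)))
    return off, 0


@dataclass
class MotifCluster:
    centre: Motif
    members: list[Motif]
    flagged: bool = False


@dataclass
class MotifClustering:
    clusters: list[MotifCluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)


def _energy_order(motifs: list[Motif]) -> list[Motif]:
    return sorted(motifs, key=lambda m: (m.total_energy, m.source_design, m.motif_id))


def cluster_motifs(motifs: list[Motif], threshold: float = 0.7) -> MotifClustering:
    """Greedy energy-sorted clustering.

    The lowest-energy unclustered motif becomes a cluster centre; every
    unclustered motif within the similarity threshold of the centre joins
    and is removed from the pool; repeat until the pool is empty.  Ties in
    energy break lexicographically, so the partition is independent of the
    input order.
    """
    pool = _energy_order(motifs)
    clusters: list[MotifCluster] = []
    while pool:
        centre = pool[0]
        members = [m for m in pool if motif_similarity(centre, m) >= threshold]
        member_set = {id(m) for m in members}
        if id(centre) not in member_set:  # self-similarity is 1; defensive
            members.insert(0, centre)
            member_set.add(id(centre))
        pool = [m for m in pool if id(m) not in member_set]
        clusters.append(MotifCluster(centre, members))
    return MotifClustering(clusters, threshold)


def select_representatives(clustering: MotifClustering) -> list[Motif]:
    """Per-cluster representative by per-position weighted energy.

    Members are anchored on the centre at their best fixed-frame offset;
    the weight at each centre position is the mean member energy there,
    and the representative minimizes sum(weight * energy) over its aligned
    positions.  Ties break by total energy, then member order.  Clusters
    whose members cannot be anchored fall back to the centre (flagged).
    """
    representatives: list[Motif] = []
    for cluster in clustering.clusters:
        centre = cluster.centre
        lc = len(centre)
        try:
            aligned: list[tuple[Motif, int, int, int]] = []
            for member in cluster.members:
                m_start, c_start = _best_offset(member, centre)
                overlap = min(len(member) - m_start, lc - c_start)
                if overlap <= 0:
                    raise MotifError("no positional overlap with centre")
                aligned.append((member, m_start, c_start, overlap))
            sums = np.zeros(lc)
            counts = np.zeros(lc)
            for member, m_start, c_start, overlap in aligned:
                sums[c_start : c_start + overlap] += member.energies[
                    m_start : m_start + overlap
                ]
                counts[c_start : c_start + overlap] += 1
            # favourable (negative) mean energies become positive weights so
            # the argmin rewards members that are strong where the cluster is
            # strong; with uniform weights this reduces to the plain total
            weights = np.where(counts > 0, -sums / np.maximum(counts, 1), 0.0)
            weights = np.maximum(weights, 0.0)
            best = None
            for order, (member, m_start, c_start, overlap) in enumerate(aligned):
                weighted = float(
                    np.dot(
                        weights[c_start : c_start + overlap],
                        member.energies[m_start : m_start + overlap],
                    )
                )
                key = (weighted, member.total_energy, order)
                if best is None or key < best[0]:
                    best = (key, member)
            representatives.append(best[1])
        except MotifError:
            cluster.flagged = True
            representatives.append(centre)
    return representatives
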