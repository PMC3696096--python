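"""Protein structure network (residue interaction network) construction.

Nodes are amino-acid residues; an edge joins two residues that make at least
one non-covalent heavy-atom contact within a distance cutoff (default 4.0 Å).
The edge weight is the inverse of the arithmetic mean distance over the
qualifying atom pairs, so tighter contacts weigh more; weights are therefore
always at least 1/cutoff.  The backbone peptide bond C(i)–N(i+1) is a
covalent contact and never counts; intra-residue pairs would be self-loops
and are excluded by construction.  Residues with no contacts at all are
dropped from the network.

Hydrogens are excluded from the contact search: the construction is the
conventional heavy-atom residue interaction network, so structures with and
without explicit hydrogens yield the same graph.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .netio import Network

__all__ = ["ResidueRecord", "StructureModel", "read_structure", "build_psn"]


@dataclass
class ResidueRecord:
    """One residue: identity plus its heavy-atom names and coordinates (Å)."""

    chain: str
    seq: int
    icode: str
    name: str
    atom_names: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def label(self) -> str:
        """Stable node label ``chain:seq[icode]:name``."""
        ic = self.icode.strip()
        return f"{self.chain}:{self.seq}{ic}:{self.name}"


@dataclass
class StructureModel:
    """Ordered residues of one model, heavy atoms only."""

    residues: list[ResidueRecord]

    def __len__(self) -> int:
        return len(self.residues)


def read_structure(text: str, chain: str | None = None) -> StructureModel:
    """Parse a PDB document into a heavy-atom :class:`StructureModel`.

    Only standard-residue ATOM records are kept (waters and ligands are
    skipped), hydrogens (and deuteriums) are filtered out, alternate
    locations resolve to the highest-occupancy conformer (first on a tie),
    and insertion codes stay part of the residue identity.  An optional
    chain filter restricts the model to one chain.

    Raises
    ------
    ValueError
        If the document yields no usable ATOM records.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", io.StringIO(text))
    residues: list[ResidueRecord] = []
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                hetflag, seq, icode = res.get_id()
                if hetflag.strip():  # HETATM (waters, ligands)
                    continue
                names, xyz = [], []
                for atom in res:
                    # DisorderedAtom.get_unpacked_list()[...] lists altlocs;
                    # the selected child is the highest-occupancy conformer
                    if atom.element in ("H", "D"):
                        continue
                    if not np.all(np.isfinite(atom.coord)):
                        raise ValueError(
                            f"non-finite coordinates on atom {atom.get_full_id()}"
                        )
                    names.append(atom.get_name())
                    xyz.append(atom.coord)
                if names:
                    residues.append(
                        ResidueRecord(
                            chain=ch.id,
                            seq=int(seq),
                            icode=icode,
                            name=res.get_resname().strip(),
                            atom_names=names,
                            coords=np.asarray(xyz, dtype=float),
                        )
                    )
        break  # first model only (NMR/MD multi-model files)
    if not residues:
        raise ValueError("no usable ATOM records in document")
    return StructureModel(residues=residues)


def _covalent_peptide_pair(
    res_a: ResidueRecord, name_a: str, res_b: ResidueRecord, name_b: str
) -> bool:
    """Is (atom a, atom b) the backbone C(i)-N(i+1) peptide bond?"""
    if res_a.chain != res_b.chain:
        return False
    if res_b.seq == res_a.seq + 1 and name_a == "C" and name_b == "N":
        return True
    if res_a.seq == res_b.seq + 1 and name_b == "C" and name_a == "N":
        return True
    return False


def build_psn(model: StructureModel, cutoff: float = 4.0) -> Network:
    """Build the residue interaction network at the given contact cutoff (Å).

    For every residue pair, heavy-atom pairs within ``cutoff`` qualify as
    contacts (excluding the covalent peptide-bond C–N pair between sequence
    neighbors); residues joined by at least one contact get an edge of
    weight 1 / mean(qualifying distances).  Contact-free residues are
    dropped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(model) < 2:
        raise ValueError("need at least 2 residues")
    coords = np.vstack([r.coords for r in model.residues])
    atom_res = np.concatenate(
        [np.full(len(r.coords), i, dtype=np.intp) for i, r in enumerate(model.residues)]
    )
    atom_idx = np.concatenate(
        [np.arange(len(r.coords), dtype=np.intp) for r in model.residues]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    # accumulate qualifying distances per residue pair
    sums: dict[tuple[int, int], list[float]] = {}
    for a, b in pairs:
        ra, rb = int(atom_res[a]), int(atom_res[b])
        if ra == rb:
            continue  # intra-residue contacts are self-loops
        res_a, res_b = model.residues[ra], model.residues[rb]
        name_a = res_a.atom_names[atom_idx[a]]
        name_b = res_b.atom_names[atom_idx[b]]
        if _covalent_peptide_pair(res_a, name_a, res_b, name_b):
            continue
        d = float(np.linalg.norm(coords[a] - coords[b]))
        key = (min(ra, rb), max(ra, rb))
        sums.setdefault(key, []).append(d)
    # keep only residues participating in at least one contact
    used = sorted({i for key in sums for i in key})
    labels = [model.residues[i].label for i in used]
    edges = [
        (
            model.residues[ra].label,
            model.residues[rb].label,
            1.0 / float(np.mean(dists)),
        )
        for (ra, rb), dists in sorted(sums.items())
    ]
    return Network(labels, edges)
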