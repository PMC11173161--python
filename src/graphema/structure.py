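"""Parsing multimeric model structures and building residue contact graphs.

A structure is reduced to backbone + CB coordinates per residue. The
residue-level contact graph connects any two residues whose representative
atoms (CB, or CA for glycine) are within a distance cutoff, 8 A by default.
Residues with at least one cross-chain neighbour under the same cutoff are
interface residues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import virtual_cb

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical by three-letter code. This
#: ordering also fixes the one-hot feature layout.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: Common non-standard residues mapped to their standard parent.
NONSTANDARD_MAP: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "MLY": "LYS",
    "CSO": "CYS", "PTR": "TYR", "SEP": "SER", "TPO": "THR",
    "HSD": "HIS", "HSE": "HIS", "HIE": "HIS", "HID": "HIS", "HIP": "HIS",
}

_WATER = {"HOH", "WAT", "DOD"}
_BACKBONE = ("N", "CA", "C")


class StructureError(ValueError):
    """Raised for unreadable or unusable structure input."""


@dataclass
class ResidueRecord:
    """One residue: identity plus named atom coordinates in Angstrom."""

    chain_id: str
    seq_pos: int
    aa: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def rep_coord(self) -> np.ndarray:
        """Representative position: CB, except CA for glycine."""
        if self.aa == "GLY":
            return self.atoms["CA"]
        if "CB" in self.atoms:
            return self.atoms["CB"]
        return self.cb_coord()

    def cb_coord(self) -> np.ndarray:
        """CB coordinate; an ideal-geometry virtual CB when absent (incl. GLY)."""
        if "CB" in self.atoms:
            return self.atoms["CB"]
        try:
            return virtual_cb(self.atoms["N"], self.atoms["CA"], self.atoms["C"])
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise StructureError(
                f"residue {self.chain_id}{self.seq_pos} lacks CB and a complete "
                f"backbone to construct one"
            ) from exc


@dataclass
class ComplexStructure:
    """A (multi-chain) model: ordered chains of ordered residues."""

    model_id: str
    chains: list[tuple[str, list[ResidueRecord]]]

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def residues(self) -> list[ResidueRecord]:
        """All residues flattened in chain order, then sequence order."""
        out: list[ResidueRecord] = []
        for _, res in self.chains:
            out.extend(res)
        return out


def representative_atom(r: ResidueRecord) -> np.ndarray:
    """Representative coordinate of a residue (CB; CA for glycine)."""
    if "CA" not in r.atoms:
        raise StructureError(f"residue {r.chain_id}{r.seq_pos} lacks CA")
    return r.rep_coord()


def _pick_atom(res: gemmi.Residue, name: str) -> np.ndarray | None:
    # prefer blank altloc, then 'A'; gemmi stores blank altloc as '\x00' or ''
    best = None
    for atom in res:
        if atom.name != name:
            continue
        alt = atom.altloc
        if alt in ("", "\x00"):
            best = atom
            break
        if alt == "A" and best is None:
            best = atom
    if best is None:
        return None
    p = best.pos
    return np.array([p.x, p.y, p.z], dtype=float)


def parse_structure(path: str | Path, dialect: str = "pdb") -> ComplexStructure:
    """Read the first model of a PDB file into a :class:`ComplexStructure`.

    Water and unmappable hetero records are excluded; residues missing any
    of N/CA/C are dropped with a warning. Raises :class:`StructureError`
    for unreadable files or files with no usable residues.
    """
    if dialect != "pdb":
        raise StructureError(f"unsupported structure dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    model = st[0]
    chains: list[tuple[str, list[ResidueRecord]]] = []
    for chain in model:
        records: list[ResidueRecord] = []
        for res in chain:
            name = res.name.strip().upper()
            if name in _WATER:
                continue
            aa = name if name in AA_INDEX else NONSTANDARD_MAP.get(name)
            if aa is None:
                logger.warning("%s: dropping unmappable residue %s %s%s",
                               path.name, name, chain.name, res.seqid.num)
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom_name in ("N", "CA", "C", "O", "CB"):
                coord = _pick_atom(res, atom_name)
                if coord is not None:
                    atoms[atom_name] = coord
            if any(a not in atoms for a in _BACKBONE):
                logger.warning("%s: dropping residue %s%s with incomplete backbone",
                               path.name, chain.name, res.seqid.num)
                continue
            records.append(ResidueRecord(chain.name, res.seqid.num, aa, atoms))
        if records:
            chains.append((chain.name, records))
    if not chains:
        raise StructureError(f"{path}: no usable residues")
    return ComplexStructure(model_id=path.stem, chains=chains)


@dataclass
class ResidueGraph:
    """Residue contact graph over a complex.

    ``edges`` holds each undirected contact once as (i, j) with i < j on
    the flattened 0-based residue index. ``interface_mask`` marks residues
    with at least one cross-chain contact.
    """

    n_nodes: int
    chain_index: np.ndarray        # (n,) int, chain ordinal per node
    rep_coords: np.ndarray         # (n, 3) representative-atom coordinates
    edges: np.ndarray              # (E, 2) int, i < j
    cross_chain_mask: np.ndarray   # (E,) bool
    interface_mask: np.ndarray     # (n,) bool
    cutoff: float
    node_labels: list[tuple[str, int, str]]  # (chain_id, seq_pos, aa) per node

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_json(self) -> str:
        """Serialize nodes, edges and masks as a readable JSON document."""
        doc = {
            "cutoff": self.cutoff,
            "nodes": [
                {"index": i, "chain": c, "seq_pos": p, "aa": a,
                 "interface": bool(self.interface_mask[i])}
                for i, (c, p, a) in enumerate(self.node_labels)
            ],
            "edges": [
                {"i": int(i), "j": int(j), "cross_chain": bool(x)}
                for (i, j), x in zip(self.edges, self.cross_chain_mask)
            ],
        }
        return json.dumps(doc, indent=1)


def build_graph(s: ComplexStructure, cutoff: float = 8.0) -> ResidueGraph:
    """Contact graph with an edge for every residue pair within ``cutoff`` A.

    Distances are measured between representative atoms; ties at exactly
    the cutoff are included. Node order is chain order then sequence order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = s.residues()
    n = len(residues)
    coords = np.array([representative_atom(r) for r in residues])
    chain_index = np.concatenate(
        [np.full(len(res), k, dtype=int) for k, (_, res) in enumerate(s.chains)]
    ) if n else np.zeros(0, dtype=int)

    if n >= 2:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=cutoff * (1 + 1e-12), output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            pairs = pairs[d <= cutoff]
            pairs = np.sort(pairs, axis=1)
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs = pairs[order]
        edges = pairs.reshape(-1, 2).astype(int)
    else:
        edges = np.zeros((0, 2), dtype=int)

    cross = chain_index[edges[:, 0]] != chain_index[edges[:, 1]] if len(edges) else (
        np.zeros(0, dtype=bool))
    interface = np.zeros(n, dtype=bool)
    if len(edges):
        interface[edges[cross].ravel()] = True
    labels = [(r.chain_id, r.seq_pos, r.aa) for r in residues]
    return ResidueGraph(
        n_nodes=n, chain_index=chain_index, rep_coords=coords, edges=edges,
        cross_chain_mask=np.asarray(cross, dtype=bool), interface_mask=interface,
        cutoff=cutoff, node_labels=labels,
    )


def interface_residues(g: ResidueGraph) -> np.ndarray:
    """Boolean mask of residues with a cross-chain contact within the cutoff."""
    if len(np.unique(g.chain_index)) < 2:
        logger.warning("interface_residues called on a single-chain graph")
    return g.interface_mask.copy()
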