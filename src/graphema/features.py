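"""Node and edge featurization for residue contact graphs.

Each node carries 83 features in six fixed blocks:

====================  =====
block                 width
====================  =====
one_hot               20
pssm                  20
energy_terms          20
sov_scores            5
positional_encoding   12
mass_potentials       6
====================  =====

The pssm, energy_terms, sov_scores and mass_potentials blocks come from
external sequence/structure tools in a production setting; here they are
filled through a :class:`FeatureProvider` contract, with a deterministic
hash-seeded synthetic provider shipped as the default so the full pipeline
runs with no external binaries. An optional language-model embedding block
(with mean / median / std / variance summaries) can be appended; it is not
part of the 83-feature count.

Each edge carries 10 features: CB-CB distance, the angle between the two
CA->CB vectors, the omega / theta / phi inter-residue orientation angles
(theta and phi once per direction), a contact-dependent potential and two
relative-solvent-accessibility potentials. The three potential features are
populated only on cross-chain (interface) edges and are zero elsewhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .geometry import dihedral, planar_angle, angle_between
from .structure import AA_INDEX, ComplexStructure, ResidueGraph, ResidueRecord

NODE_BLOCKS: tuple[tuple[str, int], ...] = (
    ("one_hot", 20),
    ("pssm", 20),
    ("energy_terms", 20),
    ("sov_scores", 5),
    ("positional_encoding", 12),
    ("mass_potentials", 6),
)
NODE_WIDTH = sum(w for _, w in NODE_BLOCKS)  # 83
EDGE_WIDTH = 10
EDGE_NAMES = ("d", "alpha", "omega", "theta_ij", "theta_ji",
              "phi_ij", "phi_ji", "cdp", "rsap_i", "rsap_j")

PROVIDER_BLOCKS = ("pssm", "energy_terms", "sov_scores", "mass_potentials")


class LayoutError(ValueError):
    """A provider's output does not match the fixed feature layout."""


def one_hot_aa(aa: str) -> np.ndarray:
    """One-hot vector over the 20 standard residues, alphabetical order."""
    if aa not in AA_INDEX:
        raise ValueError(f"unknown residue code: {aa!r}")
    v = np.zeros(20)
    v[AA_INDEX[aa]] = 1.0
    return v


def positional_encoding(seq_pos: int, width: int = 12) -> np.ndarray:
    """Sinusoidal positional encoding of a 0-based sequence position.

    Entry 2i is sin(pos / 10000^(2i/width)) and entry 2i+1 the matching
    cosine, the fixed encoding used by attention models.
    """
    if width % 2 != 0:
        raise ValueError("positional encoding width must be even")
    if seq_pos < 0:
        raise ValueError("seq_pos must be >= 0")
    i = np.arange(width // 2)
    freq = 1.0 / (10000.0 ** (2.0 * i / width))
    out = np.empty(width)
    out[0::2] = np.sin(seq_pos * freq)
    out[1::2] = np.cos(seq_pos * freq)
    return out


def _hash_unit(*parts: object) -> float:
    """Deterministic value in [-1, 1) from a stable hash of the parts."""
    key = "|".join(str(p) for p in parts).encode()
    h = hashlib.sha256(key).digest()
    u = int.from_bytes(h[:8], "little") / 2.0**64
    return 2.0 * u - 1.0


@dataclass
class SyntheticProvider:
    """Deterministic stand-in for an external per-residue feature tool.

    Values are seeded from a stable hash of (provider name, seed, residue
    identity), so they are reproducible across runs and invariant to the
    structure's coordinates — the same contract an external sequence-based
    tool would satisfy.
    """

    name: str
    width: int
    seed: int = 0

    def per_residue(self, s: ComplexStructure) -> np.ndarray:
        rows = [
            [_hash_unit(self.name, self.seed, r.chain_id, r.seq_pos, r.aa, k)
             for k in range(self.width)]
            for r in s.residues()
        ]
        return np.array(rows).reshape(len(rows), self.width)


def default_providers(seed: int = 0) -> dict[str, SyntheticProvider]:
    """Synthetic providers for every external-tool node block."""
    widths = dict(NODE_BLOCKS)
    return {name: SyntheticProvider(name, widths[name], seed)
            for name in PROVIDER_BLOCKS}


@dataclass
class EsmBlock:
    """Synthetic stand-in for per-residue language-model embeddings.

    Produces an (n, width) embedding matrix plus its per-column mean,
    median, standard deviation and variance summaries; the assembled block
    is [embedding | mean | median | std | var] per residue (5x width).
    Excluded from the 83-feature count.
    """

    width: int = 16
    seed: int = 0

    def matrix(self, s: ComplexStructure) -> np.ndarray:
        rows = [
            [_hash_unit("esm", self.seed, r.chain_id, r.seq_pos, r.aa, k)
             for k in range(self.width)]
            for r in s.residues()
        ]
        return np.array(rows).reshape(len(rows), self.width)

    @staticmethod
    def summaries(m: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "mean": m.mean(axis=0),
            "median": np.median(m, axis=0),
            "std": m.std(axis=0),
            "var": m.var(axis=0),
        }

    def assemble(self, s: ComplexStructure) -> np.ndarray:
        m = self.matrix(s)
        su = self.summaries(m)
        tail = np.concatenate([su["mean"], su["median"], su["std"], su["var"]])
        return np.hstack([m, np.tile(tail, (m.shape[0], 1))])


def assemble_node_features(
    s: ComplexStructure,
    providers: Mapping[str, object] | None = None,
    esm: EsmBlock | None = None,
) -> np.ndarray:
    """Per-residue feature matrix, (n, 83) or (n, 83 + 5*esm.width).

    Blocks with no registered provider are zero-filled; the one-hot and
    positional-encoding blocks are always computed internally. Positions
    for the encoding run 0-based over the concatenated multi-chain
    sequence in chain order.
    """
    providers = dict(providers or {})
    residues = s.residues()
    n = len(residues)
    widths = dict(NODE_BLOCKS)
    blocks: dict[str, np.ndarray] = {
        "one_hot": np.array([one_hot_aa(r.aa) for r in residues]).reshape(n, 20),
        "positional_encoding": np.array(
            [positional_encoding(i, widths["positional_encoding"]) for i in range(n)]
        ).reshape(n, widths["positional_encoding"]),
    }
    for name in PROVIDER_BLOCKS:
        prov = providers.get(name)
        if prov is None:
            blocks[name] = np.zeros((n, widths[name]))
            continue
        mat = np.asarray(prov.per_residue(s), dtype=float)
        if mat.shape != (n, widths[name]):
            raise LayoutError(
                f"provider for block {name!r} returned shape {mat.shape}, "
                f"expected {(n, widths[name])}"
            )
        blocks[name] = mat
    out = np.hstack([blocks[name] for name, _ in NODE_BLOCKS])
    assert out.shape == (n, NODE_WIDTH)
    if esm is not None:
        out = np.hstack([out, esm.assemble(s)])
    return out


def edge_geometry(ri: ResidueRecord, rj: ResidueRecord) -> tuple[float, ...]:
    """Distance + orientation features between two residues.

    Returns (d, alpha, omega, theta_ij, theta_ji, phi_ij, phi_ji) where d
    is the CB-CB distance, alpha the angle between the CA->CB vectors,
    omega the CA-CB-CB-CA dihedral, theta the N-CA-CB-CB dihedrals and phi
    the CA-CB-CB planar angles, each evaluated in both directions where
    asymmetric. Glycine (or a missing CB) uses the ideal virtual CB.
    """
    cai, caj = ri.atoms["CA"], rj.atoms["CA"]
    ni, nj = ri.atoms["N"], rj.atoms["N"]
    cbi, cbj = ri.cb_coord(), rj.cb_coord()
    d = float(np.linalg.norm(cbi - cbj))
    alpha = angle_between(cbi - cai, cbj - caj)
    omega = dihedral(cai, cbi, cbj, caj)
    theta_ij = dihedral(ni, cai, cbi, cbj)
    theta_ji = dihedral(nj, caj, cbj, cbi)
    phi_ij = planar_angle(cai, cbi, cbj)
    phi_ji = planar_angle(caj, cbj, cbi)
    return d, alpha, omega, theta_ij, theta_ji, phi_ij, phi_ji


# Edge potential stand-ins follow the same hash-seeded contract as
# SyntheticProvider; real CDP/RSAP tables can be swapped in via the
# callables below.
PairPotential = Callable[[ResidueRecord, ResidueRecord], float]
ResiduePotential = Callable[[ResidueRecord], float]


def synthetic_pair_potential(seed: int = 0) -> PairPotential:
    def cdp(ri: ResidueRecord, rj: ResidueRecord) -> float:
        return _hash_unit("cdp", seed, ri.aa, rj.aa)
    return cdp


def synthetic_residue_potential(seed: int = 0) -> ResiduePotential:
    def rsap(r: ResidueRecord) -> float:
        return _hash_unit("rsap", seed, r.chain_id, r.seq_pos, r.aa)
    return rsap


def assemble_edge_features(
    g: ResidueGraph,
    s: ComplexStructure,
    cdp: PairPotential | None = None,
    rsap: ResiduePotential | None = None,
) -> np.ndarray:
    """Per-edge feature matrix (E, 10) aligned with ``g.edges``.

    Geometry features are always present; the contact-dependent and
    solvent-accessibility potentials are populated only on cross-chain
    edges (zero otherwise), reflecting that they describe the interface.
    """
    residues = s.residues()
    if len(residues) != g.n_nodes:
        raise ValueError("graph and structure are inconsistent")
    cdp = cdp or synthetic_pair_potential()
    rsap = rsap or synthetic_residue_potential()
    out = np.zeros((g.n_edges, EDGE_WIDTH))
    for e, (i, j) in enumerate(g.edges):
        ri, rj = residues[i], residues[j]
        out[e, :7] = edge_geometry(ri, rj)
        if g.cross_chain_mask[e]:
            out[e, 7] = cdp(ri, rj)
            out[e, 8] = rsap(ri)
            out[e, 9] = rsap(rj)
    return out


def features_to_tsv(matrix: np.ndarray, kind: str = "node") -> str:
    """Render a feature matrix as TSV with per-column block names."""
    if kind == "node":
        names: list[str] = []
        for block, width in NODE_BLOCKS:
            names.extend(f"{block}_{k}" for k in range(width))
        extra = matrix.shape[1] - NODE_WIDTH
        names.extend(f"esm_{k}" for k in range(extra))
    elif kind == "edge":
        names = list(EDGE_NAMES)
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    header = "\t".join(names)
    body = "\n".join("\t".join(f"{v:.6g}" for v in row) for row in matrix)
    return header + "\n" + body + "\n"
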