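"""Synthetic structures, decoys and datasets for exercising the pipeline.

The generator builds ideal-geometry helical chains (N, CA, C, O, CB
backbones from standard bond lengths/angles and alpha-helical torsions),
packs several copies close enough to form an interface, and derives decoys
by per-chain rigid-body perturbation plus Gaussian atomic jitter. Quality
labels come from two documented stand-in scorers:

* :func:`fold_label` — Kabsch superposition on CA atoms with fixed residue
  correspondence, then the TM-style length-normalized distance score
  (1/L) * sum 1 / (1 + (d_i/d0)^2), d0 = 1.24 (L-15)^(1/3) - 1.8 floored
  at 0.5 A. This is *not* the official TM-score program: there is no
  alignment search.
* :func:`interface_label` — Jaccard overlap of cross-chain residue contact
  sets at the 8 A representative-atom cutoff. This is *not* QS-best; it
  preserves the [0, 1] scale and the orderings needed for training and
  evaluation.

A separate embedding dataset generator provides (embedding, score) pairs
whose ground-truth mapping is known, for energy-model recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ebm import sigmoid
from .geometry import kabsch, place_atom, rotation_matrix, virtual_cb
from .structure import (ComplexStructure, ResidueRecord, STANDARD_AA,
                        build_graph)

# Ideal backbone internal coordinates (lengths in A, angles/torsions in rad)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = np.deg2rad(111.2)
_ANG_CA_C_N = np.deg2rad(116.2)
_ANG_C_N_CA = np.deg2rad(121.7)
_ANG_CA_C_O = np.deg2rad(120.8)
_PHI = np.deg2rad(-57.0)   # alpha-helix torsions
_PSI = np.deg2rad(-47.0)
_OMEGA = np.pi              # trans peptide


@dataclass
class DecoySpec:
    """Parameters of a decoy set: geometry of the native and the
    perturbation magnitudes applied to each decoy."""

    n_chains: int = 2
    chain_length: int = 20
    rigid_rotation_max: float = 10.0     # degrees
    rigid_translation_max: float = 2.0   # A
    jitter_sd: float = 0.3               # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.chain_length < 4:
            raise ValueError("chain_length must be >= 4")
        for name in ("rigid_rotation_max", "rigid_translation_max", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _helical_chain(chain_id: str, length: int, rng: np.random.Generator
                   ) -> list[ResidueRecord]:
    """Ideal alpha-helical backbone built atom-by-atom (NeRF)."""
    aas = [STANDARD_AA[i] for i in rng.integers(0, 20, size=length)]
    # seed triad for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(np.pi - _ANG_N_CA_C),
                                      np.sin(np.pi - _ANG_N_CA_C), 0.0])
    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, length):
        prev = backbone[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       _BOND_C_N, _ANG_CA_C_N, _PSI)
        ca = place_atom(prev["CA"], prev["C"], n,
                        _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c = place_atom(prev["C"], n, ca, _BOND_CA_C, _ANG_N_CA_C, _PHI)
        backbone.append({"N": n, "CA": ca, "C": c})
    records = []
    for i, (aa, atoms) in enumerate(zip(aas, backbone), start=1):
        full = dict(atoms)
        if i < length:
            nxt = backbone[i]["N"]
            full["O"] = place_atom(nxt, atoms["CA"], atoms["C"],
                                   _BOND_C_O, _ANG_CA_C_O, np.pi)
        if aa != "GLY":
            full["CB"] = virtual_cb(full["N"], full["CA"], full["C"])
        records.append(ResidueRecord(chain_id, i, aa, full))
    return records


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def generate_toy_complex(spec: DecoySpec) -> ComplexStructure:
    """Deterministic multi-chain helical complex with >= 1 interface.

    Chains are parallel helices offset 8.5 A apart in x, guaranteeing
    cross-chain representative-atom contacts under the 8 A cutoff while
    avoiding steric collapse; overlapping placements are re-shifted.
    """
    rng = np.random.default_rng(spec.seed)
    chains: list[tuple[str, list[ResidueRecord]]] = []
    base = _helical_chain("A", spec.chain_length, rng)
    for k in range(spec.n_chains):
        cid = _CHAIN_IDS[k]
        offset = np.array([8.5 * k, 0.35 * k, 0.0])
        for attempt in range(5):
            shifted = _translate_records(base, cid, offset)
            if k == 0 or _min_interchain_distance(chains, shifted) > 2.0:
                break
            offset = offset + np.array([0.8, 0.0, 0.0])  # nudge apart
        chains.append((cid, shifted))
    return ComplexStructure(model_id=f"toy_c{spec.n_chains}_l{spec.chain_length}"
                            f"_s{spec.seed}", chains=chains)


def _translate_records(records: list[ResidueRecord], chain_id: str,
                       offset: np.ndarray) -> list[ResidueRecord]:
    return [ResidueRecord(chain_id, r.seq_pos, r.aa,
                          {k: v + offset for k, v in r.atoms.items()})
            for r in records]


def _min_interchain_distance(chains, new_records) -> float:
    existing = np.array([a for _, recs in chains for r in recs
                         for a in r.atoms.values()])
    new = np.array([a for r in new_records for a in r.atoms.values()])
    if not len(existing) or not len(new):
        return np.inf
    d = np.linalg.norm(existing[:, None, :] - new[None, :, :], axis=-1)
    return float(d.min())


def perturb_decoy(native: ComplexStructure, spec: DecoySpec,
                  rng: np.random.Generator) -> ComplexStructure:
    """Decoy by independent per-chain rigid motion plus atomic jitter.

    Each chain is rotated about its centroid by a random axis/angle
    (angle uniform in [0, rigid_rotation_max] degrees), translated by a
    uniform vector of length <= rigid_translation_max, and every atom gets
    i.i.d. Gaussian jitter of the given standard deviation.
    """
    chains_out: list[tuple[str, list[ResidueRecord]]] = []
    for cid, records in native.chains:
        coords = np.array([a for r in records for a in r.atoms.values()])
        centroid = coords.mean(axis=0)
        if spec.rigid_rotation_max > 0:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(0.0, spec.rigid_rotation_max))
            rot = rotation_matrix(axis, angle)
        else:
            rot = np.eye(3)
        if spec.rigid_translation_max > 0:
            vec = rng.standard_normal(3)
            vec /= np.linalg.norm(vec)
            trans = vec * rng.uniform(0.0, spec.rigid_translation_max)
        else:
            trans = np.zeros(3)
        new_records = []
        for r in records:
            atoms = {}
            for name, xyz in r.atoms.items():
                moved = (xyz - centroid) @ rot.T + centroid + trans
                if spec.jitter_sd > 0:
                    moved = moved + rng.normal(0.0, spec.jitter_sd, 3)
                atoms[name] = moved
            new_records.append(ResidueRecord(cid, r.seq_pos, r.aa, atoms))
        chains_out.append((cid, new_records))
    return ComplexStructure(model_id=native.model_id + "_decoy",
                            chains=chains_out)


def _ca_matrix(s: ComplexStructure) -> np.ndarray:
    return np.array([r.atoms["CA"] for r in s.residues()])


def tm_d0(length: int) -> float:
    """TM-style normalization distance, floored at 0.5 A for short chains."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def fold_label(native: ComplexStructure, decoy: ComplexStructure) -> float:
    """Overall-fold stand-in score in (0, 1].

    CA atoms are superposed by least squares under the fixed native
    correspondence, then scored with the TM-style kernel. Identical or
    rigidly moved copies score 1.
    """
    a = _ca_matrix(decoy)
    b = _ca_matrix(native)
    if a.shape != b.shape:
        raise ValueError("native and decoy differ in residue count")
    r, t = kabsch(a, b)
    moved = a @ r + t
    d = np.linalg.norm(moved - b, axis=1)
    d0 = tm_d0(len(b))
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def _contact_set(s: ComplexStructure, cutoff: float = 8.0) -> set[tuple]:
    g = build_graph(s, cutoff)
    out = set()
    for (i, j), cross in zip(g.edges, g.cross_chain_mask):
        if cross:
            ci, pi, _ = g.node_labels[i]
            cj, pj, _ = g.node_labels[j]
            out.add(((ci, pi), (cj, pj)))
    return out


def interface_label(native: ComplexStructure, decoy: ComplexStructure,
                    cutoff: float = 8.0) -> float:
    """Interface stand-in score: Jaccard overlap of cross-chain contacts.

    Raises when the native has no cross-chain contacts (score undefined).
    """
    nat = _contact_set(native, cutoff)
    if not nat:
        raise ValueError("native structure has no cross-chain contacts")
    dec = _contact_set(decoy, cutoff)
    union = nat | dec
    return float(len(nat & dec) / len(union))


def generate_decoy_set(spec: DecoySpec, n_decoys: int
                       ) -> tuple[ComplexStructure,
                                  list[tuple[ComplexStructure, float, float]]]:
    """Native plus graded decoys with fold / interface labels.

    Decoy k is perturbed at magnitude scale (k+1)/n_decoys of the spec's
    maxima, so the set spans a range of qualities.
    """
    native = generate_toy_complex(spec)
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    for k in range(n_decoys):
        scale = (k + 1) / n_decoys
        scaled = DecoySpec(
            n_chains=spec.n_chains, chain_length=spec.chain_length,
            rigid_rotation_max=spec.rigid_rotation_max * scale,
            rigid_translation_max=spec.rigid_translation_max * scale,
            jitter_sd=spec.jitter_sd * scale, seed=spec.seed,
        )
        decoy = perturb_decoy(native, scaled, rng)
        decoy.model_id = f"{native.model_id}_d{k:03d}"
        out.append((decoy, fold_label(native, decoy),
                    interface_label(native, decoy)))
    return native, out


def write_pdb(s: ComplexStructure, path) -> None:
    """Write the structure as a minimal PDB file (deterministic output)."""
    lines = []
    serial = 1
    for cid, records in s.chains:
        for r in records:
            for name in ("N", "CA", "C", "O", "CB"):
                if name not in r.atoms:
                    continue
                x, y, z = r.atoms[name]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {r.aa:>3s} {cid}"
                    f"{r.seq_pos:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {r.aa:>3s} {cid}{r.seq_pos:4d}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_graph_dataset(n: int, seed: int = 0, chain_length: int = 12):
    """Featurized graphs labelled by a known statistic for recovery tests.

    Each graph is a perturbed two- or three-chain helical complex and its
    label is the fraction of contact edges that cross chains — a quantity
    a graph network can learn from topology alone. Returns a list of
    :class:`~graphema.backbone.GraphData`.
    """
    from .pipeline import featurize_structure

    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        spec = DecoySpec(
            n_chains=int(rng.integers(2, 4)),
            chain_length=chain_length,
            rigid_rotation_max=float(rng.uniform(0.0, 25.0)),
            rigid_translation_max=float(rng.uniform(0.0, 6.0)),
            jitter_sd=float(rng.uniform(0.0, 0.4)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        native = generate_toy_complex(spec)
        decoy = perturb_decoy(native, spec, rng)
        decoy.model_id = f"graphset_{k:04d}"
        g = featurize_structure(decoy, seed=seed)
        graph = build_graph(decoy)
        if graph.n_edges:
            g.label = float(graph.cross_chain_mask.mean())
        else:  # pragma: no cover - contact loss is extremely unlikely
            g.label = 0.0
        out.append(g)
    return out


def make_embedding_dataset(n: int, width: int = 16, noise_sd: float = 0.02,
                           seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray, dict]:
    """(embedding, score) pairs with a known sigmoid-linear ground truth.

    Embeddings are i.i.d. standard normal; the score is
    sigmoid(w . x + b) plus bounded Gaussian noise, clamped to (0, 1).
    The returned mapping dict records w and b for recovery tests.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    rng = np.random.default_rng(seed)
    w_rng = np.random.default_rng(12345)  # mapping fixed across seeds
    w = w_rng.normal(0.0, 1.6 / np.sqrt(width), size=width)
    b = 0.1
    x = rng.standard_normal((n, width))
    raw = x @ w + b
    scores = sigmoid(raw)
    if noise_sd > 0:
        scores = scores + np.clip(rng.normal(0.0, noise_sd, n),
                                  -3 * noise_sd, 3 * noise_sd)
    scores = np.clip(scores, 1e-4, 1.0 - 1e-4)
    return x, scores, {"w": w, "b": b}
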