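import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from graphema.structure import ComplexStructure, ResidueRecord
from graphema.synthetic import DecoySpec, generate_toy_complex


def make_residue(chain_id, seq_pos, aa, ca, cb=None, n=None, c=None):
    """Residue with sensible default backbone placement around CA."""
    ca = np.asarray(ca, dtype=float)
    atoms = {
        "CA": ca,
        "N": np.asarray(n, dtype=float) if n is not None else ca + [-1.46, 0, 0],
        "C": np.asarray(c, dtype=float) if c is not None else ca + [1.0, 1.0, 0],
    }
    if cb is not None:
        atoms["CB"] = np.asarray(cb, dtype=float)
    elif aa != "GLY":
        atoms["CB"] = ca + [0.0, -1.0, 1.0]
    return ResidueRecord(chain_id, seq_pos, aa, atoms)


def make_two_residue_complex(distance):
    """Two single-residue chains with representative atoms ``distance`` apart."""
    r1 = make_residue("A", 1, "ALA", [0.0, 0.0, 0.0], cb=[0.0, 0.0, 0.0])
    r2 = make_residue("B", 1, "ALA", [distance, 0.0, 0.0],
                      cb=[distance, 0.0, 0.0])
    return ComplexStructure("pair", [("A", [r1]), ("B", [r2])])


def brute_force_edges(structure, cutoff=8.0):
    """All-pairs oracle for the contact graph edge set."""
    from graphema.structure import representative_atom
    residues = structure.residues()
    coords = [representative_atom(r) for r in residues]
    edges = set()
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                edges.add((i, j))
    return edges


def rigid_transform(structure, seed=0):
    """A random rotation + translation applied to every atom."""
    from graphema.geometry import rotation_matrix
    rng = np.random.default_rng(seed)
    axis = rng.standard_normal(3)
    rot = rotation_matrix(axis, rng.uniform(0.3, 2.5))
    shift = rng.uniform(-20, 20, 3)
    chains = []
    for cid, records in structure.chains:
        moved = [
            ResidueRecord(r.chain_id, r.seq_pos, r.aa,
                          {k: v @ rot.T + shift for k, v in r.atoms.items()})
            for r in records
        ]
        chains.append((cid, moved))
    return ComplexStructure(structure.model_id + "_moved", chains)


@pytest.fixture(scope="session")
def dimer():
    return generate_toy_complex(DecoySpec(n_chains=2, chain_length=16, seed=11))


@pytest.fixture(scope="session")
def trimer():
    return generate_toy_complex(DecoySpec(n_chains=3, chain_length=12, seed=12))


@pytest.fixture(scope="session")
def dimer_graph_data(dimer):
    from graphema.pipeline import featurize_structure
    return featurize_structure(dimer)
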