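"""End-to-end plumbing: structure file -> featurized graph -> score."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .backbone import Backbone, GraphData, predict, to_graph_data
from .ebm import EnergyNet, grid_inference
from .features import (EsmBlock, assemble_edge_features, assemble_node_features,
                       default_providers)
from .structure import ComplexStructure, build_graph, parse_structure


def featurize_structure(s: ComplexStructure, cutoff: float = 8.0,
                        seed: int = 0, esm: EsmBlock | None = None
                        ) -> GraphData:
    """Build the residue graph and assemble node/edge feature matrices."""
    g = build_graph(s, cutoff)
    node_feats = assemble_node_features(s, default_providers(seed), esm=esm)
    edge_feats = assemble_edge_features(g, s)
    return to_graph_data(g, node_feats, edge_feats, model_id=s.model_id)


def score_structure(path: str | Path, backbone: Backbone,
                    ebm: EnergyNet | None = None, cutoff: float = 8.0,
                    seed: int = 0) -> dict:
    """Score one model file; EBM mode runs grid inference on the embedding."""
    s = parse_structure(path)
    g = featurize_structure(s, cutoff=cutoff, seed=seed)
    reg_score, emb = predict(backbone, g)
    row = {"model_id": s.model_id, "score_type": backbone.cfg.score_type,
           "regression_score": reg_score}
    if ebm is not None:
        row["ebm_score"] = grid_inference(ebm, np.asarray(emb))
    return row
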