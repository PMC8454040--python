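"""End-to-end orchestration: design candidates, score them, rank by s.

``explore`` chains the two halves of the method — pathway design (subset
sampling + binary DE + ordering + reconstruction + molecular-weight pruning)
and pathway scoring (ensemble voting, v_p, s) — and returns candidates sorted
ascending by score.  ``RunConfig`` captures every knob so a persisted
configuration re-runs to identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .design import CandidatePathway, DEConfig, compute_pathway_vector, design_candidates
from .embedding import EmbeddingBackend
from .errors import ConfigurationError
from .reactions import ReactionFeatureDB
from .scoring import EnsembleModel, build_training_collection, rank_pathways, score_pathway, train_ensemble


@dataclass
class RunConfig:
    """Serializable run plan: design, ensemble and interpretation settings."""

    seed: int = 0
    design: DEConfig = field(default_factory=DEConfig)
    design_part: str = "tree"
    q_per_virtual_type: int = 2
    r_folds: int = 5
    virtual_size: int = 1000
    nn_max_iter: int = 300
    hidden_layer_sizes: tuple[int, ...] = (64, 32, 8)
    score_mode: str = "ratio"  # Eq-6 interpretation: s = |e|/v_p (or "product")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_layer_sizes"] = list(self.hidden_layer_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = DEConfig(**d["design"])
        if "hidden_layer_sizes" in d:
            d["hidden_layer_sizes"] = tuple(d["hidden_layer_sizes"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def explore(
    start_id: str,
    target_id: str,
    db: ReactionFeatureDB,
    backend: EmbeddingBackend,
    config: RunConfig,
    ensemble: EnsembleModel | None = None,
    compounds: dict | None = None,
) -> list[CandidatePathway]:
    """Design, score and rank candidate pathways from start to target.

    If no trained ensemble is supplied, one is trained on the fly from the
    reaction DB (which must then be combined-part) using the config's recipe
    sizes.  Candidates are sorted ascending by score s; an empty list is a
    valid outcome.
    """
    if not start_id or not target_id:
        raise ConfigurationError("explore requires both start_id and target_id")
    start = backend.encode(start_id)
    target = backend.encode(target_id)
    part = config.design_part if db.part == "combined" else db.part
    query = compute_pathway_vector(start.latent(part), target.latent(part), start_id, target_id)
    de_cfg = dataclasses.replace(config.design, seed=config.seed)
    candidates = design_candidates(query, db, de_cfg, backend, design_part=part)
    if not candidates:
        return []
    if ensemble is None and db.part == "combined":
        from .embedding import encode_compounds

        if compounds is None:
            ids = {f.record.substrate_id for f in db} | {f.record.product_id for f in db}
            compounds = encode_compounds(backend, sorted(ids))
        real, virtuals = build_training_collection(
            db, compounds, config.q_per_virtual_type, config.virtual_size, seed=config.seed
        )
        ensemble = train_ensemble(
            real,
            virtuals,
            config.r_folds,
            seed=config.seed,
            hidden_layer_sizes=config.hidden_layer_sizes,
            max_iter=config.nn_max_iter,
        )
    if ensemble is not None:
        for pw in candidates:
            score_pathway(pw, ensemble, score_mode=config.score_mode)
        return rank_pathways(candidates)
    return sorted(candidates, key=lambda pw: pw.abs_error)


def pathway_to_dict(pw: CandidatePathway, db: ReactionFeatureDB | None = None) -> dict:
    """JSON-serializable report row for one candidate pathway."""
    d = {
        "start_id": pw.query.start_id,
        "target_id": pw.query.target_id,
        "ec_sequence": list(pw.ec_sequence),
        "pairs": [list(p) for p in pw.pair_sequence],
        "intermediate_structures": pw.intermediate_structures,
        "final_structure": pw.final_structure,
        "segment_delta_mws": pw.segment_delta_mws,
        "abs_error": pw.abs_error,
        "v_r": pw.v_r,
        "v_p": pw.v_p,
        "score": None if pw.score is None else (pw.score if np.isfinite(pw.score) else "inf"),
        "removal_reason": pw.removal_reason,
    }
    if db is not None:
        index = {(f.record.ec_number, f.record.substrate_id, f.record.product_id): i for i, f in enumerate(db.features)}
        d["db_indices"] = [
            index.get((f.record.ec_number, f.record.substrate_id, f.record.product_id))
            for f in pw.ordered_reactions
        ]
    return d


def write_report(pathways, path, db: ReactionFeatureDB | None = None, meta: dict | None = None) -> None:
    payload = {"meta": meta or {}, "candidates": [pathway_to_dict(pw, db) for pw in pathways]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
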