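"""Reaction-possibility prediction and pathway scoring.

A candidate pathway may sum to the right latent displacement while containing
segments no enzyme would catalyse.  The scorer judges each segment with an
ensemble of small binary classifiers: each network takes the concatenation
[reaction vector ‖ substrate tree latent ‖ substrate graph latent] and outputs
0 (virtual) or 1 (real).  Training data come in four recipes that factor the
two relevant axes — whether the substrate/product *pair* is registered and
whether the attached *substrate* is the pair's own:

- ``REAL``      registered pair, own substrate              (label 1)
- ``VIRTUAL1``  registered pair, substrate swapped out      (label 0)
- ``VIRTUAL2``  random pair, the random pair's own substrate (label 0)
- ``VIRTUAL3``  random pair, unrelated third substrate      (label 0)

The ensemble holds Q × R models: one combined dataset (all real examples plus
one virtual dataset) per q ∈ 1..Q, trained with R-fold cross-validation
(each model sees R−1 folds).  At prediction time every model votes 0/1 and
the reaction-possibility value v_r is the vote fraction, in [0, 1].  A
pathway's feasibility is v_p = Π v_r over its segments, and its final score
is s = |e| / v_p (lower is better; v_p = 0 scores +inf and ranks last).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler

from .design import CandidatePathway
from .embedding import EncodedCompound, LatentVector
from .errors import DimensionError, ParameterError, ScoringError
from .reactions import ReactionFeatureDB

logger = logging.getLogger(__name__)

RECIPES = ("REAL", "VIRTUAL1", "VIRTUAL2", "VIRTUAL3")
RECIPE_LABELS = {
    "REAL": "Real pair, Substrate in",
    "VIRTUAL1": "Real pair, Substrate out",
    "VIRTUAL2": "Virtual pair, Substrate in",
    "VIRTUAL3": "Virtual pair, Substrate out",
}


@dataclass(frozen=True)
class ReactionExample:
    """One classifier input: reaction vector + substrate latents + label."""

    reaction_vector: np.ndarray  # combined part
    substrate_tree: np.ndarray
    substrate_graph: np.ndarray
    label: int
    provenance: str
    substrate_id: str = ""
    pair: tuple[str, str] = ("", "")

    def feature_row(self) -> np.ndarray:
        return np.concatenate([self.reaction_vector, self.substrate_tree, self.substrate_graph])


@dataclass(frozen=True)
class DatasetRecipe:
    recipe: str
    n_records: int
    seed: int = 0

    def __post_init__(self):
        if self.recipe not in RECIPES:
            raise ParameterError(f"unknown recipe {self.recipe!r}; expected one of {RECIPES}")
        if self.n_records < 1:
            raise ParameterError("n_records must be >= 1")


def example_matrix(examples) -> np.ndarray:
    return np.stack([ex.feature_row() for ex in examples])


def dump_examples_tsv(examples, path) -> None:
    """Audit dump: one row per example with recipe, label and vector columns."""
    with open(path, "w") as fh:
        n_r = len(examples[0].reaction_vector)
        n_t = len(examples[0].substrate_tree)
        n_g = len(examples[0].substrate_graph)
        header = (
            ["recipe", "label", "substrate_id", "pair_substrate", "pair_product"]
            + [f"r{i}" for i in range(n_r)]
            + [f"t{i}" for i in range(n_t)]
            + [f"g{i}" for i in range(n_g)]
        )
        fh.write("\t".join(header) + "\n")
        for ex in examples:
            row = [ex.provenance, str(ex.label), ex.substrate_id, ex.pair[0], ex.pair[1]]
            row += [repr(float(v)) for v in ex.feature_row()]
            fh.write("\t".join(row) + "\n")


def _require_combined(db: ReactionFeatureDB) -> None:
    if db.part != "combined":
        raise ParameterError(
            "possibility scoring needs a combined-part reaction DB "
            f"(got part={db.part!r}); rebuild with part='combined'"
        )


def build_virtual_dataset(
    db: ReactionFeatureDB,
    compounds: dict[str, EncodedCompound],
    recipe: DatasetRecipe,
) -> list[ReactionExample]:
    """Generate exactly ``recipe.n_records`` examples satisfying the recipe.

    REAL draws registered reactions with their own substrates (label 1); the
    virtual recipes (label 0) swap the substrate out (VIRTUAL1), replace the
    pair by a uniformly random non-registered compound pair (VIRTUAL2), or do
    both (VIRTUAL3).  Reproducible per ``recipe.seed``.
    """
    _require_combined(db)
    if not compounds:
        raise ParameterError("compound set must be non-empty")
    rng = np.random.default_rng(recipe.seed)
    ids = sorted(compounds)
    if recipe.recipe != "REAL" and len(ids) < 2:
        raise ParameterError(f"recipe {recipe.recipe} needs at least 2 compounds")
    registered = {(f.record.substrate_id, f.record.product_id) for f in db}

    def pick_other(excluded: set[str]) -> str:
        while True:
            cid = ids[int(rng.integers(len(ids)))]
            if cid not in excluded:
                return cid

    def random_pair() -> tuple[str, str]:
        while True:
            s, p = (ids[int(i)] for i in rng.integers(len(ids), size=2))
            if s != p and (s, p) not in registered:
                return s, p

    out: list[ReactionExample] = []
    if recipe.recipe in ("REAL", "VIRTUAL1"):
        n = len(db)
        if recipe.n_records <= n:
            feat_idx = rng.choice(n, size=recipe.n_records, replace=False)
        else:
            feat_idx = rng.integers(n, size=recipe.n_records)
        for i in feat_idx:
            feat = db[int(i)]
            if recipe.recipe == "REAL":
                sub_id = feat.record.substrate_id
                label = 1
            else:
                sub_id = pick_other({feat.record.substrate_id})
                label = 0
            sub = compounds[sub_id]
            out.append(
                ReactionExample(
                    feat.vector.values,
                    sub.tree_latent.values,
                    sub.graph_latent.values,
                    label,
                    recipe.recipe,
                    substrate_id=sub_id,
                    pair=(feat.record.substrate_id, feat.record.product_id),
                )
            )
    else:
        for _ in range(recipe.n_records):
            s_id, p_id = random_pair()
            vec = compounds[p_id].combined_latent.values - compounds[s_id].combined_latent.values
            att_id = s_id if recipe.recipe == "VIRTUAL2" else pick_other({s_id, p_id})
            att = compounds[att_id]
            out.append(
                ReactionExample(
                    vec,
                    att.tree_latent.values,
                    att.graph_latent.values,
                    0,
                    recipe.recipe,
                    substrate_id=att_id,
                    pair=(s_id, p_id),
                )
            )
    return out


def build_training_collection(
    db: ReactionFeatureDB,
    compounds: dict[str, EncodedCompound],
    q_per_type: int,
    virtual_size: int,
    seed: int = 0,
):
    """One REAL dataset plus Q = 3·q_per_type virtual datasets.

    The reference setup uses several independently sampled datasets per
    virtual recipe; each combined training set is the full real data plus one
    virtual dataset.  Returns ``(real_examples, virtual_datasets)`` with
    per-dataset derived seeds.
    """
    rng = np.random.default_rng(seed)
    real = build_virtual_dataset(
        db, compounds, DatasetRecipe("REAL", len(db), seed=int(rng.integers(2**31 - 1)))
    )
    virtuals = [
        build_virtual_dataset(
            db, compounds, DatasetRecipe(recipe, virtual_size, seed=int(rng.integers(2**31 - 1)))
        )
        for recipe in ("VIRTUAL1", "VIRTUAL2", "VIRTUAL3")
        for _ in range(q_per_type)
    ]
    return real, virtuals


# --------------------------------------------------------------------------
# Ensemble training
# --------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Q × R trained classifiers combined by 0/1 voting.

    Each member is a StandardScaler + MLP pipeline with three hidden layers
    (64, 32, 8 by default), ReLU activations and a thresholded binary output.
    ``fold_meta`` records, per model, its combined-dataset index q, fold index
    and held-out example indices (real examples occupy rows 0..n_real−1 of
    every combined dataset).
    """

    models: list[Pipeline]
    q: int
    r: int
    input_dim: int
    hidden_layer_sizes: tuple[int, ...]
    seed: int
    fold_meta: list[dict] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Per-row vote fraction v_r = (#models predicting 1) / (Q·R)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise DimensionError(f"expected input dimension {self.input_dim}, got {X.shape[1]}")
        total = np.zeros(X.shape[0])
        for m in self.models:
            total += m.predict(X)
        return total / self.n_models


def train_ensemble(
    real_examples,
    virtual_datasets,
    r_folds: int,
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (64, 32, 8),
    max_iter: int = 300,
) -> EnsembleModel:
    """Train Q × R networks: one R-fold CV per combined (real ∪ virtual_q) dataset.

    Folds are stratified by label; a degenerate single-class training fold is
    re-stratified with a fresh shuffle (up to 5 attempts) before raising.
    Deterministic for a fixed ``seed``.
    """
    q = len(virtual_datasets)
    if q < 1:
        raise ParameterError("need at least one virtual dataset (Q >= 1)")
    if r_folds < 2:
        raise ParameterError("R-fold cross-validation needs R >= 2")
    real_X = example_matrix(real_examples)
    n_real = real_X.shape[0]
    rng = np.random.default_rng(seed)
    models, fold_meta = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for qi, vds in enumerate(virtual_datasets):
            X = np.vstack([real_X, example_matrix(vds)])
            y = np.concatenate([
                np.array([ex.label for ex in real_examples]),
                np.array([ex.label for ex in vds]),
            ])
            for attempt in range(5):
                skf = StratifiedKFold(
                    n_splits=r_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
                )
                splits = list(skf.split(X, y))
                if all(len(np.unique(y[tr])) > 1 for tr, _ in splits):
                    break
            else:
                raise ParameterError("could not stratify folds into two-class training sets")
            for fi, (train_idx, test_idx) in enumerate(splits):
                clf = make_pipeline(
                    StandardScaler(),
                    MLPClassifier(
                        hidden_layer_sizes=hidden_layer_sizes,
                        activation="relu",
                        max_iter=max_iter,
                        random_state=int(rng.integers(2**31 - 1)),
                    ),
                )
                clf.fit(X[train_idx], y[train_idx])
                models.append(clf)
                fold_meta.append({"q": qi, "fold": fi, "test_indices": test_idx, "n_real": n_real})
    logger.info("train_ensemble: trained %d models (Q=%d, R=%d)", len(models), q, r_folds)
    return EnsembleModel(
        models, q, r_folds, real_X.shape[1], tuple(hidden_layer_sizes), seed, fold_meta
    )


def predict_possibility(
    ensemble: EnsembleModel,
    reaction_vector,
    substrate_tree,
    substrate_graph,
) -> float:
    """Voting reaction-possibility value v_r ∈ [0, 1] for one (reaction, substrate) pair."""
    vals = [
        v.values if isinstance(v, LatentVector) else np.asarray(v, dtype=np.float64)
        for v in (reaction_vector, substrate_tree, substrate_graph)
    ]
    return float(ensemble.votes(np.concatenate(vals)[None, :])[0])


def held_out_real_possibility(ensemble: EnsembleModel, real_examples) -> np.ndarray:
    """Out-of-fold v_r for each real training example.

    For each q, exactly one of the R models held a given real example out of
    training; its vote is taken, yielding Q held-out votes per example.
    """
    X = example_matrix(real_examples)
    votes = np.zeros(X.shape[0])
    counts = np.zeros(X.shape[0])
    for model, meta in zip(ensemble.models, ensemble.fold_meta):
        idx = meta["test_indices"]
        real_idx = idx[idx < meta["n_real"]]
        if len(real_idx):
            votes[real_idx] += model.predict(X[real_idx])
            counts[real_idx] += 1
    with np.errstate(invalid="ignore"):
        return votes / counts


# --------------------------------------------------------------------------
# Pathway scoring
# --------------------------------------------------------------------------

def score_pathway(
    pathway: CandidatePathway, ensemble: EnsembleModel, score_mode: str = "ratio"
) -> CandidatePathway:
    """Fill v_r per segment, feasibility v_p = Π v_r and score s.

    ``score_mode="ratio"`` (default) uses s = |e| / v_p, lower is better,
    with v_p = 0 mapped to +inf; ``"product"`` uses s = |e| · v_p, provided
    for comparison (under it a feasible pathway with |e| = 0 still scores 0).
    Segment inputs are the combined reaction vector and the decoded segment
    substrate's tree and graph latents.
    """
    if score_mode not in ("ratio", "product"):
        raise ParameterError(f"unknown score_mode {score_mode!r}")
    rows = []
    for feat, sub in zip(pathway.ordered_reactions, pathway.substrate_encodings):
        if sub is None:
            raise ScoringError("segment substrate undecoded; cannot score pathway")
        if feat.vector.part != "combined":
            raise ScoringError("scoring requires combined-part reaction vectors")
        rows.append(
            np.concatenate([feat.vector.values, sub.tree_latent.values, sub.graph_latent.values])
        )
    v_r = ensemble.votes(np.stack(rows))
    v_p = float(np.prod(v_r))
    pathway.v_r = [float(v) for v in v_r]
    pathway.v_p = v_p
    if score_mode == "product":
        pathway.score = pathway.abs_error * v_p
    else:
        pathway.score = (pathway.abs_error / v_p) if v_p > 0 else math.inf
    return pathway


def rank_pathways(pathways) -> list[CandidatePathway]:
    """Ascending by score; ties broken by higher feasibility, then lower |e|."""
    return sorted(
        pathways,
        key=lambda pw: (
            pw.score if pw.score is not None else math.inf,
            -(pw.v_p if pw.v_p is not None else 0.0),
            pw.abs_error,
        ),
    )


def summarize_possibilities(ensemble: EnsembleModel, groups: dict) -> dict:
    """Per-recipe mean ± population standard deviation of v_r.

    ``groups`` maps a recipe name to its examples; the returned mapping holds
    ``{"mean", "std", "n", "label"}`` per group, mirroring the 2×2
    pair-type × substrate-in/out layout.
    """
    out = {}
    for name, examples in groups.items():
        if not len(examples):
            raise ParameterError(f"group {name!r} is empty")
        v = ensemble.votes(example_matrix(examples))
        out[name] = {
            "mean": float(np.mean(v)),
            "std": float(np.std(v)),
            "n": int(len(v)),
            "label": RECIPE_LABELS.get(name, name),
        }
    return out
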