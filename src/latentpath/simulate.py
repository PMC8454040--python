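"""Seeded synthetic worlds with class-structured reactions and planted pathways.

The generator emulates the statistical structure the method relies on, inside
the exactly-linear toy chemistry:

- each synthetic EC class has an integer *fragment-change motif* — all
  reactions of the class change the substrate's fragment counts by that motif
  (optionally ±1 on one fragment, the within-class noise) — so
  reaction-feature vectors cluster tightly by class while classes stay far
  apart (tunable via ``separation``);
- each class also has an *anchor fragment* its substrates must carry in
  quantity (≥4 copies, while unrelated compounds carry 0–2 of any fragment)
  and its reaction consumes 2–3 copies of that anchor — a stand-in for enzyme
  substrate specificity: applying a reaction to an incompatible substrate
  implies an impossible (negative-count) product, so whether a substrate fits
  a reaction vector is learnable and rarely satisfied by chance, which is
  what separates "substrate in" from "substrate out" examples;
- planted queries are start/target pairs connected by known chains of
  *unperturbed* class motifs, so the planted reaction sequence satisfies
  |e| = 0 exactly, and the manifest records the ground truth.

Synthetic EC numbers are hierarchical (``a.b.c.serial``) with several
three-digit classes sharing two-digit prefixes, so confusion-matrix
aggregation is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EncodedCompound, ToyChemistry, encode_compounds
from .errors import ParameterError
from .reactions import ReactionFeatureDB, ReactionRecord, build_reaction_db

# Non-anchor fragment counts range 0..2; a class's substrates carry 4..7
# copies of the class anchor fragment while its reaction consumes 2-3, so a
# valid substrate keeps a clear positive margin (implied product anchor >= 1)
# and a random compound almost never qualifies as a substrate by chance.
_BASE_COUNT_MAX = 2
_ANCHOR_MIN = 4
_ANCHOR_MAX = 7


def _class_ec_prefix(cls: int) -> str:
    """Three-digit synthetic EC prefix for a class index (hierarchically spread)."""
    return f"{cls % 3 + 1}.{cls // 6 + 1}.{(cls // 3) % 2 + 1}"


@dataclass(frozen=True)
class PlantedQuery:
    """Ground truth for one planted exploration problem.

    Reactions of one class built from the unperturbed motif share an
    identical feature vector, so recovery is identifiable at the
    three-digit-class level (``ec_class_sequence``), not at the level of a
    specific registered reaction.
    """

    start_id: str
    target_id: str
    ec_sequence: tuple[str, ...]
    class_sequence: tuple[int, ...]
    intermediate_ids: tuple[str, ...]

    @property
    def ec_class_sequence(self) -> tuple[str, ...]:
        from .reactions import truncate_ec

        return tuple(truncate_ec(ec, 3) for ec in self.ec_sequence)


@dataclass
class SimulatedWorld:
    backend: ToyChemistry
    compounds: dict[str, EncodedCompound]
    records: list[ReactionRecord]
    db: ReactionFeatureDB  # combined part
    manifest: list[PlantedQuery]
    motifs: np.ndarray  # (n_classes, n_fragments) integer fragment-change motifs
    anchors: np.ndarray  # (n_classes,) anchor fragment per class
    seed: int


def simulate(
    n_compounds: int = 120,
    n_reactions: int = 240,
    n_ec_classes: int = 6,
    planted_lengths: tuple[int, ...] = (1, 2),
    seed: int = 0,
    n_fragments: int = 8,
    latent_dim: int = 8,
    separation: float = 1.0,
    perturb_prob: float = 0.25,
    graph_mode: str = "mirror",
) -> SimulatedWorld:
    """Build a toy universe, a class-clustered reaction DB and planted queries.

    ``separation`` scales the class motifs (0 collapses every class onto pure
    noise, dropping EC classification to chance); ``perturb_prob`` is the
    fraction of reactions whose fragment change deviates from the class motif
    by ±1 on one fragment.
    """
    if n_ec_classes < 2 or n_reactions < n_ec_classes:
        raise ParameterError("need >= 2 classes and at least one reaction per class")
    if not (latent_dim >= n_fragments >= 2):
        raise ParameterError("require latent_dim >= n_fragments >= 2")
    if any(l < 1 for l in planted_lengths):
        raise ParameterError("planted pathway lengths must be >= 1")
    rng = np.random.default_rng(seed)

    masses = rng.uniform(10.0, 40.0, size=n_fragments)
    mixing = rng.standard_normal((latent_dim, n_fragments))
    while np.linalg.matrix_rank(mixing) < n_fragments:  # pragma: no cover
        mixing = rng.standard_normal((latent_dim, n_fragments))

    # Distinct class motifs with moderate L1 size.  Each class's reaction
    # consumes 2-3 copies of its anchor fragment, so a substrate lacking the
    # anchor implies a negative-count (impossible) product: substrate
    # compatibility and product validity are one coupled, learnable cue.
    anchors = np.array([c % n_fragments for c in range(n_ec_classes)])
    motifs, seen_motifs = [], set()
    while len(motifs) < n_ec_classes:
        m = rng.integers(-2, 3, size=n_fragments)
        m[anchors[len(motifs)]] = -int(rng.integers(2, 4))
        l1 = int(np.abs(m).sum())
        if 3 <= l1 <= 8 and tuple(m) not in seen_motifs:
            seen_motifs.add(tuple(m))
            motifs.append(m)
    motifs = np.array(motifs)
    deltas = np.rint(motifs * separation).astype(np.int64)

    universe: dict[tuple, str] = {}
    order: list[tuple] = []

    def add_compound(counts: np.ndarray) -> str:
        key = tuple(int(c) for c in counts)
        if key not in universe:
            universe[key] = f"T{len(universe):05d}"
            order.append(key)
        return universe[key]

    def sample_substrate(cls: int) -> np.ndarray:
        counts = rng.integers(0, _BASE_COUNT_MAX + 1, size=n_fragments)
        counts[anchors[cls]] = rng.integers(_ANCHOR_MIN, _ANCHOR_MAX + 1)
        return counts

    def reaction_delta(cls: int) -> np.ndarray:
        delta = deltas[cls].copy()
        perturb = rng.random() < perturb_prob
        while perturb or not delta.any():
            j = int(rng.integers(n_fragments))
            delta[j] += rng.choice((-1, 1))
            perturb = False
        return delta

    records: list[ReactionRecord] = []
    serial = 0
    for r in range(n_reactions):
        cls = r % n_ec_classes
        for _ in range(1000):
            sub = sample_substrate(cls)
            delta = reaction_delta(cls)
            pro = sub + delta
            if np.all(pro >= 0) and pro.any() and sub.any():
                break
        else:  # pragma: no cover
            raise ParameterError("could not sample a feasible reaction; adjust motifs")
        serial += 1
        records.append(
            ReactionRecord(f"{_class_ec_prefix(cls)}.{serial}", add_compound(sub), add_compound(pro))
        )

    # Planted chains of unperturbed motifs; registered like any other reaction.
    manifest: list[PlantedQuery] = []
    for qi, length in enumerate(planted_lengths):
        for attempt in range(2000):
            # rotate the class sequence occasionally in case one is infeasible
            classes = tuple((qi + attempt // 200 + j) % n_ec_classes for j in range(length))
            start = rng.integers(0, _BASE_COUNT_MAX + 1, size=n_fragments)
            for cls in classes:  # a chain substrate carries every step's anchor moiety
                start[anchors[cls]] = rng.integers(_ANCHOR_MIN, _ANCHOR_MAX + 1)
            chain = [start]
            ok = True
            for step, cls in enumerate(classes):
                nxt = chain[-1] + deltas[cls]
                if np.any(nxt < 0) or not nxt.any() or not deltas[cls].any():
                    ok = False
                    break
                if step + 1 < length and nxt[anchors[classes[step + 1]]] < _ANCHOR_MIN:
                    ok = False
                    break
                chain.append(nxt)
            if ok and not np.array_equal(chain[0], chain[-1]):
                break
        else:
            raise ParameterError("could not plant a feasible pathway; adjust sizes/motifs")
        ids = [add_compound(c) for c in chain]
        ecs = []
        for step, cls in enumerate(classes):
            serial += 1
            ec = f"{_class_ec_prefix(cls)}.{serial}"
            records.append(ReactionRecord(ec, ids[step], ids[step + 1]))
            ecs.append(ec)
        manifest.append(
            PlantedQuery(ids[0], ids[-1], tuple(ecs), classes, tuple(ids[1:-1]))
        )

    # Pad the universe with random distinct compounds up to n_compounds.
    while len(universe) < n_compounds:
        c = rng.integers(0, _BASE_COUNT_MAX + 1, size=n_fragments)
        if c.any():
            add_compound(c)

    backend = ToyChemistry(
        masses,
        mixing,
        {cid: np.array(key) for key, cid in universe.items()},
        seed=seed,
        graph_mode=graph_mode,
    )
    compounds = encode_compounds(backend, backend.compound_ids)
    db = build_reaction_db(records, backend, compounds, part="combined")
    return SimulatedWorld(backend, compounds, records, db, manifest, motifs, anchors, seed)


# Study conditions for the scaled-down four-recipe possibility benchmark:
# 1000 registered reactions over 12 classes so that one real dataset balances
# one 1000-record virtual dataset (the reference combined dataset is likewise
# near-balanced), with a class count rich enough that the reaction vector
# alone does not trivially give away pair realness.
SCORING_BENCHMARK_CONDITIONS = dict(
    n_reactions=1000, n_ec_classes=12, n_fragments=12, latent_dim=12
)


def scoring_benchmark_world(seed: int) -> SimulatedWorld:
    """The fixed synthetic world used for the reaction-possibility benchmark."""
    return simulate(seed=seed, **SCORING_BENCHMARK_CONDITIONS)
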