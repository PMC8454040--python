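"""Reaction-feature vectors and the EC-annotated reaction-feature database.

An enzymatic reaction is represented by the difference vector between its
main product's and main substrate's latent vectors,

    r = z_pro − z_sub,

recorded together with the reaction's EC number and the registered
molecular-weight change ΔMW = MW(product) − MW(substrate).  Cofactors and
co-substrates are ignored: a reaction *is* its main substrate → main product
pair.  The database keeps one feature per input record (duplicates included,
as given) in stable input order and supports retrieval by full EC number or
any dotted-field prefix, plus nearest-vector queries in Euclidean distance.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import EmbeddingBackend, EncodedCompound, LatentVector, check_compatible
from .errors import DimensionError, EmptyDatabaseError, FormatError, ParameterError

logger = logging.getLogger(__name__)

_EC_RE = re.compile(r"^\d+(\.\d+){0,3}$")


def truncate_ec(ec_number: str, digits: int) -> str:
    """Truncate an EC number to its first ``digits`` dotted fields."""
    return ".".join(ec_number.split(".")[:digits])


def ec_matches_prefix(ec_number: str, prefix: str) -> bool:
    fields = ec_number.split(".")
    want = prefix.split(".")
    return len(want) <= len(fields) and fields[: len(want)] == want


@dataclass(frozen=True)
class ReactionRecord:
    """EC number plus main-substrate / main-product compound ids."""

    ec_number: str
    substrate_id: str
    product_id: str

    def __post_init__(self):
        if not _EC_RE.match(self.ec_number):
            raise ParameterError(f"malformed EC number {self.ec_number!r}")
        if self.substrate_id == self.product_id:
            raise ParameterError("substrate and product ids must differ")


@dataclass(frozen=True)
class ReactionFeature:
    """A registered reaction: record, latent difference vector, registered ΔMW."""

    record: ReactionRecord
    vector: LatentVector
    delta_mw_registered: float

    @property
    def ec_number(self) -> str:
        return self.record.ec_number


def compute_reaction_vector(z_sub: LatentVector, z_pro: LatentVector) -> LatentVector:
    """Latent difference r = z_pro − z_sub (same part, same dimension)."""
    check_compatible(z_sub, z_pro)
    return LatentVector(z_pro.values - z_sub.values, z_sub.part)


class ReactionFeatureDB:
    """Ordered collection of reaction features with EC-prefix indexing.

    When built with the combined part, the tree and graph sub-vectors remain
    individually addressable (the combined vector is their concatenation), so
    one database serves both pathway design (tree part) and possibility
    scoring (combined part).
    """

    def __init__(self, features, part: str, tree_dim: int = 0, graph_dim: int = 0):
        self.features: list[ReactionFeature] = list(features)
        if not self.features:
            raise EmptyDatabaseError("reaction-feature DB has no usable records")
        self.part = part
        self.tree_dim = int(tree_dim)
        self.graph_dim = int(graph_dim)
        dim = self.features[0].vector.dimension
        for f in self.features:
            if f.vector.part != part or f.vector.dimension != dim:
                raise DimensionError("all features must share the DB's part and dimension")
        self.dimension = dim
        if part == "combined" and self.tree_dim + self.graph_dim != dim:
            raise DimensionError("tree_dim + graph_dim must equal the combined dimension")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i) -> ReactionFeature:
        return self.features[i]

    def by_ec_prefix(self, prefix: str) -> list[ReactionFeature]:
        """All features whose EC number starts with the dotted prefix, in DB order."""
        return [f for f in self.features if ec_matches_prefix(f.ec_number, prefix)]

    def ec_numbers(self) -> list[str]:
        return [f.ec_number for f in self.features]

    def vector_matrix(self, part: str | None = None) -> np.ndarray:
        """Stacked feature vectors, optionally sliced to a sub-part.

        A combined-part DB can be sliced to ``"tree"`` (first ``tree_dim``
        columns) or ``"graph"`` (remaining columns).
        """
        mat = np.stack([f.vector.values for f in self.features])
        if part is None or part == self.part:
            return mat
        if self.part == "combined" and part == "tree":
            return mat[:, : self.tree_dim]
        if self.part == "combined" and part == "graph":
            return mat[:, self.tree_dim :]
        raise ParameterError(f"part {part!r} unavailable in a {self.part!r}-part DB")


def build_reaction_db(
    records,
    backend: EmbeddingBackend,
    compounds: dict[str, EncodedCompound] | None = None,
    part: str = "tree",
) -> ReactionFeatureDB:
    """Encode every reaction record into a feature vector, in input order.

    ``compounds`` is an optional pre-encoded lookup table; ids not found there
    are encoded on demand through the backend.  Records whose substrate or
    product cannot be encoded are skipped and counted in the log.
    """
    cache: dict[str, EncodedCompound] = dict(compounds or {})

    def lookup(cid: str) -> EncodedCompound:
        if cid not in cache:
            cache[cid] = backend.encode(cid)
        return cache[cid]

    features, skipped = [], 0
    for rec in records:
        try:
            sub = lookup(rec.substrate_id)
            pro = lookup(rec.product_id)
        except Exception:
            skipped += 1
            continue
        vec = compute_reaction_vector(sub.latent(part), pro.latent(part))
        features.append(
            ReactionFeature(rec, vec, pro.molecular_weight - sub.molecular_weight)
        )
    if skipped:
        logger.info("build_reaction_db: skipped %d record(s) that failed to encode", skipped)
    if not features:
        raise EmptyDatabaseError("no records could be encoded")
    tree_dim = backend.tree_dim if part in ("tree", "combined") else 0
    graph_dim = backend.graph_dim if part in ("graph", "combined") else 0
    db = ReactionFeatureDB(features, part, tree_dim=tree_dim, graph_dim=graph_dim)
    db.skipped = skipped
    return db


def nearest_reactions(
    db: ReactionFeatureDB,
    query: LatentVector,
    ec_prefix: str | None = None,
    k: int = 5,
) -> list[tuple[ReactionFeature, float]]:
    """The ``k`` stored reactions nearest to ``query`` in Euclidean distance.

    Optionally restricted to an EC-number prefix.  Ties preserve DB order
    (stable sort); if fewer than ``k`` features match, all are returned.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    pool = db.by_ec_prefix(ec_prefix) if ec_prefix is not None else db.features
    if not pool:
        return []
    if query.dimension != pool[0].vector.dimension:
        raise DimensionError("query dimension does not match DB vectors")
    mat = np.stack([f.vector.values for f in pool])
    dist = np.sqrt(np.sum((mat - query.values) ** 2, axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    return [(pool[int(i)], float(dist[int(i)])) for i in order]


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def write_reaction_db(db: ReactionFeatureDB, path) -> None:
    """Write the DB as schema-versioned JSON with full-precision vectors."""
    payload = {
        "schema": 1,
        "part": db.part,
        "tree_dim": db.tree_dim,
        "graph_dim": db.graph_dim,
        "features": [
            {
                "ec_number": f.record.ec_number,
                "substrate_id": f.record.substrate_id,
                "product_id": f.record.product_id,
                "delta_mw_registered": f.delta_mw_registered,
                "vector": f.vector.values.tolist(),
            }
            for f in db.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_reaction_db(path) -> ReactionFeatureDB:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid JSON: {exc}") from exc
    for key in ("part", "features"):
        if key not in payload:
            raise FormatError(f"reaction-DB file missing field {key!r}")
    features = []
    for i, row in enumerate(payload["features"]):
        missing = {"ec_number", "substrate_id", "product_id", "vector"} - set(row)
        if missing:
            raise FormatError(f"feature {i}: missing field(s) {sorted(missing)}")
        features.append(
            ReactionFeature(
                ReactionRecord(row["ec_number"], row["substrate_id"], row["product_id"]),
                LatentVector(np.array(row["vector"], dtype=np.float64), payload["part"]),
                float(row.get("delta_mw_registered", 0.0)),
            )
        )
    return ReactionFeatureDB(
        features,
        payload["part"],
        tree_dim=payload.get("tree_dim", 0),
        graph_dim=payload.get("graph_dim", 0),
    )


def read_reaction_table(path) -> list[ReactionRecord]:
    """Read a TSV/CSV reaction table with columns ``ec_number, substrate_id, product_id``."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"ec_number", "substrate_id", "product_id"} - set(df.columns)
    if missing:
        raise FormatError(f"reaction table missing column(s): {sorted(missing)}")
    return [
        ReactionRecord(r.ec_number, r.substrate_id, r.product_id)
        for r in df.itertuples(index=False)
    ]
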