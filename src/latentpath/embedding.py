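"""Chemical latent-space embedding backends.

Every downstream stage (reaction features, pathway design, possibility
scoring) only needs three things from a chemistry: a deterministic encoder
from structure strings to fixed-dimension latent vectors (a *tree* part
capturing backbone structure and a *graph* part), a decoder from latent
vectors back to structures, and exact molecular weights.  The
:class:`EmbeddingBackend` ABC is that contract; an adapter to any pretrained
generative encoder/decoder implements it.

The default backend is :class:`ToyChemistry`, a fully synthetic, exactly
linear chemistry: compounds are non-negative integer fragment-count vectors,
encoding is a full-rank linear map of the counts, molecular weight is the
exact dot product of counts with fragment masses, and decoding snaps a latent
point to the nearest compound of a finite universe.  Linearity makes latent
reaction arithmetic exact, so every pipeline stage is testable end to end
without a trained generative model.
"""

from __future__ import annotations

import json
import re
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CapabilityError,
    DimensionError,
    FormatError,
    ParameterError,
    StructureError,
    UnsupportedCompoundError,
)

PARTS = ("tree", "graph", "combined")


@dataclass(frozen=True, eq=False)
class LatentVector:
    """A point (or difference) in chemical latent space.

    Parameters
    ----------
    values : ndarray
        1-D float64 array; all entries finite.
    part : {"tree", "graph", "combined"}
        Which latent component the values belong to.  The combined part is
        the concatenation ``[tree ‖ graph]``.
    """

    values: np.ndarray
    part: str

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise DimensionError(f"latent values must be 1-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise DimensionError("latent values must all be finite")
        if self.part not in PARTS:
            raise ParameterError(f"unknown latent part {self.part!r}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def dimension(self) -> int:
        return int(self.values.shape[0])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LatentVector)
            and self.part == other.part
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # short, array omitted
        return f"LatentVector(part={self.part!r}, dimension={self.dimension})"


def check_compatible(a: LatentVector, b: LatentVector) -> None:
    """Raise :class:`DimensionError` unless ``a`` and ``b`` share part and dimension."""
    if a.part != b.part:
        raise DimensionError(f"latent parts differ: {a.part!r} vs {b.part!r}")
    if a.dimension != b.dimension:
        raise DimensionError(f"latent dimensions differ: {a.dimension} vs {b.dimension}")


@dataclass(frozen=True)
class EncodedCompound:
    """A compound together with its latent embedding and molecular weight (u)."""

    compound_id: str
    smiles: str
    tree_latent: LatentVector
    graph_latent: LatentVector
    molecular_weight: float

    @property
    def combined_latent(self) -> LatentVector:
        return LatentVector(
            np.concatenate([self.tree_latent.values, self.graph_latent.values]),
            "combined",
        )

    def latent(self, part: str) -> LatentVector:
        if part == "tree":
            return self.tree_latent
        if part == "graph":
            return self.graph_latent
        if part == "combined":
            return self.combined_latent
        raise ParameterError(f"unknown latent part {part!r}")


class EmbeddingBackend(ABC):
    """Encoder/decoder contract over a chemical latent space.

    Implementations must be deterministic at inference: encoding the same
    structure twice yields bit-identical latents (posterior means, never
    samples), so that reaction-vector arithmetic is reproducible.
    """

    name: str = "abstract"

    @property
    @abstractmethod
    def tree_dim(self) -> int: ...

    @property
    @abstractmethod
    def graph_dim(self) -> int: ...

    @property
    def combined_dim(self) -> int:
        return self.tree_dim + self.graph_dim

    @property
    @abstractmethod
    def can_decode(self) -> bool: ...

    @abstractmethod
    def encode(self, smiles_or_id: str) -> EncodedCompound:
        """Encode a structure string (or registered compound id)."""

    @abstractmethod
    def decode(self, latent: LatentVector) -> str | None:
        """Decode a latent vector to a structure string, or ``None`` on failure.

        Decode failure is a represented outcome, not an exception; exceptions
        are reserved for contract violations (wrong dimension, no decoder).
        """


# --------------------------------------------------------------------------
# Toy chemistry
# --------------------------------------------------------------------------

_RENDER_RE = re.compile(r"^f(\d+):(\d+)$")


def render_counts(counts: np.ndarray) -> str:
    """Canonical structure string of a fragment-count vector, e.g. ``"f0:2+f3:1"``."""
    parts = [f"f{i}:{int(c)}" for i, c in enumerate(counts) if c > 0]
    return "+".join(parts) if parts else "empty"


def parse_counts(smiles: str, n_fragments: int) -> np.ndarray:
    counts = np.zeros(n_fragments, dtype=np.int64)
    if smiles == "empty":
        return counts
    for token in smiles.split("+"):
        m = _RENDER_RE.match(token.strip())
        if m is None:
            raise StructureError(f"cannot parse toy structure token {token!r}")
        idx, c = int(m.group(1)), int(m.group(2))
        if idx >= n_fragments:
            raise StructureError(f"fragment index {idx} outside 0..{n_fragments - 1}")
        counts[idx] = c
    return counts


class ToyChemistry(EmbeddingBackend):
    """Deterministic synthetic chemistry over a finite compound universe.

    Compounds are non-negative integer fragment-count vectors.  The tree
    latent of a compound is ``mixing_matrix @ counts`` (a full-rank linear,
    hence injective, map), its molecular weight the exact dot product
    ``counts · fragment_masses``.  The graph latent depends on ``graph_mode``:

    - ``"mirror"`` (default): identical to the tree latent;
    - ``"linear"``: a second full-rank linear map ``graph_matrix @ counts``;
    - ``"random"``: a deterministic pseudo-random vector per compound,
      carrying *no* structural signal — useful for contrasting parts.

    Decoding maps a latent back through the Moore–Penrose pseudo-inverse of
    the mixing matrix and returns the universe compound whose count vector is
    nearest in Euclidean distance, ties broken by lowest compound id.
    """

    name = "toy"

    def __init__(
        self,
        fragment_masses,
        mixing_matrix,
        universe: dict[str, np.ndarray],
        seed: int = 0,
        graph_mode: str = "mirror",
        graph_matrix=None,
    ):
        self.fragment_masses = np.asarray(fragment_masses, dtype=np.float64)
        if np.any(self.fragment_masses <= 0):
            raise ParameterError("fragment masses must be positive")
        self.mixing_matrix = np.asarray(mixing_matrix, dtype=np.float64)
        n_frag = self.fragment_masses.shape[0]
        if self.mixing_matrix.ndim != 2 or self.mixing_matrix.shape[1] != n_frag:
            raise ParameterError("mixing_matrix must be (latent_dim, n_fragments)")
        if np.linalg.matrix_rank(self.mixing_matrix) < n_frag:
            raise ParameterError("mixing_matrix must have full column rank")
        if graph_mode not in ("mirror", "linear", "random"):
            raise ParameterError(f"unknown graph_mode {graph_mode!r}")
        if graph_mode == "linear":
            if graph_matrix is None:
                raise ParameterError("graph_mode='linear' requires graph_matrix")
            graph_matrix = np.asarray(graph_matrix, dtype=np.float64)
            if graph_matrix.shape[1] != n_frag:
                raise ParameterError("graph_matrix must be (graph_dim, n_fragments)")
        self.graph_matrix = graph_matrix
        self.graph_mode = graph_mode
        self.seed = int(seed)

        # Universe in sorted-id order so argmin tie-breaks to the lowest id.
        ids = sorted(universe)
        if len(ids) < 1:
            raise ParameterError("universe must be non-empty")
        self._ids = ids
        self._counts = np.array(
            [np.asarray(universe[i], dtype=np.int64) for i in ids]
        )
        if self._counts.shape[1] != n_frag:
            raise ParameterError("universe count vectors must have n_fragments entries")
        if np.any(self._counts < 0):
            raise ParameterError("fragment counts must be non-negative")
        keys = [tuple(c) for c in self._counts]
        if len(set(keys)) != len(keys):
            raise ParameterError("universe compounds must be distinct")
        self._by_counts = {k: ids[i] for i, k in enumerate(keys)}
        self._by_id = {ids[i]: self._counts[i] for i in range(len(ids))}
        self._pinv = np.linalg.pinv(self.mixing_matrix)
        self._index_of = {cid: i for i, cid in enumerate(ids)}

    # -- contract properties -------------------------------------------------

    @property
    def tree_dim(self) -> int:
        return self.mixing_matrix.shape[0]

    @property
    def graph_dim(self) -> int:
        if self.graph_mode == "mirror":
            return self.mixing_matrix.shape[0]
        if self.graph_mode == "linear":
            return self.graph_matrix.shape[0]
        return self.mixing_matrix.shape[0]  # random mode mirrors the tree dim

    @property
    def can_decode(self) -> bool:
        return True

    @property
    def n_fragments(self) -> int:
        return self.fragment_masses.shape[0]

    @property
    def compound_ids(self) -> list[str]:
        return list(self._ids)

    def counts_of(self, compound_id: str) -> np.ndarray:
        try:
            return self._by_id[compound_id].copy()
        except KeyError:
            raise UnsupportedCompoundError(f"unknown compound id {compound_id!r}") from None

    def id_for_counts(self, counts) -> str | None:
        return self._by_counts.get(tuple(int(c) for c in counts))

    # -- encode / decode -----------------------------------------------------

    def _graph_latent_values(self, counts: np.ndarray, compound_id: str) -> np.ndarray:
        if self.graph_mode == "mirror":
            return self.mixing_matrix @ counts
        if self.graph_mode == "linear":
            return self.graph_matrix @ counts
        # random: deterministic per compound, independent of structure
        idx = self._index_of[compound_id]
        rng = np.random.default_rng((self.seed, 0x6A7, idx))
        return rng.standard_normal(self.graph_dim)

    def encode(self, smiles_or_id: str) -> EncodedCompound:
        if smiles_or_id in self._by_id:
            cid = smiles_or_id
            counts = self._by_id[cid]
        else:
            counts = parse_counts(smiles_or_id, self.n_fragments)
            cid = self.id_for_counts(counts)
            if cid is None:
                raise UnsupportedCompoundError(
                    f"structure {smiles_or_id!r} is outside the toy universe"
                )
        tree = LatentVector(self.mixing_matrix @ counts, "tree")
        graph = LatentVector(self._graph_latent_values(counts, cid), "graph")
        mw = float(np.dot(counts, self.fragment_masses))
        return EncodedCompound(cid, render_counts(counts), tree, graph, mw)

    def decode(self, latent: LatentVector) -> str | None:
        if latent.part == "tree":
            z = latent.values
            if latent.dimension != self.tree_dim:
                raise DimensionError(
                    f"expected tree dimension {self.tree_dim}, got {latent.dimension}"
                )
        elif latent.part == "combined":
            if latent.dimension != self.combined_dim:
                raise DimensionError(
                    f"expected combined dimension {self.combined_dim}, got {latent.dimension}"
                )
            z = latent.values[: self.tree_dim]
        else:
            raise CapabilityError("toy backend decodes tree or combined latents only")
        est = self._pinv @ z
        d2 = np.sum((self._counts - est) ** 2, axis=1)
        # argmin returns the first minimum; universe is in sorted-id order,
        # so exact ties resolve to the lowest compound id.
        return render_counts(self._counts[int(np.argmin(d2))])

    # -- serialization -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema": 1,
            "seed": self.seed,
            "graph_mode": self.graph_mode,
            "fragment_masses": self.fragment_masses.tolist(),
            "mixing_matrix": self.mixing_matrix.tolist(),
            "graph_matrix": None if self.graph_matrix is None else self.graph_matrix.tolist(),
            "universe": {cid: self._by_id[cid].tolist() for cid in self._ids},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ToyChemistry":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("fragment_masses", "mixing_matrix", "universe", "seed"):
            if key not in payload:
                raise FormatError(f"toy-universe file missing field {key!r}")
        return cls(
            payload["fragment_masses"],
            payload["mixing_matrix"],
            {k: np.asarray(v) for k, v in payload["universe"].items()},
            seed=payload["seed"],
            graph_mode=payload.get("graph_mode", "mirror"),
            graph_matrix=payload.get("graph_matrix"),
        )


def make_toy_universe(
    n_compounds: int,
    n_fragments: int,
    latent_dim: int,
    seed: int,
    max_count: int = 4,
    graph_mode: str = "mirror",
) -> ToyChemistry:
    """Generate a reproducible random toy chemistry.

    Fragment masses are drawn uniformly from 10–40 u, the mixing matrix is
    standard normal (redrawn until full rank, which is almost sure), and the
    universe consists of ``n_compounds`` distinct non-zero count vectors with
    entries in ``0..max_count``.
    """
    if n_compounds < 2:
        raise ParameterError("need at least 2 compounds")
    if not (latent_dim >= n_fragments >= 1):
        raise ParameterError("require latent_dim >= n_fragments >= 1")
    if (max_count + 1) ** n_fragments - 1 < n_compounds:
        raise ParameterError("count space too small for requested universe size")
    rng = np.random.default_rng(seed)
    masses = rng.uniform(10.0, 40.0, size=n_fragments)
    mixing = rng.standard_normal((latent_dim, n_fragments))
    while np.linalg.matrix_rank(mixing) < n_fragments:  # pragma: no cover
        mixing = rng.standard_normal((latent_dim, n_fragments))
    seen: dict[tuple, None] = {}
    while len(seen) < n_compounds:
        c = rng.integers(0, max_count + 1, size=n_fragments)
        if c.any():
            seen.setdefault(tuple(int(x) for x in c), None)
    width = max(4, len(str(n_compounds)))
    universe = {f"T{i:0{width}d}": np.array(k) for i, k in enumerate(seen)}
    return ToyChemistry(masses, mixing, universe, seed=seed, graph_mode=graph_mode)


# --------------------------------------------------------------------------
# Compound tables
# --------------------------------------------------------------------------

def read_compound_table(path) -> pd.DataFrame:
    """Read a TSV/CSV compound table with columns ``compound_id, smiles``."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"compound_id", "smiles"} - set(df.columns)
    if missing:
        raise FormatError(f"compound table missing column(s): {sorted(missing)}")
    return df[["compound_id", "smiles"]]


def encode_compounds(backend: EmbeddingBackend, ids) -> dict[str, EncodedCompound]:
    """Encode an iterable of compound ids (or structures) into a lookup table."""
    return {cid: backend.encode(cid) for cid in ids}
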