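"""Candidate-pathway design.

A desired overall transformation is the pathway-feature vector

    p = z_target − z_start,

and designing a pathway means picking a small set of registered
reaction-feature vectors whose sum approximates p.  The design loop is:

(i)   compute p;
(ii)  draw a random subset of M reaction features from the DB;
(iii) select reactions within the subset by a binary differential-evolution
      (DE/rand/1) search minimising f(x) = |e|² + λ, where
      |e|² = ‖p − Σᵢ xᵢ rᵢ‖² and λ penalises selections longer than the
      maximum step count K;
(iv)  order the selected reactions every possible way and reconstruct the
      intermediate compounds by decoding the cumulative latent sums;
(v)   prune orderings whose per-segment molecular-weight change deviates
      from the registered ΔMW of the segment's reaction by more than a
      tolerance (default ±3 u).

Repeating (ii)–(v) accumulates a deduplicated candidate-pathway list.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .embedding import EmbeddingBackend, EncodedCompound, LatentVector, check_compatible
from .errors import DimensionError, ParameterError
from .reactions import ReactionFeature, ReactionFeatureDB, compute_reaction_vector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayQuery:
    """Start/target compound ids and their pathway-feature vector p."""

    start_id: str
    target_id: str
    p: LatentVector


def compute_pathway_vector(
    z_start: LatentVector, z_target: LatentVector, start_id: str = "", target_id: str = ""
) -> PathwayQuery:
    """p = z_target − z_start."""
    check_compatible(z_start, z_target)
    return PathwayQuery(start_id, target_id, compute_reaction_vector(z_start, z_target))


@dataclass
class DEConfig:
    """Binary-DE and design-loop parameters.

    Defaults follow the reference operating point: scaling F = 0.5, crossover
    rate CR = 0.5, penalty constant C = 1000.0, error threshold Th = 50.0,
    population 2000, at most 50 generations, subset size 500, at most K = 3
    reaction steps, 2000 repetitions.  Desk-scale runs override population,
    subset size and repetitions downward.
    """

    F: float = 0.5
    CR: float = 0.5
    population: int = 2000
    max_generations: int = 50
    subset_size: int = 500
    max_steps: int = 3
    error_threshold: float = 50.0
    penalty_constant: float = 1000.0
    repetitions: int = 2000
    seed: int = 0
    penalty_mode: str = "exp_squared"  # C·(e^xlen)²; alternative: "exp_of_square"
    guaranteed_crossover: bool = True  # one component always taken from the mutant
    early_stop: bool = True  # stop once best |e| <= error_threshold
    mw_tolerance: float = 3.0

    def __post_init__(self):
        if self.population < 4:
            raise ParameterError("population must be >= 4 (three parents + current)")
        if self.subset_size < 1 or self.max_steps < 1:
            raise ParameterError("subset_size and max_steps must be >= 1")
        if self.error_threshold <= 0:
            raise ParameterError("error_threshold must be > 0")
        if not (0.0 <= self.CR <= 1.0):
            raise ParameterError("CR must lie in [0, 1]")
        if self.penalty_mode not in ("exp_squared", "exp_of_square"):
            raise ParameterError(f"unknown penalty_mode {self.penalty_mode!r}")


@dataclass
class SelectionResult:
    subset: list[ReactionFeature]
    x: np.ndarray  # binary selection vector over the subset
    squared_error: float
    fitness: float
    generations_run: int
    trace: list[float] = field(default_factory=list)  # best fitness per generation

    @property
    def selected(self) -> list[ReactionFeature]:
        return [f for f, xi in zip(self.subset, self.x) if xi]

    @property
    def abs_error(self) -> float:
        return math.sqrt(self.squared_error)


def sample_subset(db: ReactionFeatureDB, m: int, seed) -> list[ReactionFeature]:
    """Uniform sample of ``m`` features without replacement, reproducible per seed."""
    if m > len(db):
        raise ParameterError(f"subset size {m} exceeds DB size {len(db)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(db), size=m, replace=False)
    return [db[int(i)] for i in idx]


def subset_coverage_probability(db_size: int, planted: int, m: int) -> float:
    """P(all ``planted`` required features land in a uniform subset of size ``m``).

    Hypergeometric: C(db_size − planted, m − planted) / C(db_size, m).
    Monotone increasing in m — larger subsets are likelier to cover the
    reactions a pathway needs, at higher per-repetition search cost.
    """
    if m < planted:
        return 0.0
    lognum = gammaln(db_size - planted + 1) - gammaln(m - planted + 1) - gammaln(db_size - m + 1)
    logden = gammaln(db_size + 1) - gammaln(m + 1) - gammaln(db_size - m + 1)
    return float(np.exp(lognum - logden))


# --------------------------------------------------------------------------
# Fitness
# --------------------------------------------------------------------------

def penalty(x_len: int, max_steps: int, constant: float, mode: str = "exp_squared") -> float:
    """λ: zero when x_len ≤ K, a steeply growing penalty above K."""
    if x_len <= max_steps:
        return 0.0
    if mode == "exp_squared":
        return constant * math.exp(x_len) ** 2
    return constant * math.exp(x_len**2)


def evaluate_fitness(
    x, subset, p: LatentVector, max_steps: int, constant: float, penalty_mode: str = "exp_squared"
) -> tuple[float, float, float]:
    """(|e|², λ, f(x)) for one binary selection vector over the subset."""
    x = np.asarray(x)
    if len(x) != len(subset):
        raise DimensionError("selection vector length must equal subset size")
    mat = subset if isinstance(subset, np.ndarray) else np.stack([f.vector.values for f in subset])
    resid = p.values - x @ mat
    sq = float(resid @ resid)
    lam = penalty(int(np.sum(x)), max_steps, constant, penalty_mode)
    return sq, lam, sq + lam


def binarize(v: np.ndarray) -> np.ndarray:
    """Round a mutant vector to binary: components ≥ 0.5 become 1, else 0."""
    return (v >= 0.5).astype(np.int8)


def _batch_fitness(pop, mat, p_vals, max_steps, constant, mode):
    resid = p_vals[None, :] - pop @ mat
    sq = np.einsum("ij,ij->i", resid, resid)
    lens = pop.sum(axis=1)
    if mode == "exp_squared":
        lam = np.where(lens > max_steps, constant * np.exp(2.0 * lens), 0.0)
    else:
        lam = np.where(lens > max_steps, constant * np.exp(lens.astype(float) ** 2), 0.0)
    return sq, sq + lam


def binary_de_select(
    subset: list[ReactionFeature], p: LatentVector, cfg: DEConfig, seed=None
) -> SelectionResult:
    """Binary DE/rand/1 search for the reaction subset minimising f(x).

    Each individual is a binary vector over the subset.  Initial individuals
    select between 1 and K random reactions.  Per generation and individual,
    three mutually distinct parents a, b, c (all differing from the current
    index) are drawn; the mutant v = x_a + F·(x_b − x_c) is rounded to binary
    at 0.5; uniform crossover with rate CR (plus one guaranteed mutant
    component when ``guaranteed_crossover``) forms the trial u, which replaces
    the current individual iff f(u) < f(x).  Optional early stop once the best
    |e| falls below the error threshold.
    """
    if not subset:
        raise ParameterError("subset must be non-empty")
    m = len(subset)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mat = np.stack([f.vector.values for f in subset])
    if p.dimension != mat.shape[1]:
        raise DimensionError("pathway vector dimension does not match subset features")
    pop_n, k = cfg.population, cfg.max_steps

    pop = np.zeros((pop_n, m), dtype=np.int8)
    for i in range(pop_n):
        n_sel = int(rng.integers(1, min(k, m) + 1))
        pop[i, rng.choice(m, size=n_sel, replace=False)] = 1

    sq, fit = _batch_fitness(pop, mat, p.values, k, cfg.penalty_constant, cfg.penalty_mode)
    best_i = int(np.argmin(fit))
    best_x, best_sq, best_fit = pop[best_i].copy(), float(sq[best_i]), float(fit[best_i])
    gens = 0
    trace = [best_fit]

    for g in range(1, cfg.max_generations + 1):
        gens = g
        if cfg.early_stop and math.sqrt(best_sq) <= cfg.error_threshold:
            gens = g - 1
            logger.debug(
                "binary_de_select: early stop after %d generation(s), |e|=%.4g <= Th",
                gens, math.sqrt(best_sq),
            )
            break
        trials = np.empty_like(pop)
        for i in range(pop_n):
            a, b, c = rng.choice(pop_n - 1, size=3, replace=False)
            # shift indices >= i so parents are distinct from the current individual
            a, b, c = (int(v) + (v >= i) for v in (a, b, c))
            v = binarize(pop[a] + cfg.F * (pop[b].astype(np.float64) - pop[c]))
            cross = rng.random(m) < cfg.CR
            u = np.where(cross, v, pop[i])
            if cfg.guaranteed_crossover:
                j = int(rng.integers(m))
                u[j] = v[j]
            trials[i] = u
        t_sq, t_fit = _batch_fitness(trials, mat, p.values, k, cfg.penalty_constant, cfg.penalty_mode)
        improved = t_fit < fit
        pop[improved] = trials[improved]
        sq = np.where(improved, t_sq, sq)
        fit = np.where(improved, t_fit, fit)
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_x, best_sq, best_fit = pop[gen_best].copy(), float(sq[gen_best]), float(fit[gen_best])
        trace.append(best_fit)

    return SelectionResult(list(subset), best_x, best_sq, best_fit, gens, trace)


def enumerate_selections(m: int, max_steps: int):
    """All binary selections of length m with 0..max_steps ones (oracle helper).

    The empty selection is part of the binary search space (it can arise from
    mutation/crossover and carries no penalty), so the oracle includes it;
    the design loop discards empty selections downstream.
    """
    yield np.zeros(m, dtype=np.int8)
    for k in range(1, max_steps + 1):
        for combo in itertools.combinations(range(m), k):
            x = np.zeros(m, dtype=np.int8)
            x[list(combo)] = 1
            yield x


def exhaustive_select(subset, p: LatentVector, cfg: DEConfig) -> SelectionResult:
    """Brute-force optimum over all selections of size ≤ K (small subsets only)."""
    mat = np.stack([f.vector.values for f in subset])
    best = None
    for x in enumerate_selections(len(subset), cfg.max_steps):
        sq, _, f = evaluate_fitness(x, mat, p, cfg.max_steps, cfg.penalty_constant, cfg.penalty_mode)
        if best is None or f < best[2]:
            best = (x, sq, f)
    x, sq, f = best
    return SelectionResult(list(subset), x, sq, f, 0)


# --------------------------------------------------------------------------
# Ordering, reconstruction, pruning
# --------------------------------------------------------------------------

@dataclass
class CandidatePathway:
    """An ordered reaction sequence from start to target with reconstructions.

    ``intermediate_latents``/``intermediate_structures`` cover the strict
    intermediates (one fewer than the number of reactions); the final
    cumulative latent and its decoded structure are kept separately.
    ``segment_delta_mws`` holds the decoded-structure ΔMW of each segment
    (None where an endpoint failed to decode).  ``v_r``, ``v_p`` and ``score``
    are filled by possibility scoring.
    """

    query: PathwayQuery
    ordered_reactions: list[ReactionFeature]
    intermediate_latents: list[LatentVector]
    intermediate_structures: list[str | None]
    final_latent: LatentVector
    final_structure: str | None
    substrate_encodings: list[EncodedCompound | None]
    segment_delta_mws: list[float | None]
    abs_error: float
    removal_reason: str | None = None
    v_r: list[float] | None = None
    v_p: float | None = None
    score: float | None = None

    @property
    def ec_sequence(self) -> tuple[str, ...]:
        return tuple(f.ec_number for f in self.ordered_reactions)

    @property
    def pair_sequence(self) -> tuple[tuple[str, str], ...]:
        return tuple((f.record.substrate_id, f.record.product_id) for f in self.ordered_reactions)

    def dedup_key(self):
        return (self.ec_sequence, self.pair_sequence)


def enumerate_orderings(selected) -> list[tuple[ReactionFeature, ...]]:
    """All permutations of the selected reactions, in lexicographic index order."""
    selected = list(selected)
    if not selected:
        raise ParameterError("cannot order an empty selection")
    return [
        tuple(selected[i] for i in perm)
        for perm in itertools.permutations(range(len(selected)))
    ]


def reconstruct_intermediates(
    query: PathwayQuery,
    ordering,
    backend: EmbeddingBackend,
    start: EncodedCompound | None = None,
) -> CandidatePathway:
    """Cumulative-sum reconstruction of one ordering's intermediate compounds.

    Latents: z_k = z_start + Σ_{j≤k} r_(j).  Every cumulative point (strict
    intermediates and the final point) is decoded; decode failures are
    recorded per segment and leave the pathway flagged rather than removed
    here.  Segment ΔMW values come from the decoded structures' molecular
    weights; the starting segment uses the actual start compound.
    """
    if not backend.can_decode:
        raise ParameterError("backend cannot decode; intermediate reconstruction impossible")
    ordering = list(ordering)
    if not ordering:
        raise ParameterError("ordering must contain at least one reaction")
    start = backend.encode(query.start_id) if start is None else start
    part = ordering[0].vector.part if ordering else query.p.part
    z = start.latent(part).values.copy()
    if ordering and ordering[0].vector.dimension != z.shape[0]:
        raise DimensionError("reaction vectors do not match the start latent dimension")

    latents, structures, encodings, seg_mws = [], [], [], []
    prev_mw: float | None = start.molecular_weight
    prev_enc: EncodedCompound | None = start
    for step, feat in enumerate(ordering):
        encodings.append(prev_enc)
        z = z + feat.vector.values
        lv = LatentVector(z, part)
        decoded = backend.decode(lv)
        enc = backend.encode(decoded) if decoded is not None else None
        mw = enc.molecular_weight if enc is not None else None
        seg_mws.append(
            mw - prev_mw if (mw is not None and prev_mw is not None) else None
        )
        if step < len(ordering) - 1:
            latents.append(lv)
            structures.append(decoded)
        else:
            final_latent, final_structure = lv, decoded
        prev_mw, prev_enc = mw, enc

    residual = query.p.values - (z - start.latent(part).values)
    return CandidatePathway(
        query=query,
        ordered_reactions=ordering,
        intermediate_latents=latents,
        intermediate_structures=structures,
        final_latent=final_latent,
        final_structure=final_structure,
        substrate_encodings=encodings,
        segment_delta_mws=seg_mws,
        abs_error=float(np.sqrt(residual @ residual)),
    )


@dataclass(frozen=True)
class PruneDecision:
    keep: bool
    segment_reasons: tuple[str, ...]

    @property
    def reason(self) -> str | None:
        bad = [r for r in self.segment_reasons if r != "ok"]
        return bad[0] if bad else None


def prune_unrealistic(pathway: CandidatePathway, tolerance: float = 3.0) -> PruneDecision:
    """Molecular-weight consistency check, segment by segment.

    Each segment's decoded ΔMW is compared against the registered ΔMW of the
    reaction assigned to that segment; a deviation beyond ``tolerance``
    (default ±3 u) on any segment removes the pathway, as does an undecodable
    segment endpoint (the rule cannot be evaluated there).
    """
    reasons = []
    for feat, seg in zip(pathway.ordered_reactions, pathway.segment_delta_mws):
        if seg is None:
            reasons.append("decode-failure")
        elif abs(seg - feat.delta_mw_registered) > tolerance:
            reasons.append(f"mw-deviation:{seg - feat.delta_mw_registered:+.3f}")
        else:
            reasons.append("ok")
    keep = all(r == "ok" for r in reasons)
    if not keep:
        pathway.removal_reason = next(r for r in reasons if r != "ok")
    return PruneDecision(keep, tuple(reasons))


# --------------------------------------------------------------------------
# The full design loop
# --------------------------------------------------------------------------

def design_candidates(
    query: PathwayQuery,
    db: ReactionFeatureDB,
    cfg: DEConfig,
    backend: EmbeddingBackend,
    design_part: str | None = None,
) -> list[CandidatePathway]:
    """Repeat subset → DE → ordering → reconstruction → pruning.

    Runs ``cfg.repetitions`` independent repetitions with per-repetition
    derived seeds, keeps selections with |e| ≤ Th whose orderings survive the
    molecular-weight check, and deduplicates candidates by their ordered EC
    list plus ordered substrate/product pairs.  An empty list is a valid
    outcome.  ``design_part`` (default: tree when available) selects which
    latent sub-part drives the DE search on a combined-part DB.
    """
    if cfg.repetitions < 1:
        raise ParameterError("repetitions must be >= 1")
    if design_part is None:
        design_part = "tree" if db.part == "combined" or db.part == "tree" else db.part
    mat = db.vector_matrix(design_part)
    design_feats = [
        ReactionFeature(f.record, LatentVector(mat[i], design_part), f.delta_mw_registered)
        for i, f in enumerate(db.features)
    ]
    design_db = ReactionFeatureDB(
        design_feats,
        design_part,
        tree_dim=db.tree_dim if design_part != "graph" else 0,
        graph_dim=db.graph_dim if design_part != "tree" else 0,
    )
    full_by_key = {id(design_feats[i]): db.features[i] for i in range(len(db))}

    start = backend.encode(query.start_id)
    if query.p.part != design_part:
        target = backend.encode(query.target_id)
        q = compute_pathway_vector(
            start.latent(design_part), target.latent(design_part), query.start_id, query.target_id
        )
    else:
        q = query

    ss = np.random.SeedSequence(cfg.seed)
    seen, out = set(), []
    m = min(cfg.subset_size, len(design_db))
    for rep, child in enumerate(ss.spawn(cfg.repetitions)):
        s_subset, s_de = child.spawn(2)
        subset = sample_subset(design_db, m, s_subset)
        result = binary_de_select(subset, q.p, cfg, seed=s_de)
        if result.abs_error > cfg.error_threshold or not result.selected:
            logger.debug("repetition %d: no admissible selection (|e|=%.3f)", rep, result.abs_error)
            continue
        for ordering in enumerate_orderings(result.selected):
            pathway = reconstruct_intermediates(q, ordering, backend, start=start)
            decision = prune_unrealistic(pathway, cfg.mw_tolerance)
            if not decision.keep:
                logger.debug("repetition %d: pruned ordering (%s)", rep, pathway.removal_reason)
                continue
            # restore full-part reaction features for downstream scoring
            pathway.ordered_reactions = [full_by_key[id(f)] for f in ordering]
            key = pathway.dedup_key()
            if key in seen:
                continue
            seen.add(key)
            out.append(pathway)
    logger.info("design_candidates: %d unique candidate(s) after %d repetition(s)", len(out), cfg.repetitions)
    return out
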