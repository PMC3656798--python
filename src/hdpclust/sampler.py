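"""Collapsed Gibbs sampler for the two-level HDP in its franchise form.

One sweep visits every customer ``(j, i)`` in row-major order and resamples
its table from the finite conditional — occupied tables of row ``j``
weighted by occupancy times the dish-conditional predictive density, plus
one "new table" option whose weight mixes every served dish and a fresh
dish — then revisits every occupied table and resamples its dish, and
finally (optionally) redraws both concentrations from their Gamma prior.

Two sampling modes share the same stationary distribution: ``direct`` draws
from the exactly normalized finite conditional; ``metropolis_hastings``
proposes uniformly over the same finite support and accepts by the weight
ratio.  Direct is the default.

Cluster labels are not identifiable across MCMC samples, so each recorded
snapshot is canonicalized (dishes renumbered by first appearance in
row-major order) before frequencies are aggregated into the membership
posterior.

:func:`exact_posterior_small` enumerates every seating of a tiny instance
and serves as the ground-truth posterior in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ChainConfig,
    ExpressionMatrix,
    Hyperparameters,
    ObservationModel,
    Partition,
    SeatingState,
    init_state,
    validate_state,
)
from .marginals import log_predictive, log_predictive_set

__all__ = [
    "ChainTrace",
    "MembershipPosterior",
    "table_weights",
    "dish_log_weights",
    "dish_weights",
    "mh_acceptance",
    "mh_step",
    "sample_table",
    "sample_dish",
    "sample_concentrations",
    "gibbs_sweep",
    "run_chain",
    "aggregate_posterior",
    "map_assignment",
    "cluster",
    "exact_posterior_small",
    "partition_frequencies",
    "total_variation",
    "HDPResult",
]


# --------------------------------------------------------------------------
# conditional weights


def table_weights(j: int, i: int, state: SeatingState, data: ExpressionMatrix,
                  model: ObservationModel, hyper: Hyperparameters,
                  ) -> tuple[list[int], list[float], float]:
    """Unnormalized table-assignment weights for customer ``(j, i)``.

    The customer must already be unseated (its counts removed).  Returns
    ``(tables, weights, new_weight)``: each occupied table ``t`` of row
    ``j`` weighted by ``c_jt * f_dish(g | dish data)``, and the new-table
    weight ``alpha0 * [ sum_k D_k/(D+alpha1) f_k(g|.) + alpha1/(D+alpha1) p0(g) ]``
    where ``D_k`` counts tables serving dish ``k`` over all rows and ``D``
    is the total table count.  An empty restaurant yields the single weight
    ``alpha0 * p0(g)``.
    """
    if (j, i) in state.phi:
        raise ValueError(f"customer {(j, i)} must be unseated first")
    g = float(data.values[j, i])
    dish_n, dish_sum = state.dish_n, state.dish_sum
    f_cache: dict[int, float] = {}

    def f_dish(k: int) -> float:
        f = f_cache.get(k)
        if f is None:
            f = math.exp(log_predictive(g, dish_n[k], dish_sum[k], model))
            f_cache[k] = f
        return f

    tables = state.tables_in_row(j)
    weights = [state.c[(j, t)] * f_dish(state.lam[(j, t)]) for t in tables]

    p0 = math.exp(log_predictive(g, 0, 0.0, model))
    total_tables = state.total_tables
    denom = total_tables + hyper.alpha1
    mix = sum(state.dish_tables[k] * f_dish(k) for k in state.dish_tables)
    new_weight = hyper.alpha0 * (mix + hyper.alpha1 * p0) / denom
    return tables, weights, new_weight


def dish_log_weights(j: int, t: int, state: SeatingState,
                     data: ExpressionMatrix, model: ObservationModel,
                     hyper: Hyperparameters,
                     ) -> tuple[list[int], list[float], float]:
    """Unnormalized log dish weights for table ``(j, t)``.

    The table must be detached from its dish (its data removed from the
    dish statistics).  Served dish ``k`` gets ``log D_k + log m(G | dish
    data)`` where ``G`` is the table's data and ``m`` the joint conditional
    predictive; a fresh dish gets ``log alpha1 + log m(G)``.
    """
    members = state.members.get((j, t))
    if not members:
        raise ValueError(f"table {(j, t)} is unoccupied")
    values = [float(data.values[j, i]) for i in sorted(members)]
    dishes = state.dishes()
    logw = [
        math.log(state.dish_tables[k])
        + log_predictive_set(values, state.dish_n[k], state.dish_sum[k], model)
        for k in dishes
    ]
    new_logw = math.log(hyper.alpha1) + log_predictive_set(values, 0, 0.0, model)
    return dishes, logw, new_logw


def dish_weights(j: int, t: int, state: SeatingState, data: ExpressionMatrix,
                 model: ObservationModel, hyper: Hyperparameters,
                 ) -> tuple[list[int], list[float], float]:
    """Linear-space version of :func:`dish_log_weights` (may underflow for
    very large tables; the sampler itself works in log space)."""
    dishes, logw, new_logw = dish_log_weights(j, t, state, data, model, hyper)
    return dishes, [math.exp(w) for w in logw], math.exp(new_logw)


# --------------------------------------------------------------------------
# Metropolis–Hastings primitive


def mh_acceptance(candidate_weight: float, current_weight: float) -> float:
    """Acceptance probability min(1, candidate/current) for a symmetric
    proposal; a zero-weight current state always moves (if the candidate
    has positive weight)."""
    if candidate_weight < 0 or current_weight < 0:
        raise ValueError("weights must be nonnegative")
    if current_weight == 0.0:
        return 1.0 if candidate_weight > 0 else 0.0
    return min(1.0, candidate_weight / current_weight)


def mh_step(candidate_weight: float, current_weight: float,
            rng: np.random.Generator) -> bool:
    """One accept/reject decision."""
    a = mh_acceptance(candidate_weight, current_weight)
    return a >= 1.0 or rng.random() < a


# --------------------------------------------------------------------------
# per-variable moves


def _categorical(weights: list[float], rng: np.random.Generator) -> int:
    total = math.fsum(weights)
    if not (total > 0 and math.isfinite(total)):
        raise FloatingPointError(f"degenerate weight vector (sum={total})")
    u = rng.random() * total
    acc = 0.0
    for idx, w in enumerate(weights):
        acc += w
        if u < acc:
            return idx
    return len(weights) - 1


def _sample_dish_for_new_table(j: int, g: float, state: SeatingState,
                               model: ObservationModel,
                               hyper: Hyperparameters,
                               rng: np.random.Generator) -> int:
    """Dish for a newly created table: served dish k with weight D_k * f_k(g),
    fresh dish with weight alpha1 * p0(g)."""
    dishes = state.dishes()
    w = [
        state.dish_tables[k]
        * math.exp(log_predictive(g, state.dish_n[k], state.dish_sum[k], model))
        for k in dishes
    ]
    w.append(hyper.alpha1 * math.exp(log_predictive(g, 0, 0.0, model)))
    idx = _categorical(w, rng)
    if idx < len(dishes):
        return dishes[idx]
    return state.create_dish()


def sample_table(j: int, i: int, state: SeatingState, data: ExpressionMatrix,
                 model: ObservationModel, hyper: Hyperparameters,
                 rng: np.random.Generator, mode: str = "direct") -> SeatingState:
    """Resample the table of customer ``(j, i)`` in place.

    The customer is unseated (emptied tables garbage-collected), a target
    option is drawn — directly from the normalized weights, or by one
    symmetric-proposal M–H step from the current option — and the customer
    reseated; a new table immediately draws its dish.
    """
    g = float(data.values[j, i])
    prev_t = state.unseat(j, i, g)
    tables, weights, new_weight = table_weights(j, i, state, data, model, hyper)

    if mode == "direct":
        idx = _categorical(weights + [new_weight], rng)
        target = tables[idx] if idx < len(tables) else None
    elif mode == "metropolis_hastings":
        options: list[int | None] = list(tables) + [None]
        wvec = weights + [new_weight]
        current_idx = options.index(prev_t) if prev_t in options else len(options) - 1
        cand_idx = int(rng.integers(len(options)))
        if mh_step(wvec[cand_idx], wvec[current_idx], rng):
            target = options[cand_idx]
        else:
            target = options[current_idx]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    if target is None:
        k = _sample_dish_for_new_table(j, g, state, model, hyper, rng)
        target = state.create_table(j, k)
    state.seat(j, i, target, g)
    return state


def sample_dish(j: int, t: int, state: SeatingState, data: ExpressionMatrix,
                model: ObservationModel, hyper: Hyperparameters,
                rng: np.random.Generator, mode: str = "direct") -> SeatingState:
    """Resample the dish of occupied table ``(j, t)`` in place (log-space
    weights; unserved dishes garbage-collected)."""
    members = state.members.get((j, t))
    if not members:
        raise ValueError(f"table {(j, t)} is unoccupied")
    values = [float(data.values[j, i]) for i in members]
    vsum = math.fsum(values)
    prev_k = state.detach_table_from_dish(j, t, vsum, len(values))
    dishes, logw, new_logw = dish_log_weights(j, t, state, data, model, hyper)
    all_logw = logw + [new_logw]
    shift = max(all_logw)
    wvec = [math.exp(w - shift) for w in all_logw]

    if mode == "direct":
        idx = _categorical(wvec, rng)
    elif mode == "metropolis_hastings":
        current_idx = dishes.index(prev_k) if prev_k in dishes else len(dishes)
        cand_idx = int(rng.integers(len(wvec)))
        idx = cand_idx if mh_step(wvec[cand_idx], wvec[current_idx], rng) \
            else current_idx
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    k = dishes[idx] if idx < len(dishes) else state.create_dish()
    state.attach_table_to_dish(j, t, k, vsum, len(values))
    return state


def sample_concentrations(hyper: Hyperparameters,
                          rng: np.random.Generator) -> Hyperparameters:
    """Redraw alpha0 and alpha1 from their Gamma(shape, rate) prior when
    resampling is enabled; identity otherwise.  (The concentrations'
    full conditionals under this model reduce to their prior.)"""
    if not hyper.resample_concentrations:
        return hyper
    a, b = hyper.gamma_shape, hyper.gamma_rate
    a0 = float(rng.gamma(shape=a, scale=1.0 / b))
    a1 = float(rng.gamma(shape=a, scale=1.0 / b))
    return Hyperparameters(alpha0=a0, alpha1=a1, gamma_shape=a,
                           gamma_rate=b, resample_concentrations=True)


def gibbs_sweep(state: SeatingState, data: ExpressionMatrix,
                model: ObservationModel, hyper: Hyperparameters,
                rng: np.random.Generator, mode: str = "direct",
                ) -> Hyperparameters:
    """One full sweep: every customer's table (row-major), then every
    occupied table's dish, then the concentrations.  Mutates ``state`` and
    returns the (possibly updated) hyperparameters."""
    for j in range(data.n_experiments):
        for i in range(data.n_genes):
            sample_table(j, i, state, data, model, hyper, rng, mode)
    for j in range(data.n_experiments):
        for t in state.tables_in_row(j):
            sample_dish(j, t, state, data, model, hyper, rng, mode)
    return sample_concentrations(hyper, rng)


# --------------------------------------------------------------------------
# chain, trace, posterior


@dataclass(frozen=True)
class Snapshot:
    """One recorded, canonically relabeled chain state."""

    z: np.ndarray          # (M, N) dish label per customer, labels 1..K
    tables: np.ndarray     # (M, N) table label per customer, per-row 1..T_j
    alpha0: float
    alpha1: float

    @property
    def n_dishes(self) -> int:
        return int(self.z.max())


@dataclass
class ChainTrace:
    """Recorded snapshots after burn-in, plus the run configuration."""

    snapshots: list[Snapshot]
    config: ChainConfig

    def __len__(self) -> int:
        return len(self.snapshots)

    def dish_counts(self) -> np.ndarray:
        """Number of distinct dishes in each snapshot."""
        return np.array([s.n_dishes for s in self.snapshots])


def _canonical_snapshot(state: SeatingState, alpha0: float,
                        alpha1: float) -> Snapshot:
    """Relabel dishes (globally) and tables (per row) by first appearance in
    a row-major scan — the label-switching canonicalization applied before
    any frequency aggregation."""
    M, N = state.M, state.N
    z = np.zeros((M, N), dtype=np.int64)
    tb = np.zeros((M, N), dtype=np.int64)
    dish_map: dict[int, int] = {}
    for j in range(M):
        table_map: dict[int, int] = {}
        for i in range(N):
            t = state.phi[(j, i)]
            k = state.lam[(j, t)]
            if t not in table_map:
                table_map[t] = len(table_map) + 1
            if k not in dish_map:
                dish_map[k] = len(dish_map) + 1
            tb[j, i] = table_map[t]
            z[j, i] = dish_map[k]
    return Snapshot(z=z, tables=tb, alpha0=alpha0, alpha1=alpha1)


def run_chain(data: ExpressionMatrix, model: ObservationModel,
              hyper: Hyperparameters, config: ChainConfig,
              progress=None) -> ChainTrace:
    """Run the Gibbs chain: ``burnin`` discarded sweeps, then ``samples``
    snapshots recorded every ``thinning`` sweeps.

    ``progress``, if given, is called as ``progress(sweep, state)`` every
    100 sweeps.  Every recorded snapshot is validated against the state
    invariants before storage.
    """
    rng = np.random.default_rng(config.seed)
    state = init_state(data, mode=config.init_mode,
                       seed=int(rng.integers(2**31)))
    hy = hyper
    snapshots: list[Snapshot] = []
    total = config.burnin + config.samples * config.thinning
    for sweep in range(1, total + 1):
        hy = gibbs_sweep(state, data, model, hy, rng, config.sampler_mode)
        if progress is not None and sweep % 100 == 0:
            progress(sweep, state)
        if sweep > config.burnin and (sweep - config.burnin) % config.thinning == 0:
            problems = validate_state(state, data)
            if problems:
                raise RuntimeError(f"invariant violation at sweep {sweep}: {problems}")
            snapshots.append(_canonical_snapshot(state, hy.alpha0, hy.alpha1))
    return ChainTrace(snapshots=snapshots, config=config)


@dataclass(frozen=True)
class MembershipPosterior:
    """Aggregated membership frequencies over canonical dish labels.

    ``cell_probs[j, i, a-1]`` is the posterior probability that customer
    ``(j, i)`` eats canonical dish ``a``; ``gene_scores[i, a-1]`` is the
    sum over experiments, the quantity the MAP rule maximizes.
    """

    cell_probs: np.ndarray   # (M, N, K_max), rows sum to 1
    gene_scores: np.ndarray  # (N, K_max)
    gene_ids: tuple[str, ...]


def aggregate_posterior(trace: ChainTrace,
                        gene_ids: tuple[str, ...] | None = None,
                        ) -> MembershipPosterior:
    """Empirical per-customer membership distribution over canonical dish
    labels, and its per-gene aggregation across experiments."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    M, N = trace.snapshots[0].z.shape
    kmax = max(s.n_dishes for s in trace.snapshots)
    counts = np.zeros((M, N, kmax))
    jj, ii = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    for snap in trace.snapshots:
        counts[jj, ii, snap.z - 1] += 1.0
    cell = counts / len(trace)
    genes = cell.sum(axis=0)
    if gene_ids is None:
        gene_ids = tuple(f"g{i + 1}" for i in range(N))
    return MembershipPosterior(cell_probs=cell, gene_scores=genes,
                               gene_ids=tuple(gene_ids))


def map_assignment(post: MembershipPosterior) -> Partition:
    """MAP cluster per gene: the label maximizing the experiment-summed
    membership probability, ties to the smallest canonical label; output
    labels renumbered 1..K by order of first appearance over genes."""
    raw = np.argmax(post.gene_scores, axis=1)  # argmax takes smallest on ties
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return Partition.from_sequence(post.gene_ids, labels)


@dataclass(frozen=True)
class HDPResult:
    """Convenience bundle: trace, aggregated posterior and MAP partition."""

    trace: ChainTrace
    posterior: MembershipPosterior
    partition: Partition


def cluster(data: ExpressionMatrix, model: ObservationModel | None = None,
            hyper: Hyperparameters | None = None,
            config: ChainConfig | None = None, progress=None) -> HDPResult:
    """Run the full pipeline on an expression matrix: chain, posterior
    aggregation, MAP partition."""
    model = model or ObservationModel()
    hyper = hyper or Hyperparameters()
    config = config or ChainConfig()
    trace = run_chain(data, model, hyper, config, progress=progress)
    post = aggregate_posterior(trace, gene_ids=data.gene_ids)
    return HDPResult(trace=trace, posterior=post,
                     partition=map_assignment(post))


# --------------------------------------------------------------------------
# exact posterior oracle for tiny instances


def _rising_log(x: float, n: int) -> float:
    return math.fsum(math.log(x + r) for r in range(n))


def exact_posterior_small(data: ExpressionMatrix, model: ObservationModel,
                          hyper: Hyperparameters) -> dict[tuple[int, ...], float]:
    """Exhaustive posterior over seatings of a tiny instance (N*M <= 6).

    Enumerates every per-row set partition of customers into tables and
    every set partition of the resulting tables into dishes, scores each by
    the franchise prior times the product of per-dish marginal likelihoods,
    normalizes, and marginalizes onto the dish-induced partition of
    customers.  Keys are canonical label tuples in row-major customer
    order — directly comparable with :func:`partition_frequencies`.
    """
    from sympy.utilities.iterables import multiset_partitions

    M, N = data.n_experiments, data.n_genes
    if M * N > 6:
        raise ValueError("instance too large for exact enumeration")
    a0, a1 = hyper.alpha0, hyper.alpha1

    row_parts = []
    for j in range(M):
        row_parts.append(list(multiset_partitions(list(range(N)))))

    log_post: dict[tuple[int, ...], list[float]] = {}

    def recurse(j: int, tables: list[tuple[int, tuple[int, ...]]], logp: float):
        if j == M:
            T = len(tables)
            for dish_part in multiset_partitions(list(range(T))):
                lp = (len(dish_part) * math.log(a1)
                      + sum(math.lgamma(len(grp)) for grp in dish_part)
                      - _rising_log(a1, T)) + logp
                for grp in dish_part:
                    vals = [float(data.values[tables[ti][0], i])
                            for ti in grp for i in tables[ti][1]]
                    lp += log_predictive_set(vals, 0, 0.0, model)
                labels = {}
                for dish_idx, grp in enumerate(dish_part):
                    for ti in grp:
                        jj, genes = tables[ti]
                        for i in genes:
                            labels[(jj, i)] = dish_idx
                key_raw = [labels[(jj, i)] for jj in range(M) for i in range(N)]
                canon: dict[int, int] = {}
                key = []
                for lab in key_raw:
                    if lab not in canon:
                        canon[lab] = len(canon) + 1
                    key.append(canon[lab])
                log_post.setdefault(tuple(key), []).append(lp)
            return
        for part in row_parts[j]:
            lp = (len(part) * math.log(a0)
                  + sum(math.lgamma(len(grp)) for grp in part)
                  - _rising_log(a0, N))
            recurse(j + 1,
                    tables + [(j, tuple(grp)) for grp in part],
                    logp + lp)

    recurse(0, [], 0.0)

    shift = max(lp for vals in log_post.values() for lp in vals)
    probs = {k: math.fsum(math.exp(lp - shift) for lp in vals)
             for k, vals in log_post.items()}
    total = math.fsum(probs.values())
    return {k: p / total for k, p in probs.items()}


def partition_frequencies(trace: ChainTrace) -> dict[tuple[int, ...], float]:
    """Empirical frequency of each canonical dish-induced customer
    partition across the trace (same keys as
    :func:`exact_posterior_small`)."""
    counts: dict[tuple[int, ...], int] = {}
    for snap in trace.snapshots:
        key = tuple(int(v) for v in snap.z.ravel())
        counts[key] = counts.get(key, 0) + 1
    L = len(trace)
    return {k: c / L for k, c in counts.items()}


def total_variation(p: dict, q: dict) -> float:
    """Total-variation distance between two discrete distributions given as
    dicts."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
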