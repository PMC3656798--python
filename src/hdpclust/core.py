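"""Domain types for HDP clustering of expression matrices.

The observed data are a real matrix ``g[j, i]`` — the expression of gene
``i`` in experiment ``j``.  The latent state of the collapsed hierarchical
Dirichlet process is a Chinese-restaurant-franchise seating: within each
experiment (a "row" of the restaurant) every gene-observation (a
"customer") sits at a table; every occupied table serves a dish; genes
eating the same dish — possibly at different tables, in different rows —
belong to the same cluster.

Component means are never instantiated: all likelihood evaluations flow
through conjugate marginals (see :mod:`hdpclust.marginals`), so the state
tracks only discrete assignments and sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ObservationModel",
    "Hyperparameters",
    "ChainConfig",
    "Partition",
    "SeatingState",
    "init_state",
    "validate_state",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-expression data, indexed ``values[j, i]`` = (experiment j, gene i).

    Note the internal orientation: experiments are rows of ``values``.
    On disk (TSV/CSV) genes are rows; :mod:`hdpclust.io` transposes.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "experiment_ids", tuple(self.experiment_ids))
        if vals.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = vals.shape
        if m < 1 or n < 1:
            raise ValueError("need at least one experiment and one gene")
        if len(self.experiment_ids) != m:
            raise ValueError(
                f"{len(self.experiment_ids)} experiment ids for {m} rows"
            )
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} columns")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ObservationModel:
    """Gaussian observation family with conjugate Gaussian base measure.

    Each observation is ``g ~ N(theta, obs_variance)`` where the component
    mean ``theta`` carries the prior ``N(prior_mean, prior_variance)``.
    ``prior_variance = 0`` degenerates the base measure to a point mass at
    ``prior_mean``.
    """

    obs_variance: float = 1.0
    prior_mean: float = 0.0
    prior_variance: float = 1.0

    def __post_init__(self) -> None:
        if not self.obs_variance > 0:
            raise ValueError("obs_variance must be > 0")
        if self.prior_variance < 0:
            raise ValueError("prior_variance must be >= 0")


@dataclass(frozen=True)
class Hyperparameters:
    """Concentrations of the two-level franchise and their Gamma(a, b) prior.

    ``alpha0`` governs new tables within a row, ``alpha1`` new dishes on the
    shared menu.  The Gamma prior uses the shape–rate convention (mean a/b).
    When ``resample_concentrations`` is set, both are redrawn from the prior
    at every sweep; off by default for reproducibility.
    """

    alpha0: float = 1.0
    alpha1: float = 1.0
    gamma_shape: float = 1.0
    gamma_rate: float = 1.0
    resample_concentrations: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "gamma_shape", "gamma_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule: ``burnin`` discarded sweeps, then ``samples`` snapshots
    recorded every ``thinning`` sweeps."""

    burnin: int = 1000
    samples: int = 2000
    thinning: int = 1
    seed: int = 0
    sampler_mode: str = "direct"
    init_mode: str = "each-own-table"

    def __post_init__(self) -> None:
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.sampler_mode not in ("direct", "metropolis_hastings"):
            raise ValueError(f"unknown sampler_mode {self.sampler_mode!r}")


class Partition:
    """A hard clustering: mapping item -> cluster label."""

    def __init__(self, labels: dict):
        if not labels:
            raise ValueError("partition must label at least one item")
        self._labels = dict(labels)

    @classmethod
    def from_sequence(cls, items, labels) -> "Partition":
        items, labels = list(items), list(labels)
        if len(items) != len(labels):
            raise ValueError("items and labels differ in length")
        return cls(dict(zip(items, labels)))

    def __getitem__(self, item):
        return self._labels[item]

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and self._labels == other._labels

    @property
    def items(self) -> list:
        return list(self._labels)

    @property
    def labels(self) -> dict:
        return dict(self._labels)

    def clusters(self) -> dict:
        """Label -> set of items."""
        out: dict = {}
        for item, lab in self._labels.items():
            out.setdefault(lab, set()).add(item)
        return out

    def n_clusters(self) -> int:
        return len(set(self._labels.values()))

    def __repr__(self) -> str:
        return f"Partition({self.n_clusters()} clusters, {len(self)} items)"


class SeatingState:
    """Chinese-restaurant-franchise latent state with counters.

    Tracks, for every customer ``(j, i)``, its table ``phi[(j, i)]``; for
    every occupied table ``(j, t)``, its dish ``lam[(j, t)]``, its customer
    count ``c[(j, t)]`` and member set; and per-dish aggregates: ``d[(j, k)]``
    (tables in row j serving dish k), plus global per-dish table counts and
    the sufficient statistics (count, sum) of all data currently assigned to
    the dish.  Emptied tables and unserved dishes are garbage-collected;
    fresh labels come from monotone counters so labels are never reused
    within a chain.
    """

    def __init__(self, n_experiments: int, n_genes: int):
        self.M = n_experiments
        self.N = n_genes
        self.phi: dict[tuple[int, int], int] = {}
        self.lam: dict[tuple[int, int], int] = {}
        self.c: dict[tuple[int, int], int] = {}
        self.members: dict[tuple[int, int], set[int]] = {}
        self.d: dict[tuple[int, int], int] = {}
        self.dish_tables: dict[int, int] = {}  # total tables serving dish k
        self.dish_n: dict[int, int] = {}       # observations assigned to dish k
        self.dish_sum: dict[int, float] = {}
        self.row_tables: dict[int, set[int]] = {j: set() for j in range(n_experiments)}
        self.next_table: dict[int, int] = {j: 1 for j in range(n_experiments)}
        self.next_dish: int = 1

    # -- label allocation -------------------------------------------------
    def new_table_label(self, j: int) -> int:
        t = self.next_table[j]
        self.next_table[j] = t + 1
        return t

    def new_dish_label(self) -> int:
        k = self.next_dish
        self.next_dish += 1
        return k

    # -- queries ----------------------------------------------------------
    def tables_in_row(self, j: int) -> list[int]:
        return sorted(self.row_tables[j])

    def dishes(self) -> list[int]:
        return sorted(self.dish_tables)

    @property
    def total_tables(self) -> int:
        return sum(self.dish_tables.values())

    @property
    def n_dishes(self) -> int:
        return len(self.dish_tables)

    def dish_of_customer(self, j: int, i: int) -> int:
        return self.lam[(j, self.phi[(j, i)])]

    # -- mutations --------------------------------------------------------
    def create_table(self, j: int, dish: int) -> int:
        """Open a fresh table in row j serving an existing dish."""
        t = self.new_table_label(j)
        self.lam[(j, t)] = dish
        self.c[(j, t)] = 0
        self.members[(j, t)] = set()
        self.row_tables[j].add(t)
        self.d[(j, dish)] = self.d.get((j, dish), 0) + 1
        self.dish_tables[dish] = self.dish_tables.get(dish, 0) + 1
        return t

    def create_dish(self) -> int:
        k = self.new_dish_label()
        self.dish_n[k] = 0
        self.dish_sum[k] = 0.0
        self.dish_tables.setdefault(k, 0)
        return k

    def seat(self, j: int, i: int, t: int, value: float) -> None:
        if (j, i) in self.phi:
            raise ValueError(f"customer {(j, i)} already seated")
        self.phi[(j, i)] = t
        self.c[(j, t)] += 1
        self.members[(j, t)].add(i)
        k = self.lam[(j, t)]
        self.dish_n[k] += 1
        self.dish_sum[k] += value

    def unseat(self, j: int, i: int, value: float) -> int | None:
        """Remove customer (j, i); garbage-collect its table (and dish) if
        emptied.  Returns the customer's former table label, or None if the
        table was removed."""
        t = self.phi.pop((j, i))
        self.c[(j, t)] -= 1
        self.members[(j, t)].discard(i)
        k = self.lam[(j, t)]
        self.dish_n[k] -= 1
        self.dish_sum[k] -= value
        if self.c[(j, t)] == 0:
            self._remove_table(j, t)
            return None
        return t

    def _remove_table(self, j: int, t: int) -> None:
        k = self.lam.pop((j, t))
        del self.c[(j, t)]
        del self.members[(j, t)]
        self.row_tables[j].discard(t)
        self.d[(j, k)] -= 1
        if self.d[(j, k)] == 0:
            del self.d[(j, k)]
        self.dish_tables[k] -= 1
        if self.dish_tables[k] == 0:
            del self.dish_tables[k]
            del self.dish_n[k]
            del self.dish_sum[k]

    def detach_table_from_dish(self, j: int, t: int, values_sum: float,
                               n_values: int) -> int:
        """Temporarily remove table (j, t)'s contribution from its dish,
        ahead of dish resampling.  The table keeps its customers; its dish
        slot is cleared.  Returns the former dish (garbage-collected if it
        became unserved)."""
        k = self.lam[(j, t)]
        self.lam[(j, t)] = 0  # sentinel: dishless
        self.d[(j, k)] -= 1
        if self.d[(j, k)] == 0:
            del self.d[(j, k)]
        self.dish_tables[k] -= 1
        self.dish_n[k] -= n_values
        self.dish_sum[k] -= values_sum
        if self.dish_tables[k] == 0 and self.dish_n[k] == 0:
            del self.dish_tables[k]
            del self.dish_n[k]
            del self.dish_sum[k]
        return k

    def attach_table_to_dish(self, j: int, t: int, k: int, values_sum: float,
                             n_values: int) -> None:
        if self.lam.get((j, t)) != 0:
            raise ValueError(f"table {(j, t)} is not detached")
        self.lam[(j, t)] = k
        self.d[(j, k)] = self.d.get((j, k), 0) + 1
        self.dish_tables[k] = self.dish_tables.get(k, 0) + 1
        self.dish_n[k] = self.dish_n.get(k, 0) + n_values
        self.dish_sum[k] = self.dish_sum.get(k, 0.0) + values_sum


def init_state(data: ExpressionMatrix, mode: str = "each-own-table",
               seed: int | None = None) -> SeatingState:
    """Build an initial seating.

    Modes:

    - ``each-own-table`` — every customer at its own table; all tables in
      row j share one row-specific dish (the layout of the two-gene
      illustration used throughout the docs and tests).
    - ``single-table`` — one table per row; all rows share a single dish.
    - ``random`` — sequential draw from the franchise prior with unit
      concentrations, seeded.
    """
    M, N = data.n_experiments, data.n_genes
    state = SeatingState(M, N)
    if mode == "each-own-table":
        for j in range(M):
            k = state.create_dish()
            for i in range(N):
                t = state.create_table(j, k)
                state.seat(j, i, t, float(data.values[j, i]))
    elif mode == "single-table":
        k = state.create_dish()
        for j in range(M):
            t = state.create_table(j, k)
            for i in range(N):
                state.seat(j, i, t, float(data.values[j, i]))
    elif mode == "random":
        rng = np.random.default_rng(seed)
        for j in range(M):
            for i in range(N):
                tables = state.tables_in_row(j)
                weights = [state.c[(j, t)] for t in tables] + [1.0]
                w = np.asarray(weights, dtype=float)
                choice = rng.choice(len(w), p=w / w.sum())
                if choice < len(tables):
                    t = tables[choice]
                else:
                    dishes = state.dishes()
                    dw = [state.dish_tables[k] for k in dishes] + [1.0]
                    dw = np.asarray(dw, dtype=float)
                    dc = rng.choice(len(dw), p=dw / dw.sum())
                    k = dishes[dc] if dc < len(dishes) else state.create_dish()
                    t = state.create_table(j, k)
                state.seat(j, i, t, float(data.values[j, i]))
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    return state


def validate_state(state: SeatingState, data: ExpressionMatrix) -> list[str]:
    """Check every structural invariant; return a list of violations
    (empty iff the state is consistent)."""
    v: list[str] = []
    M, N = data.n_experiments, data.n_genes
    if (state.M, state.N) != (M, N):
        v.append(f"shape mismatch: state ({state.M},{state.N}) vs data ({M},{N})")
        return v
    # every customer seated exactly once, at an existing table
    for j in range(M):
        row_count = 0
        for i in range(N):
            if (j, i) not in state.phi:
                v.append(f"customer ({j},{i}) unseated")
                continue
            t = state.phi[(j, i)]
            if (j, t) not in state.c:
                v.append(f"customer ({j},{i}) at nonexistent table {t}")
            row_count += 1
        counted = sum(c for (jj, _), c in state.c.items() if jj == j)
        if counted != N:
            v.append(f"customer count: row {j} has sum c = {counted}, expected {N}")
    # table bookkeeping
    for (j, t), cnt in state.c.items():
        if cnt <= 0:
            v.append(f"zero-count table ({j},{t}) retained")
        if (j, t) not in state.lam:
            v.append(f"table ({j},{t}) has no dish")
        elif state.lam[(j, t)] == 0:
            v.append(f"table ({j},{t}) left detached from any dish")
        members = state.members.get((j, t), set())
        if len(members) != cnt:
            v.append(f"table ({j},{t}) member set size {len(members)} != c {cnt}")
        for i in members:
            if state.phi.get((j, i)) != t:
                v.append(f"member ({j},{i}) of table ({j},{t}) has phi {state.phi.get((j, i))}")
    # dish counters vs recomputation
    d_re: dict[tuple[int, int], int] = {}
    n_re: dict[int, int] = {}
    s_re: dict[int, float] = {}
    for (j, t), k in state.lam.items():
        if state.c.get((j, t), 0) > 0 and k != 0:
            d_re[(j, k)] = d_re.get((j, k), 0) + 1
            for i in state.members[(j, t)]:
                n_re[k] = n_re.get(k, 0) + 1
                s_re[k] = s_re.get(k, 0.0) + float(data.values[j, i])
    if d_re != state.d:
        v.append(f"d counters inconsistent: {state.d} vs recomputed {d_re}")
    tot_re: dict[int, int] = {}
    for (j, k), cnt in d_re.items():
        tot_re[k] = tot_re.get(k, 0) + cnt
    if tot_re != state.dish_tables:
        v.append(f"dish table counts inconsistent: {state.dish_tables} vs {tot_re}")
    if n_re != state.dish_n:
        v.append(f"dish sizes inconsistent: {state.dish_n} vs {n_re}")
    for k, s in s_re.items():
        if abs(state.dish_sum.get(k, np.nan) - s) > 1e-8 * (1 + abs(s)):
            v.append(f"dish {k} sum {state.dish_sum.get(k)} != recomputed {s}")
    for k in state.dish_tables:
        if state.dish_tables[k] <= 0:
            v.append(f"unserved dish {k} retained")
    return v
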