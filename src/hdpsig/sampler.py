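"""Chinese-restaurant-franchise Gibbs sampler for the HDP mixture model.

Every observed mutation is a customer; each DP node of the hierarchy is a
restaurant.  Customers at a leaf restaurant sit at tables; every table serves
a dish (a mutational signature) and is itself a customer of the parent
restaurant, recursively up to the root.  A new table at the root corresponds
to a brand-new dish drawn from the base distribution H, a symmetric
Dirichlet(1) over the C mutation classes (uniform on the (C-1)-simplex).
Because H is continuous, distinct root tables carry distinct dishes, so dish
identity coincides with root-table identity.

Integrating H out, the probability that a dish k generates a mutation of
class c given the mutations already ascribed to it is the
Dirichlet-multinomial posterior predictive (n_kc + 1) / (n_k + C).

A Gibbs sweep removes and reseats every mutation from its full conditional;
table creation cascades a virtual customer to the parent restaurant by the
same rule.  Concentration parameters get the standard auxiliary-variable
update for gamma-prior DP concentrations once per sweep.

Recorded Gibbs samples snapshot the per-dish mutation-class counts and
per-sample counts ("clusters of category counts"); downstream grouping of
these clusters across samples and chains turns them into signatures.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from .catalogs import MutationCatalog
from .hierarchy import HdpHierarchy

__all__ = [
    "ConcentrationPrior",
    "SamplerConfig",
    "CrfState",
    "GibbsSample",
    "PosteriorArchive",
    "CheckpointError",
    "dish_predictive",
    "seating_distribution",
    "sample_concentration",
    "gibbs_sweep",
    "run_chain",
    "resume_chain",
    "run_multi_chain",
]

_CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    """Raised for unreadable, truncated or version-incompatible checkpoints."""


@dataclass(frozen=True)
class ConcentrationPrior:
    """Gamma(shape, rate=beta) prior for DP concentration parameters.

    Larger beta pulls concentrations toward zero, discouraging creation of
    new signatures: the prior mean is shape/beta (0.05 for shape 1, beta 20).
    """

    shape: float = 1.0
    beta: float = 20.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.beta <= 0:
            raise ValueError("gamma prior shape and beta must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.beta


@dataclass(frozen=True)
class SamplerConfig:
    """Gibbs-sampling run parameters.

    ``burnin`` sweeps are discarded, then ``n_samples`` snapshots are recorded
    every ``spacing`` sweeps.  ``init_dishes`` controls the dispersed
    initialization.  ``alpha_init`` defaults to the prior mean; setting
    ``resample_concentration`` to False freezes the concentrations (useful
    for validation against closed-form posteriors).
    """

    burnin: int = 5000
    n_samples: int = 200
    spacing: int = 100
    prior: ConcentrationPrior = field(default_factory=ConcentrationPrior)
    seed: int = 0
    init_dishes: int = 10
    resample_concentration: bool = True
    alpha_init: float | None = None
    checkpoint_path: str | None = None
    checkpoint_every: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.spacing <= 0 or self.burnin < 0:
            raise ValueError("spacing must be positive and burnin non-negative")
        if self.init_dishes <= 0:
            raise ValueError("init_dishes must be positive")

    @property
    def total_sweeps(self) -> int:
        return self.burnin + self.n_samples * self.spacing


@dataclass
class GibbsSample:
    """One posterior snapshot: mutation clusters as per-class count vectors."""

    chain_id: int
    sample_index: int
    # per cluster: (class-count vector length C, per-sample count vector)
    clusters: list[tuple[np.ndarray, np.ndarray]]


@dataclass
class PosteriorArchive:
    """All retained Gibbs samples across chains."""

    samples: list[GibbsSample]
    n_chains: int
    samples_per_chain: int
    spacing: int
    burnin: int
    seeds: list[int]

    def __post_init__(self) -> None:
        if len(self.samples) != self.n_chains * self.samples_per_chain:
            raise ValueError("archive size does not match chains x samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def dish_predictive(dish_class_counts, class_idx: int, C: int) -> float:
    """Posterior predictive P(class | dish) under the symmetric Dirichlet(1) base.

    ``(n_kc + 1) / (n_k + C)``; an empty or new dish (``None`` counts) gives
    the uniform 1/C.
    """
    if dish_class_counts is None:
        return 1.0 / C
    total = 0
    for v in dish_class_counts:
        if v < 0:
            raise ValueError("negative dish class count")
        total += v
    return (dish_class_counts[class_idx] + 1.0) / (total + C)


class CrfState:
    """Full franchise state: items, tables, dishes, concentrations.

    Tables are held in flat parallel lists indexed by a global table id;
    dishes are identified with root tables, and ``dish_counts[k]`` holds the
    per-class mutation counts currently ascribed to dish ``k``.
    """

    def __init__(
        self,
        catalog: MutationCatalog,
        hierarchy: HdpHierarchy,
        config: SamplerConfig,
    ) -> None:
        hierarchy.validate()
        if len(hierarchy.leaf_sample) != catalog.n_samples:
            raise ValueError("hierarchy leaves do not match catalog samples")
        self.C = catalog.scheme.C
        self.n_samples = catalog.n_samples
        self.parent = list(hierarchy.parent)
        self.cp_group = list(hierarchy.cp_group)
        self.leaf_sample = dict(hierarchy.leaf_sample)
        self.prior = config.prior
        self.resample_concentration = config.resample_concentration
        n_groups = hierarchy.n_cp_groups
        a0 = config.alpha_init if config.alpha_init is not None else config.prior.mean
        if a0 <= 0:
            raise ValueError("initial concentration must be positive")
        self.alphas = [float(a0)] * n_groups
        self.cp_nodes: list[list[int]] = [[] for _ in range(n_groups)]
        for node, g in enumerate(self.cp_group):
            self.cp_nodes[g].append(node)

        n_nodes = hierarchy.n_nodes
        # items
        item_leaf: list[int] = []
        item_class: list[int] = []
        sample_leaf = hierarchy.sample_leaf()
        counts = np.asarray(catalog.counts)
        for s in range(catalog.n_samples):
            j = sample_leaf[s]
            col = counts[:, s]
            for c in np.flatnonzero(col):
                item_leaf.extend([j] * int(col[c]))
                item_class.extend([int(c)] * int(col[c]))
        self.item_leaf = item_leaf
        self.item_class = item_class
        self.n_items = len(item_leaf)
        self.item_table = [-1] * self.n_items

        # table registry
        self.table_node: list[int] = []
        self.table_dish: list[int] = []
        self.table_count: list[int] = []
        self.table_up: list[int] = []
        self.free_tables: list[int] = []
        self.node_tables: list[list[int]] = [[] for _ in range(n_nodes)]
        self.node_customers: list[int] = [0] * n_nodes
        self.dish_counts: list[list[int]] = []
        self.dish_total: list[int] = []

        self._initialize(config.init_dishes)

    # ---------------------------------------------------------------- tables

    def _alloc_table(self, node: int, dish: int, up: int, count: int) -> int:
        """Allocate a table; ``dish == -1`` at the root creates a new dish."""
        if self.free_tables:
            t = self.free_tables.pop()
            self.table_node[t] = node
            self.table_count[t] = count
            self.table_up[t] = up
        else:
            t = len(self.table_node)
            self.table_node.append(node)
            self.table_count.append(count)
            self.table_up.append(up)
            self.table_dish.append(-1)
            self.dish_counts.append([0] * self.C)
            self.dish_total.append(0)
        self.table_dish[t] = t if (node == 0 and dish == -1) else dish
        self.node_tables[node].append(t)
        return t

    def _remove_table(self, t: int) -> None:
        node = self.table_node[t]
        self.node_tables[node].remove(t)
        self.free_tables.append(t)
        up = self.table_up[t]
        if up >= 0:
            pnode = self.table_node[up]
            cnt = self.table_count[up] - 1
            self.table_count[up] = cnt
            self.node_customers[pnode] -= 1
            if cnt == 0:
                self._remove_table(up)

    # ------------------------------------------------------------------ init

    def _initialize(self, init_dishes: int) -> None:
        """Round-robin items over dishes; one table per (node, dish) path."""
        if self.n_items == 0:
            return
        n_dishes = min(init_dishes, self.n_items)
        # dish id -> root table; (node, dish) -> table at node
        root_table: dict[int, int] = {}
        path_table: dict[tuple[int, int], int] = {}

        def table_for(node: int, d: int) -> int:
            """Table serving logical dish d at node, creating the chain up."""
            if node == 0:
                if d not in root_table:
                    root_table[d] = self._alloc_table(0, -1, -1, 0)
                return root_table[d]
            key = (node, d)
            if key not in path_table:
                up = table_for(self.parent[node], d)
                self.table_count[up] += 1
                self.node_customers[self.parent[node]] += 1
                k = self.table_dish[up]
                path_table[key] = self._alloc_table(node, k, up, 0)
            return path_table[key]

        for i in range(self.n_items):
            d = i % n_dishes
            j = self.item_leaf[i]
            t = table_for(j, d)
            self.item_table[i] = t
            self.table_count[t] += 1
            self.node_customers[j] += 1
            k = self.table_dish[t]
            self.dish_counts[k][self.item_class[i]] += 1
            self.dish_total[k] += 1

    # ------------------------------------------------------------- predictive

    def _level_predictive(self, node: int, c: int) -> float:
        """P(class c | a new draw at `node`), recursing to the base H."""
        if node < 0:
            return 1.0 / self.C
        table_dish = self.table_dish
        table_count = self.table_count
        dish_counts = self.dish_counts
        dish_total = self.dish_total
        C = self.C
        tot = 0.0
        for t in self.node_tables[node]:
            k = table_dish[t]
            tot += table_count[t] * (dish_counts[k][c] + 1.0) / (dish_total[k] + C)
        a = self.alphas[self.cp_group[node]]
        up = a * self._level_predictive(self.parent[node], c)
        return (tot + up) / (self.node_customers[node] + a)

    # --------------------------------------------------------------- seating

    def _seat_new_customer(self, node: int, c: int, rng) -> tuple[int, int]:
        """Seat a (virtual) customer of class c at `node`; return (dish, table)."""
        tables = self.node_tables[node]
        table_dish = self.table_dish
        table_count = self.table_count
        dish_counts = self.dish_counts
        dish_total = self.dish_total
        C = self.C
        masses = []
        tot = 0.0
        for t in tables:
            k = table_dish[t]
            m = table_count[t] * (dish_counts[k][c] + 1.0) / (dish_total[k] + C)
            masses.append(m)
            tot += m
        a = self.alphas[self.cp_group[node]]
        tot += a * self._level_predictive(self.parent[node], c)
        x = rng.random() * tot
        for idx, t in enumerate(tables):
            x -= masses[idx]
            if x < 0.0:
                self.table_count[t] += 1
                self.node_customers[node] += 1
                return self.table_dish[t], t
        if node == 0:
            t = self._alloc_table(0, -1, -1, 1)
            self.node_customers[0] += 1
            return self.table_dish[t], t
        k, up = self._seat_new_customer(self.parent[node], c, rng)
        t = self._alloc_table(node, k, up, 1)
        self.node_customers[node] += 1
        return k, t

    def _reseat_item(self, i: int, u: float, rng) -> None:
        item_table = self.item_table
        table_dish = self.table_dish
        table_count = self.table_count
        dish_counts = self.dish_counts
        dish_total = self.dish_total
        C = self.C
        j = self.item_leaf[i]
        c = self.item_class[i]
        # remove from current seat
        t = item_table[i]
        k = table_dish[t]
        dish_counts[k][c] -= 1
        dish_total[k] -= 1
        cnt = table_count[t] - 1
        table_count[t] = cnt
        self.node_customers[j] -= 1
        if cnt == 0:
            self._remove_table(t)
        # conditional over seats at the leaf
        tables = self.node_tables[j]
        masses = []
        tot = 0.0
        for tt in tables:
            kk = table_dish[tt]
            m = table_count[tt] * (dish_counts[kk][c] + 1.0) / (dish_total[kk] + C)
            masses.append(m)
            tot += m
        a = self.alphas[self.cp_group[j]]
        tot += a * self._level_predictive(self.parent[j], c)
        x = u * tot
        chosen = -1
        for idx, tt in enumerate(tables):
            x -= masses[idx]
            if x < 0.0:
                chosen = tt
                break
        if chosen >= 0:
            table_count[chosen] += 1
            self.node_customers[j] += 1
            k = table_dish[chosen]
            item_table[i] = chosen
        else:
            k, up = self._seat_new_customer(self.parent[j], c, rng)
            tnew = self._alloc_table(j, k, up, 1)
            self.node_customers[j] += 1
            item_table[i] = tnew
        dish_counts[k][c] += 1
        dish_total[k] += 1

    # ------------------------------------------------------------- inspection

    def dishes(self) -> list[int]:
        return sorted(self.node_tables[0])

    def item_dish_partition(self) -> tuple[tuple[int, ...], ...]:
        """Partition of item indices by dish, in canonical sorted form."""
        by_dish: dict[int, list[int]] = {}
        for i in range(self.n_items):
            k = self.table_dish[self.item_table[i]]
            by_dish.setdefault(k, []).append(i)
        blocks = [tuple(sorted(v)) for v in by_dish.values()]
        return tuple(sorted(blocks))

    def snapshot(self, chain_id: int, sample_index: int) -> GibbsSample:
        dishes = self.dishes()
        pos = {k: idx for idx, k in enumerate(dishes)}
        class_counts = np.zeros((len(dishes), self.C), dtype=np.int64)
        per_sample = np.zeros((len(dishes), self.n_samples), dtype=np.int64)
        for idx, k in enumerate(dishes):
            class_counts[idx] = self.dish_counts[k]
        for leaf, s in self.leaf_sample.items():
            for t in self.node_tables[leaf]:
                per_sample[pos[self.table_dish[t]], s] += self.table_count[t]
        return GibbsSample(
            chain_id,
            sample_index,
            [(class_counts[i], per_sample[i]) for i in range(len(dishes))],
        )

    def check_consistency(self) -> None:
        """Assert all franchise count invariants (test/debug aid)."""
        if any(a <= 0 for a in self.alphas):
            raise AssertionError("non-positive concentration parameter")
        total = sum(self.dish_total[k] for k in self.dishes())
        if total != self.n_items:
            raise AssertionError("dish totals do not sum to item count")
        # rebuild dish class counts from items
        rebuilt: dict[int, np.ndarray] = {
            k: np.zeros(self.C, dtype=np.int64) for k in self.dishes()
        }
        for i in range(self.n_items):
            t = self.item_table[i]
            rebuilt[self.table_dish[t]][self.item_class[i]] += 1
        for k in self.dishes():
            if not np.array_equal(rebuilt[k], np.asarray(self.dish_counts[k])):
                raise AssertionError(f"dish {k} class counts inconsistent")
        # table occupancy: leaf tables count items; internal tables count child tables
        occ = {t: 0 for node in range(len(self.node_tables))
               for t in self.node_tables[node]}
        for i in range(self.n_items):
            occ[self.item_table[i]] += 1
        for node in range(1, len(self.node_tables)):
            for t in self.node_tables[node]:
                occ[self.table_up[t]] += 1
        for t, n in occ.items():
            if n != self.table_count[t]:
                raise AssertionError(f"table {t} count {self.table_count[t]} != {n}")
            if n <= 0:
                raise AssertionError("empty table present")
        for node, tabs in enumerate(self.node_tables):
            if sum(self.table_count[t] for t in tabs) != self.node_customers[node]:
                raise AssertionError(f"node {node} customer count inconsistent")


def seating_distribution(
    state: CrfState, node: int, class_idx: int
) -> tuple[np.ndarray, float]:
    """Normalized seat probabilities at `node` for an item of a given class.

    Returns (probabilities over existing tables in ``state.node_tables[node]``
    order, new-table probability).  The item under consideration must already
    have been removed from the state.
    """
    masses = []
    for t in state.node_tables[node]:
        k = state.table_dish[t]
        if state.table_count[t] < 0 or state.dish_counts[k][class_idx] < 0:
            raise ValueError("inconsistent state: negative count")
        masses.append(
            state.table_count[t]
            * dish_predictive(state.dish_counts[k], class_idx, state.C)
        )
    a = state.alphas[state.cp_group[node]]
    new_mass = a * state._level_predictive(state.parent[node], class_idx)
    masses = np.asarray(masses + [new_mass], dtype=float)
    probs = masses / masses.sum()
    return probs[:-1], float(probs[-1])


def sample_concentration(
    alpha: float,
    per_node_customer_counts,
    per_node_table_counts,
    prior: ConcentrationPrior,
    rng: np.random.Generator,
) -> float:
    """Auxiliary-variable Gibbs update for a gamma-prior DP concentration.

    For each node j with n_j > 0 customers and t_j tables, draw
    w_j ~ Beta(alpha+1, n_j) and s_j ~ Bernoulli(n_j / (n_j + alpha)); then
    alpha' ~ Gamma(shape + sum t_j - sum s_j, rate = beta - sum log w_j).
    With no customers anywhere this reduces to a draw from the prior.
    """
    shape = prior.shape
    rate = prior.beta
    for n, t in zip(per_node_customer_counts, per_node_table_counts):
        if n < 0 or t < 0:
            raise ValueError("negative customer or table count")
        if n == 0:
            continue
        w = rng.beta(alpha + 1.0, n)
        s = 1.0 if rng.random() < n / (n + alpha) else 0.0
        shape += t - s
        rate -= math.log(w)
    if rate <= 0 or shape <= 0:
        raise ValueError("degenerate posterior for concentration parameter")
    return float(rng.gamma(shape, 1.0 / rate))


def gibbs_sweep(state: CrfState, rng: np.random.Generator) -> CrfState:
    """One full sweep: reseat every mutation, then resample concentrations.

    Items are visited in a freshly drawn random order each sweep.
    """
    n = state.n_items
    if n:
        order = rng.permutation(n)
        us = rng.random(n)
        reseat = state._reseat_item
        for idx in range(n):
            reseat(order[idx], us[idx], rng)
    if state.resample_concentration:
        for g, nodes in enumerate(state.cp_nodes):
            customers = [state.node_customers[j] for j in nodes]
            tables = [len(state.node_tables[j]) for j in nodes]
            state.alphas[g] = sample_concentration(
                state.alphas[g], customers, tables, state.prior, rng
            )
    return state


# ------------------------------------------------------------------- chains


def _write_checkpoint(path, payload: dict) -> None:
    blob = {"magic": "hdpsig-checkpoint", "version": _CHECKPOINT_VERSION,
            "payload": payload}
    with open(path, "wb") as fh:
        pickle.dump(blob, fh)


def _read_checkpoint(path) -> dict:
    try:
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
    except (OSError, pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if not isinstance(blob, dict) or blob.get("magic") != "hdpsig-checkpoint":
        raise CheckpointError(f"{path} is not a sampler checkpoint")
    if blob.get("version") != _CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {blob.get('version')} incompatible with "
            f"{_CHECKPOINT_VERSION}"
        )
    return blob["payload"]


def _chain_loop(
    state: CrfState,
    rng: np.random.Generator,
    config: SamplerConfig,
    chain_id: int,
    samples: list[GibbsSample],
    start_sweep: int,
    stop_after: int | None,
) -> list[GibbsSample] | None:
    """Advance a chain from `start_sweep`; returns samples when complete."""
    total = config.total_sweeps
    every = config.checkpoint_every or max(1, total // 10)
    sweep = start_sweep
    while sweep < total:
        if stop_after is not None and sweep - start_sweep >= stop_after:
            if config.checkpoint_path:
                _write_checkpoint(config.checkpoint_path, {
                    "state": state, "rng": rng, "config": config,
                    "chain_id": chain_id, "samples": samples, "sweep": sweep,
                })
            return None
        gibbs_sweep(state, rng)
        sweep += 1
        if sweep > config.burnin and (sweep - config.burnin) % config.spacing == 0:
            samples.append(state.snapshot(chain_id, len(samples)))
        if config.checkpoint_path and (sweep % every == 0 or sweep == total):
            _write_checkpoint(config.checkpoint_path, {
                "state": state, "rng": rng, "config": config,
                "chain_id": chain_id, "samples": samples, "sweep": sweep,
            })
    return samples


def run_chain(
    catalog: MutationCatalog,
    hierarchy: HdpHierarchy,
    config: SamplerConfig,
    chain_id: int = 0,
    stop_after: int | None = None,
) -> list[GibbsSample] | None:
    """Run one Gibbs chain; returns its recorded samples.

    With ``stop_after`` set, the chain halts after that many sweeps, writes a
    checkpoint (if configured) and returns None; ``resume_chain`` continues it
    bit-for-bit identically to an uninterrupted run.
    """
    if catalog.n_samples == 0:
        raise ValueError("catalog has no samples")
    state = CrfState(catalog, hierarchy, config)
    rng = np.random.default_rng(config.seed)
    return _chain_loop(state, rng, config, chain_id, [], 0, stop_after)


def resume_chain(checkpoint_path, stop_after: int | None = None):
    """Continue an interrupted chain from its checkpoint to completion."""
    payload = _read_checkpoint(checkpoint_path)
    return _chain_loop(
        payload["state"], payload["rng"], payload["config"],
        payload["chain_id"], payload["samples"], payload["sweep"], stop_after,
    )


def _one_chain(catalog, hierarchy, config, chain_id):
    cfg = replace(
        config,
        seed=config.seed + chain_id,
        checkpoint_path=(
            f"{config.checkpoint_path}.chain{chain_id}"
            if config.checkpoint_path else None
        ),
    )
    return run_chain(catalog, hierarchy, cfg, chain_id=chain_id)


def run_multi_chain(
    catalog: MutationCatalog,
    hierarchy: HdpHierarchy,
    config: SamplerConfig,
    n_chains: int = 20,
    n_jobs: int = 1,
) -> PosteriorArchive:
    """Run independent chains (chain i seeded with seed + i) and pool samples.

    The archive is identical whether chains run serially or in parallel.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_jobs != 1:
        from joblib import Parallel, delayed

        per_chain = Parallel(n_jobs=n_jobs)(
            delayed(_one_chain)(catalog, hierarchy, config, i)
            for i in range(n_chains)
        )
    else:
        per_chain = [_one_chain(catalog, hierarchy, config, i)
                     for i in range(n_chains)]
    samples = [s for chain in per_chain for s in chain]
    return PosteriorArchive(
        samples=samples,
        n_chains=n_chains,
        samples_per_chain=config.n_samples,
        spacing=config.spacing,
        burnin=config.burnin,
        seeds=[config.seed + i for i in range(n_chains)],
    )
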