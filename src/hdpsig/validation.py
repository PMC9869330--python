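"""Exact small-instance oracles for validating the Gibbs sampler.

For a handful of mutations the posterior over partitions of mutations into
dishes (signatures) can be computed by brute-force enumeration: sum, over
every seating arrangement (a set partition of mutations into tables and a
set partition of tables into dishes), the product of the two Chinese
restaurant process probabilities and the Dirichlet-multinomial likelihood of
each dish's class counts.  Comparing these exact probabilities to empirical
frequencies from long sampler runs checks the sampler end to end.

A similar grid-integration oracle gives the exact conditional density of a
DP concentration parameter given table/customer counts, for validating the
auxiliary-variable update.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import numpy as np

from .catalogs import CatalogScheme, MutationCatalog
from .hierarchy import build_hierarchy
from .sampler import ConcentrationPrior, CrfState, SamplerConfig, gibbs_sweep

__all__ = [
    "set_partitions",
    "crf_partition_probabilities",
    "empirical_partition_frequencies",
    "concentration_posterior_grid",
]


def set_partitions(items: Iterable) -> Iterator[list[list]]:
    """All set partitions of ``items`` (Bell(n) of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def _crp_logp(block_sizes: list[int], alpha: float) -> float:
    n = sum(block_sizes)
    lp = len(block_sizes) * math.log(alpha)
    lp += sum(math.lgamma(s) for s in block_sizes)
    lp -= sum(math.log(alpha + i) for i in range(n))
    return lp


def _dirichlet_multinomial_logp(counts: list[int], C: int) -> float:
    """Log-probability of one labelled sequence with these class counts under
    a symmetric Dirichlet(1) over C classes."""
    n = sum(counts)
    lp = sum(math.lgamma(c + 1) for c in counts)
    lp -= sum(math.log(C + i) for i in range(n))
    return lp


def crf_partition_probabilities(
    classes: list[int], C: int, alpha_leaf: float, alpha_root: float
) -> dict[tuple, float]:
    """Exact posterior of the mutation-to-dish partition, one leaf, fixed alphas.

    ``classes[i]`` is the mutation class of item i.  Keys are canonical
    partitions: sorted tuples of sorted item-index tuples.
    """
    probs: dict[tuple, float] = {}
    for tables in set_partitions(range(len(classes))):
        lp_tables = _crp_logp([len(b) for b in tables], alpha_leaf)
        for dish_groups in set_partitions(range(len(tables))):
            lp = lp_tables + _crp_logp(
                [len(g) for g in dish_groups], alpha_root
            )
            blocks = []
            for g in dish_groups:
                members = sorted(x for bi in g for x in tables[bi])
                counts = [0] * C
                for x in members:
                    counts[classes[x]] += 1
                lp += _dirichlet_multinomial_logp(counts, C)
                blocks.append(tuple(members))
            key = tuple(sorted(blocks))
            probs[key] = probs.get(key, 0.0) + math.exp(lp)
    z = sum(probs.values())
    return {k: v / z for k, v in probs.items()}


def empirical_partition_frequencies(
    classes: list[int],
    C: int,
    alpha: float,
    n_sweeps: int,
    seed: int,
) -> dict[tuple, float]:
    """Dish-partition frequencies over ``n_sweeps`` sweeps at fixed alpha.

    Builds a one-sample catalog over a generic C-class scheme and runs the
    sampler with concentration resampling disabled.
    """
    scheme = CatalogScheme(f"classes{C}", tuple(f"c{i}" for i in range(C)))
    counts = np.zeros((C, 1), dtype=np.int64)
    for c in classes:
        counts[c, 0] += 1
    catalog = MutationCatalog(scheme, ["S0"], counts)
    hier = build_hierarchy(catalog.sample_ids)
    cfg = SamplerConfig(
        burnin=0, n_samples=1, spacing=1, seed=seed,
        init_dishes=len(classes), resample_concentration=False,
        alpha_init=alpha,
    )
    state = CrfState(catalog, hier, cfg)
    rng = np.random.default_rng(seed)
    freq: dict[tuple, int] = {}
    for _ in range(n_sweeps):
        gibbs_sweep(state, rng)
        key = state.item_dish_partition()
        freq[key] = freq.get(key, 0) + 1
    return {k: v / n_sweeps for k, v in freq.items()}


def concentration_posterior_grid(
    n: int, t: int, prior: ConcentrationPrior, grid: np.ndarray
) -> np.ndarray:
    """Exact conditional density of alpha given n customers at t tables.

    p(alpha | t, n) is proportional to
    prior(alpha) * alpha^t * Gamma(alpha) / Gamma(alpha + n),
    evaluated on ``grid`` and normalized by trapezoidal integration.
    """
    from scipy.special import gammaln
    from scipy.stats import gamma as gamma_dist

    log_dens = (
        gamma_dist.logpdf(grid, prior.shape, scale=1.0 / prior.beta)
        + t * np.log(grid)
        + gammaln(grid)
        - gammaln(grid + n)
    )
    dens = np.exp(log_dens - log_dens.max())
    dens /= np.trapezoid(dens, grid)
    return dens
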