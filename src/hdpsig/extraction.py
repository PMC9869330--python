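"""From posterior mutation clusters to signatures.

Each retained Gibbs sample realizes every active signature as one or more
"mutation clusters" (per-class count vectors).  Across samples and chains
these realizations of the same underlying signature differ slightly, so they
are pooled and grouped by divisive hierarchical clustering (DIANA) on cosine
distance between normalized profiles.  A group's signature estimate is its
class-wise summed counts normalized to 1, and its *support* is the fraction
of Gibbs samples contributing at least one member cluster.  Groups supported
by at least ``support_cutoff`` of the Gibbs samples (default 0.9) are
retained as discovered signatures; exposures are posterior-mean attributed
mutation counts per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import CatalogScheme, MutationCatalog, SignatureSet
from .sampler import PosteriorArchive

__all__ = [
    "ClusterPool",
    "SignatureGroup",
    "ExtractionResult",
    "pool_clusters",
    "group_clusters",
    "group_support",
    "extract_signatures",
    "signature_diagnostics",
]


@dataclass
class ClusterPool:
    """All non-empty mutation clusters pooled across Gibbs samples."""

    class_counts: np.ndarray      # (C, M) integer counts, column-per-cluster
    per_sample_counts: np.ndarray  # (n_samples, M)
    provenance: list[tuple[int, int]]  # per column: (chain id, sample index)

    @property
    def n_columns(self) -> int:
        return self.class_counts.shape[1]

    @property
    def profiles(self) -> np.ndarray:
        """Column-normalized class counts."""
        return self.class_counts / self.class_counts.sum(axis=0, keepdims=True)


@dataclass
class SignatureGroup:
    """A group of similar posterior mutation clusters (one putative signature)."""

    member_indices: list[int]
    class_counts: np.ndarray       # class-wise sum over members
    per_sample_counts: np.ndarray  # sample-wise sum over members
    profile: np.ndarray            # normalized summed counts
    support: float = 0.0
    single_class: bool = False     # >0.95 of mass on one mutation class

    def __post_init__(self) -> None:
        if self.profile.sum() > 0:
            self.single_class = bool(self.profile.max() > 0.95)


@dataclass
class ExtractionResult:
    """Retained signatures, their exposures, and discarded low-support groups."""

    signatures: SignatureSet
    exposures: np.ndarray          # (K, n_samples) posterior-mean counts
    exposure_sd: np.ndarray        # (K, n_samples) spread across Gibbs samples
    retained_groups: list[SignatureGroup]
    discarded_groups: list[SignatureGroup]
    support_cutoff: float
    warning: str | None = None

    @property
    def K(self) -> int:
        return len(self.signatures.signature_ids)


def pool_clusters(archive: PosteriorArchive) -> ClusterPool:
    """One pool column per non-empty cluster per Gibbs sample, with provenance."""
    if archive.n_samples == 0:
        raise ValueError("empty posterior archive")
    cols, per_sample, prov = [], [], []
    for gs in archive.samples:
        for class_counts, sample_counts in gs.clusters:
            if class_counts.sum() == 0:
                continue
            cols.append(class_counts)
            per_sample.append(sample_counts)
            prov.append((gs.chain_id, gs.sample_index))
    if not cols:
        raise ValueError("archive contains no non-empty clusters")
    return ClusterPool(np.column_stack(cols), np.column_stack(per_sample), prov)


def _cosine_matrix(profiles: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(profiles, axis=0)
    sim = (profiles.T @ profiles) / np.outer(norms, norms)
    return np.clip(sim, -1.0, 1.0)


def _cohesion(pool: ClusterPool, members: list[int]) -> float:
    """Mean cosine similarity of member profiles to the summed-count profile."""
    summed = pool.class_counts[:, members].sum(axis=1).astype(float)
    summed /= np.linalg.norm(summed)
    prof = pool.profiles[:, members]
    prof = prof / np.linalg.norm(prof, axis=0)
    return float((prof.T @ summed).mean())


def _diana_split(dist: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One divisive step: seed a splinter with the most alienated member and
    move members closer (on average) to the splinter than to the remainder.

    Ties break toward the lowest column index for determinism.
    """
    sub = dist[np.ix_(members, members)]
    m = len(members)
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))  # np.argmax returns first max: lowest index
    in_splinter = np.zeros(m, dtype=bool)
    in_splinter[seed] = True
    while (~in_splinter).sum() > 1:
        rest = np.flatnonzero(~in_splinter)
        spl = np.flatnonzero(in_splinter)
        d_spl = sub[np.ix_(rest, spl)].mean(axis=1)
        d_rest = sub[np.ix_(rest, rest)].sum(axis=1) / (len(rest) - 1)
        diff = d_rest - d_spl
        best = int(np.argmax(diff))
        if diff[best] <= 0:
            break
        in_splinter[rest[best]] = True
    a = [members[i] for i in np.flatnonzero(in_splinter)]
    b = [members[i] for i in np.flatnonzero(~in_splinter)]
    return a, b


def group_clusters(
    pool: ClusterPool, cohesion_threshold: float = 0.90
) -> list[SignatureGroup]:
    """Group pooled clusters by DIANA on cosine distance between profiles.

    Branches of the divisive dendrogram stop splitting once their members'
    mean cosine similarity to the branch's summed-count profile reaches
    ``cohesion_threshold``; the stopped branches are the groups.
    """
    if not 0 < cohesion_threshold <= 1:
        raise ValueError("cohesion_threshold must be in (0, 1]")
    if pool.n_columns == 0:
        raise ValueError("empty cluster pool")
    dist = 1.0 - _cosine_matrix(pool.profiles)
    final: list[list[int]] = []
    work: list[list[int]] = [list(range(pool.n_columns))]
    while work:
        still: list[list[int]] = []
        for members in work:
            if len(members) == 1 or _cohesion(pool, members) >= cohesion_threshold:
                final.append(members)
            else:
                still.append(members)
        if not still:
            break
        # split the branch of largest diameter; ties -> lowest first index
        diams = [dist[np.ix_(m, m)].max() for m in still]
        pick = int(np.argmax(diams))
        a, b = _diana_split(dist, still[pick])
        work = still[:pick] + [a, b] + still[pick + 1:]
    groups = []
    for members in sorted(final, key=lambda m: m[0]):
        summed = pool.class_counts[:, members].sum(axis=1)
        groups.append(SignatureGroup(
            member_indices=members,
            class_counts=summed,
            per_sample_counts=pool.per_sample_counts[:, members].sum(axis=1),
            profile=summed / summed.sum(),
        ))
    return groups


def group_support(group: SignatureGroup, pool: ClusterPool,
                  archive: PosteriorArchive) -> float:
    """Fraction of distinct Gibbs samples contributing >= 1 member cluster."""
    contributing = {pool.provenance[i] for i in group.member_indices}
    return len(contributing) / archive.n_samples


def extract_signatures(
    pool: ClusterPool,
    archive: PosteriorArchive,
    support_cutoff: float = 0.9,
    cohesion_threshold: float = 0.90,
    scheme: CatalogScheme | None = None,
    sample_ids: list[str] | None = None,
) -> ExtractionResult:
    """Group the pool, keep groups supported by >= ``support_cutoff`` of the
    Gibbs samples, and report signatures, exposures and discarded groups.

    Exposures are posterior means over *all* Gibbs samples: a sample where
    the group has no member cluster contributes zero.
    """
    if not 0 < support_cutoff <= 1:
        raise ValueError("support_cutoff must be in (0, 1]")
    groups = group_clusters(pool, cohesion_threshold)
    for g in groups:
        g.support = group_support(g, pool, archive)
    retained = [g for g in groups if g.support >= support_cutoff]
    discarded = [g for g in groups if g.support < support_cutoff]
    # largest groups first, for stable, meaningful output ordering
    retained.sort(key=lambda g: (-g.class_counts.sum(), g.member_indices[0]))
    C, n_samples = pool.class_counts.shape[0], pool.per_sample_counts.shape[0]
    warning = None
    if not retained:
        warning = "no signature group reached the support cutoff"
    n_gibbs = archive.n_samples
    K = len(retained)
    exposures = np.zeros((K, n_samples))
    exposure_sd = np.zeros((K, n_samples))
    for k, g in enumerate(retained):
        # per-Gibbs-sample attributed counts (0 where the group is absent)
        per_gibbs: dict[tuple[int, int], np.ndarray] = {}
        for i in g.member_indices:
            key = pool.provenance[i]
            per_gibbs.setdefault(key, np.zeros(n_samples))
            per_gibbs[key] += pool.per_sample_counts[:, i]
        stack = np.zeros((n_gibbs, n_samples))
        for row, vec in enumerate(per_gibbs.values()):
            stack[row] = vec
        exposures[k] = stack.sum(axis=0) / n_gibbs
        exposure_sd[k] = stack.std(axis=0)
    if scheme is None:
        from .catalogs import CatalogScheme as _CS
        scheme = _CS(f"classes{C}", tuple(f"class{i}" for i in range(C)))
    ids = [f"hdp.{k + 1}" for k in range(K)]
    profiles = (np.column_stack([g.profile for g in retained])
                if retained else np.zeros((C, 0)))
    signatures = SignatureSet(scheme, ids, profiles)
    return ExtractionResult(
        signatures=signatures,
        exposures=exposures,
        exposure_sd=exposure_sd,
        retained_groups=retained,
        discarded_groups=discarded,
        support_cutoff=support_cutoff,
        warning=warning,
    )


def signature_diagnostics(
    result: ExtractionResult,
    catalog: MutationCatalog,
    pool: ClusterPool | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-signature attribution tables and (optionally) support traces.

    For every retained signature: each sample's attributed mutation count,
    the attributed proportion of the sample's total (0 for empty samples),
    and a flag marking the five samples with the highest proportions.  With
    the pool given, a per-signature trace of contributing clusters per Gibbs
    sample is included under key ``"<id>/trace"``.
    """
    if result.exposures.shape[1] != catalog.n_samples:
        raise ValueError("extraction result and catalog sample sets differ")
    totals = catalog.sample_totals()
    out: dict[str, pd.DataFrame] = {}
    for k, sig_id in enumerate(result.signatures.signature_ids):
        counts = result.exposures[k]
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, counts / totals, 0.0)
        order = np.argsort(-props, kind="stable")
        top5 = set(order[:5])
        df = pd.DataFrame({
            "sample": catalog.sample_ids,
            "attributed_count": counts,
            "attributed_proportion": props,
            "top5": [j in top5 for j in range(catalog.n_samples)],
        })
        out[sig_id] = df
        if pool is not None:
            g = result.retained_groups[k]
            trace: dict[tuple[int, int], int] = {}
            for i in g.member_indices:
                key = pool.provenance[i]
                trace[key] = trace.get(key, 0) + 1
            out[f"{sig_id}/trace"] = pd.DataFrame(
                [(c, s, n) for (c, s), n in sorted(trace.items())],
                columns=["chain", "gibbs_sample", "n_clusters"],
            )
    return out
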