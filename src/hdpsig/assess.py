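"""Benchmarking discovered signatures against ground truth.

Discovered and truth profiles are matched one-to-one by minimizing total
cosine distance with the Hungarian algorithm, after replacing distances
above ``max_distance`` (default 0.1) with a prohibitively large value L so
such pairs are never counted as matches.  Matched pairs are true positives;
leftover discovered profiles are false positives and leftover truth profiles
false negatives.  Performance is summarized as PPV = TP/(TP+FP),
TPR = TP/(TP+FN), the mean cosine similarity over true-positive pairs, and
their sum, the composite measure (range 0..3).

``reconstruct_signature`` decomposes a profile as a non-negative combination
of reference profiles (non-negative least squares), which is how one checks
whether an apparent false positive is really a merge of known signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .catalogs import SignatureSet

__all__ = [
    "MatchConfig",
    "MatchResult",
    "Metrics",
    "cosine_similarity",
    "match_signatures",
    "signature_metrics",
    "composite_measure",
    "reconstruct_signature",
]


@dataclass(frozen=True)
class MatchConfig:
    max_distance: float = 0.1   # cosine-distance cutoff for a valid match
    L: float = 1000.0           # substitute cost for over-cutoff pairs

    def __post_init__(self) -> None:
        if not 0 < self.max_distance < 1 < self.L:
            raise ValueError("require 0 < max_distance < 1 < L")


@dataclass
class MatchResult:
    tp_pairs: list[tuple[str, str, float]]  # (discovered, truth, cosine sim)
    fp_ids: list[str]
    fn_ids: list[str]

    @property
    def TP(self) -> int:
        return len(self.tp_pairs)

    @property
    def FP(self) -> int:
        return len(self.fp_ids)

    @property
    def FN(self) -> int:
        return len(self.fn_ids)


@dataclass
class Metrics:
    PPV: float
    TPR: float
    mean_cosine: float

    @property
    def composite(self) -> float:
        return self.PPV + self.TPR + self.mean_cosine


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def match_signatures(
    discovered: SignatureSet | None,
    truth: SignatureSet,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Hungarian matching of discovered to truth signatures.

    Over-cutoff cosine distances are replaced by L before the assignment and
    assigned pairs at cost L are discarded afterwards, so every reported
    true-positive pair has cosine distance <= ``config.max_distance``.
    An empty discovered set yields all-false-negatives.
    """
    if discovered is None or discovered.K == 0:
        return MatchResult([], [], list(truth.signature_ids))
    if discovered.scheme.name != truth.scheme.name:
        raise ValueError("discovered and truth sets use different schemes")
    nd, nt = discovered.K, truth.K
    D = np.empty((nd, nt))
    for i in range(nd):
        for j in range(nt):
            D[i, j] = 1.0 - cosine_similarity(
                discovered.profiles[:, i], truth.profiles[:, j]
            )
    cost = np.where(D > config.max_distance, config.L, D)
    # pad to square with L-cost dummies; dummy assignments are discarded
    n = max(nd, nt)
    padded = np.full((n, n), config.L)
    padded[:nd, :nt] = cost
    rows, cols = optimize.linear_sum_assignment(padded)
    tp_pairs = []
    matched_d, matched_t = set(), set()
    for i, j in zip(rows, cols):
        if i < nd and j < nt and padded[i, j] < config.L:
            tp_pairs.append((
                discovered.signature_ids[i],
                truth.signature_ids[j],
                1.0 - D[i, j],
            ))
            matched_d.add(i)
            matched_t.add(j)
    fp = [s for i, s in enumerate(discovered.signature_ids) if i not in matched_d]
    fn = [s for j, s in enumerate(truth.signature_ids) if j not in matched_t]
    return MatchResult(tp_pairs, fp, fn)


def signature_metrics(match: MatchResult) -> Metrics:
    """PPV, TPR and mean TP cosine (each 0 when its denominator is 0)."""
    tp, fp, fn = match.TP, match.FP, match.FN
    ppv = tp / (tp + fp) if tp + fp else 0.0
    tpr = tp / (tp + fn) if tp + fn else 0.0
    mean_cos = (
        sum(c for _, _, c in match.tp_pairs) / tp if tp else 0.0
    )
    return Metrics(ppv, tpr, mean_cos)


def composite_measure(ppv: float, tpr: float, mean_cosine: float) -> float:
    """The summary measure: PPV + TPR + mean cosine similarity."""
    return Metrics(ppv, tpr, mean_cosine).composite


def reconstruct_signature(
    target, reference_set: SignatureSet
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best non-negative reconstruction of a profile from reference profiles.

    Solves min_{w >= 0} ||target - R w||_2 (non-negative least squares) and
    returns (weights, reconstruction, cosine to target).
    """
    if reference_set.K == 0:
        raise ValueError("empty reference set")
    target = np.asarray(target, dtype=float)
    if target.shape != (reference_set.scheme.C,):
        raise ValueError("target length does not match the reference scheme")
    weights, _ = optimize.nnls(reference_set.profiles, target)
    recon = reference_set.profiles @ weights
    cos = cosine_similarity(target, recon) if recon.any() else 0.0
    return weights, recon, cos
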