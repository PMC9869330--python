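"""Proportional downsampling of hypermutated spectra.

Gibbs-sampling cost grows with the number of mutations, and very highly
mutated samples can also dominate the posterior.  Spectra whose total exceeds
a threshold are rescaled class-wise to approximately that total, preserving
their mutation-class proportions; spectra at or below the threshold pass
through unchanged.  The benchmarked default threshold for SBS catalogs is
3000; downsampling is off by default for indel catalogs, where it degrades
accuracy.
"""

from __future__ import annotations

import numpy as np

from .catalogs import MutationCatalog

__all__ = ["downsample_spectra", "DEFAULT_SBS_THRESHOLD"]

DEFAULT_SBS_THRESHOLD = 3000


def downsample_spectra(catalog: MutationCatalog, threshold: int) -> MutationCatalog:
    """Rescale every spectrum with total > threshold to ~threshold mutations.

    Each class count c becomes round(c * threshold / total) with half-up
    rounding, so proportions shift by at most 1/threshold per class and the
    resulting total lies within C/2 of the threshold.  Deterministic.
    """
    if int(threshold) != threshold or threshold <= 0:
        raise ValueError("threshold must be a positive integer")
    counts = catalog.counts.copy()
    totals = counts.sum(axis=0)
    for j in np.flatnonzero(totals > threshold):
        scaled = counts[:, j] * (threshold / totals[j])
        counts[:, j] = np.floor(scaled + 0.5).astype(np.int64)  # half-up
    return MutationCatalog(
        catalog.scheme, list(catalog.sample_ids), counts,
        dict(catalog.sample_groups) if catalog.sample_groups else None,
    )
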