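"""Mutation-class schemes and catalog / signature matrix I/O.

A mutational *spectrum* is the vector of mutation counts of one sample over a
fixed classification of mutations; a *catalog* stacks the spectra of many
samples into a classes x samples integer matrix.  Two canonical schemes are
supported:

* ``SBS96`` -- single-base substitutions in pyrimidine-centred trinucleotide
  context, 96 classes, COSMIC ordering (C>A, C>G, C>T, T>A, T>C, T>G blocks,
  within each block the 5' flank varies slowest, both flanks in A,C,G,T order).
* ``ID83`` -- small insertions/deletions, 83 classes, COSMIC v3 ordering
  (1-bp indels by base and homopolymer length, longer indels by length and
  repeat count, deletions at microhomology).

Signature profiles use the same row layout with per-class probabilities that
sum to one per signature column.

Files are plain tab-separated matrices: first column holds the class labels,
the header row holds sample (or signature) identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CatalogScheme",
    "MutationCatalog",
    "SignatureSet",
    "UnknownSchemeError",
    "CatalogFormatError",
    "enumerate_classes",
    "read_catalog",
    "read_signatures",
    "write_catalog",
    "write_signatures",
]


class UnknownSchemeError(ValueError):
    """Raised for a mutation-classification scheme this package does not know."""


class CatalogFormatError(ValueError):
    """Raised when a catalog or signature file violates the matrix contract."""


def _sbs96_labels() -> list[str]:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    return [
        f"{five}[{sub}]{three}"
        for sub in subs
        for five in bases
        for three in bases
    ]


def _id83_labels() -> list[str]:
    labels: list[str] = []
    # 1-bp deletions / insertions by base, homopolymer length 1..6+ coded 0..5
    for base in ("C", "T"):
        labels += [f"DEL:{base}:1:{n}" for n in range(6)]
    for base in ("C", "T"):
        labels += [f"INS:{base}:1:{n}" for n in range(6)]
    # longer deletions / insertions by length 2..5+, repeat count 0..5+
    for length in range(2, 6):
        labels += [f"DEL:repeats:{length}:{n}" for n in range(6)]
    for length in range(2, 6):
        labels += [f"INS:repeats:{length}:{n}" for n in range(6)]
    # deletions with microhomology: length 2..5+, homology 1..(length-1), 5+ capped
    for length in range(2, 6):
        top = min(length - 1, 5) if length < 5 else 5
        labels += [f"DEL:MH:{length}:{h}" for h in range(1, top + 1)]
    return labels


@dataclass(frozen=True)
class CatalogScheme:
    """A fixed, ordered mutation classification."""

    name: str
    class_labels: tuple[str, ...]

    @property
    def C(self) -> int:
        return len(self.class_labels)

    def __post_init__(self) -> None:
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("class labels must be unique")


_SCHEMES: dict[str, CatalogScheme] = {
    "SBS96": CatalogScheme("SBS96", tuple(_sbs96_labels())),
    "ID83": CatalogScheme("ID83", tuple(_id83_labels())),
}


def enumerate_classes(scheme_name: str) -> CatalogScheme:
    """Return the canonical scheme for ``scheme_name`` ('SBS96' or 'ID83')."""
    try:
        return _SCHEMES[scheme_name]
    except KeyError:
        raise UnknownSchemeError(
            f"unknown catalog scheme {scheme_name!r}; known: {sorted(_SCHEMES)}"
        ) from None


def _as_scheme(scheme: str | CatalogScheme) -> CatalogScheme:
    return enumerate_classes(scheme) if isinstance(scheme, str) else scheme


@dataclass
class MutationCatalog:
    """Integer mutation-count matrix (classes x samples) over a fixed scheme."""

    scheme: CatalogScheme
    sample_ids: list[str]
    counts: np.ndarray  # shape (C, n_samples), non-negative integers
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.scheme.C, len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({self.scheme.C}, {len(self.sample_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("mutation counts must be non-negative")
        if self.sample_groups is not None:
            missing = [s for s in self.sample_ids if s not in self.sample_groups]
            if missing:
                raise ValueError(f"samples missing from sample_groups: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureSet:
    """Signature profiles: each column a multinomial probability vector."""

    scheme: CatalogScheme
    signature_ids: list[str]
    profiles: np.ndarray  # shape (C, K)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (self.scheme.C, len(self.signature_ids)):
            raise ValueError("profile matrix shape mismatch")
        if np.any(self.profiles < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [self.signature_ids[i] for i in np.flatnonzero(
                np.abs(sums - 1.0) > 1e-9)]
            raise ValueError(f"signature columns must sum to 1: {bad}")

    @property
    def K(self) -> int:
        return len(self.signature_ids)


def _read_matrix(path, scheme: CatalogScheme) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8",
                     keep_default_na=False)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise CatalogFormatError(f"duplicate sample ids: {dups}")
    labels = df.index.astype(str)
    if labels.duplicated().any():
        dups = labels[labels.duplicated()].tolist()
        raise CatalogFormatError(f"duplicate class labels: {dups}")
    want = set(scheme.class_labels)
    have = set(labels)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        parts = []
        if missing:
            parts.append(f"missing labels: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        if extra:
            parts.append(f"unknown labels: {extra[:5]}{'...' if len(extra) > 5 else ''}")
        raise CatalogFormatError(
            f"file does not match scheme {scheme.name}: " + "; ".join(parts)
        )
    # canonical row order regardless of file order
    return df.loc[list(scheme.class_labels)]


def read_catalog(path, scheme: str | CatalogScheme) -> MutationCatalog:
    """Read a tab-separated count matrix, reordering rows to canonical order."""
    scheme = _as_scheme(scheme)
    df = _read_matrix(path, scheme)
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise CatalogFormatError(
                    f"non-integer count {raw!r} at class "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
            if val < 0:
                raise CatalogFormatError(
                    f"negative count {val} at class {df.index[i]!r}, sample {col!r}"
                )
            counts[i, j] = val
    return MutationCatalog(scheme, [str(c) for c in df.columns], counts)


def read_signatures(path, scheme: str | CatalogScheme) -> SignatureSet:
    """Read a tab-separated signature-profile matrix in canonical row order."""
    scheme = _as_scheme(scheme)
    df = _read_matrix(path, scheme).astype(float)
    return SignatureSet(scheme, [str(c) for c in df.columns], df.to_numpy())


def write_catalog(catalog: MutationCatalog, path) -> None:
    """Write a catalog as a tab-separated integer matrix in canonical order."""
    if not catalog.sample_ids:
        raise ValueError("cannot write a catalog with no samples")
    df = pd.DataFrame(
        catalog.counts.astype(np.int64),
        index=list(catalog.scheme.class_labels),
        columns=catalog.sample_ids,
    )
    df.to_csv(path, sep="\t", index_label="MutationType", encoding="utf-8")


def write_signatures(signatures: SignatureSet, path) -> None:
    """Write signature profiles with fixed precision (canonical row order)."""
    if not signatures.signature_ids:
        raise ValueError("cannot write an empty signature set")
    df = pd.DataFrame(
        signatures.profiles,
        index=list(signatures.scheme.class_labels),
        columns=signatures.signature_ids,
    )
    df.to_csv(path, sep="\t", index_label="MutationType",
              float_format="%.12g", encoding="utf-8")
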