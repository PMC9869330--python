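"""Synthetic mutation catalogs with known ground truth.

The generator mimics how real cohorts look to a signature-discovery method.
For each cancer type and signature ``s`` it carries three parameters fitted
from (or chosen like) a real exposure matrix:

* ``p_s`` -- probability that a tumor of this type carries the signature;
* ``mu_s`` -- mean mutation burden of the signature among carriers;
* ``size_s`` -- negative-binomial dispersion of that burden
  (variance = mu + mu^2/size).

A tumor's spectrum is built by drawing presence ~ Bernoulli(p_s), burden
m_s ~ NB(mu_s, size_s), spreading m_s over mutation classes via the
signature profile, and then adding per-class resampling noise
m_{s,t,d} ~ NB(m_{s,t}, d).  The noise dispersion d defaults to 30 for
SBS96 and 10 for ID83 catalogs; d = inf disables noise.  Class sums over
signatures, rounded to integers, form the spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .catalogs import CatalogScheme, MutationCatalog, SignatureSet

__all__ = [
    "NoiseModel",
    "PrevalenceModel",
    "SpectrumDraw",
    "GroundTruth",
    "POISSON_LIKE_SIZE",
    "DEFAULT_NOISE_DISPERSION",
    "fit_nb",
    "fit_prevalence_model",
    "synthesize_spectrum",
    "synthesize_dataset",
    "save_prevalence_model",
    "load_prevalence_model",
    "random_signatures",
    "example_prevalence_model",
]

# dispersion sentinel for near-Poisson burdens (too few carriers for an NB fit)
POISSON_LIKE_SIZE = 1e6

DEFAULT_NOISE_DISPERSION = {"SBS96": 30.0, "ID83": 10.0}


@dataclass(frozen=True)
class NoiseModel:
    """Per-class negative-binomial resampling noise; d = inf means none."""

    d: float

    def __post_init__(self) -> None:
        if not (self.d > 0):
            raise ValueError("noise dispersion d must be positive (or inf)")

    @classmethod
    def for_scheme(cls, scheme_name: str) -> "NoiseModel":
        return cls(DEFAULT_NOISE_DISPERSION.get(scheme_name, 30.0))


@dataclass
class PrevalenceModel:
    """Per-(cancer type, signature) presence/burden parameters."""

    params: pd.DataFrame  # columns: cancer_type, signature, p, mu, size
    n_tumors: dict[str, int]

    def __post_init__(self) -> None:
        need = {"cancer_type", "signature", "p", "mu", "size"}
        if not need <= set(self.params.columns):
            raise ValueError(f"params must have columns {sorted(need)}")
        p = self.params["p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("presence probabilities must lie in [0, 1]")
        active = self.params[self.params["p"] > 0]
        if ((active["mu"] <= 0) | (active["size"] <= 0)).any():
            raise ValueError("mu and size must be positive where p > 0")

    def rows_for_type(self, cancer_type: str) -> pd.DataFrame:
        return self.params[self.params["cancer_type"] == cancer_type]

    @property
    def cancer_types(self) -> list[str]:
        return list(self.n_tumors)


@dataclass
class SpectrumDraw:
    """Full record of one synthesized tumor."""

    burdens: dict[str, int]            # m_s per present signature
    expected: dict[str, np.ndarray]    # m_{s,t} = m_s * profile
    noisy: dict[str, np.ndarray]       # m_{s,t,d}


@dataclass
class GroundTruth:
    """What the generator actually planted in a synthetic catalog."""

    signatures: SignatureSet
    exposures: np.ndarray        # (K, n_tumors) true burdens m_s
    tumor_types: list[str]
    seed: int

    def active_signatures(self) -> SignatureSet:
        """The subset of signatures with non-zero exposure somewhere."""
        mask = self.exposures.sum(axis=1) > 0
        ids = [s for s, m in zip(self.signatures.signature_ids, mask) if m]
        return SignatureSet(
            self.signatures.scheme, ids, self.signatures.profiles[:, mask]
        )


def fit_nb(x) -> tuple[float, float]:
    """Maximum-likelihood NB fit in (mean, size) parameterization.

    The MLE of the mean is the sample mean; the size is found by 1-D
    likelihood maximization.  Underdispersed data (variance <= mean) or
    fewer than 3 observations get the Poisson-like size sentinel.
    """
    x = np.asarray(np.round(x), dtype=np.int64)
    if len(x) == 0:
        raise ValueError("cannot fit NB to no data")
    mu = float(x.mean())
    if len(x) < 3 or mu == 0 or x.var() <= mu:
        return mu, POISSON_LIKE_SIZE

    def nll(log_size: float) -> float:
        size = math.exp(log_size)
        return -stats.nbinom.logpmf(x, size, size / (size + mu)).sum()

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(1e-4), math.log(POISSON_LIKE_SIZE)),
        method="bounded",
    )
    return mu, float(math.exp(res.x))


def fit_prevalence_model(
    exposures: pd.DataFrame,
    tumor_types: list[str],
    n_tumors: dict[str, int] | None = None,
) -> PrevalenceModel:
    """Fit per-type presence probabilities and NB burden parameters.

    ``exposures`` has one row per signature and one column per tumor
    (attributed mutation counts); ``tumor_types`` gives each tumor's type.
    ``p`` is the fraction of tumors of the type with exposure > 0; ``mu`` and
    ``size`` are fitted on the positive exposures only.
    """
    if (np.asarray(exposures) < 0).any():
        raise ValueError("exposure matrix must be non-negative")
    if len(tumor_types) != exposures.shape[1]:
        raise ValueError("one tumor type per exposure column required")
    tumor_types = list(tumor_types)
    rows = []
    for ctype in dict.fromkeys(tumor_types):  # first-appearance order
        cols = [j for j, t in enumerate(tumor_types) if t == ctype]
        sub = np.asarray(exposures)[:, cols]
        for i, sig in enumerate(exposures.index):
            positive = sub[i][sub[i] > 0]
            p = len(positive) / len(cols)
            if p == 0:
                mu, size = float("nan"), float("nan")
            elif len(positive) < 3:
                mu, size = float(positive.mean()), POISSON_LIKE_SIZE
            else:
                mu, size = fit_nb(positive)
            rows.append((ctype, str(sig), p, mu, size))
    params = pd.DataFrame(
        rows, columns=["cancer_type", "signature", "p", "mu", "size"]
    )
    counts = {t: tumor_types.count(t) for t in dict.fromkeys(tumor_types)}
    return PrevalenceModel(params, n_tumors or counts)


def _nb_draw(rng: np.random.Generator, mean, size):
    """NB(mean, size) draw(s); degenerate mean 0 -> 0, size inf -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if np.isinf(size):
        return mean  # no-noise sentinel: the expectation itself
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def synthesize_spectrum(
    model_rows: pd.DataFrame,
    signatures: SignatureSet,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, SpectrumDraw]:
    """Synthesize one tumor spectrum from its cancer type's parameter rows."""
    sig_pos = {s: i for i, s in enumerate(signatures.signature_ids)}
    C = signatures.scheme.C
    burdens: dict[str, int] = {}
    expected: dict[str, np.ndarray] = {}
    noisy: dict[str, np.ndarray] = {}
    total = np.zeros(C, dtype=float)
    for row in model_rows.itertuples(index=False):
        if row.p <= 0:
            continue
        if row.signature not in sig_pos:
            raise ValueError(
                f"signature {row.signature!r} not present in the profile set"
            )
        if rng.random() >= row.p:
            continue
        m_s = int(_nb_draw(rng, row.mu, row.size))
        profile = signatures.profiles[:, sig_pos[row.signature]]
        m_st = m_s * profile
        m_std = _nb_draw(rng, m_st, noise.d)
        burdens[row.signature] = m_s
        expected[row.signature] = m_st
        noisy[row.signature] = np.asarray(m_std, dtype=float)
        total += m_std
    spectrum = np.rint(total).astype(np.int64)
    return spectrum, SpectrumDraw(burdens, expected, noisy)


def synthesize_dataset(
    model: PrevalenceModel,
    signatures: SignatureSet,
    noise: NoiseModel,
    seed: int,
) -> tuple[MutationCatalog, GroundTruth]:
    """Synthesize ``model.n_tumors[type]`` tumors per cancer type.

    Sample ids encode the cancer type ("Type::T3"); the same seed always
    yields the identical catalog and ground truth.
    """
    if not model.n_tumors or any(n <= 0 for n in model.n_tumors.values()):
        raise ValueError("every cancer type must request >= 1 tumor")
    rng = np.random.default_rng(seed)
    columns, ids, types = [], [], []
    exposures_cols = []
    K = signatures.K
    sig_pos = {s: i for i, s in enumerate(signatures.signature_ids)}
    for ctype, n in model.n_tumors.items():
        rows = model.rows_for_type(ctype)
        for i in range(n):
            spectrum, draw = synthesize_spectrum(rows, signatures, noise, rng)
            columns.append(spectrum)
            ids.append(f"{ctype}::T{i + 1}")
            types.append(ctype)
            expo = np.zeros(K)
            for s, m in draw.burdens.items():
                expo[sig_pos[s]] = m
            exposures_cols.append(expo)
    catalog = MutationCatalog(
        signatures.scheme, ids, np.column_stack(columns),
        dict(zip(ids, types)),
    )
    truth = GroundTruth(
        signatures, np.column_stack(exposures_cols), types, seed
    )
    return catalog, truth


# ------------------------------------------------------------- serialization


def save_prevalence_model(
    model: PrevalenceModel, path, noise: NoiseModel | None = None
) -> None:
    """TSV of (cancer_type, signature, p, mu, size) with a YAML '#' header."""
    header = {"n_tumors": dict(model.n_tumors)}
    if noise is not None:
        header["d"] = noise.d
    with open(path, "w", encoding="utf-8") as fh:
        for line in yaml.safe_dump(header, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        model.params.to_csv(fh, sep="\t", index=False)


def load_prevalence_model(path) -> tuple[PrevalenceModel, NoiseModel | None]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    header_lines = [l[2:] for l in lines if l.startswith("# ")]
    body = [l for l in lines if not l.startswith("#")]
    meta = yaml.safe_load("".join(header_lines)) or {}
    from io import StringIO

    params = pd.read_csv(StringIO("".join(body)), sep="\t")
    params["signature"] = params["signature"].astype(str)
    model = PrevalenceModel(params, dict(meta.get("n_tumors", {})))
    noise = NoiseModel(float(meta["d"])) if "d" in meta else None
    return model, noise


# ------------------------------------------------------------------ fixtures


def random_signatures(
    scheme: CatalogScheme,
    K: int,
    seed: int,
    max_pairwise_cosine: float = 0.6,
    concentration: float = 0.15,
) -> SignatureSet:
    """K sparse random profiles with all pairwise cosines below a bound.

    Dirichlet(concentration) draws are sparse, like real signatures; draws
    too similar to an accepted profile are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    profiles: list[np.ndarray] = []
    attempts = 0
    while len(profiles) < K:
        cand = rng.dirichlet(np.full(scheme.C, concentration))
        ok = all(
            float(cand @ p / (np.linalg.norm(cand) * np.linalg.norm(p)))
            < max_pairwise_cosine
            for p in profiles
        )
        if ok:
            profiles.append(cand)
        attempts += 1
        if attempts > 1000 * K:
            raise RuntimeError("could not generate well-separated signatures")
    return SignatureSet(
        scheme, [f"TRUTH{i + 1}" for i in range(K)], np.column_stack(profiles)
    )


def uniform_prevalence_model(
    signature_ids,
    n_tumors: int = 30,
    p: float = 0.9,
    mu: float = 200.0,
    size: float = 3.0,
    cancer_type: str = "Synth",
) -> PrevalenceModel:
    """One-type model giving every signature the same presence and burden law."""
    params = pd.DataFrame(
        [(cancer_type, s, p, mu, size) for s in signature_ids],
        columns=["cancer_type", "signature", "p", "mu", "size"],
    )
    return PrevalenceModel(params, {cancer_type: n_tumors})


def example_prevalence_model() -> PrevalenceModel:
    """A small hand-written model: 2 cancer types, 5 signatures.

    Burden scales and prevalences are in the range seen in real exposure
    matrices for moderately mutated cancer types.
    """
    rows = [
        # type       signature  p     mu    size
        ("TypeA", "TRUTH1", 1.00, 400.0, 3.0),
        ("TypeA", "TRUTH2", 0.90, 250.0, 2.0),
        ("TypeA", "TRUTH3", 0.60, 150.0, 2.5),
        ("TypeA", "TRUTH4", 0.00, float("nan"), float("nan")),
        ("TypeA", "TRUTH5", 0.30, 100.0, 1.5),
        ("TypeB", "TRUTH1", 0.95, 300.0, 2.0),
        ("TypeB", "TRUTH2", 0.00, float("nan"), float("nan")),
        ("TypeB", "TRUTH3", 0.80, 200.0, 3.0),
        ("TypeB", "TRUTH4", 0.70, 180.0, 2.0),
        ("TypeB", "TRUTH5", 0.25, 120.0, 1.5),
    ]
    params = pd.DataFrame(
        rows, columns=["cancer_type", "signature", "p", "mu", "size"]
    )
    return PrevalenceModel(params, {"TypeA": 15, "TypeB": 15})
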