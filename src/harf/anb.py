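"""Adaptive naïve Bayes (A-NB) training statistics.

Plain Gaussian naïve Bayes needs every raw sample in memory to compute the
class-conditional mean and variance of each feature.  On a phone that is a
real constraint, so A-NB instead maintains, per feature, a *chunk* of
bounded-memory running moments

    mu_N = (mu_{N-1} * (N-1) + x_N) / N          (running mean)
    v_N  = (v_{N-1} * (N-1) + x_N**2) / N        (running mean square)
    sigma2_N = v_N - mu_N**2                     (population variance)

and closes the chunk every ``chunk_size`` samples (the scheme's period
``t``).  The finalized chunk summaries ``(mu_k, sigma2_k, N_k)`` are then
combined into one class-conditional Gaussian per feature:

* ``mode="adaptive"`` — the scheme's native rule: the combined mean ``mu_m``
  is the unweighted mean of the chunk means and the combined variance
  ``mu_v`` is the unweighted mean of the chunk variances.  It is exact when
  chunks are homogeneous and slightly biased otherwise (it drops the
  between-chunk mean spread).
* ``mode="pooled"`` — exact count-weighted batch moments via the law of
  total variance; used by the oracle tests and available for users who
  prefer exactness over fidelity to the adaptive rule.

Combined variances are clamped from below by ``variance_floor`` so that a
constant feature (e.g. a proximity sensor that never moves) cannot produce
an infinite-density Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureVector

#: Minimum admissible class-conditional variance, in squared feature units.
VARIANCE_FLOOR = 1e-6

#: Default chunk period, expressed as a sample (feature-vector) count.
DEFAULT_CHUNK_SIZE = 50

COMBINE_MODES = ("adaptive", "pooled")


# ---------------------------------------------------------------------------
# chunk-level running moments
# ---------------------------------------------------------------------------

@dataclass
class ChunkStats:
    """Bounded-memory running moments of one scalar feature within a chunk.

    Attributes
    ----------
    n : int
        Number of samples absorbed so far.
    mu : float
        Running mean of the samples.
    v : float
        Running mean of the squared samples.
    """

    n: int = 0
    mu: float = 0.0
    v: float = 0.0

    @property
    def sigma2(self) -> float:
        """Population variance ``v - mu**2`` (may be ``-eps`` in fp)."""
        return self.v - self.mu * self.mu

    def add(self, x: float) -> None:
        """Absorb one sample in place; constant memory, no sample retained."""
        if not math.isfinite(x):
            raise ValueError(f"non-finite sample {x!r} rejected by ChunkStats")
        n = self.n + 1
        self.mu = (self.mu * (n - 1) + x) / n
        self.v = (self.v * (n - 1) + x * x) / n
        self.n = n

    def finalized(self) -> tuple[float, float, int]:
        """Return ``(mu, sigma2, n)`` with the variance clamped to >= 0."""
        if self.n < 1:
            raise ValueError("cannot finalize an empty chunk")
        return self.mu, max(self.sigma2, 0.0), self.n


def chunk_update(stats: ChunkStats, x: float) -> ChunkStats:
    """Functional form of :meth:`ChunkStats.add`: returns updated stats."""
    out = replace(stats)
    out.add(x)
    return out


# ---------------------------------------------------------------------------
# chunk combination
# ---------------------------------------------------------------------------

def combine_chunks(
    chunks: Sequence[tuple],
    mode: str = "adaptive",
    variance_floor: float = VARIANCE_FLOOR,
):
    """Combine finalized chunk summaries into ``(mu_m, mu_v)``.

    Parameters
    ----------
    chunks
        Sequence of ``(mu_k, sigma2_k, n_k)``.  ``mu_k``/``sigma2_k`` may be
        scalars or per-feature arrays.
    mode
        ``"adaptive"`` (unweighted mean of chunk means and of chunk
        variances) or ``"pooled"`` (exact count-weighted batch moments).
    variance_floor
        Lower clamp applied to the combined variance.

    Returns
    -------
    (mu_m, mu_v)
        Scalars for scalar chunks, arrays for vector chunks.
    """
    if mode not in COMBINE_MODES:
        raise ValueError(f"unknown combine mode {mode!r}; expected one of {COMBINE_MODES}")
    if len(chunks) == 0:
        raise ValueError("combine_chunks requires at least one chunk")
    ns = np.asarray([c[2] for c in chunks], dtype=np.int64)
    if np.any(ns < 1):
        raise ValueError("every chunk must contain at least one sample")
    mus = np.asarray([np.asarray(c[0], dtype=float) for c in chunks])
    sig2s = np.asarray([np.asarray(c[1], dtype=float) for c in chunks])
    scalar = mus.ndim == 1

    if mode == "adaptive":
        mu_m = mus.mean(axis=0)
        mu_v = sig2s.mean(axis=0)
    else:
        w = (ns / ns.sum()).reshape((-1,) + (1,) * (mus.ndim - 1))
        mu_m = (w * mus).sum(axis=0)
        # law of total variance: within-chunk + between-chunk components
        mu_v = (w * sig2s).sum(axis=0) + (w * (mus - mu_m) ** 2).sum(axis=0)
    mu_v = np.maximum(mu_v, variance_floor)
    if scalar:
        return float(mu_m), float(mu_v)
    return mu_m, mu_v


# ---------------------------------------------------------------------------
# Gaussian likelihood
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


def gaussian_log_likelihood(v, mu_m, mu_v, variance_floor: float = VARIANCE_FLOOR):
    """Log of the Gaussian density ``N(v; mu_m, mu_v)``, elementwise.

    Works on scalars or aligned arrays.  ``mu_v`` below the variance floor is
    a contract violation (a finalized model can never contain one).
    """
    v = np.asarray(v, dtype=float)
    mu_m = np.asarray(mu_m, dtype=float)
    mu_v = np.asarray(mu_v, dtype=float)
    if np.any(mu_v < variance_floor):
        raise ValueError("variance below the variance floor; model not finalized?")
    out = -0.5 * (_LOG_2PI + np.log(mu_v)) - (v - mu_m) ** 2 / (2.0 * mu_v)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# class model + training
# ---------------------------------------------------------------------------

@dataclass
class ClassModel:
    """Per-class Gaussian naïve Bayes model produced by A-NB training."""

    label: str
    prior: float
    feature_names: tuple
    mu_m: np.ndarray
    mu_v: np.ndarray
    chunk_count: int
    n_samples: int
    combine_mode: str = "adaptive"
    variance_floor: float = VARIANCE_FLOOR
    #: optional audit trail: list of (mu_vec, sigma2_vec, n) per chunk
    chunks: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.prior <= 1.0):
            raise ValueError(f"prior must lie in (0, 1], got {self.prior}")
        self.mu_m = np.asarray(self.mu_m, dtype=float)
        self.mu_v = np.asarray(self.mu_v, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if not (len(self.feature_names) == self.mu_m.size == self.mu_v.size):
            raise ValueError("feature_names, mu_m and mu_v must have equal length")

    @property
    def n_features(self) -> int:
        return self.mu_m.size

    def log_likelihood(self, values: np.ndarray) -> float:
        """Sum of per-feature Gaussian log densities (naïve independence)."""
        ll = gaussian_log_likelihood(values, self.mu_m, self.mu_v, self.variance_floor)
        return float(np.sum(ll))

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "prior": self.prior,
            "feature_names": list(self.feature_names),
            "mu_m": self.mu_m.tolist(),
            "mu_v": self.mu_v.tolist(),
            "chunk_count": self.chunk_count,
            "n_samples": self.n_samples,
            "combine_mode": self.combine_mode,
            "variance_floor": self.variance_floor,
        }
        if self.chunks is not None:
            d["chunks"] = [
                {"mu": np.asarray(m).tolist(), "sigma2": np.asarray(s).tolist(), "n": int(n)}
                for m, s, n in self.chunks
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassModel":
        chunks = None
        if "chunks" in d:
            chunks = [
                (np.asarray(c["mu"], dtype=float), np.asarray(c["sigma2"], dtype=float), int(c["n"]))
                for c in d["chunks"]
            ]
        return cls(
            label=d["label"],
            prior=float(d["prior"]),
            feature_names=tuple(d["feature_names"]),
            mu_m=np.asarray(d["mu_m"], dtype=float),
            mu_v=np.asarray(d["mu_v"], dtype=float),
            chunk_count=int(d["chunk_count"]),
            n_samples=int(d["n_samples"]),
            combine_mode=d.get("combine_mode", "adaptive"),
            variance_floor=float(d.get("variance_floor", VARIANCE_FLOOR)),
            chunks=chunks,
        )

    def __eq__(self, other) -> bool:  # array fields need explicit comparison
        if not isinstance(other, ClassModel):
            return NotImplemented
        same_chunks = (self.chunks is None) == (other.chunks is None)
        if same_chunks and self.chunks is not None:
            same_chunks = len(self.chunks) == len(other.chunks) and all(
                np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1]) and a[2] == b[2]
                for a, b in zip(self.chunks, other.chunks)
            )
        return (
            self.label == other.label
            and self.prior == other.prior
            and self.feature_names == other.feature_names
            and np.array_equal(self.mu_m, other.mu_m)
            and np.array_equal(self.mu_v, other.mu_v)
            and self.chunk_count == other.chunk_count
            and self.n_samples == other.n_samples
            and self.combine_mode == other.combine_mode
            and self.variance_floor == other.variance_floor
            and same_chunks
        )


def _vector_of(item) -> tuple[np.ndarray, tuple | None]:
    """Accept a FeatureVector or a bare 1-D array-like."""
    values = getattr(item, "values", None)
    if values is not None:
        return np.asarray(values, dtype=float), tuple(getattr(item, "names"))
    return np.asarray(item, dtype=float), None


def train_class(
    feature_stream: Iterable,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    prior: float = 1.0,
    label: str = "",
    mode: str = "adaptive",
    variance_floor: float = VARIANCE_FLOOR,
    retain_chunks: bool = False,
) -> ClassModel:
    """Train one class model from a stream of feature vectors.

    Vectors are consumed one at a time through the chunked running-moment
    update; per-feature chunks are finalized every ``chunk_size`` vectors and
    folded into running combination aggregates, so peak retained state is
    O(features) regardless of stream length.  A trailing partial chunk is
    finalized as a chunk of its own (with its actual sample count).

    ``feature_stream`` may yield :class:`~harf.features.FeatureVector`
    instances or bare 1-D arrays; all vectors must share one length (a
    mismatch is reported with the offending vector index).
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if mode not in COMBINE_MODES:
        raise ValueError(f"unknown combine mode {mode!r}; expected one of {COMBINE_MODES}")

    names: tuple | None = None
    d = -1
    n_in_chunk = 0
    mu = v = None  # per-feature running chunk moments
    j = 0
    total = 0
    # adaptive-mode aggregates
    sum_mu = sum_sig = None
    # pooled-mode aggregates (classic sufficient statistics)
    s1 = s2 = None
    audit: list | None = [] if retain_chunks else None

    def _finalize_chunk() -> None:
        nonlocal j, sum_mu, sum_sig, s1, s2, mu, v, n_in_chunk
        sig = np.maximum(v - mu * mu, 0.0)
        if sum_mu is None:
            sum_mu = mu.copy()
            sum_sig = sig.copy()
            s1 = n_in_chunk * mu
            s2 = n_in_chunk * (sig + mu * mu)
        else:
            sum_mu += mu
            sum_sig += sig
            s1 += n_in_chunk * mu
            s2 += n_in_chunk * (sig + mu * mu)
        if audit is not None:
            audit.append((mu.copy(), sig.copy(), n_in_chunk))
        j += 1
        mu = np.zeros(d)
        v = np.zeros(d)
        n_in_chunk = 0

    for idx, item in enumerate(feature_stream):
        values, item_names = _vector_of(item)
        if d < 0:
            d = values.size
            names = item_names
            mu = np.zeros(d)
            v = np.zeros(d)
        elif values.size != d:
            raise ValueError(
                f"feature vector {idx} has length {values.size}, expected {d}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite value in feature vector {idx}")
        n = n_in_chunk + 1
        mu = (mu * (n - 1) + values) / n
        v = (v * (n - 1) + values * values) / n
        n_in_chunk = n
        total += 1
        if n_in_chunk == chunk_size:
            _finalize_chunk()

    if total == 0:
        raise ValueError("train_class requires at least one feature vector")
    if n_in_chunk > 0:
        _finalize_chunk()

    if mode == "adaptive":
        mu_m = sum_mu / j
        mu_v = sum_sig / j
    else:
        mu_m = s1 / total
        mu_v = s2 / total - mu_m * mu_m
    mu_v = np.maximum(mu_v, variance_floor)

    if names is None:
        names = tuple(f"f{i}" for i in range(d))
    return ClassModel(
        label=label,
        prior=prior,
        feature_names=names,
        mu_m=mu_m,
        mu_v=mu_v,
        chunk_count=j,
        n_samples=total,
        combine_mode=mode,
        variance_floor=variance_floor,
        chunks=audit,
    )
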