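"""Posterior scoring and argmax classification over A-NB class models.

All probability arithmetic is done in log space: with a dozen features and
small class-conditional variances the linear-space product of densities
underflows a double.  The evidence term is handled by log-sum-exp
normalization over the candidate set only, so restricting candidates (as the
hierarchical router does) renormalizes the surviving posteriors without
changing their relative order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .anb import ClassModel
from .errors import CompatibilityError

#: absolute slack (scaled by score magnitude) for declaring a score tie
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class PosteriorScore:
    """One candidate's unnormalized log score and normalized posterior."""

    label: str
    log_score: float
    posterior: float


@dataclass(frozen=True)
class Classification:
    label: str
    scores: tuple
    tie: bool


def _select(models: Sequence[ClassModel], candidates) -> list[ClassModel]:
    by_label = {m.label: m for m in models}
    if len(by_label) != len(models):
        raise ValueError("duplicate class labels in model set")
    if candidates is None:
        return list(models)
    missing = [c for c in candidates if c not in by_label]
    if missing:
        raise CompatibilityError(f"candidate labels not covered by models: {missing}")
    return [by_label[c] for c in candidates]


def score(models: Sequence[ClassModel], fv, candidates=None) -> list[PosteriorScore]:
    """Posterior scores of ``fv`` for each candidate class.

    ``fv`` is a :class:`~harf.features.FeatureVector`; its feature names and
    order must match every model's schema exactly, otherwise a
    :class:`~harf.errors.CompatibilityError` is raised.  Log scores are
    ``log p(C) + sum_i log N(v_i; mu_m_i, mu_v_i)``; posteriors are the
    log-sum-exp normalization over the candidate set and sum to one.
    """
    chosen = _select(models, candidates)
    if not chosen:
        raise ValueError("no candidate models to score")
    names = tuple(fv.names)
    values = np.asarray(fv.values, dtype=float)
    logs = np.empty(len(chosen))
    for i, m in enumerate(chosen):
        if m.feature_names != names:
            raise CompatibilityError(
                f"feature order mismatch for model {m.label!r}: "
                f"model schema {m.feature_names}, vector {names}"
            )
        logs[i] = math.log(m.prior) + m.log_likelihood(values)
    posts = np.exp(logs - logsumexp(logs))
    return [
        PosteriorScore(m.label, float(ls), float(p))
        for m, ls, p in zip(chosen, logs, posts)
    ]


def classify(models: Sequence[ClassModel], fv, candidates=None) -> Classification:
    """Argmax-posterior classification with a deterministic tie-break.

    Scores within a relative tolerance of the maximum are treated as tied;
    the lexicographically smallest tied label wins and the tie is flagged.
    """
    scores = score(models, fv, candidates)
    best = max(s.log_score for s in scores)
    tol = _TIE_RTOL * max(1.0, abs(best))
    tied = sorted(s.label for s in scores if s.log_score >= best - tol)
    return Classification(label=tied[0], scores=tuple(scores), tie=len(tied) > 1)
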