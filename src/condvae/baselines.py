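"""Reference rankers: Null frequency model, ranking kNN, likelihood ranking.

* **Null** — query-independent ranking of complete training conditions by
  frequency; records with unknown temperature or pressure are ignored.
* **kNN** — conditions of the nearest training transformations in Euclidean
  descriptor space, deduplicated keeping the best rank.
* **LRM** (likelihood ranking model) — a one-hidden-layer network (2000 ReLU
  units, sigmoid outputs) predicts each condition bit's probability; every
  enumerable condition vector is scored with the independent-Bernoulli
  likelihood Π pᵢ^{bᵢ}(1−pᵢ)^{1−bᵢ} and the top-k kept. Scoring requires
  enumerating the whole condition space, so the ranker refuses schemes whose
  space exceeds a configurable cap — exactly the scalability wall that
  motivates generative condition prediction.
"""

from __future__ import annotations

import numpy as np

from .conditions import (ConditionScheme, ConditionVector, SchemeError,
                         enumerate_space, space_size, vector_from_bits)
from .inference import RankedConditionList
from .model import FNet

__all__ = ["null_rank", "knn_rank", "LikelihoodRankingModel",
           "lrm_train_and_rank", "LRM_DEFAULT_CAP"]

LRM_DEFAULT_CAP = 200_000


def _complete(vec: ConditionVector) -> bool:
    return not (vec.temp_unknown or vec.pressure_unknown)


def null_rank(train_conditions, query_id: str = "") -> RankedConditionList:
    """Global frequency ranking over complete training condition vectors."""
    complete = [v for v in train_conditions if _complete(v)]
    if not complete:
        raise ValueError("no complete (known T and P) condition records in training data")
    from collections import Counter

    counts = Counter(complete)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].sort_key()))
    return RankedConditionList(entries=ordered, query_id=query_id,
                               total_draws=len(complete))


def knn_rank(query_x: np.ndarray, train_x: np.ndarray, train_conditions,
             query_id: str = "") -> RankedConditionList:
    """Rank training conditions by ascending Euclidean distance to the query.

    Distance ties keep training order; duplicate conditions are deduplicated
    at their best (smallest-distance) rank. The per-entry count is the number
    of training reactions sharing the condition (informational only; ranking
    is by distance).
    """
    train_x = np.asarray(train_x, dtype=np.float64)
    query_x = np.asarray(query_x, dtype=np.float64).reshape(-1)
    conditions = list(train_conditions)
    if len(conditions) != len(train_x):
        raise ValueError("train_x and train_conditions lengths differ")
    if train_x.shape[1] != query_x.shape[0]:
        raise ValueError(f"descriptor dim mismatch: {train_x.shape[1]} vs {query_x.shape[0]}")
    d = np.linalg.norm(train_x - query_x, axis=1)
    order = np.argsort(d, kind="stable")
    seen: dict[ConditionVector, int] = {}
    ranked: list[ConditionVector] = []
    for i in order:
        vec = conditions[i]
        if vec in seen:
            seen[vec] += 1
        else:
            seen[vec] = 1
            ranked.append(vec)
    return RankedConditionList(entries=[(v, seen[v]) for v in ranked],
                               query_id=query_id, total_draws=len(conditions))


class LikelihoodRankingModel:
    """Per-bit Bernoulli predictor + exhaustive likelihood ranking."""

    def __init__(self, scheme: ConditionScheme, descriptor_dim: int,
                 hidden: int = 2000, space_cap: int = LRM_DEFAULT_CAP,
                 seed: int = 0):
        n = space_size(scheme)
        if n > space_cap:
            raise SchemeError(
                f"condition space of {n} elements exceeds the enumeration cap "
                f"({space_cap}); likelihood ranking requires exhaustive "
                f"enumeration and does not scale to this scheme")
        self.scheme = scheme
        self.space_cap = space_cap
        self.net = FNet(descriptor_dim, scheme.n_bits, hidden,
                        np.random.default_rng(seed))
        self.fitted = False

    def fit(self, X: np.ndarray, Y: np.ndarray, epochs: int = 50,
            batch_size: int = 128, seed: int = 0) -> "LikelihoodRankingModel":
        self.net.pretrain(np.asarray(X, dtype=np.float64),
                          np.asarray(Y, dtype=np.float64), epochs, batch_size,
                          np.random.default_rng(seed))
        self.fitted = True
        return self

    def bit_probabilities(self, query_x: np.ndarray) -> np.ndarray:
        return self.net.predict(np.asarray(query_x, dtype=np.float64)
                                .reshape(1, -1))[0]

    def rank(self, query_x: np.ndarray, k_max: int = 100,
             query_id: str = "") -> RankedConditionList:
        """Score every enumerable condition by Bernoulli log-likelihood.

        Vectors violating record validity (acid+base together under a
        forbidding scheme) are skipped — they can never match a recorded
        condition. Ties are broken by canonical bitstring order.
        """
        p = np.clip(self.bit_probabilities(query_x), 1e-12, 1 - 1e-12)
        log_p, log_q = np.log(p), np.log(1.0 - p)
        scored = []
        for bits in enumerate_space(self.scheme, limit=self.space_cap):
            try:
                vec = vector_from_bits(bits, self.scheme)
            except SchemeError:
                continue
            b = np.asarray(bits)
            ll = float(np.where(b == 1, log_p, log_q).sum())
            scored.append((ll, vec))
        scored.sort(key=lambda t: (-t[0], t[1].sort_key()))
        entries = [(vec, 1) for _, vec in scored[:k_max]]
        return RankedConditionList(entries=entries, query_id=query_id,
                                   total_draws=len(scored))


def lrm_train_and_rank(train_x, train_bits, scheme: ConditionScheme,
                       query_x, k_max: int = 100, epochs: int = 50,
                       hidden: int = 2000, space_cap: int = LRM_DEFAULT_CAP,
                       seed: int = 0, query_id: str = "") -> RankedConditionList:
    """Fit a likelihood ranking model and rank the space for one query."""
    train_x = np.asarray(train_x, dtype=np.float64)
    model = LikelihoodRankingModel(scheme, train_x.shape[1], hidden=hidden,
                                   space_cap=space_cap, seed=seed)
    model.fit(train_x, np.asarray(train_bits, dtype=np.float64),
              epochs=epochs, seed=seed)
    return model.rank(query_x, k_max=k_max, query_id=query_id)
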